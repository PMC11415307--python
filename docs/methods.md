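# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `gjflux`, in the spirit of a package methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Kinetic models and units

All models assume well-mixed compartments, Fickian flux proportional to the
concentration difference with a single lumped permeability, and fluorescence
linear in concentration (`F = f·C + f0`; tracer self-quenching only appears
in the millimolar range, far above working concentrations). Units are fixed
package-wide: seconds, picoliters, µM, pl/s for permeabilities, so
first-order rates `P/Vol` are in 1/s — cell-scale magnitudes for which a
typical junctional transfer rate is ~1e−3 /s.

The efflux ODE is taken as `dC_in/dt = (α − P·C_in)/Vol_in` with α in
amount per time (µM·pl/s). Grouping α inside the volume division is the only
convention under which the exponential solution (steady state `α/P`) and the
linearized slope `f(α − C_in(t0)P)/Vol_in` are exact; the package adopts it
throughout. `P = 0` is handled by explicit limit forms (linear ramp in α,
constant otherwise), never by dividing by zero.

The shipped forward models are closed-form. Fixed-step fourth-order
Runge–Kutta integration appears in two places only: as the independent
oracle in the tests and acceptance script (step 0.05 s or finer; the local
truncation error at rates ≤ 1e−2 /s is many orders below the 1e−6 checked
tolerance), and inside the transfer-trace generator, where the recipient is
integrated against a time-varying donor for which no closed form holds.

## Linear-window selection for efflux slopes

The efflux assay fits `F(t) = k·t + c` over the phase of the recording that
changes linearly. No published rule defines that phase, so the package's
selector is its own design, built around a lack-of-fit test rather than r²:

* A window qualifies when its OLS residual SD is at most `lof_tolerance`
  (default 1.3) times a model-free noise estimate — the median absolute
  second difference of the whole trace divided by `0.6745·sqrt(6)`, which is
  robust to smooth trends and isolated jumps. This accepts flat,
  noise-dominated windows (where a slope is statistically indistinguishable
  from zero and r² is meaningless) and rejects windows long enough for
  curvature or a changepoint kink to emerge from the noise.
* If no window passes — essentially noise-free but curved traces, where the
  second-difference noise estimate collapses to ~0 — windows with
  `r² ≥ r2_threshold` (default 0.98) qualify instead.
* Within the winning class the longest window is returned; ties break
  toward the earliest start (the phase right after solution exchange).
  User-declared intervals (blocker applications) are excluded outright.

r² alone is a poor linearity criterion here because it conflates slope
magnitude with fit quality: slow efflux plus imaging noise never reaches
r² = 0.98 at any window length even when the trace is exactly linear plus
noise, while a window straddling a plateau-to-decline changepoint can keep
r² ≥ 0.98 despite gross lack of fit. Both failure modes motivated the
ordering above.

The windowed OLS slope estimates the average derivative over the window,
not the tangent at its start; over a window spanning a fraction `x` of the
decay time constant the attenuation is ≈ `e^{−x/2}`. At the study
conditions emulated by the generators (rates ~1e−4 /s, 30-min recordings)
this attenuation is below 10% and nearly uniform across a 10-fold
permeability range, so group ratios are preserved; at rates ≳1e−3 /s the
trace leaves the linear regime within minutes and a windowed slope is not
the appropriate summary.

## Donor steady state and transfer-rate estimators

The donor plateau time `t_ss` is the earliest sample at which the OLS slope
over the trailing 120 s implies a relative change below 1%/min of the
background-subtracted level, confirmed by the next evaluable sample also
qualifying. The confirmation suppresses spurious early hits: at 2% noise
and 30-s sampling the noise-induced slope SD over a 120-s window is itself
≈1.3%/min, so single-window qualification is close to a coin flip near the
plateau.

The exponential route fits
`F2(t)/F2(t_ss) = R − (R − 1)·e^{−rate (t − t_ss)}` to the
background-subtracted recipient ratio by unweighted nonlinear least squares
(unweighted because no residual-weighting scheme is given for the assay;
multiplicative noise makes late residuals slightly larger, which the
Monte-Carlo recovery results absorb). Both `R` and `rate` are fitted, but
`R` is bounded within a factor (default 1.05) of its direct measurement —
donor plateau mean over recipient level at `t_ss` — because the two
parameters are jointly unidentifiable whenever `rate·(t_end − t_ss) ≲ 1:`
left free, the ratio absorbs noise and drags the rate by factors of two or
more. The bound corresponds to roughly two standard errors of the measured
ratio at 2% intensity noise and is configurable. Fitting uses multi-start
over rate scalings (1×, 0.3×, 3× a log-linear initial estimate) with
best-SSE selection.

The discretized route inverts the transfer ODE step by step,

    rate_i = [F2(t_i) − F2(t_i−1)] / { ½[(F1−F2)(t_i) + (F1−F2)(t_i−1)] · Δt },

on background-subtracted values, with the donor linearly interpolated onto
the recipient grid when timestamps differ. Per-step estimates with
`t_i ≥ 120 s` are averaged arithmetically (early steps are excluded because
the estimates vary strongly before the ~2-min mark); steps with zero
averaged driving term are excluded and flagged, and an all-excluded trace
is an estimation error. Because this route uses the measured donor rather
than assuming it constant, it is unbiased under residual donor loading,
whereas the exponential route assumes a constant donor and inherits a bias
of a few percent when fitting starts before full equilibration.

## Electrophysiology

Slope conductance at `V_m = 0` is the local regression slope of current on
voltage within ±5 mV of zero (chord conductance is singular at 0 mV); it is
exact on affine records for any window. Amplitude histograms are fitted as
Gaussian mixtures by EM (scikit-learn, k-means++ initialization, 10 seeded
restarts); components are sorted by mean, adjacent pairs closer than twice
their pooled SD are flagged unresolved, and unitary conductance is the mean
adjacent level spacing divided by |V_hold| (so it is invariant to leak
subtraction, which only shifts the closed level to 0 pA). Channel count and
open probability are never separated; only the product `n·P_o = g/γ` is
used, with explicit nS→pS conversion.

## Synthetic data

Generators emulate the assay designs: calcein efflux sampled every 10 s for
30 min; donor/recipient LY transfer sampled every 30 s for 15 min with the
donor loading as a single exponential toward a 2 mM pipette concentration
(τ = 80 s, putting the plateau near 350 s) and optional blocker intervals
during which the junctional rate is set to zero (instantaneous, complete,
fully reversible — an idealization of pharmacological block; intervals are
half-open `[start, end)`); two-state Markov gating records with exponential
dwell times for amplitude-histogram analysis. Noise is multiplicative
Gaussian on fluorescence (default CV 2%) and additive Gaussian on current;
σ = 0 reduces every generator to its closed form exactly. All generators
are deterministic under a fixed seed, cohort child seeds are spawned from
the master seed, and ground truth travels in trace metadata and a manifest
table.

Cohort defaults place permeable genotypes at `P_γ = 2e−5` pl/s per open
channel with `n_po` ~ lognormal(mean 10, CV 0.3) and volumes ~
lognormal(2 pl, CV 0.25), i.e. cell rates around 1e−4 /s — a moderate
calcein decline over 30 min, matching the qualitative appearance of real
efflux recordings and keeping traces in the quasi-linear regime the slope
fit assumes. Low-permeability genotypes are 10× lower. What the generators
do not emulate: photobleaching (optional in principle, off by default),
spatial diffusion within cells, shot noise and point-spread effects,
baseline drift in current records, and blocker pharmacokinetics. Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to every artifact of real microscopy.

## Statistics

Group comparison runs Shapiro–Wilk per group at the comparison alpha; any
failing group routes the whole comparison to Kruskal–Wallis with Dunn's
post hoc test (one failing group suffices — the conservative reading),
otherwise one-way ANOVA with Tukey's HSD. Dunn's z statistics are computed
in-package (mean pooled ranks, tie-corrected variance) because no installed
library provides them; p-values are Holm-adjusted by default (the
adjustment is configurable and recorded in the report). Pairwise contrasts
use scipy's Mann–Whitney implementation, which is exact for small tie-free
samples. Problem sizes in the calibration checks (1,000 null replicates of
four groups of 10; exhaustive enumeration at n ≤ 8) were chosen to make the
checks sharp while completing in minutes on one CPU.

## Known limitations

* The exponential transfer fit assumes a constant donor after `t_ss`;
  residual loading biases it low by a few percent. Prefer the discretized
  route when the donor has not clearly plateaued.
* The windowed efflux slope systematically attenuates the tangent slope on
  curved traces (see above); comparisons across groups with very different
  kinetics should use the rate estimators instead.
* Hemichannel normalization uses genotype-mean `n·P_o` from a separate
  electrophysiology sample (efflux cells are not patched), so per-cell
  expression variability propagates into the normalized-value spread.
* The amplitude-histogram fit assumes a known number of levels; model
  selection over component counts is out of scope.
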