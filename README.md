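# gjflux

Quantitative analysis of fluorescent-tracer flux through gap-junction (GJ)
channels and undocked connexin hemichannels: kinetic two-compartment models,
estimators that turn time-lapse fluorescence and patch-clamp conductance
measurements into single-channel permeability metrics, seeded synthetic-data
generators with known ground truth, and the group statistics used to
contrast connexin variants.

## The problem

Dye-transfer and dye-efflux assays report how permeable connexin channels
are to tracers such as Lucifer Yellow (LY, via patch pipette into a donor
cell of a coupled pair) and calcein (loaded as calcein-AM, effluxing through
hemichannels opened by divalent-cation-free solution). Raw fluorescence
changes conflate permeability with the number of open channels, so the
analysis combines flux kinetics with electrophysiology: macroscopic
conductance `g` divided by unitary conductance `γ` gives the open-channel
count `n·P_o`, and permeability metrics normalized by `g/γ` become
per-channel quantities that can be compared across genotypes.

## The model

Flux between two well-mixed compartments follows Fick's law,

    dC1/dt = P (C2 − C1) / Vol1,   dC2/dt = P (C1 − C2) / Vol2,

with total permeability `P` (pl/s) and volumes in pl; fluorescence is linear
in concentration, `F = f·C + f0`. Two reductions matter in practice:

* **Hemichannel efflux** (bath = infinite sink, optional zero-order
  production α from residual ester cleavage):
  `dC_in/dt = (α − P·C_in)/Vol_in`, whose solution is
  `C_in(t) = α/P − (α/P − C_in(0)) e^{−(P/Vol_in) t}`. Over the linear phase
  of a recording, `F_in(t) ≈ k·t + c` with
  `k = f (α − C_in(t0) P)/Vol_in`: a more negative slope means higher
  permeability. Dividing `k` by the genotype-mean `g/γ` yields the
  per-hemichannel metric.
* **GJ transfer** (donor clamped at `C1` after equilibrating with the
  pipette): `C2(t) = C1 − (C1 − C2(t0)) e^{−(P_j/Vol_2)(t − t0)}`. The rate
  constant `P_j/Vol_2` (1/s) is estimated either by fitting the saturating
  exponential of the background-subtracted recipient ratio, or by a
  finite-difference inversion of the ODE averaged after the 2-minute mark
  (usable when the donor never plateaus). Dividing by `g_j/γ_j` measured in
  the same pair yields `P_j,γ/Vol_2`, the single-channel metric.

Unitary conductance is estimated from low-expression recordings by fitting
mixtures of normal distributions to all-point amplitude histograms; the
adjacent level spacing over the holding voltage gives `γ`, and closed-level
means are used for leak subtraction.

Group comparisons follow a normality-gated decision tree: Shapiro–Wilk per
group, then one-way ANOVA with Tukey's HSD if every group passes, otherwise
Kruskal–Wallis with Dunn's post hoc test (Holm-adjusted); simple pairwise
contrasts use the Mann–Whitney rank-sum test.

## Worked example

```python
import gjflux as gj

# a synthetic two-genotype efflux study with 10-fold per-channel difference
spec = gj.CohortSpec(genotypes=(
    gj.GenotypeSpec("hi", perm_per_channel=2e-5),   # pl/s per open channel
    gj.GenotypeSpec("lo", perm_per_channel=2e-6),
), seed=3)
results = gj.analyze_cohort(gj.generate_cohort(spec))
print(results.group_summary[["genotype", "normalized_k_mean", "n_po_mean"]])
print("permeability omnibus p:", results.permeability_report.omnibus_p)
print("n*Po omnibus p:", results.n_po_report.omnibus_p)
```

prints

```
  genotype  normalized_k_mean  n_po_mean
0       hi          -0.005576   8.629725
1       lo          -0.000516   9.778007
permeability omnibus p: 2.5949607666275996e-21
n*Po omnibus p: 0.39808826586585666
```

i.e. the fitted efflux slope per open hemichannel is ~10.8× more negative
for the high-permeability genotype (generating truth: 10×), the difference
is highly significant, while the open-channel counts — equal by design —
are statistically indistinguishable.

The same analysis runs from files via the CLI:

```sh
gjflux simulate --out demo/ --seed 3 --genotypes hi:2e-5,lo:2e-6 --cells 10
gjflux fit-efflux --traces demo/efflux_traces.csv --background 100
gjflux ephys --ramp demo/ramp_hi_ephys00.csv
gjflux compare --estimates results/per_cell_estimates.csv --groupby genotype
```

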