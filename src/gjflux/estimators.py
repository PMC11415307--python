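"""Permeability estimators operating on fluorescence traces.

Three routes from a time-lapse recording to a permeability metric:

* hemichannel efflux — a straight line is fitted to the linear phase of the
  decline in fluorescence; the slope ``k`` (a.u./s) is proportional to
  ``-f * C_in(t0) * P / Vol_in`` and, divided by the mean number of open
  hemichannels ``g/gamma``, yields a per-channel metric;
* gap-junctional transfer, exponential route — once the donor cell has
  equilibrated with the pipette, the recipient's background-subtracted
  fluorescence ratio follows a saturating exponential whose rate constant is
  ``P_j / Vol_2`` (1/s);
* gap-junctional transfer, discretized route — a finite-difference inversion
  of the transfer ODE usable when the donor never plateaus; per-step rate
  estimates are averaged once they stabilize (after ~2 min by default).

The fit-shaped operations are exposed as scikit-learn style estimator
classes (``fit`` + trailing-underscore attributes); the module-level
functions with the classic names are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .electrophys import ChannelPopulation
from .exceptions import EstimationError
from .flux_model import relative_fluorescence
from .traces import FluorescenceTrace

__all__ = [
    "FluorescenceTrace",
    "LinearFitResult",
    "RateEstimate",
    "NormalizedPermeability",
    "EffluxSlopeEstimator",
    "TransferRateEstimator",
    "select_linear_window",
    "fit_efflux_slope",
    "detect_donor_steady_state",
    "fit_recipient_exponential",
    "estimate_rate_discretized",
    "normalize_hemichannel",
    "normalize_gj",
]


@dataclass(frozen=True)
class LinearFitResult:
    """Ordinary-least-squares line fitted to a trace window.

    slope_k (a.u./s) is the efflux metric: more negative means faster net
    efflux, hence higher total permeability.
    """

    slope_k: float
    intercept_c: float
    window: tuple[float, float]
    r_squared: float
    slope_stderr: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError("window end must exceed window start")


@dataclass(frozen=True)
class RateEstimate:
    """A fitted first-order transfer rate ``P_j / Vol_2`` (1/s)."""

    rate: float
    method: str  # "exponential_fit" | "discretized"
    window: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")
        if self.method not in ("exponential_fit", "discretized"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class NormalizedPermeability:
    """A permeability metric divided by the open-channel count g/gamma.

    For hemichannel efflux the value is ``k / (g/gamma)`` (a.u./s per open
    channel; the sign carries direction). For gap junctions it is
    ``(P_j/Vol_2) / (g_j/gamma_j)`` — per-channel permeability over recipient
    volume, in 1/s per channel.
    """

    value: float
    n_po_used: float
    source: str  # "per-cell" | "group-mean"

    def __post_init__(self) -> None:
        if self.n_po_used <= 0:
            raise ValueError("n_po_used must be positive")


# ---------------------------------------------------------------------------
# linear-window machinery


def _robust_noise_sd(values: np.ndarray) -> float:
    """Model-free noise SD estimate from second differences.

    For a smooth trend plus iid noise of SD sigma, the second difference has
    SD sqrt(6)*sigma; the median absolute value is robust to the trend and to
    occasional jumps (e.g. solution exchange).
    """
    if values.size < 4:
        return 0.0
    d2 = np.diff(values, n=2)
    return float(np.median(np.abs(d2)) / (0.6744897501960817 * np.sqrt(6.0)))


def _window_scan(t: np.ndarray, y: np.ndarray, min_points: int):
    """All-windows OLS statistics via prefix sums.

    Yields, per start index i, arrays over end index j >= i+min_points-1 of
    (n, slope, sse, sst). O(n^2) windows but O(n) numpy work per start.
    """
    n = t.size
    ct = np.concatenate([[0.0], np.cumsum(t)])
    ct2 = np.concatenate([[0.0], np.cumsum(t * t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cy2 = np.concatenate([[0.0], np.cumsum(y * y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    for i in range(0, n - min_points + 1):
        j = np.arange(i + min_points - 1, n)
        m = (j - i + 1).astype(float)
        st = ct[j + 1] - ct[i]
        st2 = ct2[j + 1] - ct2[i]
        sy = cy[j + 1] - cy[i]
        sy2 = cy2[j + 1] - cy2[i]
        sty = cty[j + 1] - cty[i]
        stt = st2 - st * st / m
        syy = sy2 - sy * sy / m
        sty_c = sty - st * sy / m
        slope = sty_c / stt
        sse = np.maximum(syy - slope * sty_c, 0.0)
        yield i, j, m, slope, sse, syy


def _contiguous_runs(t: np.ndarray, exclude: Sequence[tuple[float, float]]):
    """Index runs of samples falling outside every excluded interval."""
    keep = np.ones(t.size, dtype=bool)
    for a, b in exclude:
        keep &= ~((t >= a) & (t <= b))
    runs = []
    start = None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, t.size - 1))
    return runs


def select_linear_window(
    trace: FluorescenceTrace,
    min_points: int = 12,
    r2_threshold: float = 0.98,
    lof_tolerance: float = 1.3,
    exclude: Sequence[tuple[float, float]] = (),
) -> tuple[float, float]:
    """Longest contiguous window over which the trace is adequately linear.

    Two qualification classes, in order of preference:

    * no lack of fit — a window qualifies when its linear-fit residual SD
      does not exceed ``lof_tolerance`` times a model-free noise estimate
      taken from second differences of the whole trace. This is the actual
      linearity test: it rejects windows long enough for curvature (or a
      changepoint kink) to emerge from the noise, and it accepts windows
      whose slope is small relative to the noise — r^2 is meaningless there,
      including the flat slope-indistinguishable-from-0 case, which is
      accepted on exactly these residual-variance grounds.
    * resolved r^2 — when no window passes the residual test (e.g. an
      essentially noise-free but curved trace, where the second-difference
      noise estimate collapses), a window qualifies if its OLS coefficient
      of determination satisfies ``r^2 >= r2_threshold``.

    Within the winning class the longest window is returned, ties broken
    toward the earliest start (the phase right after solution exchange).
    Samples inside ``exclude`` intervals (e.g. blocker applications) are
    never part of a window.
    """
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    t, y = trace.times, trace.values
    if t.size < min_points:
        raise ValueError(
            f"trace has {t.size} samples, fewer than min_points={min_points}"
        )
    sigma = _robust_noise_sd(y)
    scale = max(np.ptp(y), np.max(np.abs(y)), 1.0)
    abs_tol = 1e-9 * scale  # exact lines qualify despite rounding

    best_r2 = None  # (length_in_samples, -start_index, t_start, t_end)
    best_lof = None
    n_scanned = 0
    for i0, i1 in _contiguous_runs(t, exclude):
        if i1 - i0 + 1 < min_points:
            continue
        ts, ys = t[i0 : i1 + 1], y[i0 : i1 + 1]
        for i, j, m, slope, sse, syy in _window_scan(ts, ys, min_points):
            n_scanned += int(j.size)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(syy > 0, 1.0 - sse / np.where(syy > 0, syy, 1.0), 1.0)
            resid_sd = np.sqrt(sse / np.maximum(m - 2.0, 1.0))
            for ok, which in (
                (r2 >= r2_threshold, "r2"),
                (resid_sd <= lof_tolerance * sigma + abs_tol, "lof"),
            ):
                if not ok.any():
                    continue
                lengths = np.where(ok, m, -1.0)
                k = int(np.argmax(lengths))
                if lengths[k] <= 0:
                    continue
                cand = (int(lengths[k]), -(i0 + i), ts[i], ts[j[k]])
                if which == "r2":
                    if best_r2 is None or cand[:2] > best_r2[:2]:
                        best_r2 = cand
                elif best_lof is None or cand[:2] > best_lof[:2]:
                    best_lof = cand
    best = best_lof if best_lof is not None else best_r2
    if best is None:
        raise EstimationError(
            "no window satisfies the linearity criteria",
            diagnostics={
                "n_windows_scanned": n_scanned,
                "noise_sd": sigma,
                "min_points": min_points,
                "r2_threshold": r2_threshold,
                "lof_tolerance": lof_tolerance,
            },
        )
    return float(best[2]), float(best[3])


class EffluxSlopeEstimator(BaseEstimator):
    """Fit the linear-phase slope of a calcein-efflux recording.

    Parameters
    ----------
    window : explicit (t_start, t_end) in seconds, or None to select the
        longest adequately linear window automatically.
    min_points, r2_threshold, lof_tolerance : window-selection controls, see
        :func:`select_linear_window`.
    exclude : time intervals (s) never included in a window (blocker
        applications, solution exchanges).

    Attributes (after ``fit``)
    --------------------------
    slope_k_ : fitted slope (a.u./s); negative = net efflux.
    intercept_c_ : intercept (a.u.).
    window_ : (t_start, t_end) actually used.
    r_squared_, slope_stderr_, n_points_ : fit diagnostics.
    result_ : the assembled :class:`LinearFitResult`.
    """

    def __init__(
        self,
        window: tuple[float, float] | None = None,
        min_points: int = 12,
        r2_threshold: float = 0.98,
        lof_tolerance: float = 1.3,
        exclude: Sequence[tuple[float, float]] = (),
    ):
        self.window = window
        self.min_points = min_points
        self.r2_threshold = r2_threshold
        self.lof_tolerance = lof_tolerance
        self.exclude = exclude

    def fit(self, trace: FluorescenceTrace, y=None) -> "EffluxSlopeEstimator":
        if self.window is None:
            win = select_linear_window(
                trace,
                min_points=self.min_points,
                r2_threshold=self.r2_threshold,
                lof_tolerance=self.lof_tolerance,
                exclude=self.exclude,
            )
        else:
            win = (float(self.window[0]), float(self.window[1]))
        mask = (trace.times >= win[0]) & (trace.times <= win[1])
        t, v = trace.times[mask], trace.values[mask]
        if t.size < 3:
            raise ValueError("window must contain at least 3 samples")
        if np.ptp(t) == 0:
            raise ValueError("degenerate window: constant time")
        res = stats.linregress(t, v)
        self.slope_k_ = float(res.slope)
        self.intercept_c_ = float(res.intercept)
        self.window_ = (float(t[0]), float(t[-1]))
        self.r_squared_ = float(res.rvalue**2)
        self.slope_stderr_ = float(res.stderr)
        self.n_points_ = int(t.size)
        self.result_ = LinearFitResult(
            slope_k=self.slope_k_,
            intercept_c=self.intercept_c_,
            window=self.window_,
            r_squared=self.r_squared_,
            slope_stderr=self.slope_stderr_,
            n_points=self.n_points_,
        )
        return self

    def predict(self, times) -> np.ndarray:
        return self.slope_k_ * np.asarray(times, dtype=float) + self.intercept_c_


def fit_efflux_slope(
    trace: FluorescenceTrace, window: tuple[float, float]
) -> LinearFitResult:
    """OLS line over the given window; see :class:`EffluxSlopeEstimator`."""
    return EffluxSlopeEstimator(window=window).fit(trace).result_


# ---------------------------------------------------------------------------
# donor steady state


def detect_donor_steady_state(
    donor: FluorescenceTrace,
    trailing_window: float = 120.0,
    rel_change_per_min: float = 0.01,
    level_fraction: float = 0.98,
) -> float | None:
    """Earliest time after which the donor trace stays at plateau.

    A sample time t qualifies when two conditions hold over the window
    [t, t + trailing_window]:

    * flatness — the OLS slope implies a relative change not significantly
      above ``rel_change_per_min`` per minute of the background-subtracted
      level (significance judged at 1.645 standard errors of the fitted
      slope: at realistic imaging noise the slope's sampling error is
      comparable to the threshold, so a point-estimate comparison would flip
      randomly near the plateau);
    * equilibration — the window-mean level has reached at least
      ``level_fraction`` of the plateau, estimated as the mean over the
      final ``2 * trailing_window`` of the trace. This is the direct reading
      of "the concentrations equilibrated": without it, noisy flat-looking
      stretches during late loading qualify a few percent below plateau.

    The plateau onset is the earliest qualifying time confirmed by the next
    evaluable sample also qualifying (the confirmation suppresses spurious
    early hits; the last evaluable sample needs no confirmation). Returns
    None when the plateau is never reached.
    """
    if donor.times[-1] - donor.times[0] < 300.0:
        raise ValueError("donor trace must span at least 5 minutes")
    t = donor.times
    v = donor.corrected
    plateau = float(np.mean(v[t >= t[-1] - 2.0 * trailing_window]))
    ok: list[bool | None] = []
    for i in range(t.size):
        mask = (t >= t[i]) & (t <= t[i] + trailing_window)
        if mask.sum() < 3 or t[-1] < t[i] + trailing_window:
            ok.append(None)  # not evaluable
            continue
        res = stats.linregress(t[mask], v[mask])
        level = max(abs(v[i]), 1e-12)
        stderr = res.stderr if np.isfinite(res.stderr) else 0.0
        slope_lo = max(abs(res.slope) - 1.645 * stderr, 0.0)
        flat = slope_lo * 60.0 / level < rel_change_per_min
        at_level = plateau <= 0 or float(np.mean(v[mask])) >= level_fraction * plateau
        ok.append(flat and at_level)
    evaluable = [i for i, o in enumerate(ok) if o is not None]
    if not evaluable:
        return None
    for pos, i in enumerate(evaluable):
        if not ok[i]:
            continue
        nxt = evaluable[pos + 1] if pos + 1 < len(evaluable) else None
        if nxt is None or ok[nxt]:
            return float(t[i])
    return None


# ---------------------------------------------------------------------------
# transfer-rate estimation


class TransferRateEstimator(BaseEstimator):
    """Estimate ``P_j / Vol_2`` from a donor/recipient trace pair.

    method="exponential_fit": nonlinear least squares of the saturating
    exponential to the background-subtracted recipient ratio for t >= t_ss
    (the donor plateau time, detected automatically when ``t_ss`` is None).
    The amplitude ratio C1/C2(t_ss) is co-fitted, initialized from the
    directly measured donor-plateau / recipient fluorescence ratio and
    bounded within ``ratio_bound_factor`` of it (roughly two standard errors
    of that measurement at 2% intensity noise; left unconstrained, the
    two-parameter fit is unidentifiable on short post-plateau windows). The
    rate is the parameter of interest.

    method="discretized": finite-difference inversion of the transfer ODE at
    every sampling step, with the driving term F1 - F2 averaged over the
    step (trapezoid); per-step estimates with t_i >= ``t_min`` are averaged
    arithmetically. Works without a donor plateau.

    Attributes (after ``fit``): ``rate_`` (1/s), ``window_``,
    ``amplitude_ratio_`` (exponential route), ``diagnostics_``, ``result_``.
    """

    def __init__(
        self,
        method: str = "exponential_fit",
        t_ss: float | None = None,
        t_min: float = 120.0,
        trailing_window: float = 120.0,
        rel_change_per_min: float = 0.01,
        level_fraction: float = 0.98,
        ratio_bound_factor: float = 1.05,
    ):
        self.method = method
        self.t_ss = t_ss
        self.t_min = t_min
        self.trailing_window = trailing_window
        self.rel_change_per_min = rel_change_per_min
        self.level_fraction = level_fraction
        self.ratio_bound_factor = ratio_bound_factor

    def fit(
        self, donor: FluorescenceTrace, recipient: FluorescenceTrace
    ) -> "TransferRateEstimator":
        if self.method == "exponential_fit":
            self._fit_exponential(donor, recipient)
        elif self.method == "discretized":
            self._fit_discretized(donor, recipient)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    # -- exponential route

    def _fit_exponential(self, donor, recipient):
        t_ss = self.t_ss
        if t_ss is None:
            t_ss = detect_donor_steady_state(
                donor,
                trailing_window=self.trailing_window,
                rel_change_per_min=self.rel_change_per_min,
                level_fraction=self.level_fraction,
            )
            if t_ss is None:
                raise EstimationError(
                    "donor never reached steady state; use method='discretized'"
                )
        mask = recipient.times >= t_ss
        if mask.sum() < 4:
            raise EstimationError("too few recipient samples after donor plateau")
        t = recipient.times[mask]
        f2 = recipient.corrected[mask]
        if f2[0] <= 0:
            raise ValueError(
                "recipient at or below background at t_ss; ratio undefined"
            )
        y = f2 / f2[0]
        donor_plateau = float(np.mean(donor.corrected[donor.times >= t_ss]))
        ratio0 = donor_plateau / f2[0]
        if ratio0 <= 1.0 + 1e-6 or abs(y[-1] - 1.0) < 1e-9:
            raise EstimationError(
                "recipient already equilibrated with donor; rate unidentifiable",
                diagnostics={"amplitude_ratio_init": ratio0},
            )
        # rate initialization: with ratio pinned at the measured donor/recipient
        # ratio, (ratio0 - y)/(ratio0 - 1) should decay as exp(-rate (t - t0));
        # a log-linear regression over the positive part gives a robust start
        z = (ratio0 - y) / (ratio0 - 1.0)
        pos = z > 1e-3
        if pos.sum() >= 3:
            rate0 = max(-stats.linregress(t[pos] - t[0], np.log(z[pos])).slope, 1e-6)
        else:
            rate0 = 1.0 / max(t[-1] - t[0], 1.0)

        def model(tt, ratio, rate):
            return relative_fluorescence(ratio, rate, t[0], tt)

        # The ratio is directly observed (donor plateau over recipient level),
        # so the co-fit refines it only within a generous factor of the
        # measurement; letting it roam freely makes (ratio, rate) jointly
        # unidentifiable whenever rate*(t_end - t0) is small.
        lo = max(1.0 + 1e-9, ratio0 / self.ratio_bound_factor)
        hi = max(ratio0 * self.ratio_bound_factor, lo * (1.0 + 1e-9))

        def try_fit(p0):
            p0 = [float(np.clip(p0[0], lo, hi)), max(p0[1], 0.0)]
            return optimize.curve_fit(
                model,
                t,
                y,
                p0=p0,
                bounds=([lo, 0.0], [hi, np.inf]),
                maxfev=20000,
            )

        # multi-start over rate scalings; the (ratio, rate) landscape has a
        # flat valley when rate*(t_end - t0) is small, so keep the best SSE
        best = None
        for scale in (1.0, 0.3, 3.0):
            try:
                popt, pcov = try_fit([max(ratio0, 1.0 + 1e-3), rate0 * scale])
            except RuntimeError:
                continue
            sse = float(np.sum((y - model(t, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
        if best is None:
            raise EstimationError(
                "exponential fit did not converge",
                diagnostics={"p0": [ratio0, rate0]},
            )
        _, popt, pcov = best
        resid = y - model(t, *popt)
        self.amplitude_ratio_ = float(popt[0])
        self.rate_ = float(popt[1])
        self.window_ = (float(t[0]), float(t[-1]))
        self.diagnostics_ = {
            "t_ss": float(t_ss),
            "amplitude_ratio": self.amplitude_ratio_,
            "rate_stderr": float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan,
            "residual_rms": float(np.sqrt(np.mean(resid**2))),
            "n_points": int(t.size),
        }
        self.result_ = RateEstimate(
            rate=self.rate_,
            method="exponential_fit",
            window=self.window_,
            diagnostics=self.diagnostics_,
        )

    # -- discretized route

    def _fit_discretized(self, donor, recipient):
        t = recipient.times
        f2 = recipient.corrected
        # donor resampled onto the recipient grid if the timestamps differ
        if donor.times.shape == t.shape and np.allclose(donor.times, t):
            f1 = donor.corrected
        else:
            f1 = np.interp(t, donor.times, donor.corrected)
        num = np.diff(f2)
        drive = 0.5 * ((f1[1:] - f2[1:]) + (f1[:-1] - f2[:-1]))
        dt = np.diff(t)
        denom = drive * dt
        t_i = t[1:]
        retained = t_i >= self.t_min
        degenerate = retained & (denom == 0.0)
        usable = retained & (denom != 0.0)
        if not usable.any():
            raise EstimationError(
                "no usable steps: all retained steps have zero driving term",
                diagnostics={
                    "n_retained": int(retained.sum()),
                    "n_degenerate": int(degenerate.sum()),
                },
            )
        per_step = np.full(t_i.shape, np.nan)
        per_step[usable] = num[usable] / denom[usable]
        self.rate_ = float(np.mean(per_step[usable]))
        self.window_ = (float(t_i[usable][0]), float(t_i[usable][-1]))
        self.diagnostics_ = {
            "t_min": float(self.t_min),
            "per_step_times": t_i[retained],
            "per_step_estimates": per_step[retained],
            "n_excluded_zero_drive": int(degenerate.sum()),
            "per_step_sd": float(np.std(per_step[usable])),
        }
        self.result_ = RateEstimate(
            rate=self.rate_,
            method="discretized",
            window=self.window_,
            diagnostics=self.diagnostics_,
        )


def fit_recipient_exponential(
    donor: FluorescenceTrace,
    recipient: FluorescenceTrace,
    t_ss: float | None = None,
) -> RateEstimate:
    """Exponential-route transfer rate; see :class:`TransferRateEstimator`."""
    return (
        TransferRateEstimator(method="exponential_fit", t_ss=t_ss)
        .fit(donor, recipient)
        .result_
    )


def estimate_rate_discretized(
    donor: FluorescenceTrace,
    recipient: FluorescenceTrace,
    t_min: float = 120.0,
) -> RateEstimate:
    """Discretized-route transfer rate; see :class:`TransferRateEstimator`."""
    return (
        TransferRateEstimator(method="discretized", t_min=t_min)
        .fit(donor, recipient)
        .result_
    )


# ---------------------------------------------------------------------------
# per-channel normalization


def normalize_hemichannel(
    fit: LinearFitResult,
    population: ChannelPopulation,
    source: str = "group-mean",
) -> NormalizedPermeability:
    """Efflux slope divided by the open-hemichannel count g/gamma.

    The efflux cells themselves are not patched, so ``population`` normally
    carries the genotype-group mean conductance from separate
    electrophysiological recordings (source="group-mean").
    """
    if population.n_po <= 0:
        raise ValueError("population n_po must be positive")
    return NormalizedPermeability(
        value=fit.slope_k / population.n_po,
        n_po_used=population.n_po,
        source=source,
    )


def normalize_gj(
    rate: RateEstimate | float, gj_ns: float, gamma_j_ps: float
) -> NormalizedPermeability:
    """Transfer rate divided by the junctional channel count g_j/gamma_j.

    ``g_j`` (nS) is measured in the same cell pair at the end of the
    recording; ``gamma_j`` (pS) is the unitary junctional conductance. The
    result is the single-channel permeability over recipient volume,
    P_j,gamma / Vol_2, in 1/s per channel.
    """
    if gj_ns <= 0:
        raise ValueError("gj must be positive")
    if gamma_j_ps <= 0:
        raise ValueError("gamma_j must be positive")
    r = rate.rate if isinstance(rate, RateEstimate) else float(rate)
    n_channels = gj_ns * 1e3 / gamma_j_ps
    return NormalizedPermeability(
        value=r / n_channels, n_po_used=n_channels, source="per-cell"
    )
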