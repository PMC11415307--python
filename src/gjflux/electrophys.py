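"""Conductance and open-channel-count estimation from patch-clamp records.

The permeability metrics need a channel count to normalize by. Macroscopic
membrane (or junctional) conductance ``g`` comes from the local slope of the
I-V relation at V_m = 0 during a voltage ramp; unitary conductance ``gamma``
comes from the spacing of current levels in low-expression recordings,
resolved by fitting a mixture of normal distributions to the all-point
amplitude histogram. Their ratio ``g/gamma`` equals the number of channels
times the open probability, n*P_o — the two are never separated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .exceptions import EstimationError

__all__ = [
    "RampRecord",
    "UnitaryRecord",
    "ChannelPopulation",
    "AmplitudeMixture",
    "AmplitudeHistogramModel",
    "conductance_at_zero",
    "leak_subtract",
    "fit_amplitude_histogram",
    "unitary_conductance",
    "estimate_channel_count",
]


@dataclass
class RampRecord:
    """Whole-cell current response to a slow voltage ramp.

    times (s), voltage (mV), current (pA); the ramp must cross 0 mV for the
    conductance readout to be defined.
    """

    times: np.ndarray
    voltage: np.ndarray
    current: np.ndarray
    label: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if not (self.times.shape == self.voltage.shape == self.current.shape):
            raise ValueError("times, voltage and current must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("samples must be time-ordered")
        if self.voltage.min() > 0 or self.voltage.max() < 0:
            raise ValueError("the voltage ramp must cover 0 mV")


@dataclass
class UnitaryRecord:
    """Constant-voltage current record showing discrete gating events.

    times (s), current (pA), holding voltage (mV, non-zero for conductance
    conversion).
    """

    times: np.ndarray
    current: np.ndarray
    holding_mv: float
    label: str = ""
    genotype: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have equal length")
        if self.holding_mv == 0:
            raise ValueError("holding voltage must be non-zero")


@dataclass(frozen=True)
class ChannelPopulation:
    """Macroscopic + unitary conductance for one genotype or cell.

    g (nS), gamma (pS); ``n_po = g/gamma`` (unit-consistent) is the number of
    channels times open probability.
    """

    g_ns: float
    gamma_ps: float
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.g_ns < 0:
            raise ValueError("g must be non-negative")
        if self.gamma_ps <= 0:
            raise ValueError("gamma must be positive")

    @property
    def n_po(self) -> float:
        return self.g_ns * 1e3 / self.gamma_ps


@dataclass(frozen=True)
class AmplitudeMixture:
    """Gaussian mixture fitted to an all-point amplitude histogram.

    Components are sorted by mean; the lowest-mean component is taken as the
    closed level. ``resolved`` is False when any adjacent pair of means is
    closer than twice their pooled SD (the levels cannot be told apart).
    """

    means_pa: tuple[float, ...]
    sds_pa: tuple[float, ...]
    weights: tuple[float, ...]
    log_likelihood: float
    resolved: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(np.diff(self.means_pa) < 0):
            raise ValueError("component means must be sorted")

    @property
    def closed_mean_pa(self) -> float:
        return self.means_pa[0]

    @property
    def level_spacings_pa(self) -> tuple[float, ...]:
        return tuple(np.diff(self.means_pa))


def conductance_at_zero(record: RampRecord, window_mv: float = 5.0) -> float:
    """Slope conductance dI/dV (nS) at V_m = 0 from a voltage ramp.

    Local linear regression of current on voltage over |V| <= window_mv;
    pA/mV equals nS. Exact for ohmic records regardless of window width.
    """
    mask = np.abs(record.voltage) <= window_mv
    if mask.sum() < 10:
        raise ValueError(
            f"only {int(mask.sum())} samples within +/-{window_mv} mV; need >= 10"
        )
    v, i = record.voltage[mask], record.current[mask]
    if np.ptp(v) == 0:
        raise ValueError("no voltage excursion within the window")
    return float(stats.linregress(v, i).slope)


class AmplitudeHistogramModel(BaseEstimator):
    """Mixture-of-normals model of an all-point amplitude histogram.

    Maximum-likelihood EM fit (k-means initialization, ``n_init`` restarts,
    seeded) of ``n_components`` Gaussian levels to the raw current samples.

    Attributes (after ``fit``): ``means_`` (pA, sorted), ``sds_`` (pA),
    ``weights_``, ``log_likelihood_``, ``resolved_``, ``mixture_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_init: int = 10,
        random_state: int = 0,
        max_iter: int = 500,
        min_samples: int = 5000,
    ):
        self.n_components = n_components
        self.n_init = n_init
        self.random_state = random_state
        self.max_iter = max_iter
        self.min_samples = min_samples

    def fit(self, record: "UnitaryRecord | np.ndarray", y=None):
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        x = record.current if isinstance(record, UnitaryRecord) else np.asarray(record)
        x = np.asarray(x, dtype=float).ravel()
        if x.size < self.min_samples:
            raise ValueError(
                f"record has {x.size} samples; need >= {self.min_samples} for a "
                "stable all-point histogram fit"
            )
        gm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            n_init=self.n_init,
            max_iter=self.max_iter,
            init_params="k-means++",
            random_state=self.random_state,
        ).fit(x.reshape(-1, 1))
        if not gm.converged_:
            raise EstimationError("EM did not converge for the amplitude histogram")
        order = np.argsort(gm.means_.ravel())
        means = gm.means_.ravel()[order]
        sds = np.sqrt(gm.covariances_.reshape(-1)[order])
        weights = gm.weights_[order]
        pooled = np.sqrt(0.5 * (sds[:-1] ** 2 + sds[1:] ** 2))
        resolved = bool(np.all(np.diff(means) >= 2.0 * pooled))
        self.means_ = means
        self.sds_ = sds
        self.weights_ = weights
        self.log_likelihood_ = float(gm.score(x.reshape(-1, 1)) * x.size)
        self.resolved_ = resolved
        self.mixture_ = AmplitudeMixture(
            means_pa=tuple(means),
            sds_pa=tuple(sds),
            weights=tuple(weights / weights.sum()),
            log_likelihood=self.log_likelihood_,
            resolved=resolved,
        )
        return self

    def predict_density(self, grid: np.ndarray) -> np.ndarray:
        """Mixture probability density over a current grid (pA)."""
        g = np.asarray(grid, dtype=float)
        out = np.zeros_like(g)
        for m, s, w in zip(self.means_, self.sds_, self.weights_):
            out += w * stats.norm.pdf(g, m, s)
        return out


def fit_amplitude_histogram(
    record: UnitaryRecord | np.ndarray,
    n_components: int = 2,
    random_state: int = 0,
) -> AmplitudeMixture:
    """Fit a mixture of normals to an all-point amplitude histogram."""
    return (
        AmplitudeHistogramModel(n_components=n_components, random_state=random_state)
        .fit(record)
        .mixture_
    )


def leak_subtract(
    record: UnitaryRecord, mixture: AmplitudeMixture | None = None
) -> UnitaryRecord:
    """Shift a unitary record so the closed-event level sits at 0 pA.

    The closed level is the lowest-magnitude-mean mixture component (fitted
    here with two components when no mixture is supplied). Idempotent: a
    record whose closed level is already at zero is returned unchanged up to
    fit precision.
    """
    if mixture is None:
        mixture = fit_amplitude_histogram(record)
    # level nearest zero on the open-direction axis: for negative holding
    # voltages open levels are more negative, so "lowest amplitude" means
    # smallest |mean - baseline|; the closed level is the component whose
    # mean has the smallest absolute current magnitude
    closed = min(mixture.means_pa, key=abs)
    return UnitaryRecord(
        times=record.times,
        current=record.current - closed,
        holding_mv=record.holding_mv,
        label=record.label,
        genotype=record.genotype,
        meta={**record.meta, "leak_subtracted_pa": closed},
    )


def unitary_conductance(mixture: AmplitudeMixture, holding_mv: float) -> float:
    """Unitary conductance gamma (pS) from fitted current-level spacing.

    gamma = (mean adjacent level spacing in pA) / |V_hold in mV| * 1e3.
    Multi-channel records contribute several equally spaced levels; the mean
    adjacent spacing is used.
    """
    if holding_mv == 0:
        raise ValueError("holding voltage must be non-zero")
    if not mixture.resolved or len(mixture.means_pa) < 2:
        raise EstimationError(
            "mixture components unresolved; unitary conductance undefined"
        )
    spacing = float(np.mean(np.abs(mixture.level_spacings_pa)))
    return spacing / abs(holding_mv) * 1e3


def estimate_channel_count(g_ns: float, gamma_ps: float) -> float:
    """Open-channel count n*P_o = g/gamma, with nS/pS conversion."""
    if gamma_ps <= 0:
        raise ValueError("gamma must be positive")
    if g_ns < 0:
        raise ValueError("g must be non-negative")
    return g_ns * 1e3 / gamma_ps
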