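"""Closed-form two-compartment models of fluorescent-tracer flux.

Dye movement between two well-mixed compartments (cell/bath for hemichannel
efflux, donor/recipient cell for gap-junctional transfer) follows Fick's law:
the molar flux is proportional to the concentration difference, with a single
lumped permeability ``P`` (pl/s) and compartment volumes in picoliters,

    dC1/dt = P * (C2 - C1) / Vol1
    dC2/dt = P * (C1 - C2) / Vol2

Fluorescence is assumed linear in concentration, ``F = f * C + f0`` (dye
self-quenching only matters in the millimolar range, far above the working
concentrations), so every model here has a direct fluorescence counterpart.

Units throughout: seconds, picoliters, micromolar, pl/s for permeabilities;
first-order rates ``P/Vol`` are therefore in 1/s.

For calcein efflux the bath is an effectively infinite sink (C_out = 0) and a
small zero-order production term ``alpha`` (µM·pl/s) absorbs residual
esterase cleavage of the AM ester:

    dC_in/dt = (alpha - P * C_in) / Vol_in

with solution ``C_in(t) = alpha/P - (alpha/P - C_in(0)) * exp(-(P/Vol_in) t)``
and linearization ``F(t) ≈ F(t0) + f * (alpha - C_in(t0) P) / Vol_in * (t-t0)``
— the slope actually fitted from time-lapse recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoCompartmentParams",
    "EffluxParams",
    "FluorescenceCalibration",
    "simulate_two_compartment",
    "efflux_solution",
    "efflux_linear_approx",
    "recipient_solution",
    "relative_fluorescence",
]


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Parameters of the symmetric two-compartment exchange model.

    vol1, vol2 : compartment volumes (pl); perm : total permeability P (pl/s);
    c1_0, c2_0 : initial concentrations (µM).
    """

    vol1: float
    vol2: float
    perm: float
    c1_0: float
    c2_0: float

    def __post_init__(self) -> None:
        if self.vol1 <= 0 or self.vol2 <= 0:
            raise ValueError("compartment volumes must be positive")
        if self.perm < 0:
            raise ValueError("permeability must be non-negative")
        if self.c1_0 < 0 or self.c2_0 < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class EffluxParams:
    """Parameters of the one-compartment efflux model with production.

    vol_in : cell volume (pl); perm : total permeability P (pl/s);
    c_in_0 : initial intracellular concentration (µM);
    alpha : zero-order production (µM·pl/s, amount per unit time).
    """

    vol_in: float
    perm: float
    c_in_0: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.vol_in <= 0:
            raise ValueError("vol_in must be positive")
        if self.perm < 0:
            raise ValueError("permeability must be non-negative")
        if self.c_in_0 < 0:
            raise ValueError("c_in_0 must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass(frozen=True)
class FluorescenceCalibration:
    """Linear fluorescence/concentration map ``F = f * C + f0``.

    f : fluorescence per unit concentration (a.u./µM); f0 : background (a.u.).
    """

    f: float
    f0: float = 0.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("f must be positive")
        if self.f0 < 0:
            raise ValueError("f0 must be non-negative")

    def to_fluorescence(self, conc: np.ndarray | float) -> np.ndarray | float:
        return self.f * np.asarray(conc, dtype=float) + self.f0

    def to_concentration(self, fluor: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(fluor, dtype=float) - self.f0) / self.f


def simulate_two_compartment(
    params: TwoCompartmentParams, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration traces C1(t), C2(t) of the closed two-compartment system.

    The total amount ``Vol1*C1 + Vol2*C2`` is conserved; both compartments
    relax exponentially toward the common equilibrium concentration with rate
    ``P * (1/Vol1 + 1/Vol2)``.

    Parameters
    ----------
    times : strictly increasing sample times (s), starting at 0.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if t[0] != 0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    amount = params.vol1 * params.c1_0 + params.vol2 * params.c2_0
    c_eq = amount / (params.vol1 + params.vol2)
    rate = params.perm * (1.0 / params.vol1 + 1.0 / params.vol2)
    decay = np.exp(-rate * t)
    c1 = c_eq + (params.c1_0 - c_eq) * decay
    c2 = c_eq + (params.c2_0 - c_eq) * decay
    return c1, c2


def efflux_solution(params: EffluxParams, t: np.ndarray | float) -> np.ndarray | float:
    """Intracellular concentration C_in(t) under efflux with production.

    ``C_in(t) = alpha/P - (alpha/P - C_in(0)) * exp(-(P/Vol_in) t)`` for P > 0;
    the P = 0 limit is the linear ramp ``C_in(0) + (alpha/Vol_in) t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if params.perm == 0.0:
        out = params.c_in_0 + (params.alpha / params.vol_in) * t_arr
    else:
        c_ss = params.alpha / params.perm
        out = c_ss - (c_ss - params.c_in_0) * np.exp(
            -(params.perm / params.vol_in) * t_arr
        )
    return out if np.ndim(t) else float(out)


def efflux_derivative(params: EffluxParams, t: float) -> float:
    """Exact dC_in/dt at time t: ``(alpha - P * C_in(t)) / Vol_in``."""
    c_t = efflux_solution(params, t)
    return (params.alpha - params.perm * c_t) / params.vol_in


def efflux_linear_approx(
    params: EffluxParams,
    calib: FluorescenceCalibration,
    t0: float,
    t: np.ndarray | float,
) -> np.ndarray | float:
    """First-order (tangent-line) fluorescence around t0.

    ``F(t) = F(t0) + f * (alpha - C_in(t0) P) / Vol_in * (t - t0)`` — the
    linear regime exploited when fitting a slope to early efflux recordings.
    Valid while ``(t - t0) << Vol_in / P``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < t0):
        raise ValueError("t must be >= t0")
    f_t0 = calib.to_fluorescence(efflux_solution(params, t0))
    slope = calib.f * efflux_derivative(params, t0)
    out = f_t0 + slope * (t_arr - t0)
    return out if np.ndim(t) else float(out)


def recipient_solution(
    c1: float,
    c2_t0: float,
    rate: float,
    t0: float,
    t: np.ndarray | float,
) -> np.ndarray | float:
    """Recipient-cell concentration during transfer from a clamped donor.

    Once the donor cell has equilibrated with the patch pipette it holds a
    constant concentration ``c1``; the recipient then relaxes exponentially,

        C2(t) = c1 - (c1 - C2(t0)) * exp(-rate * (t - t0)),

    where ``rate = P_j / Vol_2`` (1/s) is the quantity the transfer assay
    estimates.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < t0):
        raise ValueError("t must be >= t0")
    out = c1 - (c1 - c2_t0) * np.exp(-rate * (t_arr - t0))
    return out if np.ndim(t) else float(out)


def relative_fluorescence(
    amplitude_ratio: float,
    rate: float,
    t0: float,
    t: np.ndarray | float,
) -> np.ndarray | float:
    """Background-subtracted fluorescence ratio F2(t)/F2(t0) in the recipient.

    With ``R = C1 / C2(t0)`` (donor over recipient concentration at t0):

        F2(t)/F2(t0) = R - (R - 1) * exp(-rate * (t - t0))

    This is the curve fitted to transfer recordings; it is exact for
    background-subtracted fluorescence since F - f0 is proportional to C.
    """
    if amplitude_ratio <= 0:
        raise ValueError("amplitude ratio must be positive (C2(t0) must be > 0)")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    t_arr = np.asarray(t, dtype=float)
    out = amplitude_ratio - (amplitude_ratio - 1.0) * np.exp(-rate * (t_arr - t0))
    return out if np.ndim(t) else float(out)
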