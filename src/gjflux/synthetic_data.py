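"""Seeded generators for fluorescence traces, gating records, and cohorts.

Everything the analysis pipeline consumes can be generated here with known
ground truth: calcein-efflux recordings (10-s sampling, ~30 min), donor/
recipient dye-transfer pairs (30-s sampling, 15 min, optional blocker
intervals during which junctional flux is zeroed), single/multi-channel
gating records for amplitude-histogram fitting, and multi-genotype cohorts
combining efflux traces with voltage-ramp conductance records.

Noise model: multiplicative Gaussian on fluorescence (coefficient of
variation ``noise``), additive Gaussian on current. With zero noise every
generator reduces to the closed-form models, which the tests exploit.
All generators are deterministic under a fixed seed; cohort child seeds are
spawned from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .electrophys import RampRecord, UnitaryRecord
from .flux_model import EffluxParams, FluorescenceCalibration, efflux_solution
from .traces import FluorescenceTrace

__all__ = [
    "EffluxScenario",
    "TransferScenario",
    "GenotypeSpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_efflux_trace",
    "generate_transfer_traces",
    "generate_unitary_record",
    "generate_ramp_record",
    "generate_cohort",
]


@dataclass(frozen=True)
class EffluxScenario:
    """One synthetic calcein-efflux recording.

    Defaults follow the efflux assay design: one frame every 10 s for 30 min.
    """

    params: EffluxParams
    calibration: FluorescenceCalibration
    interval_s: float = 10.0
    duration_s: float = 1800.0
    noise: float = 0.02
    seed: int = 0
    label: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValueError("interval must be positive")
        if self.duration_s < 10 * self.interval_s:
            raise ValueError("duration must cover at least 10 sampling intervals")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


@dataclass(frozen=True)
class TransferScenario:
    """One synthetic donor/recipient dye-transfer recording.

    The donor loads from the patch pipette as a single exponential toward
    ``plateau_conc`` with time constant ``tau_load_s`` (default 80 s, putting
    the plateau near 350 s); the recipient integrates the transfer ODE
    against the time-varying donor. Junctional flux is zeroed inside
    ``blocker_intervals`` (idealized, fully reversible block).
    Defaults follow the transfer assay: one frame every 30 s for 15 min; the
    pipette dye concentration is 2 mM.
    """

    rate: float  # P_j / Vol_2, 1/s
    plateau_conc_um: float = 2000.0
    tau_load_s: float = 80.0
    calibration: FluorescenceCalibration = FluorescenceCalibration(f=0.5, f0=50.0)
    interval_s: float = 30.0
    duration_s: float = 900.0
    blocker_intervals: tuple[tuple[float, float], ...] = ()
    noise: float = 0.02
    seed: int = 0
    label: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        last_end = -np.inf
        for a, b in self.blocker_intervals:
            if not (0 <= a < b <= self.duration_s):
                raise ValueError("blocker intervals must lie within the recording")
            if a < last_end:
                raise ValueError("blocker intervals must not overlap")
            last_end = b
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


def _times(interval: float, duration: float) -> np.ndarray:
    n = int(round(duration / interval))
    return np.arange(n + 1) * interval


def _apply_mult_noise(values: np.ndarray, cv: float, rng: np.random.Generator):
    if cv == 0:
        return values
    return values * (1.0 + cv * rng.standard_normal(values.shape))


def generate_efflux_trace(scenario: EffluxScenario) -> FluorescenceTrace:
    """Synthetic calcein-efflux trace with ground truth in ``meta``."""
    rng = np.random.default_rng(scenario.seed)
    t = _times(scenario.interval_s, scenario.duration_s)
    conc = efflux_solution(scenario.params, t)
    fluor = scenario.calibration.to_fluorescence(conc)
    fluor = _apply_mult_noise(np.asarray(fluor), scenario.noise, rng)
    p = scenario.params
    return FluorescenceTrace(
        times=t,
        values=fluor,
        background=scenario.calibration.f0,
        label=scenario.label,
        genotype=scenario.genotype,
        meta={
            "true_perm_pl_s": p.perm,
            "true_rate_per_s": p.perm / p.vol_in,
            "true_alpha": p.alpha,
            "true_c_in_0_um": p.c_in_0,
            "true_initial_slope_au_s": scenario.calibration.f
            * (p.alpha - p.c_in_0 * p.perm)
            / p.vol_in,
            "seed": scenario.seed,
        },
    )


def _integrate_recipient(
    t_grid: np.ndarray,
    scenario: TransferScenario,
    substeps: int = 20,
) -> np.ndarray:
    """RK4 integration of dC2/dt = r(t) * (C1(t) - C2) on the sample grid."""

    def donor_conc(tt):
        return scenario.plateau_conc_um * (1.0 - np.exp(-tt / scenario.tau_load_s))

    def rate_at(tt):
        for a, b in scenario.blocker_intervals:
            if a <= tt < b:
                return 0.0
        return scenario.rate

    def deriv(tt, c2):
        return rate_at(tt) * (donor_conc(tt) - c2)

    c2 = 0.0
    out = np.empty(t_grid.shape)
    out[0] = c2
    for k in range(1, t_grid.size):
        h = (t_grid[k] - t_grid[k - 1]) / substeps
        tt = t_grid[k - 1]
        for _ in range(substeps):
            k1 = deriv(tt, c2)
            k2 = deriv(tt + h / 2, c2 + h / 2 * k1)
            k3 = deriv(tt + h / 2, c2 + h / 2 * k2)
            k4 = deriv(tt + h, c2 + h * k3)
            c2 += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            tt += h
        out[k] = c2
    return out


def generate_transfer_traces(
    scenario: TransferScenario,
) -> tuple[FluorescenceTrace, FluorescenceTrace]:
    """Synthetic (donor, recipient) trace pair with ground truth in ``meta``."""
    rng = np.random.default_rng(scenario.seed)
    t = _times(scenario.interval_s, scenario.duration_s)
    c1 = scenario.plateau_conc_um * (1.0 - np.exp(-t / scenario.tau_load_s))
    c2 = _integrate_recipient(t, scenario)
    calib = scenario.calibration
    f1 = _apply_mult_noise(np.asarray(calib.to_fluorescence(c1)), scenario.noise, rng)
    f2 = _apply_mult_noise(np.asarray(calib.to_fluorescence(c2)), scenario.noise, rng)
    meta = {
        "true_rate_per_s": scenario.rate,
        "tau_load_s": scenario.tau_load_s,
        "plateau_conc_um": scenario.plateau_conc_um,
        "blocker_intervals": scenario.blocker_intervals,
        "seed": scenario.seed,
    }
    donor = FluorescenceTrace(
        t, f1, background=calib.f0, label=scenario.label or "donor",
        genotype=scenario.genotype, meta=dict(meta),
    )
    recipient = FluorescenceTrace(
        t, f2, background=calib.f0, label=(scenario.label + "/recipient") if scenario.label else "recipient",
        genotype=scenario.genotype, meta=dict(meta),
    )
    return donor, recipient


def generate_unitary_record(
    gamma_ps: float,
    holding_mv: float,
    p_open: float = 0.5,
    mean_open_dwell_s: float = 0.02,
    sampling_hz: float = 5000.0,
    duration_s: float = 2.0,
    noise_sd_pa: float = 2.0,
    n_channels: int = 1,
    baseline_pa: float = 0.0,
    seed: int = 0,
    genotype: str = "",
) -> UnitaryRecord:
    """Two-state Markov gating record for amplitude-histogram analysis.

    Each of ``n_channels`` gates independently between closed and open with
    exponential dwell times; the open dwell mean is ``mean_open_dwell_s`` and
    the closed dwell mean is set so the stationary open probability equals
    ``p_open``. The unitary current step is ``gamma_ps * holding_mv / 1000``
    pA; additive Gaussian noise is applied on top of a constant baseline.
    """
    if not 0 < p_open < 1:
        raise ValueError("p_open must be in (0, 1)")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if holding_mv == 0:
        raise ValueError("holding voltage must be non-zero")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_hz))
    t = np.arange(n) / sampling_hz
    tau_open = mean_open_dwell_s
    tau_closed = tau_open * (1.0 - p_open) / p_open
    n_open = np.zeros(n, dtype=int)
    for _ in range(n_channels):
        state = rng.random() < p_open
        pos = 0.0
        open_mask = np.zeros(n, dtype=bool)
        while pos < duration_s:
            dwell = rng.exponential(tau_open if state else tau_closed)
            i0 = int(np.ceil(pos * sampling_hz))
            i1 = min(int(np.ceil((pos + dwell) * sampling_hz)), n)
            if state:
                open_mask[i0:i1] = True
            pos += dwell
            state = not state
        n_open += open_mask
    step_pa = gamma_ps * holding_mv / 1e3
    current = baseline_pa + n_open * step_pa
    if noise_sd_pa > 0:
        current = current + noise_sd_pa * rng.standard_normal(n)
    return UnitaryRecord(
        times=t,
        current=current,
        holding_mv=holding_mv,
        genotype=genotype,
        meta={
            "true_gamma_ps": gamma_ps,
            "true_p_open": p_open,
            "n_channels": n_channels,
            "true_step_pa": step_pa,
            "seed": seed,
        },
    )


def generate_ramp_record(
    g_ns: float,
    v_start_mv: float = 50.0,
    v_end_mv: float = -70.0,
    duration_s: float = 120.0,
    sampling_hz: float = 10.0,
    noise_sd_pa: float = 5.0,
    seed: int = 0,
    genotype: str = "",
) -> RampRecord:
    """Ohmic voltage-ramp record (+50 to -70 mV over 2 min by default)."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_hz))
    t = np.arange(n) / sampling_hz
    v = v_start_mv + (v_end_mv - v_start_mv) * t / duration_s
    i = g_ns * v + noise_sd_pa * rng.standard_normal(n)
    return RampRecord(times=t, voltage=v, current=i, genotype=genotype)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GenotypeSpec:
    """Ground-truth parameters of one genotype in a synthetic cohort.

    perm_per_channel : single-channel permeability P_gamma (pl/s per open
    channel); total cell permeability is ``perm_per_channel * n_po``.
    n_po is drawn log-normally (mean ``n_po_mean``, CV ``n_po_cv``) per cell.
    """

    label: str
    perm_per_channel: float
    gamma_ps: float = 340.0
    n_po_mean: float = 10.0
    n_po_cv: float = 0.3
    n_cells: int = 30
    n_ephys: int = 8

    def __post_init__(self) -> None:
        if self.n_cells < 3 or self.n_ephys < 3:
            raise ValueError("each genotype needs at least 3 cells and 3 recordings")
        if self.perm_per_channel < 0 or self.gamma_ps <= 0:
            raise ValueError("invalid permeability or conductance")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-genotype efflux + electrophysiology study design."""

    genotypes: tuple[GenotypeSpec, ...]
    calibration: FluorescenceCalibration = FluorescenceCalibration(f=5.0, f0=100.0)
    c_in_0_um: float = 100.0
    volume_mean_pl: float = 2.0
    volume_cv: float = 0.25
    interval_s: float = 10.0
    duration_s: float = 1800.0
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genotypes) < 2:
            raise ValueError("a cohort needs at least 2 genotypes")
        labels = [g.label for g in self.genotypes]
        if len(set(labels)) != len(labels):
            raise ValueError("genotype labels must be unique")


@dataclass
class SyntheticCohort:
    """Generated cohort: traces, ramp records, and a ground-truth manifest."""

    spec: CohortSpec
    efflux_traces: list[FluorescenceTrace]
    ramp_records: list[RampRecord]
    gamma_by_genotype: dict[str, float]
    ground_truth: pd.DataFrame


def _lognormal(rng, mean, cv, size):
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full synthetic cohort with deterministic child seeds.

    Per genotype: ``n_cells`` efflux traces (per-cell volume and n_po drawn
    log-normally, total permeability = P_gamma * n_po) and ``n_ephys``
    voltage-ramp records from a separate sample of cells (the efflux cells
    are never patched, matching the assay design).
    """
    ss = np.random.SeedSequence(spec.seed)
    traces: list[FluorescenceTrace] = []
    ramps: list[RampRecord] = []
    rows = []
    for geno in spec.genotypes:
        child = ss.spawn(1)[0]
        rng = np.random.default_rng(child)
        cell_seeds = rng.integers(0, 2**31 - 1, size=geno.n_cells + geno.n_ephys)
        volumes = _lognormal(rng, spec.volume_mean_pl, spec.volume_cv, geno.n_cells)
        n_pos = _lognormal(rng, geno.n_po_mean, geno.n_po_cv, geno.n_cells)
        ephys_n_pos = _lognormal(rng, geno.n_po_mean, geno.n_po_cv, geno.n_ephys)
        for c in range(geno.n_cells):
            perm = geno.perm_per_channel * n_pos[c]
            params = EffluxParams(
                vol_in=volumes[c], perm=perm, c_in_0=spec.c_in_0_um, alpha=0.0
            )
            scen = EffluxScenario(
                params=params,
                calibration=spec.calibration,
                interval_s=spec.interval_s,
                duration_s=spec.duration_s,
                noise=spec.noise,
                seed=int(cell_seeds[c]),
                label=f"{geno.label}_cell{c:03d}",
                genotype=geno.label,
            )
            traces.append(generate_efflux_trace(scen))
            rows.append(
                {
                    "genotype": geno.label,
                    "label": scen.label,
                    "kind": "efflux",
                    "volume_pl": volumes[c],
                    "n_po": n_pos[c],
                    "perm_pl_s": perm,
                    "rate_per_s": perm / volumes[c],
                    "perm_per_channel_pl_s": geno.perm_per_channel,
                    "gamma_ps": geno.gamma_ps,
                }
            )
        for e in range(geno.n_ephys):
            g_ns = ephys_n_pos[e] * geno.gamma_ps / 1e3
            ramp = generate_ramp_record(
                g_ns=g_ns,
                seed=int(cell_seeds[geno.n_cells + e]),
                genotype=geno.label,
            )
            ramp.label = f"{geno.label}_ephys{e:02d}"
            ramps.append(ramp)
            rows.append(
                {
                    "genotype": geno.label,
                    "label": ramp.label,
                    "kind": "ramp",
                    "volume_pl": np.nan,
                    "n_po": ephys_n_pos[e],
                    "perm_pl_s": np.nan,
                    "rate_per_s": np.nan,
                    "perm_per_channel_pl_s": geno.perm_per_channel,
                    "gamma_ps": geno.gamma_ps,
                }
            )
    manifest = pd.DataFrame(rows)
    return SyntheticCohort(
        spec=spec,
        efflux_traces=traces,
        ramp_records=ramps,
        gamma_by_genotype={g.label: g.gamma_ps for g in spec.genotypes},
        ground_truth=manifest,
    )
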