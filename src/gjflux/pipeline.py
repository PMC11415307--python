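"""End-to-end analysis: traces + electrophysiology -> statistics report.

The efflux pipeline reproduces the hemichannel study design: per-genotype
open-channel counts ``g/gamma`` from a separate set of voltage-ramp
recordings, linear-phase slope fits per efflux trace, slopes normalized by
the genotype-mean channel count, and the normality-gated group comparison of
both the normalized permeabilities and the channel counts. Every per-cell
decision (window chosen, fit diagnostics, excluded records) is logged into
the result bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gjio
from .electrophys import ChannelPopulation, RampRecord, conductance_at_zero
from .estimators import EffluxSlopeEstimator, normalize_hemichannel
from .exceptions import EstimationError
from .stats_compare import ComparisonReport, compare_groups
from .synthetic_data import SyntheticCohort
from .traces import FluorescenceTrace

__all__ = ["EffluxResults", "analyze_efflux", "analyze_cohort", "run_pipeline"]


@dataclass
class EffluxResults:
    """Result bundle of an efflux analysis run."""

    per_cell: pd.DataFrame  # one row per trace: slope, window, normalized value
    n_po: pd.DataFrame  # one row per electrophysiology recording
    group_summary: pd.DataFrame  # mean +/- SEM per genotype
    permeability_report: ComparisonReport
    n_po_report: ComparisonReport
    log: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_cell.to_csv(out / "per_cell_estimates.csv", index=False)
        self.n_po.to_csv(out / "n_po_estimates.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        for name, rep in (
            ("permeability", self.permeability_report),
            ("n_po", self.n_po_report),
        ):
            rep.pairwise.to_csv(out / f"stats_{name}_pairwise.csv", index=False)
        with open(out / "run_manifest.txt", "w") as fh:
            fh.write(
                f"branch_permeability: {self.permeability_report.branch}\n"
                f"omnibus_p_permeability: {self.permeability_report.omnibus_p:.6g}\n"
                f"branch_n_po: {self.n_po_report.branch}\n"
                f"omnibus_p_n_po: {self.n_po_report.omnibus_p:.6g}\n"
            )
            fh.write("\n".join(self.log) + "\n")


def _group_n_po(
    ramp_records: Sequence[RampRecord],
    gamma_by_genotype: Mapping[str, float],
    g_ns_by_genotype: Mapping[str, Sequence[float]] | None,
    log: list[str],
) -> pd.DataFrame:
    rows = []
    for rec in ramp_records:
        gamma = gamma_by_genotype[rec.genotype]
        g = conductance_at_zero(rec)
        rows.append(
            {
                "genotype": rec.genotype,
                "label": rec.label,
                "g_ns": g,
                "gamma_ps": gamma,
                "n_po": g * 1e3 / gamma,
            }
        )
        log.append(f"ramp {rec.label}: g={g:.3f} nS, n_po={g * 1e3 / gamma:.2f}")
    if g_ns_by_genotype:
        for geno, values in g_ns_by_genotype.items():
            gamma = gamma_by_genotype[geno]
            for k, g in enumerate(values):
                rows.append(
                    {
                        "genotype": geno,
                        "label": f"{geno}_g{k:02d}",
                        "g_ns": float(g),
                        "gamma_ps": gamma,
                        "n_po": float(g) * 1e3 / gamma,
                    }
                )
    if not rows:
        raise ValueError("no electrophysiology records or conductances supplied")
    return pd.DataFrame(rows)


def analyze_efflux(
    traces: Sequence[FluorescenceTrace],
    ramp_records: Sequence[RampRecord],
    gamma_by_genotype: Mapping[str, float],
    g_ns_by_genotype: Mapping[str, Sequence[float]] | None = None,
    min_points: int = 12,
    r2_threshold: float = 0.98,
    lof_tolerance: float = 1.3,
    blocker_intervals: Sequence[tuple[float, float]] = (),
    alpha: float = 0.05,
) -> EffluxResults:
    """Slope-fit every trace, normalize by group-mean g/gamma, compare groups.

    Traces whose window selection or fit fails are excluded and logged, not
    fatal; a genotype losing all its traces is an error.
    """
    log: list[str] = []
    n_po_df = _group_n_po(ramp_records, gamma_by_genotype, g_ns_by_genotype, log)
    group_n_po = n_po_df.groupby("genotype")["n_po"].mean()

    rows = []
    for tr in traces:
        if tr.genotype not in group_n_po.index:
            raise ValueError(f"trace {tr.label!r}: no electrophysiology for "
                             f"genotype {tr.genotype!r}")
        est = EffluxSlopeEstimator(
            min_points=min_points,
            r2_threshold=r2_threshold,
            lof_tolerance=lof_tolerance,
            exclude=blocker_intervals,
        )
        try:
            est.fit(tr)
        except EstimationError as exc:
            log.append(f"trace {tr.label}: EXCLUDED ({exc})")
            continue
        pop = ChannelPopulation(
            g_ns=group_n_po[tr.genotype] * gamma_by_genotype[tr.genotype] / 1e3,
            gamma_ps=gamma_by_genotype[tr.genotype],
            genotype=tr.genotype,
        )
        norm = normalize_hemichannel(est.result_, pop, source="group-mean")
        log.append(
            f"trace {tr.label}: window=[{est.window_[0]:.0f},{est.window_[1]:.0f}] s, "
            f"k={est.slope_k_:.4g} a.u./s, r2={est.r_squared_:.3f}"
        )
        rows.append(
            {
                "genotype": tr.genotype,
                "label": tr.label,
                "slope_k_au_s": est.slope_k_,
                "window_start_s": est.window_[0],
                "window_end_s": est.window_[1],
                "r_squared": est.r_squared_,
                "n_po_groupmean": norm.n_po_used,
                "normalized_k_au_s_per_channel": norm.value,
            }
        )
    per_cell = pd.DataFrame(rows)
    if per_cell.empty:
        raise EstimationError("no trace produced a usable slope fit")
    missing = set(t.genotype for t in traces) - set(per_cell["genotype"])
    if missing:
        raise EstimationError(f"all traces excluded for genotypes {sorted(missing)}")

    perm_groups = {
        g: sub["normalized_k_au_s_per_channel"].to_numpy()
        for g, sub in per_cell.groupby("genotype")
    }
    n_po_groups = {g: sub["n_po"].to_numpy() for g, sub in n_po_df.groupby("genotype")}
    perm_report = compare_groups(perm_groups, alpha=alpha)
    n_po_report = compare_groups(n_po_groups, alpha=alpha)
    log.append(f"permeability comparison branch: {perm_report.branch}, "
               f"omnibus p={perm_report.omnibus_p:.4g}")
    log.append(f"n_po comparison branch: {n_po_report.branch}, "
               f"omnibus p={n_po_report.omnibus_p:.4g}")

    summaries = []
    for geno in sorted(perm_groups):
        v = perm_groups[geno]
        npo = n_po_groups[geno]
        summaries.append(
            {
                "genotype": geno,
                "n_cells": v.size,
                "normalized_k_mean": float(np.mean(v)),
                "normalized_k_sem": float(np.std(v, ddof=1) / np.sqrt(v.size)),
                "slope_k_mean_au_s": float(
                    per_cell[per_cell.genotype == geno]["slope_k_au_s"].mean()
                ),
                "n_po_mean": float(np.mean(npo)),
                "n_po_sem": float(np.std(npo, ddof=1) / np.sqrt(npo.size)),
            }
        )
    return EffluxResults(
        per_cell=per_cell,
        n_po=n_po_df,
        group_summary=pd.DataFrame(summaries),
        permeability_report=perm_report,
        n_po_report=n_po_report,
        log=log,
    )


def analyze_cohort(cohort: SyntheticCohort, alpha: float = 0.05) -> EffluxResults:
    """Run the efflux pipeline on an in-memory synthetic cohort."""
    return analyze_efflux(
        traces=cohort.efflux_traces,
        ramp_records=cohort.ramp_records,
        gamma_by_genotype=cohort.gamma_by_genotype,
        alpha=alpha,
    )


def run_pipeline(config: gjio.PipelineConfig, base: str | Path | None = None) -> EffluxResults:
    """File-based pipeline entry point driven by a :class:`PipelineConfig`."""
    config.validate(base=Path(base) if base is not None else None)
    root = Path(base) if base is not None else Path(".")
    traces: list[FluorescenceTrace] = []
    for entry in config.traces:
        traces.extend(
            gjio.read_trace_table(
                root / entry.path, background=entry.background, genotype=entry.genotype
            )
        )
    ramps: list[RampRecord] = []
    gamma_by_genotype: dict[str, float] = {}
    g_ns_by_genotype: dict[str, list[float]] = {}
    for entry in config.ephys:
        gamma_by_genotype[entry.genotype] = entry.gamma_ps
        for rp in entry.ramp_paths:
            ramps.append(gjio.read_ramp_table(root / rp, genotype=entry.genotype))
        if entry.g_ns:
            g_ns_by_genotype[entry.genotype] = list(entry.g_ns)
    results = analyze_efflux(
        traces=traces,
        ramp_records=ramps,
        gamma_by_genotype=gamma_by_genotype,
        g_ns_by_genotype=g_ns_by_genotype or None,
        min_points=config.min_points,
        r2_threshold=config.r2_threshold,
        lof_tolerance=config.lof_tolerance,
        blocker_intervals=config.blocker_intervals,
        alpha=config.alpha,
    )
    if config.outdir:
        results.write(root / config.outdir)
    return results
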