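"""Delimited-text readers/writers and the pipeline configuration.

Trace tables are long-format delimited text with a header naming at least
``time_s`` and ``value_au``; an optional ``roi`` column separates multiple
traces in one file. Ramp records carry ``time_s, voltage_mv, current_pa``;
unitary records ``time_s, current_pa`` with the holding voltage in a
``# holding_mv = <value>`` comment line or supplied by the caller. Comma vs
tab is auto-detected from the header line. All numeric output columns carry
explicit unit suffixes.

The pipeline configuration is a YAML file; see :class:`PipelineConfig`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .electrophys import RampRecord, UnitaryRecord
from .exceptions import ParseError
from .traces import FluorescenceTrace

__all__ = [
    "read_trace_table",
    "write_trace_table",
    "read_ramp_table",
    "read_unitary_table",
    "write_ramp_table",
    "write_unitary_table",
    "PipelineConfig",
    "load_config",
]


def _detect_sep(path: str | os.PathLike) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ParseError("file has no header line", path=str(path))


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"could not parse delimited text: {exc}", path=str(path)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns {missing}", path=str(path))
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ParseError(
                f"non-numeric value in column {col!r}", path=str(path), line=line
            )
        df[col] = pd.to_numeric(df[col])
    if df[required[0]].isna().any():
        line = int(np.flatnonzero(df[required[0]].isna())[0]) + 2
        raise ParseError("missing time value", path=str(path), line=line)
    return df


def read_trace_table(
    path: str | os.PathLike,
    background: float = 0.0,
    genotype: str = "",
) -> list[FluorescenceTrace]:
    """Read one or more fluorescence traces from a delimited-text table.

    Columns: ``time_s``, ``value_au``, optional ``roi``. Returns one trace
    per distinct roi (file stem used as label when absent). Non-monotone
    time within a trace is a parse error naming the offending line.
    """
    df = _read_table(path, ["time_s", "value_au"])
    stem = Path(path).stem
    traces = []
    if "roi" in df.columns:
        items = [(f"{stem}:{roi}", sub) for roi, sub in df.groupby("roi", sort=False)]
    else:
        items = [(stem, df)]
    for label, sub in items:
        t = sub["time_s"].to_numpy(dtype=float)
        dt_bad = np.flatnonzero(np.diff(t) <= 0)
        if dt_bad.size:
            line = int(sub.index[dt_bad[0] + 1]) + 2
            raise ParseError(
                f"time not strictly increasing in trace {label!r}",
                path=str(path),
                line=line,
            )
        traces.append(
            FluorescenceTrace(
                times=t,
                values=sub["value_au"].to_numpy(dtype=float),
                background=background,
                label=label,
                genotype=genotype,
            )
        )
    return traces


def write_trace_table(
    path: str | os.PathLike, traces: FluorescenceTrace | Iterable[FluorescenceTrace]
) -> None:
    """Write traces in long format (``time_s, value_au, roi``)."""
    if isinstance(traces, FluorescenceTrace):
        traces = [traces]
    frames = [
        pd.DataFrame(
            {"time_s": tr.times, "value_au": tr.values, "roi": tr.label or f"roi{i}"}
        )
        for i, tr in enumerate(traces)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_ramp_table(path: str | os.PathLike, genotype: str = "") -> RampRecord:
    df = _read_table(path, ["time_s", "voltage_mv", "current_pa"])
    return RampRecord(
        times=df["time_s"].to_numpy(float),
        voltage=df["voltage_mv"].to_numpy(float),
        current=df["current_pa"].to_numpy(float),
        label=Path(path).stem,
        genotype=genotype,
    )


def write_ramp_table(path: str | os.PathLike, record: RampRecord) -> None:
    pd.DataFrame(
        {
            "time_s": record.times,
            "voltage_mv": record.voltage,
            "current_pa": record.current,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def _holding_from_header(path) -> float | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "holding_mv" in line:
                return float(line.split("=")[1])
            if not line.startswith("#"):
                return None
    return None


def read_unitary_table(
    path: str | os.PathLike, holding_mv: float | None = None, genotype: str = ""
) -> UnitaryRecord:
    """Read a constant-voltage current record.

    The holding voltage comes from the ``holding_mv`` argument or a
    ``# holding_mv = <mV>`` header comment; missing both is a parse error.
    """
    if holding_mv is None:
        holding_mv = _holding_from_header(path)
    if holding_mv is None:
        raise ParseError(
            "holding voltage not given and no '# holding_mv =' header", path=str(path)
        )
    df = _read_table(path, ["time_s", "current_pa"])
    return UnitaryRecord(
        times=df["time_s"].to_numpy(float),
        current=df["current_pa"].to_numpy(float),
        holding_mv=float(holding_mv),
        label=Path(path).stem,
        genotype=genotype,
    )


def write_unitary_table(path: str | os.PathLike, record: UnitaryRecord) -> None:
    with open(path, "w") as fh:
        fh.write(f"# holding_mv = {record.holding_mv:g}\n")
        pd.DataFrame(
            {"time_s": record.times, "current_pa": record.current}
        ).to_csv(fh, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TraceEntry:
    path: str
    genotype: str
    background: float = 0.0


@dataclass
class EphysEntry:
    genotype: str
    gamma_ps: float
    ramp_paths: list[str] = field(default_factory=list)
    g_ns: list[float] = field(default_factory=list)  # pre-measured conductances


@dataclass
class PipelineConfig:
    """Validated configuration of an end-to-end efflux analysis run.

    traces : per-file genotype assignment and background fluorescence.
    ephys : per-genotype unitary conductance plus either raw ramp files or
        pre-measured macroscopic conductances.
    Window-selection overrides, blocker intervals, the master seed, and the
    output directory complete the run description.
    """

    traces: list[TraceEntry]
    ephys: list[EphysEntry]
    min_points: int = 12
    r2_threshold: float = 0.98
    lof_tolerance: float = 1.3
    blocker_intervals: list[tuple[float, float]] = field(default_factory=list)
    alpha: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def validate(self, base: Path | None = None) -> None:
        if not self.traces:
            raise ValueError("config lists no trace files")
        trace_genos = {t.genotype for t in self.traces}
        ephys_genos = {e.genotype for e in self.ephys}
        if not trace_genos <= ephys_genos:
            raise ValueError(
                f"genotypes {sorted(trace_genos - ephys_genos)} have traces but no "
                "electrophysiology entry"
            )
        for e in self.ephys:
            if not e.ramp_paths and not e.g_ns:
                raise ValueError(
                    f"genotype {e.genotype!r}: need ramp_paths or g_ns values"
                )
        for t in self.traces:
            p = Path(t.path) if base is None else base / t.path
            if not p.exists():
                raise FileNotFoundError(f"trace file not found: {p}")
        for e in self.ephys:
            for rp in e.ramp_paths:
                p = Path(rp) if base is None else base / rp
                if not p.exists():
                    raise FileNotFoundError(f"ramp file not found: {p}")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError("config must be a YAML mapping", path=str(path))
    try:
        cfg = PipelineConfig(
            traces=[TraceEntry(**t) for t in raw.get("traces", [])],
            ephys=[EphysEntry(**e) for e in raw.get("ephys", [])],
            min_points=raw.get("min_points", 12),
            r2_threshold=raw.get("r2_threshold", 0.98),
            lof_tolerance=raw.get("lof_tolerance", 1.3),
            blocker_intervals=[tuple(b) for b in raw.get("blocker_intervals", [])],
            alpha=raw.get("alpha", 0.05),
            seed=raw.get("seed", 0),
            outdir=raw.get("outdir"),
        )
    except TypeError as exc:
        raise ParseError(f"bad config structure: {exc}", path=str(path)) from exc
    cfg.validate(base=Path(path).parent)
    return cfg
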