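"""The fluorescence time-series container shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluorescenceTrace"]


@dataclass
class FluorescenceTrace:
    """Sampled fluorescence intensity for one region of interest.

    Attributes
    ----------
    times : array of sample times (s), strictly increasing.
    values : fluorescence intensities (a.u.), finite.
    background : scalar background fluorescence f0 (a.u.) measured from a
        cell-free region of the same recording.
    label : ROI / cell identifier.
    genotype : group label (e.g. connexin variant) for downstream statistics.
    meta : free-form metadata; synthetic generators attach ground truth here.
    """

    times: np.ndarray
    values: np.ndarray
    background: float = 0.0
    label: str = ""
    genotype: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("a trace needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def corrected(self) -> np.ndarray:
        """Background-subtracted intensities (a.u.)."""
        return self.values - self.background

    def crop(self, t_start: float, t_end: float) -> "FluorescenceTrace":
        """Sub-trace with t_start <= t <= t_end (background and labels kept)."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        if mask.sum() < 2:
            raise ValueError("crop window contains fewer than two samples")
        return FluorescenceTrace(
            self.times[mask],
            self.values[mask],
            background=self.background,
            label=self.label,
            genotype=self.genotype,
            meta=dict(self.meta),
        )
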