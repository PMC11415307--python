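"""Group and pairwise comparison of permeability estimates.

The decision tree mirrors common practice for small-sample physiology data:
Shapiro-Wilk normality per group; if every group passes, one-way ANOVA with
Tukey's HSD post hoc; if any group fails, Kruskal-Wallis (ANOVA on ranks)
with Dunn's post hoc test. Simple pairwise contrasts use the two-sided
Mann-Whitney rank-sum test. Omnibus and post hoc routines are scipy's; only
Dunn's z statistics are computed in-package (rank sums with tie correction,
Holm-adjusted by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonReport",
    "PairwiseResult",
    "compare_groups",
    "compare_pairwise",
    "dunn_test",
]


@dataclass(frozen=True)
class ComparisonReport:
    """Outcome of the group-comparison decision tree.

    branch : "anova_tukey" or "kruskal_dunn" (which path fired).
    shapiro_p : per-group Shapiro-Wilk p-values driving the branch choice.
    pairwise : one row per group pair with raw and adjusted p-values.
    """

    branch: str
    alpha: float
    shapiro_p: dict[str, float]
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame
    notes: tuple[str, ...] = field(default_factory=tuple)

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["p_adj"] < self.alpha]
        return list(zip(sig["group1"], sig["group2"]))


@dataclass(frozen=True)
class PairwiseResult:
    """Two-sided Mann-Whitney comparison of two samples."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str = "mann-whitney"


def _validate(data: Mapping[str, Sequence[float]], min_n: int = 3):
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for label, vals in data.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_n:
            raise ValueError(f"group {label!r} has {arr.size} values; need >= {min_n}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite values")
        out[str(label)] = arr
    return out


def dunn_test(
    data: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> pd.DataFrame:
    """Dunn's post hoc test on pooled ranks after Kruskal-Wallis.

    For groups i, j with mean pooled ranks Rbar_i, Rbar_j over N total
    observations, the statistic is

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),

    with tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups;
    two-sided normal p-values, adjusted with ``adjust`` (any method accepted
    by statsmodels ``multipletests``; "none" disables adjustment).
    """
    groups = _validate(data)
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = float(np.mean(ranks[start : start + n]))
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "statistic": z, "p_raw": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if adjust and adjust != "none":
        out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    else:
        out["p_adj"] = out["p_raw"]
    return out


def compare_groups(
    data: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    dunn_adjust: str = "holm",
) -> ComparisonReport:
    """Omnibus + post hoc comparison with normality-gated test selection.

    Every group is Shapiro-Wilk tested at ``alpha``; if all pass, one-way
    ANOVA with Tukey's HSD; if any group fails, Kruskal-Wallis with Dunn's
    post hoc (Holm-adjusted by default). The report records which branch
    fired and the full pairwise matrix.
    """
    groups = _validate(data)
    labels = list(groups)
    shapiro_p = {g: float(stats.shapiro(groups[g]).pvalue) for g in labels}
    failing = [g for g in labels if shapiro_p[g] < alpha]
    notes = []
    if not failing:
        branch = "anova_tukey"
        stat, p = stats.f_oneway(*(groups[g] for g in labels))
        tk = stats.tukey_hsd(*(groups[g] for g in labels))
        rows = []
        for i, j in itertools.combinations(range(len(labels)), 2):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "statistic": float(tk.statistic[i, j]),
                    "p_raw": float(tk.pvalue[i, j]),
                    "p_adj": float(tk.pvalue[i, j]),  # Tukey is family-adjusted
                }
            )
        pairwise = pd.DataFrame(rows)
        notes.append("all groups passed Shapiro-Wilk; ANOVA + Tukey HSD")
    else:
        branch = "kruskal_dunn"
        stat, p = stats.kruskal(*(groups[g] for g in labels))
        pairwise = dunn_test(groups, adjust=dunn_adjust)
        notes.append(
            f"normality failed for {failing}; Kruskal-Wallis + Dunn "
            f"({dunn_adjust}-adjusted)"
        )
    return ComparisonReport(
        branch=branch,
        alpha=alpha,
        shapiro_p=shapiro_p,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        notes=tuple(notes),
    )


def compare_pairwise(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> PairwiseResult:
    """Mann-Whitney rank-sum comparison of two samples.

    Uses scipy's exact null distribution for small tie-free samples and the
    normal approximation otherwise (method="auto").
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.size < 3 or b_arr.size < 3:
        raise ValueError("each sample needs at least 3 values")
    res = stats.mannwhitneyu(a_arr, b_arr, alternative=alternative, method="auto")
    return PairwiseResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(a_arr.size),
        n2=int(b_arr.size),
    )
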