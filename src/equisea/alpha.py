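"""Per-sample alpha diversity and group comparison.

Four metrics per sample: observed richness, Shannon entropy (natural
log), the order-1 Hill number ``exp(H)`` (the effective number of
equally abundant taxa), and an order-1 phylogenetic Hill number in the
Chao–Chiu–Jost framework. Groups are compared metric-by-metric with a
two-tailed Welch t-test; estimates are reported as mean ± SEM.

The phylogenetic metric aggregates relative abundance up the tree: for
each branch b with length L_b, let a_b be the summed relative abundance
of tips below it and T = Σ_b L_b a_b (the abundance-weighted tree
depth). The mean-diversity form

    phylo_hill1 = exp(−Σ_b (L_b a_b / T) ln a_b)

reduces to exp(H) on a star tree with equal branch lengths. The
T-scaled total form (phylo_hill1 * T, in branch-length units) is also
computed as ``phylo_hill1_pd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable
from .trees import PhyloTree

__all__ = [
    "AlphaDiversityResult",
    "GroupComparison",
    "alpha_metrics",
    "alpha_metrics_table",
    "compare_alpha",
]


@dataclass(frozen=True)
class AlphaDiversityResult:
    sample_id: str
    richness: int
    shannon: float  # nats
    hill1: float
    phylo_hill1: float | None = None
    phylo_hill1_pd: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison of one metric between two groups."""

    metric: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    t_statistic: float
    p_value: float
    group_sizes: tuple[int, int]

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _shannon(proportions: np.ndarray) -> float:
    p = proportions[proportions > 0]
    return float(-(p * np.log(p)).sum())


def alpha_metrics(
    counts: np.ndarray,
    feature_ids: tuple[str, ...],
    sample_id: str,
    tree: PhyloTree | None = None,
) -> AlphaDiversityResult:
    """Compute all alpha metrics for one sample (one count row).

    If a tree is supplied, every feature with a nonzero count must be a
    tip of it; phylogenetic Hill numbers are omitted otherwise.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id!r} has zero total count")
    p = counts / total
    richness = int((counts > 0).sum())
    h = _shannon(p)
    hill1 = math.exp(h)

    phylo = phylo_pd = None
    if tree is not None:
        present = {fid for fid, c in zip(feature_ids, counts) if c > 0}
        missing = present - set(tree.tip_names)
        if missing:
            raise ValueError(
                f"tree lacks tips for nonzero features: {sorted(missing)}"
            )
        tip_p = np.zeros(tree.n_tips)
        idx = {n: i for i, n in enumerate(tree.tip_names)}
        for fid, pi in zip(feature_ids, p):
            if pi > 0:
                tip_p[idx[fid]] = pi
        a = tree.branch_tip_masks @ tip_p  # a_b per branch
        L = tree.branch_lengths
        T = float((L * a).sum())
        nz = a > 0
        exponent = -float((L[nz] * a[nz] * np.log(a[nz])).sum()) / T
        phylo = math.exp(exponent)
        phylo_pd = phylo * T
    return AlphaDiversityResult(sample_id, richness, h, hill1, phylo, phylo_pd)


def alpha_metrics_table(
    table: FeatureTable, tree: PhyloTree | None = None
) -> pd.DataFrame:
    """Alpha metrics for every sample of a feature table."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        r = alpha_metrics(table.counts[i], table.feature_ids, sid, tree)
        rows.append(
            {
                "sample_id": r.sample_id,
                "richness": r.richness,
                "shannon": r.shannon,
                "hill1": r.hill1,
                "phylo_hill1": r.phylo_hill1,
                "phylo_hill1_pd": r.phylo_hill1_pd,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_alpha(
    values_a: np.ndarray | list[float],
    values_b: np.ndarray | list[float],
    metric: str = "",
    group_names: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Welch two-sample, two-sided t-test between two groups of values.

    Both groups need at least 2 values. When both groups are constant
    with equal means (t undefined, 0/0) the comparison carries no
    evidence against the null and p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:  # zero variance, different means: maximal evidence
            t, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
    return GroupComparison(
        metric=metric,
        group_names=group_names,
        means=(float(a.mean()), float(b.mean())),
        sems=(float(stats.sem(a)), float(stats.sem(b))),
        t_statistic=float(t),
        p_value=float(p),
        group_sizes=(a.size, b.size),
    )
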