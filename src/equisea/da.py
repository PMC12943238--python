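"""Two-step differential abundance with combination-resampling robustness.

Step 1 — screen. Counts are rank-collapsed, prevalence-filtered and
log-transformed (ln(count + pseudocount)). Each sample's unknown
sampling fraction (the multiplicative bias between sequenced counts and
true abundances) is estimated as a per-sample offset by median
centering: offset_j = median over taxa of (y_ij − mean over samples of
y_i·). Offsets are subtracted and each taxon is tested between groups
with a Welch t-test; taxa with unadjusted p below the screening level
become candidates. The screen deliberately applies no multiplicity
adjustment — it nominates, it does not confirm.

Step 2 — combination resampling. For each candidate taxon, every
possible subset of k subjects (default 3) is enumerated within each
group, and the taxon's mean relative abundance over the subset is
recorded: an unbalanced 8 vs 4 cohort yields C(8,3) = 56 and
C(4,3) = 4 subset means. The spread of subset means shows how much a
candidate's signal depends on particular animals. Two p-values are
attached: a Welch t on the subset means (mirroring common practice, but
anticonservative because overlapping subsets are not independent) and a
subject-level permutation p that is valid by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import (
    FeatureTable,
    TaxonomyMap,
    collapse_taxonomy,
    prevalence_filter,
    to_relative_abundance,
)

__all__ = [
    "ScreenConfig",
    "CandidateTaxon",
    "SubsetPlan",
    "CombinationSummary",
    "estimate_sample_offsets",
    "da_screen",
    "enumerate_subsets",
    "subset_means",
    "combination_summaries",
    "combination_test",
    "combination_permutation_test",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the differential-abundance screen."""

    rank: str = "genus"
    min_prevalence: float = 0.2
    alpha: float = 0.05  # unadjusted screening level
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_prevalence <= 1):
            raise ValueError("min_prevalence must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass(frozen=True)
class CandidateTaxon:
    taxon: str  # lineage string at the screened rank
    effect: float  # mean corrected log-abundance difference (group_a - group_b)
    statistic: float
    p_value: float
    direction: str  # group label with the higher corrected abundance


@dataclass(frozen=True)
class SubsetPlan:
    """All unordered k-subsets of one group's members."""

    group: str
    k: int
    subsets: tuple[tuple[str, ...], ...]

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


@dataclass(frozen=True)
class CombinationSummary:
    taxon: str
    group: str
    means: np.ndarray  # one subset-mean relative abundance per subset
    median: float
    q1: float
    q3: float
    p_t: float | None = None  # Welch t on subset means vs the other group
    p_perm: float | None = None  # subject-level permutation p


def estimate_sample_offsets(log_counts: np.ndarray) -> np.ndarray:
    """Per-sample sampling-fraction offsets by median centering.

    `log_counts` is samples x taxa (already rank-collapsed and
    prevalence-filtered). Returns one offset per sample, identified so
    their median is 0. At least 3 taxa are required for the median to
    be usable.
    """
    y = np.asarray(log_counts, dtype=float)
    if y.ndim != 2:
        raise ValueError("log_counts must be samples x taxa")
    if y.shape[1] < 3:
        raise ValueError("need at least 3 taxa to estimate offsets")
    centered = y - y.mean(axis=0, keepdims=True)  # remove per-taxon level
    offsets = np.median(centered, axis=1)
    return offsets - np.median(offsets)


def da_screen(
    table: FeatureTable,
    groups: Mapping[str, str],
    config: ScreenConfig | None = None,
    taxonomy: TaxonomyMap | None = None,
) -> list[CandidateTaxon]:
    """Bias-corrected screen for differentially abundant taxa.

    `groups` maps sample_id -> group label; exactly two groups, each
    with >= 2 samples. If a taxonomy is given the table is collapsed at
    ``config.rank`` first; the prevalence filter then runs at the tested
    rank. Candidates are returned ordered by ascending p.
    """
    cfg = config or ScreenConfig()
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    members = {g: [s for s in table.sample_ids if groups.get(s) == g] for g in labels}
    if any(len(m) < 2 for m in members.values()):
        raise ValueError("each group needs >= 2 samples")
    used = members[labels[0]] + members[labels[1]]
    work = table.select_samples(used)
    if taxonomy is not None:
        work = collapse_taxonomy(work, taxonomy, cfg.rank)
    try:
        work, _removed = prevalence_filter(work, cfg.min_prevalence)
    except ValueError:
        import warnings

        warnings.warn("prevalence filter retained zero taxa; no candidates")
        return []
    y = np.log(work.counts + cfg.pseudocount)
    if work.n_features >= 3:
        y = y - estimate_sample_offsets(y)[:, None]
    ia = [work.sample_ids.index(s) for s in members[labels[0]]]
    ib = [work.sample_ids.index(s) for s in members[labels[1]]]
    a, b = y[ia], y[ib]
    with np.errstate(invalid="ignore"):
        t_all, p_all = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t_all = np.where(np.isnan(t_all), 0.0, t_all)  # both groups constant
    p_all = np.where(np.isnan(p_all), 1.0, p_all)
    effects = a.mean(axis=0) - b.mean(axis=0)
    candidates = []
    for j, taxon in enumerate(work.feature_ids):
        if p_all[j] < cfg.alpha:
            candidates.append(
                CandidateTaxon(
                    taxon=taxon,
                    effect=float(effects[j]),
                    statistic=float(t_all[j]),
                    p_value=float(p_all[j]),
                    direction=labels[0] if effects[j] > 0 else labels[1],
                )
            )
    return sorted(candidates, key=lambda c: c.p_value)


def enumerate_subsets(members: Sequence[str], k: int = 3) -> SubsetPlan:
    """All C(n, k) unordered k-subsets, in lexicographic member order."""
    members = list(members)
    if len(set(members)) != len(members):
        raise ValueError("duplicate member ids")
    if k > len(members):
        raise ValueError(f"k={k} exceeds group size {len(members)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    return SubsetPlan(
        group="", k=k, subsets=tuple(itertools.combinations(members, k))
    )


def subset_means(values: Mapping[str, float], plan: SubsetPlan) -> np.ndarray:
    """Mean of `values` over each subset of the plan."""
    return np.asarray(
        [np.mean([values[m] for m in subset]) for subset in plan.subsets]
    )


def combination_test(means_a: Sequence[float], means_b: Sequence[float]) -> float:
    """Two-sided Welch t-test treating subset means as observations.

    This mirrors common usage but overstates evidence: overlapping
    subsets share animals, so the subset means are not independent.
    Prefer :func:`combination_permutation_test` for a calibrated p.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need subset means")
    if a.size < 2 and b.size < 2:
        raise ValueError("at least one group needs >= 2 subset means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(p)


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) / a.size if a.size > 1 else 0.0
    vb = b.var(ddof=1) / b.size if b.size > 1 else 0.0
    denom = math.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return (a.mean() - b.mean()) / denom


def combination_permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    k: int = 3,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Subject-level permutation p for the subset-mean comparison.

    Subjects (not subset means) are relabeled; the subset means are
    recomputed on each side for every relabeling and the Welch t on
    subset means is the test statistic. Valid under subject
    exchangeability regardless of subset overlap.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    na, nb = a.size, b.size
    if min(na, nb) < k:
        raise ValueError("each group needs at least k subjects")
    pooled = np.concatenate([a, b])
    combs_a = np.asarray(list(itertools.combinations(range(na), k)))
    combs_b = np.asarray(list(itertools.combinations(range(nb), k)))

    def stat(vals_a: np.ndarray, vals_b: np.ndarray) -> float:
        ma = vals_a[combs_a].mean(axis=1)
        mb = vals_b[combs_b].mean(axis=1)
        return abs(_welch_t(ma, mb))

    obs = stat(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stat(perm[:na], perm[na:]) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def combination_summaries(
    rel: pd.DataFrame,
    candidates: Sequence[CandidateTaxon] | Sequence[str],
    plans: Mapping[str, SubsetPlan],
    n_perm: int = 999,
    seed: int = 0,
) -> list[CombinationSummary]:
    """Per-candidate, per-group subset-mean distributions with p-values.

    `rel` is a samples x taxa relative-abundance DataFrame covering
    every plan member; `plans` maps group label -> SubsetPlan over that
    group's samples. Exactly two groups are compared.
    """
    taxa = [c.taxon if isinstance(c, CandidateTaxon) else str(c) for c in candidates]
    groups = sorted(plans)
    if len(groups) != 2:
        raise ValueError("exactly two subset plans required")
    for g in groups:
        missing = [m for s in plans[g].subsets for m in s if m not in rel.index]
        if missing:
            raise KeyError(f"plan members absent from table: {sorted(set(missing))}")
    out: list[CombinationSummary] = []
    for taxon in taxa:
        if taxon not in rel.columns:
            raise KeyError(f"candidate taxon {taxon!r} absent from table")
        per_group_means = {}
        per_group_values = {}
        for g in groups:
            plan = plans[g]
            sample_ids = sorted({m for s in plan.subsets for m in s})
            vals = {s: float(rel.loc[s, taxon]) for s in sample_ids}
            per_group_values[g] = np.asarray([vals[s] for s in sample_ids])
            per_group_means[g] = subset_means(vals, plan)
        ga, gb = groups
        p_t = combination_test(per_group_means[ga], per_group_means[gb])
        k = plans[ga].k
        p_perm = combination_permutation_test(
            per_group_values[ga], per_group_values[gb], k=k, n_perm=n_perm, seed=seed
        )
        for g in groups:
            m = per_group_means[g]
            out.append(
                CombinationSummary(
                    taxon=taxon,
                    group=g,
                    means=m,
                    median=float(np.median(m)),
                    q1=float(np.percentile(m, 25)),
                    q3=float(np.percentile(m, 75)),
                    p_t=p_t,
                    p_perm=p_perm,
                )
            )
    return out
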