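"""Beta diversity: unweighted UniFrac, PCoA and PERMANOVA.

Unweighted UniFrac is the presence/absence phylogenetic dissimilarity:
the fraction of branch length observed by exactly one of the two
samples, out of the branch length observed by either. A branch is
"observed" by a sample iff any tip below it is present there.

PCoA embeds the dissimilarity matrix via eigendecomposition of the
Gower-centered matrix B = −½ J D∘D J with J = I − 11ᵀ/n. PERMANOVA
follows Anderson's sum-of-squares partition of the distance matrix with
a seeded whole-label permutation null.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, to_relative_abundance
from .trees import PhyloTree

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "unweighted_unifrac",
    "distance_matrix",
    "pcoa",
    "permanova",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(map(str, df.index)), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA coordinates and eigenvalue spectrum.

    ``coordinates`` has one row per sample and one column per retained
    (positive-eigenvalue) axis, ordered by non-increasing eigenvalue.
    ``eigenvalues`` includes the full spectrum (negatives reported but
    not embedded); ``proportion_explained`` is relative to the positive
    eigenvalue sum.
    """

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "pseudo_F": self.pseudo_f,
                "p_value": self.p_value,
                "n_permutations": self.n_permutations,
                "group_sizes": self.group_sizes,
                "seed": self.seed,
            },
            indent=2,
        )


def unweighted_unifrac(
    presence_a: set[str] | frozenset[str],
    presence_b: set[str] | frozenset[str],
    tree: PhyloTree,
) -> float:
    """Unweighted UniFrac dissimilarity between two presence sets.

    Both sets must be subsets of the tree's tips; identical sets give 0,
    tip-disjoint sets on a star tree give 1.
    """
    if not presence_a and not presence_b:
        raise ValueError("both presence sets are empty")
    mask_a = tree.tip_mask(presence_a)
    mask_b = tree.tip_mask(presence_b)
    obs_a = tree.branch_tip_masks @ mask_a > 0
    obs_b = tree.branch_tip_masks @ mask_b > 0
    either = obs_a | obs_b
    unique = obs_a ^ obs_b
    denom = tree.branch_lengths[either].sum()
    if denom == 0:
        return 0.0
    return float(tree.branch_lengths[unique].sum() / denom)


def distance_matrix(table: FeatureTable, tree: PhyloTree) -> DistanceMatrix:
    """All-pairs unweighted UniFrac over the samples of a feature table."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    # branch observation matrix per sample, then vectorized pair loop
    presence = table.counts > 0  # samples x features
    idx = {n: i for i, n in enumerate(tree.tip_names)}
    missing = set(table.feature_ids) - set(tree.tip_names)
    missing_present = {
        fid
        for j, fid in enumerate(table.feature_ids)
        if fid in missing and presence[:, j].any()
    }
    if missing_present:
        raise ValueError(
            f"tree lacks tips for observed features: {sorted(missing_present)}"
        )
    tip_presence = np.zeros((table.n_samples, tree.n_tips), dtype=bool)
    for j, fid in enumerate(table.feature_ids):
        if fid in idx:
            tip_presence[:, idx[fid]] = presence[:, j]
    observed = tip_presence @ tree.branch_tip_masks.T > 0  # samples x branches
    n = table.n_samples
    d = np.zeros((n, n))
    L = tree.branch_lengths
    for i in range(n):
        for j in range(i + 1, n):
            either = observed[i] | observed[j]
            denom = L[either].sum()
            if denom == 0:
                raise ValueError(
                    f"samples {table.sample_ids[i]!r}/{table.sample_ids[j]!r} "
                    "observe no branch length"
                )
            d[i, j] = d[j, i] = L[observed[i] ^ observed[j]].sum() / denom
    return DistanceMatrix(table.sample_ids, d)


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis by Gower double centering.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); axes with
    eigenvalue below `eig_tol` (relative to the largest) are dropped.
    Axis signs are fixed so the largest-magnitude loading is positive.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = eig_tol * max(abs(eigvals[0]), 1e-300)
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    pos_sum = eigvals[eigvals > 0].sum()
    prop = np.where(eigvals > 0, eigvals / pos_sum, 0.0)[keep] if pos_sum > 0 else (
        np.zeros(int(keep.sum()))
    )
    return OrdinationResult(d.sample_ids, coords, eigvals, prop)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.nonzero(codes == g)[0]
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_among = ss_total - ss_within
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    labels: dict[str, str] | list[str],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA with whole-label permutations.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm), so the
    smallest attainable p is 1/(n_perm + 1). Labels may be a per-sample
    list (in matrix order) or a sample_id -> group mapping. With
    ``exhaustive=True`` every distinct relabeling is enumerated instead
    of sampling (only feasible for small cohorts); the reported p is
    then exact.
    """
    if isinstance(labels, dict):
        labels = [labels[s] for s in d.sample_ids]
    labels = list(labels)
    if len(labels) != len(d.sample_ids):
        raise ValueError("one label per sample required")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: labels.count(g) for g in groups}
    if min(sizes.values()) < 2:
        small = [g for g, c in sizes.items() if c < 2]
        raise ValueError(f"group(s) with < 2 samples: {small}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    code_of = {g: i for i, g in enumerate(groups)}
    codes = np.asarray([code_of[g] for g in labels])
    d2 = d.values**2
    f_obs = _pseudo_f(d2, codes, len(groups))
    if exhaustive:
        distinct = sorted({p for p in itertools.permutations(codes)})
        hits = sum(
            _pseudo_f(d2, np.asarray(p), len(groups)) >= f_obs - 1e-12
            for p in distinct
        )
        # identity permutation is among the enumerated relabelings, so the
        # +1/+1 convention is already built in
        return PermanovaResult(
            float(f_obs), hits / len(distinct), len(distinct) - 1, sizes, seed
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(groups)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(p), n_perm, sizes, seed)
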