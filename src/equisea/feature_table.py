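"""Per-kingdom feature-count tables, taxonomy maps, and their transforms.

The central object is :class:`FeatureTable`: a samples x features matrix
of non-negative integer counts (zOTUs for bacteria/archaea, 97% OTUs for
fungi), tagged by kingdom. Views derived from it — relative abundance,
prevalence-filtered, rank-collapsed — feed every downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "FeatureTable",
    "TaxonomyMap",
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "to_relative_abundance",
    "prevalence_filter",
    "collapse_taxonomy",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

KINGDOMS = ("bacteria", "archaea", "fungi")


@dataclass(frozen=True, eq=False)
class FeatureTable:
    """Non-negative integer counts, samples (rows) x features (columns)."""

    kingdom: str
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    counts: np.ndarray  # int64, shape (n_samples, n_features)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.kingdom == other.kingdom
            and self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValueError("table needs at least one sample and one feature")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            s, f = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[s]!r}, "
                f"feature {self.feature_ids[f]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        """Subset/reorder the sample axis."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        rows = [index[s] for s in sample_ids]
        return FeatureTable(
            self.kingdom, tuple(sample_ids), self.feature_ids, self.counts[rows]
        )

    def presence_set(self, sample_id: str) -> frozenset[str]:
        """Feature ids with count > 0 in the given sample."""
        i = self.sample_ids.index(sample_id)
        nz = np.nonzero(self.counts[i])[0]
        return frozenset(self.feature_ids[j] for j in nz)


class TaxonomyMap:
    """feature_id -> ranked lineage (kingdom..species; missing ranks allowed).

    Lineages are stored as tuples aligned with :data:`RANKS`; trailing or
    internal missing ranks are ``None``.
    """

    def __init__(self, lineages: dict[str, tuple[str | None, ...]]):
        self._lineages: dict[str, tuple[str | None, ...]] = {}
        for fid, lineage in lineages.items():
            lineage = tuple(lineage) + (None,) * (len(RANKS) - len(lineage))
            if len(lineage) != len(RANKS):
                raise ValueError(f"lineage for {fid!r} longer than {len(RANKS)} ranks")
            self._lineages[fid] = lineage

    def __contains__(self, fid: str) -> bool:
        return fid in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def lineage(self, fid: str) -> tuple[str | None, ...]:
        return self._lineages[fid]

    def prefix(self, fid: str, rank: str) -> tuple[str, ...]:
        """Lineage prefix up to and including `rank`, with missing ranks
        rendered as 'unclassified'."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
        depth = RANKS.index(rank) + 1
        lineage = self._lineages.get(fid)
        if lineage is None:
            return ("unclassified",) * depth
        return tuple(x if x is not None else "unclassified" for x in lineage[:depth])


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV: feature_id <tab> semicolon-delimited lineage."""
    lineages: dict[str, tuple[str | None, ...]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
        fid, lineage_str = parts
        if fid in lineages:
            raise ValueError(f"{path}:{line_no}: duplicate feature id {fid!r}")
        ranks = tuple(
            tok.strip() or None for tok in lineage_str.strip().split(";")
        )
        lineages[fid] = ranks
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    lines = []
    for fid in sorted(taxonomy._lineages):
        lineage = taxonomy._lineages[fid]
        trimmed = [x for x in lineage]
        while trimmed and trimmed[-1] is None:
            trimmed.pop()
        lines.append(fid + "\t" + ";".join(x or "" for x in trimmed))
    Path(path).write_text("\n".join(lines) + "\n")


def read_feature_table(
    path: str | Path,
    kingdom: str,
    format: str = "tsv",
    samples_in: str = "auto",
    known_sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Read a feature table from TSV or BIOM-style JSON.

    TSV orientation (samples in rows vs columns) is auto-detected by id
    overlap with `known_sample_ids` when given; otherwise rows are taken
    as samples. Override with ``samples_in='rows'|'columns'``.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if samples_in == "auto" and known_sample_ids is not None:
            known = set(known_sample_ids)
            row_hits = len(known & set(map(str, df.index)))
            col_hits = len(known & set(map(str, df.columns)))
            samples_in = "columns" if col_hits > row_hits else "rows"
        if samples_in == "columns":
            df = df.T
        elif samples_in not in ("rows", "auto"):
            raise ValueError(f"samples_in must be rows/columns/auto, got {samples_in!r}")
        values = df.to_numpy()
        bad = ~np.isfinite(values.astype(float)) | (np.mod(values.astype(float), 1) != 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-integer cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        neg = values.astype(float) < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValueError(
                f"negative cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        return FeatureTable(
            kingdom,
            tuple(map(str, df.index)),
            tuple(map(str, df.columns)),
            values.astype(np.int64),
        )
    if format in ("biom", "biom-style"):
        return _read_biom_json(path, kingdom)
    raise ValueError(f"unknown feature-table format {format!r}")


def _read_biom_json(path: str | Path, kingdom: str) -> FeatureTable:
    """Minimal BIOM 1.0 JSON reader (dense or sparse matrix_type).

    BIOM stores the matrix as observations (features) x samples; it is
    transposed here to the package's samples x features orientation.
    """
    doc = json.loads(Path(path).read_text())
    feature_ids = tuple(str(row["id"]) for row in doc["rows"])
    sample_ids = tuple(str(col["id"]) for col in doc["columns"])
    shape = tuple(doc["shape"])
    if shape != (len(feature_ids), len(sample_ids)):
        raise ValueError("BIOM shape inconsistent with rows/columns")
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return FeatureTable(kingdom, sample_ids, feature_ids, mat.T)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write samples-in-rows TSV; round-trips through read_feature_table."""
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def to_relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Row-normalize counts to proportions; every row sums to 1.

    All-zero samples are an error (a sample with no reads carries no
    compositional information).
    """
    totals = table.counts.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total count: {[table.sample_ids[i] for i in zero]}"
        )
    props = table.counts / totals[:, None]
    return pd.DataFrame(
        props, index=list(table.sample_ids), columns=list(table.feature_ids)
    )


def prevalence_filter(
    table: FeatureTable, min_prevalence: float = 0.2
) -> tuple[FeatureTable, list[str]]:
    """Drop features present (count > 0) in less than `min_prevalence` of
    samples; the boundary is inclusive (exactly 20% of samples is kept).

    Returns the filtered table and the list of removed feature ids.
    """
    if not (0 < min_prevalence <= 1):
        raise ValueError("min_prevalence must be in (0, 1]")
    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise ValueError(
            f"prevalence filter at {min_prevalence} removed every feature"
        )
    removed = [fid for fid, k in zip(table.feature_ids, keep) if not k]
    kept_ids = tuple(fid for fid, k in zip(table.feature_ids, keep) if k)
    return (
        FeatureTable(table.kingdom, table.sample_ids, kept_ids, table.counts[:, keep]),
        removed,
    )


def collapse_taxonomy(
    table: FeatureTable, taxonomy: TaxonomyMap, rank: str
) -> FeatureTable:
    """Sum counts over features sharing the lineage prefix up to `rank`.

    Unmapped features (and missing ranks) are pooled into 'unclassified'
    lineages rather than dropped, so per-sample totals are conserved
    exactly. Output feature ids are ';'-joined lineage strings.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    groups: dict[str, list[int]] = {}
    for j, fid in enumerate(table.feature_ids):
        key = ";".join(taxonomy.prefix(fid, rank))
        groups.setdefault(key, []).append(j)
    keys = sorted(groups)
    collapsed = np.column_stack(
        [table.counts[:, groups[k]].sum(axis=1) for k in keys]
    )
    return FeatureTable(table.kingdom, table.sample_ids, tuple(keys), collapsed)
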