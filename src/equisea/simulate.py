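"""Synthetic multi-kingdom study generator with known ground truth.

Emulates the statistical structure the analysis assumes, without any
sequence-level realism: an unbalanced two-group cohort (8 healthy vs 4
SEA by default), three kingdoms at very different richness scales
(bacteria-rich, archaea-poor, fungi sparse), overdispersed compositional
counts (Dirichlet-multinomial), log-normal library sizes with a
per-sample multiplicative sampling-fraction bias, structural zeros, and
a small set of planted fold changes whose identity and direction are
returned as ground truth.

The sampling-fraction bias scales each library's total depth, not its
composition, so presence/absence quantities (unweighted UniFrac) are
unaffected while log-count analyses must remove it — isolating the bias
to the stage whose offset estimator is meant to absorb it.

Everything is deterministic under a fixed seed: identical configs give
byte-identical tables, trees, taxonomies and metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .feature_table import FeatureTable, TaxonomyMap, write_feature_table, write_taxonomy
from .phenotyping import CytologyProfile
from .trees import PhyloTree

__all__ = [
    "PlantedEffect",
    "KingdomSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_kingdom",
    "simulate_counts",
    "simulate_cytology",
    "simulate_taxonomy",
    "write_study",
]


@dataclass(frozen=True)
class PlantedEffect:
    """One planted differential taxon: index (into abundance-ranked
    taxa, 0 = most abundant), log2 fold change, and the group whose
    expected proportion is multiplied by 2**log2_fc."""

    taxon_index: int
    log2_fc: float
    group: str  # "HEALTHY" or "SEA"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2_fc):
            raise ValueError("log2 fold change must be finite")


@dataclass(frozen=True)
class KingdomSpec:
    """Per-kingdom community parameters.

    base_lognormal_sd controls rank-abundance skew (log-normal expected
    proportions, sorted descending so planted indices are
    interpretable); overdispersion is the Dirichlet-multinomial
    precision (math.inf = plain multinomial); prevalence_sparsity is the
    expected fraction of taxon-sample pairs forced to structural zero.
    Structural-zero probability rises linearly with a taxon's rarity
    rank (the most abundant taxa are present in every animal, as real
    communities show), averaging prevalence_sparsity across taxa.
    """

    n_taxa: int
    base_lognormal_sd: float = 1.5
    overdispersion: float = 100.0
    prevalence_sparsity: float = 0.2
    planted_effects: tuple[PlantedEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be > 0")
        if not (0 <= self.prevalence_sparsity < 1):
            raise ValueError("prevalence_sparsity must be in [0, 1)")
        for eff in self.planted_effects:
            if not (0 <= eff.taxon_index < self.n_taxa):
                raise ValueError(f"planted index {eff.taxon_index} out of range")


def _default_kingdoms() -> dict[str, KingdomSpec]:
    # richness ordering mirrors the three assays: rich bacteria, a few
    # dozen archaea, sparse mid-sized fungi
    return {
        "bacteria": KingdomSpec(
            n_taxa=500,
            prevalence_sparsity=0.2,
            planted_effects=(
                PlantedEffect(2, 3.0, "SEA"),
                PlantedEffect(5, -3.0, "SEA"),
                PlantedEffect(9, 3.0, "HEALTHY"),
                PlantedEffect(14, -3.0, "HEALTHY"),
            ),
        ),
        "archaea": KingdomSpec(
            n_taxa=30,
            prevalence_sparsity=0.1,
            planted_effects=(PlantedEffect(1, 3.0, "SEA"),),
        ),
        "fungi": KingdomSpec(
            n_taxa=120,
            prevalence_sparsity=0.45,
            planted_effects=(
                PlantedEffect(3, 3.0, "SEA"),
                PlantedEffect(7, 3.0, "HEALTHY"),
            ),
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full study configuration; defaults are the emulated cohort."""

    seed: int = 0
    n_healthy: int = 8
    n_sea: int = 4
    depth_log10_mean: float = 4.5  # ~30k reads median library
    depth_log10_sd: float = 0.2
    sampling_fraction_sd: float = 0.5  # sd of ln(per-sample bias)
    kingdoms: dict[str, KingdomSpec] = field(default_factory=_default_kingdoms)

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_sea < 0:
            raise ValueError("group sizes must be >= 0")
        if self.sampling_fraction_sd < 0:
            raise ValueError("sampling_fraction_sd must be >= 0")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(
            [f"H{i + 1}" for i in range(self.n_healthy)]
            + [f"S{i + 1}" for i in range(self.n_sea)]
        )

    @property
    def groups(self) -> dict[str, str]:
        return {
            s: ("HEALTHY" if s.startswith("H") else "SEA") for s in self.sample_ids
        }


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    kingdom: str
    taxon_ids: tuple[str, ...]
    group_proportions: dict[str, np.ndarray]  # group -> expected proportions
    sample_fractions: dict[str, float]  # sample -> multiplicative depth bias
    planted: tuple[tuple[str, str], ...]  # (taxon_id, group-with-higher-abundance)
    tree_newick: str


def simulate_tree(n_tips: int, seed: int) -> PhyloTree:
    """Yule (pure-birth) topology with exponential branch lengths.

    Tips are labeled t0001.. in a seed-determined order, so the same
    seed always yields the same Newick string.
    """
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    root.length = None
    tips = [root]
    for _ in range(n_tips - 1):
        parent = tips.pop(int(rng.integers(len(tips))))
        left, right = TreeNode(), TreeNode()
        parent.extend([left, right])
        tips.extend([left, right])
    for i, tip in enumerate(tips):
        tip.name = f"t{i + 1:04d}"
    for node in root.postorder(include_self=False):
        node.length = float(rng.exponential(0.1)) + 1e-6
    if n_tips == 1:
        root.name = "t0001"
        root.length = None
    return PhyloTree(root)


def simulate_taxonomy(kingdom: str, taxon_ids: tuple[str, ...], seed: int) -> TaxonomyMap:
    """Rank-correct placeholder lineages with nested structure.

    Taxa are grouped bottom-up (unique species, ~2 species per genus,
    ~3 genera per family, ...), giving collapse operations something
    real to merge. A random tenth of taxa lack genus/species ranks.
    """
    rng = np.random.default_rng(seed)
    widths = (2, 3, 2, 2, 3)  # species->genus, genus->family, ..., class->phylum
    lineages = {}
    for i, fid in enumerate(taxon_ids):
        ids = [i]
        for w in widths:
            ids.append(ids[-1] // w)
        # ids: species, genus, family, order, class, phylum indices
        lineage = [
            kingdom,
            f"{kingdom[:3]}_phy{ids[5]}",
            f"{kingdom[:3]}_cls{ids[4]}",
            f"{kingdom[:3]}_ord{ids[3]}",
            f"{kingdom[:3]}_fam{ids[2]}",
            f"{kingdom[:3]}_gen{ids[1]}",
            f"{kingdom[:3]}_sp{ids[0]}",
        ]
        if rng.random() < 0.1:  # unassigned at fine ranks
            lineage[5] = None
            lineage[6] = None
        lineages[fid] = tuple(lineage)
    return TaxonomyMap(lineages)


def _base_proportions(n_taxa: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    raw = np.exp(rng.normal(0.0, sd, size=n_taxa))
    raw = np.sort(raw)[::-1]
    return raw / raw.sum()


def simulate_kingdom(
    spec: KingdomSpec,
    config: SimulationConfig,
    tree: PhyloTree,
    kingdom: str,
    rng: np.random.Generator,
) -> tuple[FeatureTable, GroundTruth]:
    """One kingdom's count table plus its ground truth.

    The tree must have exactly spec.n_taxa tips; tip names become the
    feature ids.
    """
    if tree.n_tips != spec.n_taxa:
        raise ValueError(f"tree has {tree.n_tips} tips, spec wants {spec.n_taxa}")
    taxon_ids = tree.tip_names
    base = _base_proportions(spec.n_taxa, spec.base_lognormal_sd, rng)
    group_props: dict[str, np.ndarray] = {}
    for group in ("HEALTHY", "SEA"):
        p = base.copy()
        for eff in spec.planted_effects:
            if eff.group == group:
                p[eff.taxon_index] *= 2.0**eff.log2_fc
        group_props[group] = p / p.sum()
    planted = []
    for eff in spec.planted_effects:
        fid = taxon_ids[eff.taxon_index]
        higher = eff.group if eff.log2_fc > 0 else (
            "HEALTHY" if eff.group == "SEA" else "SEA"
        )
        planted.append((fid, higher))

    counts = np.zeros((len(config.sample_ids), spec.n_taxa), dtype=np.int64)
    fractions: dict[str, float] = {}
    # rarity-rank-dependent structural-zero probabilities, mean = sparsity
    ranks = np.arange(spec.n_taxa)
    denom = max(spec.n_taxa - 1, 1)
    p_zero = np.clip(2.0 * spec.prevalence_sparsity * ranks / denom, 0.0, 0.95)
    for i, sid in enumerate(config.sample_ids):
        p = group_props[config.groups[sid]].copy()
        if spec.prevalence_sparsity > 0:
            zero = rng.random(spec.n_taxa) < p_zero
            if zero.all():
                zero[int(np.argmax(p))] = False
            p = np.where(zero, 0.0, p)
            p = p / p.sum()
        if math.isfinite(spec.overdispersion):
            nz = p > 0
            drawn = np.zeros_like(p)
            drawn[nz] = rng.dirichlet(spec.overdispersion * p[nz])
            p = drawn
        depth = 10.0 ** rng.normal(config.depth_log10_mean, config.depth_log10_sd)
        frac = float(np.exp(rng.normal(0.0, config.sampling_fraction_sd)))
        fractions[sid] = frac
        total = max(1, int(round(depth * frac)))
        counts[i] = rng.multinomial(total, p)
    table = FeatureTable(kingdom, config.sample_ids, taxon_ids, counts)
    truth = GroundTruth(
        kingdom=kingdom,
        taxon_ids=taxon_ids,
        group_proportions=group_props,
        sample_fractions=fractions,
        planted=tuple(planted),
        tree_newick=tree.to_newick(),
    )
    return table, truth


def simulate_counts(
    config: SimulationConfig,
    trees: dict[str, PhyloTree] | None = None,
) -> dict[str, tuple[FeatureTable, GroundTruth]]:
    """Simulate every configured kingdom; trees are generated from the
    config seed unless supplied."""
    out = {}
    for offset, (kingdom, spec) in enumerate(sorted(config.kingdoms.items())):
        sub_seed = (config.seed * 10007 + 101 * offset) % (2**31)
        tree = (
            trees[kingdom]
            if trees is not None and kingdom in trees
            else simulate_tree(spec.n_taxa, sub_seed)
        )
        rng = np.random.default_rng(sub_seed + 1)
        out[kingdom] = simulate_kingdom(spec, config, tree, kingdom, rng)
    return out


def simulate_cytology(n_healthy: int, n_sea: int, seed: int) -> list[CytologyProfile]:
    """Cytology metadata consistent with the enrollment rules.

    Healthy: neutrophils 1-5%, eosinophils 0-1%, mast cells 0-2%, no
    signs. SEA: neutrophils 20-50% with respiratory signs. Every profile
    classifies to its intended label under the default thresholds.
    """
    if n_healthy < 0 or n_sea < 0:
        raise ValueError("group sizes must be >= 0")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_healthy):
        profiles.append(
            CytologyProfile(
                animal_id=f"H{i + 1}",
                neutrophil_pct=int(rng.integers(1, 6)),
                eosinophil_pct=int(rng.integers(0, 2)),
                mastcell_pct=int(rng.integers(0, 3)),
                respiratory_signs=False,
                illness_signs=False,
            )
        )
    for i in range(n_sea):
        profiles.append(
            CytologyProfile(
                animal_id=f"S{i + 1}",
                neutrophil_pct=int(rng.integers(20, 51)),
                eosinophil_pct=int(rng.integers(0, 4)),
                mastcell_pct=int(rng.integers(0, 3)),
                respiratory_signs=True,
                illness_signs=True,
            )
        )
    return profiles


def write_study(config: SimulationConfig, outdir: str | Path) -> Path:
    """Materialize a complete toy study directory.

    Writes metadata.tsv plus, per kingdom, <k>_counts.tsv,
    <k>_taxonomy.tsv and <k>_tree.nwk — the same formats the readers in
    this package ingest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = simulate_cytology(config.n_healthy, config.n_sea, config.seed)
    lines = [
        "animal_id\tneutrophil_pct\teosinophil_pct\tmastcell_pct\t"
        "respiratory_signs\tillness_signs"
    ]
    for p in profiles:
        lines.append(
            f"{p.animal_id}\t{p.neutrophil_pct}\t{p.eosinophil_pct}\t"
            f"{p.mastcell_pct}\t{str(p.respiratory_signs).lower()}\t"
            f"{str(p.illness_signs).lower()}"
        )
    (outdir / "metadata.tsv").write_text("\n".join(lines) + "\n")
    for kingdom, (table, truth) in simulate_counts(config).items():
        write_feature_table(table, outdir / f"{kingdom}_counts.tsv")
        (outdir / f"{kingdom}_tree.nwk").write_text(truth.tree_newick)
        taxonomy = simulate_taxonomy(kingdom, truth.taxon_ids, config.seed)
        write_taxonomy(taxonomy, outdir / f"{kingdom}_taxonomy.tsv")
    return outdir
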