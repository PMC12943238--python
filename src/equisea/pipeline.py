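"""End-to-end per-kingdom orchestration.

Stage order, per kingdom and independently (the three assays share only
the animal metadata): phenotype assignment (excluded animals dropped
before any microbiota computation) → alpha diversity + group comparison
→ unweighted UniFrac / PCoA / PERMANOVA → differential-abundance screen
and combination resampling at each configured rank → top-phyla summary.

All randomness flows from the seed recorded in the report; rerunning an
identical config over identical inputs writes byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_metrics_table, compare_alpha
from .beta import distance_matrix, pcoa, permanova
from .da import ScreenConfig, combination_summaries, da_screen, enumerate_subsets
from .feature_table import (
    FeatureTable,
    TaxonomyMap,
    collapse_taxonomy,
    read_feature_table,
    read_taxonomy,
    to_relative_abundance,
)
from .phenotyping import (
    PhenotypeConfig,
    PhenotypeLabel,
    assign_groups,
    read_cytology_metadata,
    write_assignments,
)
from .trees import PhyloTree, read_tree

logger = logging.getLogger("equisea")

__all__ = ["KingdomPaths", "PipelineConfig", "run_pipeline", "summarize_phyla", "significance_stars"]

ALPHA_METRICS = ("richness", "shannon", "hill1", "phylo_hill1")


def significance_stars(p: float) -> str:
    """Star banding used in report annotations (p <= 0.05 is ``*``)."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class KingdomPaths:
    table: str
    taxonomy: str
    tree: str


@dataclass(frozen=True)
class PipelineConfig:
    metadata: str
    kingdoms: dict[str, KingdomPaths]
    output_dir: str
    seed: int = 0
    phenotype: PhenotypeConfig = field(default_factory=PhenotypeConfig)
    ranks: tuple[str, ...] = ("genus", "species")
    min_prevalence: float = 0.2
    screen_alpha: float = 0.05
    pseudocount: float = 1.0
    n_perm: int = 999
    top_k_phyla: int = 7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        kingdoms = {
            name: KingdomPaths(**paths) for name, paths in doc.pop("kingdoms").items()
        }
        phenotype = PhenotypeConfig(**doc.pop("phenotype", {}))
        ranks = tuple(doc.pop("ranks", ("genus", "species")))
        return cls(kingdoms=kingdoms, phenotype=phenotype, ranks=ranks, **doc)

    def canonical_json(self) -> str:
        """Deterministic JSON of the analysis-relevant settings.

        The output location is excluded so that the same analysis written
        to two different directories yields identical reports.
        """

        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        doc = dataclasses.asdict(self)
        doc.pop("output_dir")
        return json.dumps(doc, sort_keys=True, default=enc)


def summarize_phyla(
    table: FeatureTable, taxonomy: TaxonomyMap, top_k: int = 7
) -> pd.DataFrame:
    """Per-sample relative abundance of the top-k phyla plus 'other'.

    Phyla are ranked by grand-mean relative abundance across samples;
    everything outside the top k is pooled. Rows sum to 1.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    phylum_table = collapse_taxonomy(table, taxonomy, "phylum")
    rel = to_relative_abundance(phylum_table)
    ranking = rel.mean(axis=0).sort_values(ascending=False)
    top = list(ranking.index[:top_k])
    out = rel[top].copy()
    rest = [c for c in rel.columns if c not in top]
    if rest:
        out["other"] = rel[rest].sum(axis=1)
    return out


def _comparison_record(comp, group_names) -> dict:
    return {
        "metric": comp.metric,
        "groups": list(group_names),
        "means": list(comp.means),
        "sems": list(comp.sems),
        "t": comp.t_statistic,
        "p": comp.p_value,
        "n": list(comp.group_sizes),
        "test": "welch_t_two_sided",
        "stars": significance_stars(comp.p_value),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study; returns the report dict (also written as
    report.json under the output directory)."""
    t0 = time.monotonic()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    profiles = read_cytology_metadata(config.metadata)
    assignment, counts = assign_groups(profiles, config.phenotype)
    write_assignments(
        assignment, counts, outdir / "assignments.tsv", outdir / "group_counts.json"
    )
    healthy = [a for a, l in assignment.items() if l is PhenotypeLabel.HEALTHY]
    sea = [a for a, l in assignment.items() if l is PhenotypeLabel.SEA]
    groups = {a: "HEALTHY" for a in healthy} | {a: "SEA" for a in sea}
    enrolled = healthy + sea
    if len(healthy) < 2 or len(sea) < 2:
        raise ValueError(
            f"need >= 2 animals per group after exclusion, got "
            f"{len(healthy)} healthy / {len(sea)} SEA"
        )
    logger.info(
        "phenotyping: %d healthy, %d SEA, %d excluded",
        len(healthy), len(sea), counts[PhenotypeLabel.EXCLUDED],
    )

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(
                config.canonical_json().encode()
            ).hexdigest(),
        },
        "groups": {
            "assignment": {a: l.value for a, l in assignment.items()},
            "counts": {l.value: c for l, c in counts.items()},
        },
        "kingdoms": {},
    }

    for kingdom in sorted(config.kingdoms):
        t_k = time.monotonic()
        paths = config.kingdoms[kingdom]
        table = read_feature_table(
            paths.table, kingdom, known_sample_ids=list(assignment)
        )
        table = table.select_samples([s for s in table.sample_ids if s in groups])
        missing = set(enrolled) - set(table.sample_ids)
        if missing:
            raise ValueError(f"{kingdom}: table lacks enrolled samples {sorted(missing)}")
        taxonomy = read_taxonomy(paths.taxonomy)
        tree = read_tree(paths.tree)
        section: dict = {}

        # alpha diversity on the unfiltered feature table
        metrics = alpha_metrics_table(table, tree)
        metrics.to_csv(outdir / f"{kingdom}_alpha_metrics.tsv", sep="\t")
        alpha_rows = []
        for metric in ALPHA_METRICS:
            comp = compare_alpha(
                metrics.loc[healthy, metric],
                metrics.loc[sea, metric],
                metric=metric,
                group_names=("HEALTHY", "SEA"),
            )
            alpha_rows.append(_comparison_record(comp, ("HEALTHY", "SEA")))
        pd.DataFrame(alpha_rows).to_csv(
            outdir / f"{kingdom}_alpha_comparisons.tsv", sep="\t", index=False
        )
        section["alpha"] = alpha_rows

        # beta diversity on the unfiltered table (presence/absence)
        dm = distance_matrix(table, tree)
        dm.write_tsv(outdir / f"{kingdom}_unifrac.tsv")
        ord_res = pcoa(dm)
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=list(dm.sample_ids),
            columns=[f"PCo{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        coords.to_csv(outdir / f"{kingdom}_pcoa.tsv", sep="\t", index_label="sample_id")
        perma = permanova(dm, groups, n_perm=config.n_perm, seed=config.seed)
        (outdir / f"{kingdom}_permanova.json").write_text(perma.to_json() + "\n")
        section["permanova"] = {
            "pseudo_F": perma.pseudo_f,
            "p": perma.p_value,
            "n_permutations": perma.n_permutations,
            "seed": perma.seed,
            "test": "permanova_unweighted_unifrac",
            "n": len(enrolled),
            "stars": significance_stars(perma.p_value),
        }
        section["pcoa"] = {
            "proportion_explained": ord_res.proportion_explained[:2].tolist()
        }

        # differential abundance per rank: screen + combination resampling
        plans = {
            "HEALTHY": enumerate_subsets(sorted(healthy), 3),
            "SEA": enumerate_subsets(sorted(sea), 3),
        }
        section["differential_abundance"] = {}
        for rank in config.ranks:
            cfg = ScreenConfig(
                rank=rank,
                min_prevalence=config.min_prevalence,
                alpha=config.screen_alpha,
                pseudocount=config.pseudocount,
            )
            candidates = da_screen(table, groups, cfg, taxonomy)
            cand_df = pd.DataFrame(
                [
                    {
                        "taxon": c.taxon,
                        "effect_ln": c.effect,
                        "t": c.statistic,
                        "p_unadjusted": c.p_value,
                        "direction": c.direction,
                    }
                    for c in candidates
                ]
            )
            cand_df.to_csv(
                outdir / f"{kingdom}_da_candidates_{rank}.tsv", sep="\t", index=False
            )
            # combination stage uses relative abundance of the collapsed,
            # unfiltered table
            rel = to_relative_abundance(collapse_taxonomy(table, taxonomy, rank))
            summaries = combination_summaries(
                rel, candidates, plans, n_perm=config.n_perm, seed=config.seed
            )
            summ_df = pd.DataFrame(
                [
                    {
                        "taxon": s.taxon,
                        "group": s.group,
                        "n_subsets": len(s.means),
                        "median": s.median,
                        "q1": s.q1,
                        "q3": s.q3,
                        "p_t": s.p_t,
                        "p_perm": s.p_perm,
                        "stars_t": significance_stars(s.p_t),
                    }
                    for s in summaries
                ]
            )
            summ_df.to_csv(
                outdir / f"{kingdom}_combinations_{rank}.tsv", sep="\t", index=False
            )
            section["differential_abundance"][rank] = {
                "n_candidates": len(candidates),
                "candidates": cand_df.to_dict(orient="records"),
                "combination_summaries": summ_df.to_dict(orient="records"),
                "config": dataclasses.asdict(cfg),
            }

        phyla = summarize_phyla(table, taxonomy, config.top_k_phyla)
        phyla.to_csv(outdir / f"{kingdom}_top_phyla.tsv", sep="\t", index_label="sample_id")
        section["top_phyla"] = list(phyla.columns)
        report["kingdoms"][kingdom] = section
        logger.info("%s: done in %.1fs", kingdom, time.monotonic() - t_k)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete in %.1fs", time.monotonic() - t0)
    return report
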