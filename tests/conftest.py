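import numpy as np
import pytest

from equisea.feature_table import FeatureTable
from equisea.phenotyping import CytologyProfile
from equisea.trees import PhyloTree, tree_from_newick

# The study's 12-horse BALF differential cytology (neutrophil,
# eosinophil, mast-cell percentages). Sign flags follow the enrollment
# narrative: SEA horses presented respiratory signs, healthy horses had
# no signs of illness.
CYTOLOGY_ROWS = [
    ("H1", 1, 1, 1), ("H2", 1, 0, 2), ("H3", 1, 0, 1), ("H4", 2, 1, 1),
    ("H5", 1, 1, 1), ("H6", 5, 0, 1), ("H7", 1, 1, 1), ("H8", 2, 1, 1),
    ("S1", 27, 0, 2), ("S2", 23, 3, 0), ("S3", 26, 0, 1), ("S4", 47, 0, 1),
]


@pytest.fixture(scope="session")
def cohort_profiles() -> list[CytologyProfile]:
    return [
        CytologyProfile(
            animal_id=aid,
            neutrophil_pct=neut,
            eosinophil_pct=eos,
            mastcell_pct=mast,
            respiratory_signs=aid.startswith("S"),
            illness_signs=aid.startswith("S"),
        )
        for aid, neut, eos, mast in CYTOLOGY_ROWS
    ]


@pytest.fixture(scope="session")
def balanced_tree() -> PhyloTree:
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def star_tree(n: int, length: float = 1.0) -> PhyloTree:
    newick = "(" + ",".join(f"t{i}:{length}" for i in range(n)) + ");"
    return tree_from_newick(newick)


def small_table(counts, kingdom="bacteria", sample_prefix="s", feature_prefix="f"):
    counts = np.asarray(counts)
    return FeatureTable(
        kingdom,
        tuple(f"{sample_prefix}{i}" for i in range(counts.shape[0])),
        tuple(f"{feature_prefix}{j}" for j in range(counts.shape[1])),
        counts,
    )


def random_bifurcating_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random topology with random branch lengths, built by repeated
    joining — an independent construction from the package's Yule
    generator."""
    nodes = [f"x{i}:{rng.uniform(0.1, 2.0):.6f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return inner + ";"
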