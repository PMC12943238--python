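"""Rooted phylogenies over feature identifiers.

Trees arrive as Newick with branch lengths (the product of upstream
phylogeny estimation over representative sequences). Parsing and
midpoint rooting are delegated to scikit-bio; this module wraps the
result with the branch/tip bookkeeping that unweighted UniFrac and
phylogenetic Hill numbers need: for every branch, its length and the set
of tips below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

__all__ = ["PhyloTree", "read_tree", "tree_from_newick"]


@dataclass
class PhyloTree:
    """A rooted tree with validated non-negative branch lengths.

    ``branch_lengths[k]`` and ``branch_tip_masks[k]`` describe branch k:
    its length and a boolean mask (over ``tip_names`` order) of the tips
    in the subtree below it. The root itself carries no branch.
    """

    tree: TreeNode
    tip_names: tuple[str, ...] = field(init=False)
    branch_lengths: np.ndarray = field(init=False)
    branch_tip_masks: np.ndarray = field(init=False)  # (n_branches, n_tips) bool

    def __post_init__(self) -> None:
        # a childless root is itself the single tip
        tips = list(self.tree.tips()) or [self.tree]
        names = [t.name for t in tips]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip labels in tree")
        if any(n is None for n in names):
            raise ValueError("unlabeled tip in tree")
        self.tip_names = tuple(names)
        tip_index = {n: i for i, n in enumerate(names)}

        lengths: list[float] = []
        masks: list[np.ndarray] = []
        # postorder guarantees children are visited before parents
        below: dict[int, np.ndarray] = {}
        for node in self.tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(names), dtype=bool)
                mask[tip_index[node.name]] = True
            else:
                mask = np.zeros(len(names), dtype=bool)
                for child in node.children:
                    mask |= below[id(child)]
            below[id(node)] = mask
            if node.is_root():
                continue
            if node.length is None or not np.isfinite(node.length):
                raise ValueError(
                    f"branch above {node.name or 'internal node'} has no finite length"
                )
            if node.length < 0:
                raise ValueError(
                    f"negative branch length above {node.name or 'internal node'}"
                )
            lengths.append(float(node.length))
            masks.append(mask)
        self.branch_lengths = np.asarray(lengths, dtype=float)
        self.branch_tip_masks = (
            np.vstack(masks) if masks else np.zeros((0, len(names)), dtype=bool)
        )

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def tip_mask(self, names: set[str] | frozenset[str]) -> np.ndarray:
        unknown = set(names) - set(self.tip_names)
        if unknown:
            raise KeyError(f"names not among tree tips: {sorted(unknown)}")
        return np.asarray([n in names for n in self.tip_names], dtype=bool)

    def to_newick(self) -> str:
        return str(self.tree)


def tree_from_newick(newick: str) -> PhyloTree:
    """Build a PhyloTree from a Newick string; midpoint-root if unrooted.

    A basal multifurcation (root with more than two children) is treated
    as an unrooted tree and midpoint-rooted, since UniFrac and
    phylogenetic diversity both require a root.
    """
    tree = TreeNode.read([newick])
    n_children = len(tree.children)
    if n_children > 2 and tree.count(tips=True) > n_children:
        tree = tree.root_at_midpoint()
    return PhyloTree(tree)


def read_tree(path: str | Path) -> PhyloTree:
    """Read a Newick file (see :func:`tree_from_newick`)."""
    return tree_from_newick(Path(path).read_text().strip())
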