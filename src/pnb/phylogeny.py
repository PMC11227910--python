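"""Community phylogeny: Newick parsing, patristic distances, label-permutation nulls.

The tree is consumed, never inferred. All downstream phylogenetic quantities
are derived from the tip-to-tip patristic distance matrix, and the null model
operates on that matrix by permuting the label-to-row assignment, which is
mathematically identical to shuffling species labels across the tips of the
tree itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "PhylogenyError",
    "read_newick",
    "patristic_matrix",
    "permute_labels",
]


class PhylogenyError(ValueError):
    """Raised for malformed trees: parse failures, unlabeled tips, missing branch lengths."""


@dataclass
class Phylogeny:
    """A rooted, tip-labeled tree with branch lengths.

    Attributes
    ----------
    tree : dendropy.Tree
        The underlying tree object.
    tips : list of str
        Tip labels in a stable (taxon namespace) order.
    rooted : bool
        Whether the tree was read as rooted.
    """

    tree: dendropy.Tree
    tips: list[str]
    rooted: bool = True

    @property
    def n_tips(self) -> int:
        return len(self.tips)


@dataclass
class DistanceMatrix:
    """Symmetric patristic distance matrix over an ordered species list.

    ``d[i, j]`` is the sum of branch lengths on the path between tips
    ``labels[i]`` and ``labels[j]``; units follow the tree's branch lengths.
    """

    labels: list[str]
    d: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {lab: i for i, lab in enumerate(self.labels)}
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match label count")
        self.d = d

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"species {label!r} not present in distance matrix") from None

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    @property
    def n(self) -> int:
        return len(self.labels)


def read_newick(source: str) -> Phylogeny:
    """Parse a Newick tree from a string or a file path.

    Every tip must be labeled and every non-root edge must carry a branch
    length >= 0. Polytomies and zero-length branches are allowed.

    Raises
    ------
    PhylogenyError
        On parse failure, unlabeled tips, or missing/negative branch lengths.
    """
    text = source
    if "(" not in text:  # looks like a path, not a Newick string
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise PhylogenyError(f"Newick parse error: {exc}") from exc

    tips: list[str] = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise PhylogenyError("unlabeled tip in Newick tree")
        tips.append(leaf.taxon.label)
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise PhylogenyError(f"duplicate tip labels: {dupes}")

    root = tree.seed_node
    for edge in tree.preorder_edge_iter():
        if edge.head_node is root:
            continue
        if edge.length is None:
            raise PhylogenyError(
                f"missing branch length on edge above "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else 'internal node'}"
            )
        if edge.length < 0:
            raise PhylogenyError("negative branch length")
    return Phylogeny(tree=tree, tips=tips, rooted=True)


def patristic_matrix(phylogeny: Phylogeny) -> DistanceMatrix:
    """Compute all pairwise tip-to-tip path-length distances.

    Requires >= 2 tips. The result is symmetric with a zero diagonal.
    """
    if phylogeny.n_tips < 2:
        raise PhylogenyError("patristic matrix requires at least 2 tips")
    labels = list(phylogeny.tips)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    pdm = phylogeny.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phylogeny.tree.taxon_namespace}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            j = idx[b]
            dist = pdm.patristic_distance(taxa[a], taxa[b])
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=labels, d=d)


def permute_labels(dmat: DistanceMatrix, rng: np.random.Generator) -> DistanceMatrix:
    """Return the matrix under a uniform random permutation of label-to-row assignment.

    The multiset of off-diagonal values is conserved; the labels keep their
    order while the distances among them are those of a random relabeling of
    the tree's tips.
    """
    p = rng.permutation(dmat.n)
    return DistanceMatrix(labels=list(dmat.labels), d=dmat.d[np.ix_(p, p)])


def to_newick(phylogeny: Phylogeny) -> str:
    """Serialize back to a Newick string (one tree, trailing semicolon)."""
    return phylogeny.tree.as_string(schema="newick", suppress_rooting=True).strip()
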