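"""Tree comparison: Robinson–Foulds and quartet distances with their
normalizations, split/tree compatibility tests, and guide-tree rescaling.

Trees are parsed with dendropy and treated as unrooted leaf-labelled
trees for all distance computations.  The quartet distance is computed
by direct enumeration of the C(n, 4) leaf quadruples, which is the
reference algorithm at the tree sizes handled here (n <= ~40).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy

from .errors import FormatError, TaxonMismatchError


@dataclass
class PhyloTree:
    """Unrooted leaf-labelled tree (thin wrapper around a dendropy tree)."""

    _tree: dendropy.Tree

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    @property
    def n(self) -> int:
        return len(self._tree.leaf_nodes())

    def newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side not
        containing the lexicographically smallest leaf label."""
        labels = self.leaves
        anchor = min(labels)
        result = set()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(
                leaf.taxon.label for leaf in node.leaf_iter()
            )
            if len(side) < 2 or len(labels - side) < 2:
                continue
            if anchor in side:
                side = labels - side
            if len(side) >= 2:
                result.add(side)
        return frozenset(result)

    def max_root_to_tip(self) -> float:
        heights = []
        for leaf in self._tree.leaf_node_iter():
            h, node = 0.0, leaf
            while node.parent_node is not None:
                h += node.edge.length or 0.0
                node = node.parent_node
            heights.append(h)
        return max(heights)

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))


def parse_newick(text: str | Path) -> PhyloTree:
    """Parse a Newick string or file into a tree.

    Rooted inputs are accepted; distances treat them as unrooted.
    """
    if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text
                                  and "(" not in text and Path(str(text)).exists()):
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=str(text), schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in Newick input")
    return PhyloTree(tree)


def _check_same_leaves(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.leaves != t2.leaves:
        raise TaxonMismatchError(
            f"leaf sets differ: {sorted(t1.leaves ^ t2.leaves)}"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of non-trivial splits present in exactly one tree."""
    _check_same_leaves(t1, t2)
    return len(t1.splits() ^ t2.splits())


def normalized_rf(d_rf: int, n: int) -> float:
    """d_RF / (2n - 6) for n-leaf trees; defined for n >= 4."""
    if n < 4:
        raise ValueError("normalized RF distance requires n >= 4")
    return d_rf / (2 * n - 6)


def _split_masks(tree: PhyloTree, index: dict[str, int]) -> list[int]:
    masks = []
    for split in tree.splits():
        mask = 0
        for label in split:
            mask |= 1 << index[label]
        masks.append(mask)
    return masks


def _quartet_topologies(masks: Sequence[int], quads: Iterable[tuple[int, ...]]):
    """Induced topology per leaf quadruple: 0 = ab|cd, 1 = ac|bd,
    2 = ad|bc, None = unresolved (star)."""
    out = []
    for a, b, c, d in quads:
        topo = None
        for mask in masks:
            wa = (mask >> a) & 1
            wb = (mask >> b) & 1
            wc = (mask >> c) & 1
            wd = (mask >> d) & 1
            if wa + wb + wc + wd != 2:
                continue
            if wa == wb:
                topo = 0
            elif wa == wc:
                topo = 1
            else:
                topo = 2
            break
        out.append(topo)
    return out


def quartet_distance(t1: PhyloTree, t2: PhyloTree,
                     count_unresolved: bool = True) -> int:
    """Number of leaf quadruples whose induced quartet topologies differ.

    With ``count_unresolved`` (default), a quadruple resolved in one
    tree but star-like in the other counts as a difference; both input
    trees being binary makes the flag moot.
    """
    _check_same_leaves(t1, t2)
    labels = sorted(t1.leaves)
    if len(labels) < 4:
        raise ValueError("quartet distance requires n >= 4")
    index = {label: i for i, label in enumerate(labels)}
    quads = list(combinations(range(len(labels)), 4))
    topo1 = _quartet_topologies(_split_masks(t1, index), quads)
    topo2 = _quartet_topologies(_split_masks(t2, index), quads)
    d = 0
    for x, y in zip(topo1, topo2):
        if x == y:
            continue
        if (x is None or y is None) and not count_unresolved:
            continue
        d += 1
    return d


def quartet_denominator(n: int) -> int:
    """C(n, 4): the number of leaf quadruples, the maximum possible
    quartet distance between two n-leaf trees."""
    if n < 4:
        raise ValueError("quartet denominator requires n >= 4")
    return comb(n, 4)


def normalized_quartet(d_q: int, n: int) -> float:
    """d_Q / C(n, 4) for n-leaf trees; defined for n >= 4."""
    return d_q / quartet_denominator(n)


def splits_compatible_with_tree(
    splits: Sequence[tuple[frozenset[str], frozenset[str]]],
    tree: PhyloTree,
) -> tuple[list[bool], float]:
    """Check presence|absence splits against a tree's bipartitions.

    Each query split is a (presence, absence) pair over a subset of the
    tree's leaves; taxa outside the pair are treated as missing and the
    tree's splits are restricted to the non-missing taxa before
    comparison.  A split is compatible when it equals some restricted
    branch bipartition or is trivial after restriction.  Returns the
    per-split verdicts and the compatible fraction (1.0 for no splits).
    """
    leaves = tree.leaves
    tree_splits = tree.splits()
    verdicts = []
    for presence, absence in splits:
        observed = presence | absence
        if not observed <= leaves:
            raise TaxonMismatchError(
                f"split taxa {sorted(observed - leaves)} not in tree"
            )
        if len(presence) <= 1 or len(absence) <= 1:
            verdicts.append(True)
            continue
        ok = False
        for side in tree_splits:
            restricted = side & observed
            if restricted == presence or restricted == absence:
                ok = True
                break
        verdicts.append(ok)
    fraction = sum(verdicts) / len(verdicts) if verdicts else 1.0
    return verdicts, fraction


def rescale_tree(tree: PhyloTree, target_height: float) -> PhyloTree:
    """Scale all branch lengths so the maximum root-to-tip distance
    equals ``target_height`` (rooted interpretation for the height)."""
    height = tree.max_root_to_tip()
    if height <= 0:
        raise ValueError("tree has zero height; cannot rescale")
    factor = target_height / height
    scaled = tree.clone()
    for edge in scaled._tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return scaled
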