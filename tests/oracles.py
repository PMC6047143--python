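"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the library's code paths: gap runs are found by
character-wise column scanning, loci by explicit pairwise-overlap BFS,
and the acceptance rules are applied literally to the enumerated sets.
"""

from __future__ import annotations

from itertools import combinations

RESIDUES = set("ACGTN")


def scan_runs(rows: dict[str, str]) -> dict[tuple[int, int], set[str]]:
    """Endpoint classes of maximal gap runs, by exhaustive scanning."""
    classes: dict[tuple[int, int], set[str]] = {}
    for taxon, row in rows.items():
        start = None
        for i, ch in enumerate(row + "X"):  # sentinel terminates a final run
            if ch == "-":
                if start is None:
                    start = i
            else:
                if start is not None:
                    classes.setdefault((start, i), set()).add(taxon)
                    start = None
    return classes


def _components(intervals: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Connected components of the column-overlap graph via BFS."""
    def overlap(u, v):
        return u[0] < v[1] and v[0] < u[1]

    unvisited = set(range(len(intervals)))
    components = []
    while unvisited:
        queue = [unvisited.pop()]
        comp = []
        while queue:
            i = queue.pop()
            comp.append(i)
            linked = [j for j in unvisited if overlap(intervals[i], intervals[j])]
            for j in linked:
                unvisited.remove(j)
            queue.extend(linked)
        components.append(sorted(intervals[i] for i in comp))
    return components


def code(rows: dict[str, str], universe: list[str],
         cols: tuple[int, int]) -> tuple[frozenset, frozenset, frozenset]:
    start, end = cols
    presence, absence, missing = set(), set(), set()
    for taxon in universe:
        if taxon not in rows:
            missing.add(taxon)
            continue
        row = rows[taxon]
        segment = row[start:end]
        if all(ch in RESIDUES for ch in segment):
            absence.add(taxon)
        elif (all(ch == "-" for ch in segment)
              and (start == 0 or row[start - 1] != "-")
              and (end == len(row) or row[end] != "-")):
            presence.add(taxon)
        else:
            missing.add(taxon)
    return frozenset(presence), frozenset(absence), frozenset(missing)


def extract(rows: dict[str, str], min_size: int = 2,
            max_size: int | None = None, mode: str = "strict",
            universe: list[str] | None = None) -> set:
    """Literal rule application; returns a set of
    (start, end, presence, absence, missing) tuples."""
    universe = universe if universe is not None else sorted(rows)
    classes = scan_runs(rows)
    accepted = []
    for comp in _components(list(classes)):
        candidates = [
            iv for iv in comp
            if len(classes[iv]) >= 2 and iv[1] - iv[0] >= min_size
            and (max_size is None or iv[1] - iv[0] <= max_size)
        ]
        survivors = []
        for iv in candidates:
            if any(iv != other and iv[0] < other[1] and other[0] < iv[1]
                   for other in candidates):
                continue
            survivors.append(iv)
        if mode == "strict":
            triggers = [iv for iv in comp
                        if iv[1] - iv[0] == 1 and len(classes[iv]) >= 2]
            survivors = [
                iv for iv in survivors
                if not any(iv[0] < t[1] and t[0] < iv[1] for t in triggers)
            ]
        accepted.extend(survivors)
    return {
        (iv[0], iv[1], *code(rows, universe, iv)) for iv in accepted
    }


def tree_splits_bruteforce(newick_tree) -> set:
    """All non-trivial splits by removing each internal edge in turn,
    on a dendropy tree (used as the RF oracle)."""
    import dendropy

    tree = newick_tree
    labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(labels)
    splits = set()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.parent_node is None or head.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in head.leaf_iter())
        other = labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(other if anchor in side else side)
    return splits


def quartet_topology_by_restriction(tree, quad: tuple[str, ...]):
    """Induced quartet topology by restricting the tree to 4 leaves and
    reading off its single non-trivial split (second implementation)."""
    import dendropy

    sub = tree.clone(depth=1)
    sub.retain_taxa_with_labels(list(quad))
    labels = frozenset(quad)
    for edge in sub.preorder_edge_iter():
        head = edge.head_node
        if head.parent_node is None or head.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in head.leaf_iter())
        if len(side) == 2 and len(labels - side) == 2:
            return min(side, labels - side, key=sorted)
    return None


def quartet_distance_bruteforce(dtree1, dtree2, labels: list[str]) -> int:
    d = 0
    for quad in combinations(sorted(labels), 4):
        if (quartet_topology_by_restriction(dtree1, quad)
                != quartet_topology_by_restriction(dtree2, quad)):
            d += 1
    return d
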