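"""Distance phylogenetics for the toxin-family trees.

p-distances under pairwise deletion (each pair compared only over columns
ungapped in both rows), Saitou-Nei neighbor joining with the standard Q
criterion, column-resampling bootstrap, and Newick round-trip I/O.
Trees are unrooted: the returned root is the final NJ join point (a
trifurcation for three or more taxa) and carries no meaning. Ties in Q
are broken by the smallest (i, j) index pair and negative estimated
branch lengths are clamped to zero, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import read_fasta

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "pdistance_pairwise_deletion",
    "nj_tree",
    "bootstrap_support",
    "bipartitions",
    "leaf_distance_matrix",
    "write_newick",
    "parse_newick",
    "read_alignment_fasta",
]

GAP = "-"


@dataclass
class Alignment:
    """Equal-length gapped peptide rows with names."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows) or len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 named rows")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(list(self.names), rows)


def read_alignment_fasta(path) -> Alignment:
    recs = read_fasta(path)
    return Alignment([r.id for r in recs], [r.residues for r in recs])


@dataclass
class DistanceMatrix:
    names: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match names")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("asymmetric distance matrix")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")


def pdistance_pairwise_deletion(a: Alignment) -> DistanceMatrix:
    """Proportion of mismatches over columns ungapped in both rows.

    A pair of rows sharing no ungapped column is an error naming the
    pair.
    """
    n = len(a.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = mism = 0
            for x, y in zip(a.rows[i], a.rows[j]):
                if x != GAP and y != GAP:
                    shared += 1
                    if x != y:
                        mism += 1
            if shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between "
                    f"{a.names[i]!r} and {a.names[j]!r}"
                )
            d[i, j] = d[j, i] = mism / shared
    return DistanceMatrix(list(a.names), d)


@dataclass
class TreeNode:
    """Node of an unrooted tree rooted for storage at the final NJ join.

    ``children`` holds (child, branch_length) pairs; ``support`` is the
    bootstrap percentage of the edge above this node (internal nodes
    only).
    """

    name: str | None = None
    children: list = field(default_factory=list)
    support: int | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    On an additive matrix the generating topology is returned with exact
    branch lengths. Q ties break to the smallest (i, j) pair in current
    node order; negative branch lengths are clamped to 0.
    """
    n = len(dm.names)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes = [TreeNode(name=nm) for nm in dm.names]
    d = dm.d.copy()
    if n == 2:
        half = max(0.0, d[0, 1] / 2.0)
        return TreeNode(children=[(nodes[0], half), (nodes[1], half)])
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n
    store: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        r = len(active)
        rowsum = {i: sum(dist[min(i, j), max(i, j)] for j in active if j != i)
                  for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist[min(i, j), max(i, j)] - rowsum[i] - rowsum[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _q, i, j = best
        dij = dist[min(i, j), max(i, j)]
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2.0 * (r - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        store[u] = TreeNode(children=[(store[i], max(0.0, li)),
                                      (store[j], max(0.0, lj))])
        for k in active:
            if k in (i, j):
                continue
            dik = dist[min(i, k), max(i, k)]
            djk = dist[min(j, k), max(j, k)]
            dist[min(u, k), max(u, k)] = 0.5 * (dik + djk - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    dab = dist[min(a, b), max(a, b)]
    dac = dist[min(a, c), max(a, c)]
    dbc = dist[min(b, c), max(b, c)]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    return TreeNode(children=[(store[a], max(0.0, la)),
                              (store[b], max(0.0, lb)),
                              (store[c], max(0.0, lc))])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted tree, each as the smaller-or-
    lexicographically-first side's leaf set."""
    all_leaves = frozenset(tree.leaves())
    splits: set[frozenset[str]] = set()

    def canonical(side: frozenset[str]) -> frozenset[str]:
        other = all_leaves - side
        if len(side) < len(other):
            return side
        if len(other) < len(side):
            return other
        return min(side, other, key=lambda s: sorted(s))

    def visit(node: TreeNode, is_root: bool):
        for child, _bl in node.children:
            below = frozenset(child.leaves())
            if 1 < len(below) < len(all_leaves) - 1:
                splits.add(canonical(below))
            visit(child, False)

    visit(tree, True)
    return splits


def leaf_distance_matrix(tree: TreeNode, names: list[str]) -> np.ndarray:
    """Path-length distances between leaves (for consistency checks)."""
    idx = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    d = np.zeros((n, n))

    def below(node: TreeNode) -> dict[int, float]:
        if not node.children:
            return {idx[node.name]: 0.0}
        merged: dict[int, float] = {}
        child_maps = []
        for child, bl in node.children:
            cm = {k: v + bl for k, v in below(child).items()}
            child_maps.append(cm)
        for xi, cm1 in enumerate(child_maps):
            for cm2 in child_maps[xi + 1:]:
                for u, du in cm1.items():
                    for v, dv in cm2.items():
                        d[u, v] = d[v, u] = du + dv
        for cm in child_maps:
            merged.update(cm)
        return merged

    below(tree)
    return d


def bootstrap_support(a: Alignment, replicates: int, seed: int) -> TreeNode:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; support on each
    internal edge is the percentage of replicate trees containing the
    corresponding bipartition (integer, 0-100).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if a.n_cols < 2:
        raise ValueError("alignment shorter than 2 columns")
    ref = nj_tree(pdistance_pairwise_deletion(a))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        rep = a.resample_columns(rng)
        rep_tree = nj_tree(pdistance_pairwise_deletion(rep))
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = frozenset(ref.leaves())

    def annotate(node: TreeNode):
        for child, _bl in node.children:
            below = frozenset(child.leaves())
            if child.children and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                side = below if len(below) < len(other) else (
                    other if len(other) < len(below)
                    else min(below, other, key=lambda s: sorted(s)))
                child.support = round(100 * counts.get(side, 0) / replicates)
            annotate(child)

    annotate(ref)
    return ref


def write_newick(tree: TreeNode) -> str:
    """Standard Newick with branch lengths; supports as internal labels."""
    leaves = tree.leaves()
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf names")

    def fmt(node: TreeNode, length: float | None) -> str:
        if not node.children:
            body = node.name
        else:
            inner = ",".join(fmt(c, bl) for c, bl in node.children)
            label = "" if node.support is None else str(node.support)
            body = f"({inner}){label}"
        return body if length is None else f"{body}:{length:.10g}"

    return fmt(tree, None) + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse the Newick dialect written by write_newick."""
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> tuple[TreeNode, float | None]:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_node()
                node.children.append((child, 0.0 if bl is None else bl))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label = _read_token()
            if label:
                node.support = int(label)
        else:
            node.name = _read_token()
        length = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            tok = _read_token()
            length = float(tok)
        return node, length

    def _read_token() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        return s[start:pos]

    root, _ = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in newick string")
    return root
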