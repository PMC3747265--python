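"""Distance matrices, neighbor joining, bootstrap supports, patristic
distances, and the bipartition (RF / WRF1 / WRF2) topology metrics.

All algorithms here are authored in-package; external tree libraries are
used only for Newick I/O (see :mod:`primereval.tree`).
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .io import SequenceLibrary, get_logger
from .tree import Clade, PhyloTree

__all__ = [
    "DistanceMatrix", "pairwise_seq_distance", "neighbor_joining",
    "bootstrap_supports", "patristic_matrix", "bipartitions",
    "rf_distance", "wrf1", "wrf2",
]

log = get_logger(__name__)

# JC69 distances saturate at p = 3/4; when capping, p is clipped here.
_P_CAP = 0.7499


class DistanceMatrix:
    """Symmetric nonnegative distances over an ordered id list."""

    def __init__(self, ids: list[str], data: np.ndarray):
        data = np.asarray(data, dtype=float)
        if data.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match id count")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in distance matrix")
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(data < 0):
            raise ValueError("negative distances")
        self.ids = list(ids)
        self.data = data
        self._index = {x: k for k, x in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.data[self._index[i], self._index[j]])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(ids, self.data[np.ix_(idx, idx)])

    def max(self) -> float:
        return float(self.data.max())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


# --------------------------------------------------------------------------
# pairwise sequence distances
# --------------------------------------------------------------------------

def _encode(library: SequenceLibrary) -> np.ndarray:
    arr = np.frombuffer(
        "".join(r.aligned_seq for r in library).encode(), dtype="S1")
    return arr.reshape(len(library), library.alignment_length)


def pairwise_seq_distance(
    library: SequenceLibrary,
    model: str = "p",
    gap_policy: str = "pairwise",
    saturation: str = "error",
) -> DistanceMatrix:
    """p- or Jukes-Cantor distances with pairwise deletion of gap columns.

    Columns where either sequence is not a plain A/C/G/T are skipped.
    Under ``model="jc"`` a p-distance >= 0.75 raises, or is capped when
    ``saturation="cap"``.
    """
    if model not in {"p", "jc"}:
        raise ValueError(f"unknown model {model!r}")
    if gap_policy != "pairwise":
        raise ValueError("only pairwise deletion is supported")
    if len(library) < 2:
        raise ValueError("need at least two sequences")
    seqs = _encode(library)
    valid = np.isin(seqs, np.array([b"A", b"C", b"G", b"T"]))
    n = len(library)
    dist = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = (seqs[i] != seqs[i + 1:]) & both
        counts = both.sum(axis=1)
        if np.any(counts == 0):
            j = int(np.argmax(counts == 0)) + i + 1
            raise ValueError(
                f"no comparable columns between {library.ids[i]!r} "
                f"and {library.ids[j]!r}")
        p = diff.sum(axis=1) / counts
        if model == "jc":
            if np.any(p >= 0.75):
                if saturation == "cap":
                    p = np.minimum(p, _P_CAP)
                else:
                    raise ValueError(
                        "p-distance >= 0.75: JC correction saturated "
                        "(pass saturation='cap' to clip)")
            p = -0.75 * np.log1p(-4.0 * p / 3.0)
        dist[i, i + 1:] = p
        dist[i + 1:, i] = p
    return DistanceMatrix(library.ids, dist)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration, deterministic under id relabeling.

    Ties on the Q criterion are broken on the lexicographically smallest
    (label_i, label_j) pair, where a cluster's label is its smallest member
    id. Negative branch-length estimates are clamped to zero with the
    deficit moved onto the sister edge.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    # work on a copy ordered by id so input order cannot matter
    order = sorted(range(n), key=lambda k: dm.ids[k])
    ids = [dm.ids[k] for k in order]
    D = dm.data[np.ix_(order, order)].copy()
    nodes: list[Clade] = [Clade(name=i) for i in ids]
    labels: list[str] = list(ids)  # smallest member id per cluster

    while len(nodes) > 3:
        r = len(nodes)
        row = D.sum(axis=1)
        Q = (r - 2) * D - row[:, None] - row[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tie = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[a], labels[b]))), (a, b))
            for a, b in tie if a < b)
        i, j = best[1]
        li = 0.5 * D[i, j] + (row[i] - row[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = Clade(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = max(li, 0.0), max(lj, 0.0)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, ln in zip((a, b, c), (la, lb, lc)):
        node.length = max(ln, 0.0)
    root = Clade(children=[a, b, c])
    return PhyloTree(root)


# --------------------------------------------------------------------------
# bootstrap supports
# --------------------------------------------------------------------------

def _default_builder(library: SequenceLibrary) -> PhyloTree:
    dm = pairwise_seq_distance(library, model="jc", saturation="cap")
    return neighbor_joining(dm)


def _resample_columns(library: SequenceLibrary,
                      rng: np.random.Generator) -> SequenceLibrary:
    from .io import SequenceRecord
    ncol = library.alignment_length
    cols = rng.integers(0, ncol, size=ncol)
    return SequenceLibrary([
        SequenceRecord(r.id, "".join(r.aligned_seq[c] for c in cols),
                       r.taxonomy)
        for r in library])


def star_tree(ids: list[str]) -> PhyloTree:
    return PhyloTree(Clade(children=[Clade(name=i) for i in sorted(ids)]))


def bootstrap_supports(
    library: SequenceLibrary,
    n_replicates: int = 500,
    seed: int = 0,
    tree_builder: Optional[Callable[[SequenceLibrary], PhyloTree]] = None,
) -> PhyloTree:
    """Column-resampling bootstrap; supports in [0, 1] on internal edges.

    A library with no pairwise differences yields a star tree (no internal
    edges to support).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    builder = tree_builder or _default_builder
    base_dm = pairwise_seq_distance(library, model="p")
    if base_dm.max() == 0.0:
        log.warning("all sequences identical: reporting star tree")
        return star_tree(library.ids)
    tree = builder(library)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        rep = builder(_resample_columns(library, rng))
        for bp in bipartitions(rep):
            counts[bp] = counts.get(bp, 0) + 1
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        bp = _clade_bipartition(node, set(tree.leaf_names()))
        if bp is not None:
            node.support = counts.get(bp, 0) / n_replicates
    return tree


# --------------------------------------------------------------------------
# patristic distances
# --------------------------------------------------------------------------

def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every leaf pair."""
    leaves = tree.leaves()
    ids = [lf.name for lf in leaves]
    n = len(leaves)
    # depth of each node from root, plus Euler-walk LCA-free accumulation:
    # d(i, j) = depth_i + depth_j - 2 * depth_lca
    depth: dict[int, float] = {id(tree.root): 0.0}
    parent_of: dict[int, Clade] = {}
    for node in tree.preorder():
        if node.parent is not None:
            if node.length is None:
                raise ValueError("missing branch length")
            depth[id(node)] = depth[id(node.parent)] + node.length
            parent_of[id(node)] = node.parent
    # leaf sets per internal node (postorder) to locate LCAs pairwise
    index = {id(lf): k for k, lf in enumerate(leaves)}
    dist = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [index[id(node)]]
            continue
        kids = [below[id(c)] for c in node.children]
        # all leaf pairs whose LCA is exactly this node
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for x in kids[a]:
                    for y in kids[b]:
                        d = (depth[id(leaves[x])] + depth[id(leaves[y])]
                             - 2 * depth[id(node)])
                        dist[x, y] = dist[y, x] = d
        below[id(node)] = [x for k in kids for x in k]
    return DistanceMatrix(ids, dist)


# --------------------------------------------------------------------------
# bipartitions and RF-family metrics
# --------------------------------------------------------------------------

def _clade_bipartition(node: Clade, all_leaves: set[str]):
    side = frozenset(lf.name for lf in _leaves_under(node))
    if len(side) < 2 or len(all_leaves) - len(side) < 2:
        return None  # trivial split
    other = frozenset(all_leaves - side)
    return side if min(side) < min(other) else other


def _leaves_under(node: Clade) -> list[Clade]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def bipartitions(tree: PhyloTree) -> dict[frozenset, float]:
    """Canonical non-trivial splits -> support (1.0 where absent).

    Canonical form is the side containing the lexicographically smallest
    leaf. Multifurcations simply contribute fewer splits. The tree is
    treated as unrooted: a degree-2 root is collapsed first so its two
    child edges count as the single unrooted edge they are.
    """
    if len(tree.root.children) == 2:
        tree = tree.copy().deroot()
    all_leaves = set(tree.leaf_names())
    out: dict[frozenset, float] = {}
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        bp = _clade_bipartition(node, all_leaves)
        if bp is None:
            continue
        support = 1.0 if node.support is None else node.support
        if not (0.0 <= support <= 1.0):
            raise ValueError(f"support {support} outside [0, 1]")
        out[bp] = support
    return out


def _check_same_leaves(t1: PhyloTree, t2: PhyloTree):
    s1, s2 = set(t1.leaf_names()), set(t2.leaf_names())
    if s1 != s2:
        raise ValueError("trees have different leaf sets")


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Number of bipartitions present in exactly one tree."""
    _check_same_leaves(t1, t2)
    b1, b2 = set(bipartitions(t1)), set(bipartitions(t2))
    return len(b1 ^ b2)


def wrf1(t1: PhyloTree, t2: PhyloTree) -> float:
    """Sum of supports over bipartitions unique to either tree."""
    _check_same_leaves(t1, t2)
    b1, b2 = bipartitions(t1), bipartitions(t2)
    total = sum(s for bp, s in b1.items() if bp not in b2)
    total += sum(s for bp, s in b2.items() if bp not in b1)
    return total


def wrf2(t1: PhyloTree, t2: PhyloTree) -> float:
    """wrf1 plus |support difference| over shared bipartitions."""
    _check_same_leaves(t1, t2)
    b1, b2 = bipartitions(t1), bipartitions(t2)
    total = wrf1(t1, t2)
    total += sum(abs(b1[bp] - b2[bp]) for bp in b1.keys() & b2.keys())
    return total


def jc_distance(p: float) -> float:
    """Closed-form Jukes-Cantor correction of a single p-distance."""
    if p >= 0.75:
        raise ValueError("saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)
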