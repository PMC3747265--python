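"""Branch-length-based tree comparison: paired patristic distances, Pearson
correlation and through-origin slope, 0.01-bin averaged profiles, classical
MDS + weighted Procrustes superposition (wRMSD), and the sliding-window
re-placement profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import SequenceLibrary, get_logger
from .phylo import DistanceMatrix, patristic_matrix, rf_distance, wrf1, wrf2
from .tree import Clade, PhyloTree

__all__ = [
    "PairedDistances", "TreeComparisonReport", "normalize_max1",
    "pair_distances", "pearson", "slope_through_origin", "binned_profile",
    "mds_embed", "wrmsd_superimpose", "compare_trees",
    "sliding_window_placement",
]

log = get_logger(__name__)


@dataclass
class PairedDistances:
    """One (x, y) tuple per unordered sequence pair shared by two matrices."""

    x: np.ndarray
    y: np.ndarray
    ref_label: str = "NFL"
    cmp_label: str = "SR"

    def __len__(self) -> int:
        return len(self.x)


def normalize_max1(dm: DistanceMatrix) -> DistanceMatrix:
    """Divide every entry by the matrix maximum (which becomes exactly 1)."""
    m = dm.max()
    if m == 0:
        raise ValueError("cannot normalize an all-zero distance matrix")
    return DistanceMatrix(dm.ids, dm.data / m)


def pair_distances(dm_ref: DistanceMatrix,
                   dm_cmp: DistanceMatrix) -> PairedDistances:
    shared = sorted(set(dm_ref.ids) & set(dm_cmp.ids))
    dropped = (len(dm_ref) - len(shared)) + (len(dm_cmp) - len(shared))
    if dropped:
        log.info("pair_distances: dropped %d ids absent from one matrix",
                 dropped)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared ids")
    a = dm_ref.submatrix(shared).data
    b = dm_cmp.submatrix(shared).data
    iu = np.triu_indices(len(shared), k=1)
    return PairedDistances(x=a[iu], y=b[iu])


def pearson(pd_: PairedDistances) -> float:
    """Product-moment correlation; NaN when either coordinate is constant."""
    if len(pd_) < 2:
        raise ValueError("need at least 2 tuples")
    x, y = pd_.x, pd_.y
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def slope_through_origin(pd_: PairedDistances) -> float:
    """Least-squares slope with zero intercept: sum(xy) / sum(x^2)."""
    denom = float(np.sum(pd_.x ** 2))
    if denom == 0:
        raise ValueError("all x are zero; slope undefined")
    return float(np.sum(pd_.x * pd_.y) / denom)


def binned_profile(pd_: PairedDistances, width: float = 0.01) -> pd.DataFrame:
    """Per x-bin count, mean and sample std of y; empty bins omitted.

    x must already be normalized to [0, 1]. Single-member bins report
    std = NaN (n-1 denominator). Column ``flagged`` marks bins beyond
    x = 0.8, excluded from resolving-power interpretation but still emitted.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    x, y = pd_.x, pd_.y
    if x.size and (x.min() < 0 or x.max() > 1 + 1e-9):
        raise ValueError("x must be normalized to [0, 1]")
    nbins = int(np.ceil(1.0 / width))
    idx = np.minimum((x / width).astype(int), nbins - 1)
    rows = []
    for k in sorted(set(idx.tolist())):
        vals = y[idx == k]
        std = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        rows.append(dict(bin_start=k * width, count=len(vals),
                         mean=float(vals.mean()), std=std,
                         flagged=bool(k * width > 0.8)))
    return pd.DataFrame(rows,
                        columns=["bin_start", "count", "mean", "std",
                                 "flagged"])


# --------------------------------------------------------------------------
# classical MDS + weighted Procrustes
# --------------------------------------------------------------------------

def mds_embed(dm: DistanceMatrix, dims: int = 3) -> np.ndarray:
    """Torgerson scaling: double-centered squared distances, top eigenpairs.

    Deterministic up to sign; each axis's sign is fixed so its
    largest-magnitude coordinate is positive. Negative eigenvalues are
    clamped to zero (non-Euclidean residual discarded).
    """
    n = len(dm)
    if not 1 <= dims <= n - 1:
        raise ValueError(f"dims must be in [1, {n - 1}]")
    d2 = dm.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    pts = evecs[:, order] * np.sqrt(lam)
    for k in range(dims):
        col = pts[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            pts[:, k] = -col
    return pts


def wrmsd_superimpose(points_ref: np.ndarray, points_cmp: np.ndarray,
                      weights: Optional[np.ndarray] = None) -> float:
    """Weighted orthogonal Procrustes (translation + rotation/reflection,
    no scaling), then sqrt(sum w ||x - y'||^2 / sum w)."""
    x = np.asarray(points_ref, dtype=float)
    y = np.asarray(points_cmp, dtype=float)
    if x.shape != y.shape:
        raise ValueError("point configurations differ in shape")
    n = x.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative, not all zero")
    wn = w / w.sum()
    xc = x - (wn[:, None] * x).sum(axis=0)
    yc = y - (wn[:, None] * y).sum(axis=0)
    m = yc.T @ (wn[:, None] * xc)
    u, _, vt = np.linalg.svd(m)
    rot = u @ vt
    diff = xc - yc @ rot
    return float(np.sqrt((wn * (diff ** 2).sum(axis=1)).sum()))


def inverse_density_weights(points: np.ndarray, k: int = 5) -> np.ndarray:
    """Optional wRMSD weights: mean distance to the k nearest neighbors,
    normalized to mean 1 (sparse regions weigh more). Uniform weights are
    the default everywhere; this is exposed behind a flag only."""
    from scipy.spatial.distance import squareform, pdist
    d = squareform(pdist(np.asarray(points, dtype=float)))
    np.fill_diagonal(d, np.inf)
    k = min(k, d.shape[0] - 1)
    w = np.sort(d, axis=1)[:, :k].mean(axis=1)
    return w / w.mean()


@dataclass
class TreeComparisonReport:
    pearson_r: float
    slope_through_origin: float
    wrmsd: float
    rf: int
    wrf1: float
    wrf2: float

    def as_dict(self) -> dict:
        return dict(pearson_r=self.pearson_r,
                    slope=self.slope_through_origin, wrmsd=self.wrmsd,
                    rf=self.rf, wrf1=self.wrf1, wrf2=self.wrf2)


def compare_trees(t_ref: PhyloTree, t_cmp: PhyloTree, dims: int = 3,
                  weights: Optional[np.ndarray] = None
                  ) -> TreeComparisonReport:
    """The full per-pair statistics bundle from two trees."""
    shared = set(t_ref.leaf_names()) & set(t_cmp.leaf_names())
    if len(shared) < 4:
        raise ValueError("need at least 4 shared leaves")
    pm_ref = patristic_matrix(t_ref).submatrix(sorted(shared))
    pm_cmp = patristic_matrix(t_cmp).submatrix(sorted(shared))
    norm_ref = normalize_max1(pm_ref)
    norm_cmp = normalize_max1(pm_cmp)
    paired = pair_distances(norm_ref, norm_cmp)
    pts_ref = mds_embed(norm_ref, dims=dims)
    pts_cmp = mds_embed(norm_cmp, dims=dims)
    return TreeComparisonReport(
        pearson_r=pearson(paired),
        slope_through_origin=slope_through_origin(paired),
        wrmsd=wrmsd_superimpose(pts_ref, pts_cmp, weights),
        rf=rf_distance(t_ref, t_cmp),
        wrf1=wrf1(t_ref, t_cmp),
        wrf2=wrf2(t_ref, t_cmp),
    )


# --------------------------------------------------------------------------
# sliding-window placement
# --------------------------------------------------------------------------

def _prune_leaf(tree: PhyloTree, name: str) -> tuple[PhyloTree, Clade]:
    """Remove one leaf; return (pruned tree, original attachment edge).

    Edges are identified by their child node. The attachment edge is the
    edge the leaf used to hang from (merged if its parent got suppressed).
    """
    t = tree.copy()
    leaf = next(lf for lf in t.leaves() if lf.name == name)
    parent = leaf.parent
    parent.children.remove(leaf)
    if len(parent.children) == 1 and parent.parent is not None:
        sib = parent.children[0]
        grand = parent.parent
        sib.length += parent.length
        grand.children[grand.children.index(parent)] = sib
        sib.parent = grand
        return t, sib
    if parent.parent is None and len(parent.children) == 2:
        # root became degree-2; fold it. The merged edge (the one the leaf
        # used to branch off) is the child that deroot keeps as an edge.
        a, b = parent.children
        keep, fold = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:  # only two leaves left: single-edge tree
            return t, keep
        t.deroot()
        return t, fold
    return t, parent.children[0] if parent.children else parent


def _node_leaf_distances(tree: PhyloTree) -> tuple[list, dict, np.ndarray]:
    """(nodes, leaf index, matrix of node-to-leaf path lengths)."""
    nodes = list(tree.preorder())
    pos = {id(n): k for k, n in enumerate(nodes)}
    leaves = [n for n in nodes if n.is_leaf]
    leaf_idx = {n.name: k for k, n in enumerate(leaves)}
    # adjacency
    adj: dict[int, list[tuple[int, float]]] = {id(n): [] for n in nodes}
    for n in nodes:
        if n.parent is not None:
            adj[id(n)].append((id(n.parent), n.length))
            adj[id(n.parent)].append((id(n), n.length))
    dist = np.full((len(nodes), len(leaves)), np.nan)
    for lk, leaf in enumerate(leaves):
        seen = {id(leaf): 0.0}
        stack = [id(leaf)]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + ln
                    stack.append(v)
        for n in nodes:
            dist[pos[id(n)], lk] = seen[id(n)]
    return nodes, leaf_idx, dist


def _edge_node_distance(e1: Clade, e2: Clade) -> int:
    """Nodes on the path between two (child-identified) edges; 0 if same."""
    if e1 is e2:
        return 0

    def ancestors(node: Clade) -> list[Clade]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def node_path_len(a: Clade, b: Clade) -> int:
        anc_a = ancestors(a)
        pos_a = {id(n): k for k, n in enumerate(anc_a)}
        steps = 0
        node = b
        while id(node) not in pos_a:
            node = node.parent
            steps += 1
        return steps + pos_a[id(node)]

    best = min(node_path_len(a, b)
               for a in (e1, e1.parent) for b in (e2, e2.parent))
    return best + 1


def _place_taxon(window_dists: dict[str, float], pruned: PhyloTree) -> Clade:
    """Least-squares attachment of a taxon to one edge of the pruned tree.

    For each candidate edge the attachment position along the edge and the
    nonnegative pendant length are fitted jointly; the edge minimizing the
    squared disagreement between window-implied and tree-implied leaf
    distances wins (ties: first in preorder). Exact (residual 0) when the
    window distances are additive on the tree.
    """
    nodes, leaf_idx, nl = _node_leaf_distances(pruned)
    pos = {id(n): k for k, n in enumerate(nodes)}
    names = [None] * len(leaf_idx)
    for nm, k in leaf_idx.items():
        names[k] = nm
    dw = np.array([window_dists[nm] for nm in names])
    # boolean mask of leaves below each node (child side of its edge)
    below: dict[int, np.ndarray] = {}
    for node in pruned.postorder():
        mask = np.zeros(len(names), dtype=bool)
        if node.is_leaf:
            mask[leaf_idx[node.name]] = True
        else:
            for c in node.children:
                mask |= below[id(c)]
        below[id(node)] = mask
    best_edge, best_res = None, np.inf
    for node in nodes:
        if node.parent is None:
            continue
        length = node.length
        child_side = below[id(node)]
        a = dw[~child_side] - nl[pos[id(node.parent)], ~child_side]
        b = dw[child_side] - nl[pos[id(node)], child_side]
        # model: parent-side residual (a_i - (t + v)), child side
        # (b_i - (length - t + v)), with 0 <= t <= length, v >= 0
        alpha = float(a.mean()) if a.size else 0.0
        beta = float(b.mean()) if b.size else 0.0
        t = (alpha - beta + length) / 2.0
        v = (alpha + beta - length) / 2.0
        t = min(max(t, 0.0), length)
        v = max(v, 0.0)
        res = float(((a - (t + v)) ** 2).sum()
                    + ((b - (length - t + v)) ** 2).sum())
        if res < best_res - 1e-12:
            best_res = res
            best_edge = node
    return best_edge


def sliding_window_placement(
    library: SequenceLibrary,
    tree: PhyloTree,
    window: int = 280,
    step: int = 40,
) -> pd.DataFrame:
    """Per window start: node distance of each taxon's re-placement.

    For each alignment window, every taxon is removed from the tree in turn
    and re-attached where its window-restricted p-distances fit best; the
    node distance between original and new attachment edges measures how
    well that stretch of the gene preserves the taxon's position. Returns
    long-format rows (window_start, taxon, node_distance) plus per-window
    means (taxon = '<mean>').
    """
    ids = library.ids
    if len(ids) < 4:
        raise ValueError("need at least 4 taxa")
    if set(ids) != set(tree.leaf_names()):
        raise ValueError("library and tree ids differ")
    if step <= 0:
        raise ValueError("step must be positive")
    ncol = library.alignment_length
    if window >= ncol:
        starts = [0]
        window = ncol
    else:
        starts = list(range(0, ncol - window + 1, step))

    seqs = np.frombuffer("".join(r.aligned_seq for r in library).encode(),
                         dtype="S1").reshape(len(ids), ncol)
    valid = np.isin(seqs, np.array([b"A", b"C", b"G", b"T"]))
    rows = []
    for start in starts:
        sl = slice(start, start + window)
        sub, ok = seqs[:, sl], valid[:, sl]
        n = len(ids)
        p = np.zeros((n, n))
        for i in range(n):
            both = ok[i] & ok[i + 1:]
            cnt = both.sum(axis=1)
            diff = ((sub[i] != sub[i + 1:]) & both).sum(axis=1)
            with np.errstate(invalid="ignore"):
                pi = np.where(cnt > 0, diff / np.maximum(cnt, 1), 0.0)
            p[i, i + 1:] = pi
            p[i + 1:, i] = pi
        nds = []
        for k, taxon in enumerate(ids):
            pruned, orig_edge = _prune_leaf(tree, taxon)
            wd = {ids[m]: p[k, m] for m in range(n) if m != k}
            new_edge = _place_taxon(wd, pruned)
            nd = _edge_node_distance(orig_edge, new_edge)
            rows.append(dict(window_start=start, taxon=taxon,
                             node_distance=nd))
            nds.append(nd)
        rows.append(dict(window_start=start, taxon="<mean>",
                         node_distance=float(np.mean(nds))))
    return pd.DataFrame(rows, columns=["window_start", "taxon",
                                       "node_distance"])
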