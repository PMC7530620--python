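"""Distance-based phylogenetics.

Pairwise protein distances (p, Poisson-corrected, or gamma-corrected for
rate heterogeneity across sites with shape alpha, default 0.77), the
Saitou–Nei neighbor-joining algorithm with deterministic tie-breaking,
nonparametric bootstrap supports, per-partition trees (the exon-tree
workflow), and the Robinson–Foulds split distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io import DataError, PhyloTree

SATURATION_P = 0.95


@dataclass(frozen=True)
class DistanceParams:
    model: str = "gamma"        # p | poisson | gamma
    alpha: float = 0.77         # gamma shape (rate heterogeneity among sites)
    deletion: str = "pairwise"  # pairwise | coverage95

    def __post_init__(self) -> None:
        if self.model not in {"p", "poisson", "gamma"}:
            raise DataError(f"unknown distance model {self.model!r}")
        if self.alpha <= 0:
            raise DataError("gamma shape must be positive")
        if self.deletion not in {"pairwise", "coverage95"}:
            raise DataError(f"unknown deletion mode {self.deletion!r}")


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise DataError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise DataError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise DataError("distances must be finite and non-negative")
        self.matrix = m


def _correct(p: float, params: DistanceParams) -> float:
    if p >= SATURATION_P and params.model != "p":
        raise DataError(f"saturated pair (p = {p:.3f} >= {SATURATION_P})")
    if params.model == "p":
        return p
    if params.model == "poisson":
        return -np.log(1.0 - p)
    return params.alpha * ((1.0 - p) ** (-1.0 / params.alpha) - 1.0)


def pairwise_distance(seq_a: str, seq_b: str,
                      params: DistanceParams | None = None) -> float:
    """Distance between two equal-length (possibly gapped) proteins.

    Sites gapped in either sequence are excluded (pairwise deletion);
    the proportion of mismatches among compared sites is then corrected
    according to ``params.model``.
    """
    params = params or DistanceParams()
    if len(seq_a) != len(seq_b):
        raise DataError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    gap = ord("-")
    ok = (a != gap) & (b != gap)
    n = int(ok.sum())
    if n == 0:
        raise DataError("no comparable (ungapped) sites")
    p = float((a[ok] != b[ok]).sum()) / n
    if p >= 1.0:
        raise DataError("sequences share no identical compared sites")
    return _correct(p, params)


def _coverage_filter(mat: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    gap = ord("-")
    cov = (mat != gap).mean(axis=0)
    return mat[:, cov >= threshold]


def distance_matrix(seqs: Mapping[str, str],
                    params: DistanceParams | None = None) -> DistanceMatrix:
    params = params or DistanceParams()
    labels = list(seqs)
    lens = {len(s) for s in seqs.values()}
    if len(lens) != 1:
        raise DataError("all sequences must have equal aligned length")
    mat = np.vstack([
        np.frombuffer(seqs[l].encode(), dtype=np.uint8) for l in labels
    ])
    if params.deletion == "coverage95":
        mat = _coverage_filter(mat)
        if mat.shape[1] == 0:
            raise DataError("no columns pass the 95% coverage filter")
    n = len(labels)
    gap = ord("-")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] != gap) & (mat[j] != gap)
            m = int(ok.sum())
            if m == 0:
                raise DataError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            p = float((mat[i, ok] != mat[j, ok]).sum()) / m
            if p >= 1.0:
                raise DataError(
                    f"{labels[i]} vs {labels[j]}: no shared identical sites"
                )
            D[i, j] = D[j, i] = _correct(p, params)
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining (unrooted, O(n³)).

    Ties in the Q criterion resolve to the smallest (row, column) index
    pair; negative branch lengths are clamped to zero.
    """
    n = len(dm.labels)
    if n < 2:
        raise DataError("need at least two taxa")
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for lab in dm.labels:
        t = dendropy.Taxon(label=lab)
        taxa.add_taxon(t)
        nd = dendropy.Node(taxon=t)
        nodes.append(nd)

    D = dm.matrix.copy()
    active = list(range(n))

    if n == 2:
        root = dendropy.Node()
        d = float(D[0, 1])
        for i, nd in enumerate(nodes):
            nd.edge.length = d / 2.0
            root.add_child(nd)
        tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
        return PhyloTree(tree, rooted=False)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        # zero-distance pairs are always valid cherries on an additive
        # matrix; joining them first pins down the otherwise arbitrary
        # placement of duplicate taxa (e.g. gene-converted copies)
        zi, zj = np.nonzero(sub == 0.0)
        zpairs = [(i, j) for i, j in zip(zi, zj) if i < j]
        if zpairs:
            ai, aj = min(zpairs)
        else:
            # r_i + r_j first: addition commutes exactly, keeping Q symmetric
            Q = (m - 2) * sub - (r[:, None] + r[None, :])
            np.fill_diagonal(Q, np.inf)
            # smallest Q; ties -> smallest (row, col) in active-index order
            flat = np.argmin(Q)
            qmin = Q.flat[flat]
            tie_rows, tie_cols = np.nonzero(Q == qmin)
            pairs = [(i, j) for i, j in zip(tie_rows, tie_cols) if i < j]
            ai, aj = min(pairs)
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].edge.length = max(float(li), 0.0)
        nodes[j].edge.length = max(float(lj), 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances to the new node
        newrow = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for ak in active:
            if ak in (i, j):
                continue
            duk = 0.5 * (D[i, ak] + D[j, ak] - dij)
            D[u, ak] = D[ak, u] = duk
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [u]

    hub = dendropy.Node()
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = max(float(ln), 0.0)
        hub.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=hub)
    return PhyloTree(tree, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _tree_from_columns(labels: list, mat: np.ndarray,
                       params: DistanceParams) -> PhyloTree:
    seqs = {
        lab: mat[i].tobytes().decode() for i, lab in enumerate(labels)
    }
    return nj_tree(distance_matrix(seqs, params))


def bootstrap_support(alignment: Mapping[str, str],
                      n_replicates: int = 1000,
                      params: DistanceParams | None = None,
                      seed: int = 0) -> PhyloTree:
    """NJ tree with split supports from column-resampling bootstrap.

    Support of an internal edge is the percentage of replicate NJ trees
    containing the same leaf bipartition.  With fewer than four taxa no
    internal split exists and the tree carries no supports.
    """
    params = params or DistanceParams()
    if n_replicates < 1:
        raise DataError("need at least one bootstrap replicate")
    # canonical taxon order: supports are invariant to input leaf order
    labels = sorted(alignment)
    mat = np.vstack([
        np.frombuffer(alignment[l].encode(), dtype=np.uint8) for l in labels
    ])
    ncol = mat.shape[1]
    if ncol < 1:
        raise DataError("alignment must have at least one column")
    base = _tree_from_columns(labels, mat, params)
    if len(labels) < 4:
        return base
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = _tree_from_columns(labels, mat[:, idx], params)
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    leaves = frozenset(labels)
    ref = min(leaves)
    for nd in base.tree.preorder_node_iter():
        if nd is base.tree.seed_node or nd.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            pct = 100.0 * counts.get(side, 0) / n_replicates
            nd.label = str(int(round(pct)))
    return base


def supports(tree: PhyloTree) -> dict[frozenset, float]:
    """Split → support map for a tree annotated by bootstrap_support."""
    leaves = frozenset(tree.leaf_labels)
    ref = min(leaves)
    out: dict[frozenset, float] = {}
    for nd in tree.tree.preorder_node_iter():
        if nd is tree.tree.seed_node or nd.is_leaf() or nd.label is None:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = leaves - side
        out[side] = float(nd.label)
    return out


def partition_trees(alignment: Mapping[str, str],
                    partitions: Sequence[tuple],
                    params: DistanceParams | None = None,
                    n_replicates: int = 1000,
                    seed: int = 0) -> list[PhyloTree]:
    """One bootstrapped NJ tree per column range (e.g. per exon)."""
    lens = {len(s) for s in alignment.values()}
    if len(lens) != 1:
        raise DataError("alignment sequences must have equal length")
    L = lens.pop()
    seen: list[tuple] = []
    for start, end in partitions:
        if not (0 <= start < end <= L):
            raise DataError(f"partition [{start},{end}) out of range 0..{L}")
        for s0, e0 in seen:
            if start < e0 and s0 < end:
                raise DataError("partitions must be disjoint")
        seen.append((start, end))
    trees = []
    for i, (start, end) in enumerate(partitions):
        sub = {lab: s[start:end] for lab, s in alignment.items()}
        trees.append(
            bootstrap_support(sub, n_replicates, params, seed=seed + i)
        )
    return trees


def split_distance(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Robinson–Foulds count of bipartitions present in exactly one tree."""
    la, lb = set(tree_a.leaf_labels), set(tree_b.leaf_labels)
    if la != lb:
        raise DataError("trees must share the same leaf set")
    return len(tree_a.bipartitions() ^ tree_b.bipartitions())
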