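"""Neighbor-joining trees from genetic distance matrices.

The agglomerative algorithm of Saitou & Nei: repeatedly join the pair (i, j)
minimising the rate-corrected criterion

    Q(i, j) = (r − 2) d(i, j) − Σ_k d(i, k) − Σ_k d(j, k)

(r = current number of active nodes), attach the pair to a new internal node
with branch lengths from the rate-corrected split, and replace it in the
matrix with d(u, k) = (d(i,k) + d(j,k) − d(i,j))/2.  On an additive matrix
this recovers the generating topology and branch lengths exactly.  The
result is an unrooted tree, represented as a :class:`skbio.TreeNode` whose
root is the trifurcating final join.

Determinism: Q ties are broken by the lexicographically smallest active
index pair.  Negative branch lengths (possible on non-additive input) are
clamped to zero with the deficit moved to the sibling branch, preserving
the pair's summed length, and a warning is issued.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode
from sklearn.base import BaseEstimator

from .distance import distance_matrix
from .io import FrequencyMatrix

__all__ = ["neighbor_joining", "write_newick", "read_newick", "path_distance", "NeighborJoining"]


def _as_distance_matrix(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        out = dm
    else:
        out = DistanceMatrix(np.asarray(dm, dtype=float))
    if (out.data < 0).any():
        raise ValueError("distance matrix has negative entries")
    return out


def _clamped_pair(li: float, lj: float, total: float) -> tuple[float, float]:
    """Clamp a negative branch length to 0, moving the deficit to its sibling."""
    if li < 0:
        warnings.warn("negative NJ branch length clamped to 0", UserWarning, stacklevel=3)
        return 0.0, total
    if lj < 0:
        warnings.warn("negative NJ branch length clamped to 0", UserWarning, stacklevel=3)
        return total, 0.0
    return li, lj


def neighbor_joining(dm) -> TreeNode:
    """Build an unrooted NJ tree from a symmetric distance matrix.

    Parameters
    ----------
    dm : skbio.DistanceMatrix or square array-like
        Symmetric, hollow, non-negative distances over ≥ 3 labels.

    Returns
    -------
    skbio.TreeNode
        Tree with a trifurcating root (unrooted binary topology) whose tip
        names are the matrix ids and whose branch lengths carry the NJ
        estimates.
    """
    dm = _as_distance_matrix(dm)
    r = dm.shape[0]
    if r < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    active = list(range(r))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        # first strict minimum in row-major (i < j) order = smallest index pair
        best, best_q = None, np.inf
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - row_sums[a] - row_sums[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (row_sums[a] - row_sums[b]) / (2 * (m - 2))
        li, lj = _clamped_pair(li, dij - li, dij)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.extend([nodes[i], nodes[j]])
        # reuse slot i for the new node, retire slot j
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    # three-point formulas: each terminal branch from the three pairwise sums
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    if min(li, lj, lk) < 0:
        warnings.warn("negative NJ branch length clamped to 0", UserWarning, stacklevel=2)
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, length)
        root.append(nodes[idx])
    return root


def write_newick(tree: TreeNode, path) -> None:
    """Serialise a tree to a Newick file."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def path_distance(tree: TreeNode, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two named tips."""
    try:
        ta = tree.find(leaf_a)
        tb = tree.find(leaf_b)
    except Exception as exc:  # skbio raises MissingNodeError
        raise KeyError(f"unknown leaf in {leaf_a!r}/{leaf_b!r}") from exc
    return float(ta.distance(tb))


class NeighborJoining(BaseEstimator):
    """Population tree from allele frequencies (or precomputed distances).

    Parameters
    ----------
    metric : {"nei1972", "da1983", "precomputed"}
        Distance applied to a frequency matrix; "precomputed" accepts a
        distance matrix directly.

    Attributes
    ----------
    distance_matrix_ : skbio.DistanceMatrix
    tree_ : skbio.TreeNode
        Unrooted NJ tree (trifurcating root).
    labels_ : list of str
    newick_ : str
    """

    def __init__(self, metric: str = "nei1972"):
        self.metric = metric

    def fit(self, X, y=None):
        if self.metric == "precomputed":
            dm = _as_distance_matrix(X)
        elif isinstance(X, FrequencyMatrix):
            dm = distance_matrix(X, method=self.metric)
        else:
            raise TypeError(
                "X must be a FrequencyMatrix unless metric='precomputed'"
            )
        self.distance_matrix_ = dm
        self.tree_ = neighbor_joining(dm)
        self.labels_ = list(dm.ids)
        self.newick_ = str(self.tree_).strip()
        return self
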