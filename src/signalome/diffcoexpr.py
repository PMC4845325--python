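"""Differential co-expression networks.

Per-condition Spearman correlation matrices, their difference (the
differential correlation matrix D), correlations between proteins'
differential profiles (R), hierarchical clustering of R with optimal
leaf ordering, and validation of high-R pairs against an externally
supplied semantic-similarity matrix.

Two proteins with a high profile correlation change their correlations
to all other proteins in a highly parallel fashion between conditions —
the signature of coordinated rewiring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from signalome.preprocess import ExpressionMatrix


class DiffCoexprError(ValueError):
    pass


@dataclass
class CorrelationMatrices:
    """Per-condition Spearman matrices and the differential matrix."""

    c_ctrl: pd.DataFrame
    c_dis: pd.DataFrame
    d: pd.DataFrame


@dataclass
class ClusterAssignment:
    """Flat clustering of the profile-correlation matrix.

    ``labels`` maps each protein to a cluster id 1..k, renumbered so
    clusters appear in leaf order; ``leaf_order`` is the optimal-leaf-
    ordered permutation of proteins.
    """

    labels: pd.Series
    leaf_order: list
    k: int
    linkage_matrix: np.ndarray


def _spearman_matrix(X: np.ndarray, ids: pd.Index, what: str) -> pd.DataFrame:
    const = np.ptp(X, axis=1) == 0
    if const.any():
        offenders = list(ids[const])
        raise DiffCoexprError(f"constant protein(s) in {what} group: {offenders[:10]}")
    R = stats.rankdata(X, axis=1)
    C = np.corrcoef(R)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=ids, columns=ids)


def condition_correlations(matrix: ExpressionMatrix, labels: pd.Series) -> CorrelationMatrices:
    """All-pairs Spearman correlation matrices, one per condition.

    ``labels`` assigns each sample to one of two groups (sorted order:
    first = control, second = disease). Each group needs at least 5
    samples. Also returns the differential matrix D = C_dis - C_ctrl.
    """
    if matrix.stage != "zscored":
        raise DiffCoexprError("condition_correlations expects a Z-scored matrix")
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise DiffCoexprError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise DiffCoexprError(f"exactly two groups required, got {groups}")
    X = matrix.values.to_numpy(dtype=float)
    ids = matrix.values.index
    mats = {}
    for g in groups:
        cols = (labels == g).to_numpy()
        if cols.sum() < 5:
            raise DiffCoexprError(f"group {g!r} has {int(cols.sum())} samples; need >= 5")
        mats[g] = _spearman_matrix(X[:, cols], ids, str(g))
    c_ctrl, c_dis = mats[groups[0]], mats[groups[1]]
    return CorrelationMatrices(c_ctrl=c_ctrl, c_dis=c_dis, d=differential_matrix(c_ctrl, c_dis))


def differential_matrix(c_ctrl: pd.DataFrame, c_dis: pd.DataFrame) -> pd.DataFrame:
    """Differential correlation matrix D = C_dis - C_ctrl (zero diagonal).

    Captures the direction and magnitude of each pair's correlation
    change in disease.
    """
    if list(c_ctrl.index) != list(c_dis.index) or list(c_ctrl.columns) != list(c_dis.columns):
        raise DiffCoexprError("correlation matrices cover different protein sets or orders")
    D = c_dis - c_ctrl
    np.fill_diagonal(D.values, 0.0)
    return D


def profile_correlations(D: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between differential-correlation profiles.

    R[i, j] correlates row i and row j of D over all other proteins,
    excluding the structurally degenerate self-pair columns i and j
    (D[i,i] = D[j,j] = 0 and D[i,j] appears in both rows). Computed in
    closed form from row sums, so it is exact and O(n^2).
    """
    n = D.shape[0]
    if n < 4:
        raise DiffCoexprError(f"need >= 4 proteins, got {n}")
    A = D.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise DiffCoexprError("D must be symmetric")
    m = n - 2  # columns used per pair
    S = A.sum(axis=1)
    Q = (A**2).sum(axis=1)
    P = A @ A.T
    # per-pair sums over columns excluding i and j (diagonal entries are 0)
    Sx = S[:, None] - A  # Sx[i,j] = S_i - D[i,j]
    Sy = S[None, :] - A
    Qx = Q[:, None] - A**2
    Qy = Q[None, :] - A**2
    cov = m * P - Sx * Sy
    varx = m * Qx - Sx**2
    vary = m * Qy - Sy**2
    off = ~np.eye(n, dtype=bool)
    bad = (varx <= 1e-12) & off
    if bad.any():
        offenders = sorted(set(D.index[np.where(bad)[0]]))
        raise DiffCoexprError(f"zero-variance differential profile(s): {offenders[:10]}")
    with np.errstate(invalid="ignore"):
        R = cov / np.sqrt(varx * vary)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=D.index, columns=D.columns)


def _minplus(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-plus matrix product with argmin: C[i,j] = min_m A[i,m] + B[m,j]."""
    C = np.empty((A.shape[0], B.shape[1]))
    arg = np.empty((A.shape[0], B.shape[1]), dtype=np.intp)
    for i in range(A.shape[0]):
        S = A[i][:, None] + B
        arg[i] = S.argmin(axis=0)
        C[i] = S[arg[i], np.arange(B.shape[1])]
    return C, arg


def optimal_leaf_order(Z: np.ndarray, dist: np.ndarray) -> list[int]:
    """Exact optimal leaf ordering of a dendrogram.

    Dynamic program over the tree (the Bar-Joseph recursion): for every
    node and every pair of boundary leaves (one from each child) the
    minimum total adjacent-leaf distance over all consistent linear
    orders is computed bottom-up; the optimal order is then read back
    from the stored argmins. In any consistent order the two boundary
    leaves of a subtree lie in different children, so boundary pairs
    within one child carry infinite cost. Ties break toward the lower
    local leaf index (input order), making the result deterministic.
    O(n^3) time.
    """
    n = dist.shape[0]
    if n == 1:
        return [0]
    n_nodes = 2 * n - 1
    leaves: list[np.ndarray] = [np.array([i]) for i in range(n)]
    children: list[tuple[int, int] | None] = [None] * n
    # M[v][i, j]: best cost of ordering leaves[v] with ends leaves[v][i], leaves[v][j]
    M: list[np.ndarray] = [np.zeros((1, 1)) for _ in range(n)]
    H: list[np.ndarray | None] = [None] * n
    K: list[np.ndarray | None] = [None] * n
    for v in range(n, n_nodes):
        l, r = int(Z[v - n, 0]), int(Z[v - n, 1])
        children.append((l, r))
        Ll, Lr = leaves[l], leaves[r]
        leaves.append(np.concatenate([Ll, Lr]))
        # T[i,k] = min_h M_l[i,h] + D[h,k];  cross[i,j] = min_k T[i,k] + M_r[k,j]
        T, argH = _minplus(M[l], dist[np.ix_(Ll, Lr)])
        cross, argK = _minplus(T, M[r])
        a, b = len(Ll), len(Lr)
        full = np.full((a + b, a + b), np.inf)
        full[:a, a:] = cross
        full[a:, :a] = cross.T
        M.append(full)
        H.append(argH[np.arange(a)[:, None], argK])
        K.append(argK)
    root = n_nodes - 1
    i0, j0 = np.unravel_index(int(np.argmin(M[root])), M[root].shape)

    # iterative read-back (trees can be deep); a frame whose left end
    # falls in the right child is emitted in reverse orientation
    out: list[int] = []
    stack: list[tuple[int, int, int]] = [(root, int(i0), int(j0))]
    while stack:
        v, i, j = stack.pop()
        if children[v] is None:
            out.append(int(leaves[v][0]))
            continue
        l, r = children[v]
        a = len(leaves[l])
        if i < a:
            h, k = int(H[v][i, j - a]), int(K[v][i, j - a])
            stack.append((r, k, j - a))
            stack.append((l, i, h))
        else:
            h, k = int(H[v][j, i - a]), int(K[v][j, i - a])
            stack.append((l, h, j))
            stack.append((r, i - a, k))
    return out


def cluster_profiles(R: pd.DataFrame, k: int = 8, linkage: str = "average") -> ClusterAssignment:
    """Hierarchical clustering of the profile-correlation matrix.

    Agglomerates on the distance 1 - R with the configured linkage,
    cuts the tree into ``k`` flat clusters, and orders the leaves by
    exact optimal leaf ordering (the dendrogram-consistent order that
    minimizes the summed distance between adjacent leaves). Cluster ids
    are renumbered 1..k in order of first appearance along the leaves,
    so each cluster is a contiguous block of the leaf order.
    """
    n = R.shape[0]
    if not 2 <= k <= n:
        raise DiffCoexprError(f"need 2 <= k <= {n}, got k={k}")
    dist = 1.0 - R.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = np.array(optimal_leaf_order(Z, dist))
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters in leaf order
    seen: dict[int, int] = {}
    for leaf in order:
        seen.setdefault(int(raw[leaf]), len(seen) + 1)
    labels = pd.Series([seen[int(c)] for c in raw], index=R.index, name="cluster")
    return ClusterAssignment(
        labels=labels,
        leaf_order=[R.index[i] for i in order],
        k=int(labels.max()),
        linkage_matrix=Z,
    )


def leaf_order_objective(R: pd.DataFrame, order: list) -> float:
    """Sum of similarities between adjacent leaves of an ordering."""
    idx = [R.index.get_loc(x) for x in order]
    A = R.to_numpy(dtype=float)
    return float(sum(A[idx[i], idx[i + 1]] for i in range(len(idx) - 1)))


def semantic_validation(
    R: pd.DataFrame,
    S: pd.DataFrame,
    r_threshold: float = 0.35,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Do strongly co-rewired pairs share annotation semantics?

    Takes the unordered protein pairs with profile correlation
    R > r_threshold and compares their median semantic similarity
    against a null of equally many pairs drawn uniformly at random
    (without replacement within a draw) from all pairs:

        p = (1 + #{null median >= observed}) / (n_perm + 1).

    ``S`` is an externally supplied symmetric pairwise similarity matrix
    with entries in [0, 1] on the same protein universe.
    """
    if list(R.index) != list(S.index) or list(R.columns) != list(S.columns):
        raise DiffCoexprError("R and S cover different protein sets or orders")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    r_pairs = R.to_numpy(dtype=float)[iu]
    s_pairs = S.to_numpy(dtype=float)[iu]
    if (s_pairs < 0).any() or (s_pairs > 1).any():
        raise DiffCoexprError("similarity entries must lie in [0, 1]")
    selected = r_pairs > r_threshold
    n_sel = int(selected.sum())
    if n_sel == 0:
        raise DiffCoexprError(
            f"no pairs with R > {r_threshold}; max observed R is {r_pairs.max():.4f}"
        )
    observed = float(np.median(s_pairs[selected]))
    n_pairs = s_pairs.size
    null = np.empty(n_perm)
    chunk = max(1, int(2e7) // max(n_sel, 1))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        for i in range(start, stop):
            draw = rng.choice(n_pairs, size=n_sel, replace=False)
            null[i] = np.median(s_pairs[draw])
    p = (1.0 + int((null >= observed).sum())) / (n_perm + 1.0)
    return {
        "observed_median": observed,
        "n_pairs_selected": n_sel,
        "null_median_mean": float(null.mean()),
        "null_median_sd": float(null.std(ddof=0)),
        "p": float(p),
    }
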