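"""Differential protein-level statistics.

Per-protein two-sample t statistics with class-label permutation
p-values (p_corr), direct q-value FDR estimation, and the cross-disease
comparison statistics (signed log-p quadrants, hypergeometric overlap,
binomial sign concordance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline
from scipy.special import comb

from signalome.preprocess import ExpressionMatrix


class DifferentialError(ValueError):
    pass


def _group_indicator(labels: pd.Series, sample_ids: list) -> tuple[np.ndarray, list]:
    labels = labels.reindex(sample_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise DifferentialError(f"labels missing for samples: {missing[:5]}")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise DifferentialError(f"exactly two groups required, got {groups}")
    return (labels == groups[1]).to_numpy(), groups


def _t_from_membership(X: np.ndarray, member: np.ndarray, flavor: str) -> np.ndarray:
    """Two-sample t statistics for each row of X.

    ``member`` is a boolean (n_samples,) or (n_perm, n_samples) matrix
    selecting the disease group; returns (n_proteins,) or
    (n_proteins, n_perm) t values (disease minus control).
    """
    M = np.atleast_2d(member).astype(float)  # (n_perm, n)
    n1 = M.sum(axis=1)  # disease sizes
    n0 = M.shape[1] - n1
    S1 = X @ M.T  # (p, n_perm)
    Q1 = (X**2) @ M.T
    S = X.sum(axis=1, keepdims=True)
    Q = (X**2).sum(axis=1, keepdims=True)
    S0, Q0 = S - S1, Q - Q1
    m1, m0 = S1 / n1, S0 / n0
    v1 = (Q1 - n1 * m1**2) / (n1 - 1)
    v0 = (Q0 - n0 * m0**2) / (n0 - 1)
    v1 = np.maximum(v1, 0.0)
    v0 = np.maximum(v0, 0.0)
    if flavor == "pooled":
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n0))
    elif flavor == "welch":
        se = np.sqrt(v1 / n1 + v0 / n0)
    else:
        raise DifferentialError(f"unknown t flavor {flavor!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / se
    t[~np.isfinite(t)] = 0.0  # zero-variance rows with equal means
    out = t if member.ndim > 1 else t[:, 0]
    return out


def permutation_ttest(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    flavor: str = "pooled",
    exhaustive: bool = False,
    shared_permutations: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sample t-test with class-label permutation p-values.

    The observed statistic is an unpaired two-tailed t (pooled variance
    by default, Welch via ``flavor="welch"``). Significance is assessed
    against ``n_perm`` random relabelings with the original group sizes;
    the permutation-corrected p-value uses an add-one pseudocount,

        p_corr = (1 + #{|t*| >= |t_obs|}) / (n_perm + 1),

    so it can never be zero. One shared permutation set is used for all
    proteins (reproducible given the seed); ``shared_permutations=False``
    draws an independent set per protein. With ``exhaustive=True`` all
    distinct label splits are enumerated instead (feasible for small
    cohorts) and the p-value is the exact fraction #{|t*| >= |t_obs|}/N.

    Returns a DataFrame indexed by antibody_id with columns mean_ctrl,
    mean_dis, t, direction, p_corr.
    """
    if matrix.stage != "zscored":
        raise DifferentialError("permutation_ttest expects a Z-scored matrix")
    X = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise DifferentialError("non-finite values in expression matrix")
    member, groups = _group_indicator(labels, matrix.sample_ids)
    n = X.shape[1]
    n1 = int(member.sum())
    if n1 < 2 or n - n1 < 2:
        raise DifferentialError(f"each group needs >= 2 samples, got {n - n1} vs {n1}")

    t_obs = _t_from_membership(X, member, flavor)
    m1 = X[:, member].mean(axis=1)
    m0 = X[:, ~member].mean(axis=1)
    direction = np.sign(m1 - m0).astype(int)

    # permutations are drawn in sorted-sample-id space so that permuting
    # the column order of the input leaves p_corr bit-identical
    order = np.argsort(np.array(matrix.sample_ids, dtype=object), kind="mergesort")

    def draw_memberships(rng: np.random.Generator, count: int) -> np.ndarray:
        M = np.zeros((count, n), dtype=bool)
        for i in range(count):
            M[i, order[rng.permutation(n)[:n1]]] = True
        return M

    if exhaustive:
        n_splits = int(comb(n, n1, exact=True))
        if n_splits > 200_000:
            raise DifferentialError(f"{n_splits} label splits: too many to enumerate")
        from itertools import combinations

        M = np.zeros((n_splits, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            M[i, list(idx)] = True
        t_perm = _t_from_membership(X, M, flavor)
        exceed = (np.abs(t_perm) >= np.abs(t_obs)[:, None] - 1e-12).sum(axis=1)
        p_corr = exceed / n_splits
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if shared_permutations:
            M = draw_memberships(rng, n_perm)
            t_perm = _t_from_membership(X, M, flavor)
            exceed = (np.abs(t_perm) >= np.abs(t_obs)[:, None]).sum(axis=1)
        else:
            exceed = np.zeros(X.shape[0], dtype=int)
            for j in range(X.shape[0]):
                M = draw_memberships(rng, n_perm)
                t_perm = _t_from_membership(X[j : j + 1], M, flavor)
                exceed[j] = (np.abs(t_perm[0]) >= abs(t_obs[j])).sum()
        p_corr = (1.0 + exceed) / (n_perm + 1.0)

    return pd.DataFrame(
        {
            "mean_ctrl": m0,
            "mean_dis": m1,
            "t": t_obs,
            "direction": direction,
            "p_corr": p_corr,
        },
        index=pd.Index(matrix.antibody_ids, name="antibody_id"),
    )


def estimate_pi0(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Smoothed estimate of the true-null proportion pi0.

    On a lambda grid (default 0.05, 0.10, ..., 0.95) the naive estimates
    #{p > lambda} / (m (1 - lambda)) are extrapolated to lambda -> 1
    with a cubic smoothing spline, then clipped to (1/m, 1]. Small
    inputs (m < 100) fall back to pi0 = 1 — the grid estimates are too
    noisy there and an underestimated pi0 is anticonservative.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        raise DifferentialError("empty p-value list")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_grid = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    if m < 100:
        pi0 = 1.0
    elif np.allclose(pi0_grid, pi0_grid[0]):
        pi0 = float(min(1.0, pi0_grid[-1]))
    else:
        spline = UnivariateSpline(lambdas, pi0_grid, k=3)
        pi0 = float(spline(lambdas.max()))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(pvals: np.ndarray | pd.Series, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Direct q-value estimation with smoothed pi0.

    The proportion of true nulls pi0 comes from :func:`estimate_pi0`;
    sorted q-values are the step-down minima

        q_(i) = min_{j >= i} pi0 * m * p_(j) / j,

    returned in the original input order.
    """
    idx = None
    if isinstance(pvals, pd.Series):
        idx = pvals.index
        pvals = pvals.to_numpy()
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise DifferentialError("empty p-value list")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise DifferentialError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = estimate_pi0(p, lambdas)

    order = np.argsort(p, kind="mergesort")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    if idx is not None:
        return pd.Series(q, index=idx)
    return q


def differential_results(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    alpha_q: float = 0.05,
    flavor: str = "pooled",
) -> pd.DataFrame:
    """permutation_ttest + storey_qvalues + significance call at q < alpha_q."""
    res = permutation_ttest(matrix, labels, n_perm=n_perm, seed=seed, flavor=flavor)
    res["q"] = storey_qvalues(res["p_corr"].to_numpy())
    res["significant"] = res["q"] < alpha_q
    return res


def signed_logp(p: float, direction: int) -> float:
    """Signed log-transformed p-value: direction * (-log10 p); 0 for direction 0."""
    if not 0 < p <= 1:
        raise DifferentialError(f"p must be in (0, 1], got {p}")
    if direction not in (-1, 0, 1):
        raise DifferentialError(f"direction must be -1, 0 or +1, got {direction}")
    if direction == 0:
        return 0.0
    return direction * (-np.log10(p))


def overlap_hypergeometric(n_a: int, n_b: int, overlap: int, universe: int) -> float:
    """Upper-tail hypergeometric p for the overlap of two hit lists.

    P(X >= overlap) with X ~ Hypergeom(universe, n_a, n_b): the chance of
    seeing at least the observed overlap when the two lists are drawn
    independently from the same universe.
    """
    if not (0 <= overlap <= min(n_a, n_b) <= universe and max(n_a, n_b) <= universe):
        raise DifferentialError(
            f"inconsistent counts: overlap={overlap}, n_a={n_a}, n_b={n_b}, universe={universe}"
        )
    if overlap < n_a + n_b - universe:
        raise DifferentialError("overlap below the forced minimum n_a + n_b - universe")
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def sign_concordance_binomial(n_concordant: int, n_overlap: int) -> float:
    """Upper-tail binomial p for directional concordance among shared hits.

    P(X >= n_concordant) with X ~ Binomial(n_overlap, 1/2); e.g. all 39
    of 39 shared hits changing in the same direction gives 0.5**39.
    """
    if not 0 <= n_concordant <= n_overlap:
        raise DifferentialError(f"need 0 <= n_concordant <= n_overlap, got {n_concordant}/{n_overlap}")
    if n_overlap == 0:
        return 1.0
    return float(stats.binom.sf(n_concordant - 1, n_overlap, 0.5))


QUADRANTS = ("general", "A_specific", "B_specific", "non_significant", "discordant")


@dataclass
class DiseaseComparison:
    """Cross-disease specificity classification and overlap statistics."""

    table: pd.DataFrame  # per-protein: x, y, class
    n_a: int
    n_b: int
    n_overlap: int
    n_concordant: int
    universe: int
    hypergeom_p: float
    binomial_p: float

    def counts(self) -> pd.Series:
        return self.table["class"].value_counts().reindex(QUADRANTS, fill_value=0)


def classify_specificity(
    res_a: pd.DataFrame, res_b: pd.DataFrame, alpha: float = 0.05
) -> DiseaseComparison:
    """Classify each protein by its cross-disease significance pattern.

    With p_A, p_B the permutation-corrected p-values in the two diseases
    (strict thresholds):

    - ``general``: p_A < alpha and p_B < alpha, same direction in both;
    - ``A_specific``: p_A < alpha, p_B >= alpha;
    - ``B_specific``: p_B < alpha, p_A >= alpha;
    - ``non_significant``: neither;
    - ``discordant``: significant in both but with opposite directions
      (kept as its own bucket rather than silently dropped).

    Also computes the hypergeometric overlap p and the binomial sign
    concordance p among the overlapping hits. Coordinates x, y are the
    signed log p-values for plotting.
    """
    if set(res_a.index) != set(res_b.index):
        raise DifferentialError("result sets cover different protein universes")
    res_b = res_b.loc[res_a.index]
    pa = res_a["p_corr"].to_numpy()
    pb = res_b["p_corr"].to_numpy()
    da = res_a["direction"].to_numpy()
    db = res_b["direction"].to_numpy()
    sig_a, sig_b = pa < alpha, pb < alpha
    cls = np.full(len(pa), "non_significant", dtype=object)
    cls[sig_a & ~sig_b] = "A_specific"
    cls[~sig_a & sig_b] = "B_specific"
    both = sig_a & sig_b
    cls[both & (da == db)] = "general"
    cls[both & (da != db)] = "discordant"
    table = pd.DataFrame(
        {
            "x": [signed_logp(p, int(d)) for p, d in zip(pa, da)],
            "y": [signed_logp(p, int(d)) for p, d in zip(pb, db)],
            "class": cls,
        },
        index=res_a.index,
    )
    n_overlap = int(both.sum())
    n_concordant = int((both & (da == db)).sum())
    universe = len(pa)
    return DiseaseComparison(
        table=table,
        n_a=int(sig_a.sum()),
        n_b=int(sig_b.sum()),
        n_overlap=n_overlap,
        n_concordant=n_concordant,
        universe=universe,
        hypergeom_p=overlap_hypergeometric(int(sig_a.sum()), int(sig_b.sum()), n_overlap, universe),
        binomial_p=sign_concordance_binomial(n_concordant, n_overlap),
    )
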