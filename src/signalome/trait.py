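"""Correlation of protein levels with a continuous clinical trait.

Spearman rank correlation of each protein's Z-scored levels against a
per-sample trait such as the MMSE cognition score (integer 0-30,
partially missing), with both the analytic rank-test p-value (p_rho) and
an explicit permutation p-value (p_perm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from signalome.preprocess import ExpressionMatrix


class TraitError(ValueError):
    pass


def _usable(matrix: ExpressionMatrix, trait: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    trait = pd.to_numeric(trait.reindex(matrix.sample_ids), errors="coerce")
    used = trait.notna().to_numpy()
    if used.sum() < 8:
        raise TraitError(f"only {int(used.sum())} samples have a trait value; need >= 8")
    X = matrix.values.to_numpy(dtype=float)[:, used]
    used_ids = np.array(matrix.sample_ids, dtype=object)[used]
    return X, trait.to_numpy(dtype=float)[used], used_ids


def _rank_standardize(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, centered and scaled to unit population SD.

    Returns the standardized ranks and a boolean mask of constant rows
    (undefined correlation).
    """
    R = stats.rankdata(A, axis=-1)
    sd = R.std(axis=-1, ddof=0)
    const = sd == 0
    sd = np.where(const, 1.0, sd)
    Z = (R - R.mean(axis=-1, keepdims=True)) / sd[..., None]
    return Z, const


def spearman_trait(matrix: ExpressionMatrix, trait: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each protein with the trait.

    Samples with a missing trait value are excluded (pairwise complete);
    ties receive average ranks. The analytic two-sided p-value (p_rho)
    uses the t approximation t = rho * sqrt((n-2)/(1-rho^2)). Proteins
    that are constant over the used samples get rho = NaN and a reason.

    Returns a DataFrame indexed by antibody_id with columns rho, p_rho,
    n_used, reason.
    """
    if matrix.stage != "zscored":
        raise TraitError("spearman_trait expects a Z-scored matrix")
    X, t, _ = _usable(matrix, trait)
    n = t.size
    Zx, const_x = _rank_standardize(X)
    zt, const_t = _rank_standardize(t[None, :])
    if const_t[0]:
        raise TraitError("trait is constant over the usable samples")
    rho = (Zx @ zt[0]) / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
    p_rho = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p_rho = np.where(np.abs(rho) >= 1.0, 0.0, p_rho)
    rho = np.where(const_x, np.nan, rho)
    p_rho = np.where(const_x, np.nan, p_rho)
    reason = np.where(const_x, "constant protein over used samples", "")
    return pd.DataFrame(
        {"rho": rho, "p_rho": p_rho, "n_used": n, "reason": reason},
        index=pd.Index(matrix.antibody_ids, name="antibody_id"),
    )


def permutation_trait_p(
    matrix: ExpressionMatrix,
    trait: pd.Series,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    pseudocount: bool = False,
) -> pd.Series:
    """Empirical permutation p-value for each protein-trait correlation.

    The trait values are permuted over the usable samples ``n_perm``
    times (one shared permutation set for all proteins) and

        p_perm = #{|rho*| >= |rho_obs|} / n_perm,

    the literal count estimator, which can return 0 when no permutation
    reaches the observed correlation; ``pseudocount=True`` switches to
    the add-one variant (1 + count) / (n_perm + 1).
    """
    if matrix.stage != "zscored":
        raise TraitError("permutation_trait_p expects a Z-scored matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X, t, used_ids = _usable(matrix, trait)
    n = t.size
    Zx, const_x = _rank_standardize(X)
    zt, _ = _rank_standardize(t[None, :])
    zt = zt[0]
    rho_obs = np.abs((Zx @ zt) / n)

    # permute in sorted-sample-id space: invariant to input column order
    order = np.argsort(used_ids, kind="mergesort")
    zt_sorted = zt[order]
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i, order] = zt_sorted[rng.permutation(n)]
    rho_star = np.abs(Zx @ perms.T) / n  # (p, n_perm)
    count = (rho_star >= rho_obs[:, None] - 1e-15).sum(axis=1)
    if pseudocount:
        p = (1.0 + count) / (n_perm + 1.0)
    else:
        p = count / n_perm
    p = np.where(const_x, np.nan, p)
    return pd.Series(p, index=pd.Index(matrix.antibody_ids, name="antibody_id"), name="p_perm")


def trait_results(
    matrix: ExpressionMatrix,
    trait: pd.Series,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """spearman_trait and permutation_trait_p combined into one table."""
    res = spearman_trait(matrix, trait)
    res["p_perm"] = permutation_trait_p(matrix, trait, n_perm=n_perm, seed=seed)
    return res


def select_trait_correlated(
    results: pd.DataFrame, alpha_rho: float = 0.05, alpha_perm: float = 0.05
) -> pd.DataFrame:
    """Ranked hit list of trait-correlated proteins.

    Keeps proteins with p_rho < alpha_rho, sorts them by rho (strongest
    positive first), and annotates whether each also clears the
    permutation threshold p_perm < alpha_perm.
    """
    if results.empty:
        raise TraitError("empty results table")
    hits = results[results["p_rho"] < alpha_rho].copy()
    hits["passes_perm"] = hits["p_perm"] < alpha_perm
    return hits.sort_values("rho", ascending=False, kind="mergesort")
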