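"""Spot-level preprocessing of antibody-microarray data.

Turns a long-format spot table (one row per printed spot: array/sample,
antibody, replicate, foreground mean, local background median) into a
quality-controlled, centered, normalized, Z-scored antibody x sample
matrix ready for the statistical stages.

The chain is::

    subtract_background -> to_replicate_matrix -> filter_antibodies
      -> replace_nd -> log2_replicate_average -> iterative_median_polish
      -> zscore_rows

Each step is a pure function; re-running the chain on the same input and
configuration yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

SPOT_COLUMNS = ["array_id", "antibody_id", "replicate_index", "foreground", "background"]

#: stages an ExpressionMatrix moves through, in order
STAGES = ("net", "imputed", "log2_averaged", "polished", "zscored")


class PreprocessError(ValueError):
    """Raised when input data violate the preprocessing contracts."""


@dataclass
class PreprocessConfig:
    """Constants of the preprocessing chain.

    Parameters
    ----------
    nd_margin:
        A spot is non-detectable (ND) when its foreground is less than
        ``(1 + nd_margin)`` times the local background, i.e. less than
        10% above background at the default 0.10.
    max_nd_frac:
        Antibodies whose ND fraction (replicate level, across all
        arrays) strictly exceeds this are excluded (default 0.55).
    nd_floor:
        Lower bound for ND replacement values (default 1 intensity unit).
    polish_iterations:
        Rounds of iterative row/column median centering + sum-of-squares
        normalization (default 50). Extra rounds are appended when the
        fixed point has not been reached to ``polish_tol`` (rare, small
        matrices only; capped at 20x the configured count).
    polish_tol:
        Convergence tolerance on the polish fixed point (max |median|
        and relative sum-of-squares deviation).
    nd_frac_level:
        Denominator convention for the ND-exclusion rule: ``"replicate"``
        counts every spot, ``"sample"`` counts a sample ND only when all
        of its replicates are ND.
    zscore_axis:
        Only ``"per_antibody"`` is supported: each protein row is scaled
        to mean 0, SD 1 across samples.
    """

    nd_margin: float = 0.10
    max_nd_frac: float = 0.55
    nd_floor: float = 1.0
    polish_iterations: int = 50
    polish_tol: float = 1e-8
    nd_frac_level: str = "replicate"
    zscore_axis: str = "per_antibody"
    control_antibodies: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.nd_margin < 1:
            raise PreprocessError(f"nd_margin must be in (0,1), got {self.nd_margin}")
        if not 0 < self.max_nd_frac < 1:
            raise PreprocessError(f"max_nd_frac must be in (0,1), got {self.max_nd_frac}")
        if self.polish_iterations < 1:
            raise PreprocessError("polish_iterations must be >= 1")
        if self.nd_frac_level not in ("replicate", "sample"):
            raise PreprocessError(f"unknown nd_frac_level {self.nd_frac_level!r}")
        if self.zscore_axis != "per_antibody":
            raise PreprocessError(f"unsupported zscore_axis {self.zscore_axis!r}")


@dataclass
class ExpressionMatrix:
    """Antibody x sample (or antibody x replicate) expression values.

    ``values`` is indexed by antibody_id. Before replicate averaging the
    columns are a (sample, replicate) MultiIndex and ``nd_mask`` marks
    non-detectable spots; from ``log2_averaged`` on, columns are sample
    ids and ``nd_mask`` is None.
    """

    values: pd.DataFrame
    stage: str
    nd_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise PreprocessError(f"unknown stage {self.stage!r}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise PreprocessError(f"duplicate antibody ids: {dupes}")
        if not self.values.columns.is_unique:
            raise PreprocessError("duplicate sample columns")
        if self.stage in ("log2_averaged", "polished", "zscored") and self.nd_mask is not None:
            raise PreprocessError(f"nd_mask must be dropped by stage {self.stage}")

    @property
    def antibody_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        if isinstance(self.values.columns, pd.MultiIndex):
            return list(dict.fromkeys(self.values.columns.get_level_values(0)))
        return list(self.values.columns)


def validate_spot_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Check the spot-table contract and return the validated frame.

    Requires the canonical columns, unique (array, antibody, replicate)
    keys, and finite non-negative intensities.
    """
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise PreprocessError(f"spot table missing columns: {missing}")
    key = ["array_id", "antibody_id", "replicate_index"]
    dup = spots.duplicated(subset=key)
    if dup.any():
        first = spots.loc[dup, key].iloc[0].tolist()
        raise PreprocessError(f"duplicate spot key {tuple(first)}")
    for col in ("foreground", "background"):
        vals = pd.to_numeric(spots[col], errors="coerce")
        if vals.isna().any():
            row = int(spots.index[vals.isna()][0])
            raise PreprocessError(f"non-numeric {col} at row {row}")
        if not np.isfinite(vals).all() or (vals < 0).any():
            row = int(spots.index[~(np.isfinite(vals) & (vals >= 0))][0])
            raise PreprocessError(f"negative or non-finite {col} at row {row}")
    if (spots["replicate_index"] < 1).any():
        raise PreprocessError("replicate_index must be >= 1")
    return spots


def subtract_background(spots: pd.DataFrame, cfg: PreprocessConfig | None = None) -> pd.DataFrame:
    """Local background subtraction and non-detect flagging.

    For each (array, antibody) replicate group the local background *B*
    is the median of the replicate background values. Each replicate's
    net intensity is ``foreground - B`` and the spot is flagged ND when
    its foreground is less than ``(1 + nd_margin) * B`` (i.e. less than
    10% above background by default). When *B* is zero the margin rule is
    degenerate; such a spot is ND iff its foreground is zero.

    Returns a copy of the table with ``net`` and ``nd`` columns added.
    """
    cfg = cfg or PreprocessConfig()
    spots = validate_spot_table(spots)
    out = spots.copy()
    b_local = out.groupby(["array_id", "antibody_id"], sort=False)["background"].transform("median")
    out["net"] = out["foreground"] - b_local
    fg = out["foreground"].to_numpy(dtype=float)
    b = b_local.to_numpy(dtype=float)
    nd = np.where(b > 0, fg < (1.0 + cfg.nd_margin) * b, fg <= 0)
    out["nd"] = nd
    return out


def to_replicate_matrix(spots: pd.DataFrame) -> ExpressionMatrix:
    """Pivot a background-subtracted spot table into a replicate-level matrix.

    Rows are antibodies; columns are a (sample, replicate) MultiIndex.
    Antibodies printed with fewer replicates than the widest antibody
    carry NaN in the unused replicate slots; those cells are ignored by
    every downstream step.
    """
    if "net" not in spots.columns or "nd" not in spots.columns:
        raise PreprocessError("spots must pass subtract_background first")
    values = spots.pivot(index="antibody_id", columns=["array_id", "replicate_index"], values="net")
    ndm = spots.pivot(index="antibody_id", columns=["array_id", "replicate_index"], values="nd")
    ndm = ndm.astype(object).where(ndm.notna(), False).astype(bool)
    ndm[values.isna()] = False
    return ExpressionMatrix(values=values, stage="net", nd_mask=ndm)


def drop_control_antibodies(matrix: ExpressionMatrix, control_ids: Sequence[str]) -> tuple[ExpressionMatrix, list[str]]:
    """Remove control antibodies (spike-ins, orientation markers) by id."""
    controls = [a for a in matrix.antibody_ids if a in set(control_ids)]
    keep = [a for a in matrix.antibody_ids if a not in set(control_ids)]
    if not keep:
        raise PreprocessError("all antibodies are controls")
    nd = matrix.nd_mask.loc[keep] if matrix.nd_mask is not None else None
    return ExpressionMatrix(values=matrix.values.loc[keep], stage=matrix.stage, nd_mask=nd), controls


def filter_antibodies(
    matrix: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Exclude antibodies with too many non-detectable values.

    An antibody is dropped when its ND fraction strictly exceeds
    ``cfg.max_nd_frac`` (default: more than 55% ND). The fraction is
    computed at replicate level across all arrays (every measured spot
    counts once); with ``nd_frac_level="sample"`` a sample counts as ND
    only when all of its replicates are ND.

    Returns the filtered matrix and a removal log with the ND fraction
    of every antibody (kept and dropped).
    """
    cfg = cfg or PreprocessConfig()
    if matrix.stage != "net" or matrix.nd_mask is None:
        raise PreprocessError("filter_antibodies requires stage 'net' with nd_mask")
    measured = matrix.values.notna()
    if cfg.nd_frac_level == "replicate":
        nd_frac = matrix.nd_mask.sum(axis=1) / measured.sum(axis=1)
    else:
        nd_all = (matrix.nd_mask | ~measured).T.groupby(level=0).all().T
        nd_frac = nd_all.sum(axis=1) / nd_all.shape[1]
    dropped = nd_frac > cfg.max_nd_frac
    log = pd.DataFrame({"nd_frac": nd_frac, "dropped": dropped})
    if dropped.all():
        raise PreprocessError(
            f"all {len(nd_frac)} antibodies exceed the ND limit {cfg.max_nd_frac}; "
            f"min ND fraction {nd_frac.min():.3f}"
        )
    keep = nd_frac.index[~dropped]
    out = ExpressionMatrix(
        values=matrix.values.loc[keep],
        stage="net",
        nd_mask=matrix.nd_mask.loc[keep],
    )
    return out, log


def replace_nd(matrix: ExpressionMatrix, cfg: PreprocessConfig | None = None) -> ExpressionMatrix:
    """Impute non-detectable spots with a detection-floor surrogate.

    Each ND replicate value is replaced by the greatest of

    - half the minimum non-ND net value among that antibody's replicates
      in the same sample,
    - half the minimum non-ND net value of that antibody across all
      samples (the fallback when the whole sample is ND),
    - the configured floor (default 1),

    so every imputed value is positive and never above the antibody's
    detected range. Non-ND values are untouched.
    """
    cfg = cfg or PreprocessConfig()
    if matrix.stage != "net" or matrix.nd_mask is None:
        raise PreprocessError("replace_nd requires stage 'net' with nd_mask")
    vals = matrix.values.to_numpy(dtype=float).copy()
    nd = matrix.nd_mask.to_numpy(dtype=bool)
    detected = np.where(~nd & np.isfinite(vals), vals, np.inf)

    samples = matrix.values.columns.get_level_values(0)
    sample_codes, _ = pd.factorize(samples, sort=False)
    n_samples = sample_codes.max() + 1
    # per-(antibody, sample) minimum of detected replicate values
    sample_min = np.full((vals.shape[0], n_samples), np.inf)
    for s in range(n_samples):
        sample_min[:, s] = detected[:, sample_codes == s].min(axis=1)
    global_min = detected.min(axis=1)

    half_sample = 0.5 * sample_min[:, sample_codes]
    half_global = np.broadcast_to(0.5 * global_min[:, None], vals.shape)
    replacement = np.maximum(
        np.where(np.isfinite(half_sample), half_sample, -np.inf),
        np.where(np.isfinite(half_global), half_global, -np.inf),
    )
    replacement = np.maximum(replacement, cfg.nd_floor)
    vals[nd] = replacement[nd]
    out = pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, stage="imputed", nd_mask=None)


def log2_replicate_average(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Log2-transform replicate values, then average them per sample."""
    if matrix.stage != "imputed":
        raise PreprocessError("log2_replicate_average requires stage 'imputed'")
    vals = matrix.values.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        bad = matrix.values.index[np.nanmin(vals, axis=1) <= 0][0]
        raise PreprocessError(f"non-positive value in antibody {bad!r}; run replace_nd first")
    logged = matrix.values.apply(np.log2)
    averaged = logged.T.groupby(level=0, sort=False).mean().T
    averaged = averaged[list(dict.fromkeys(matrix.values.columns.get_level_values(0)))]
    return ExpressionMatrix(values=averaged, stage="log2_averaged")


def iterative_median_polish(
    matrix: ExpressionMatrix, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Iterative row/column median centering and sum-of-squares normalization.

    Each of ``polish_iterations`` rounds applies, in this fixed order:
    row median-center, row SS-normalize, column median-center, column
    SS-normalize. Normalization scales each vector so its sum of squares
    equals its length (root-mean-square 1). Rows go first so that a
    constant offset on an antibody row is removed before it can leak
    into the column statistics (making the result exactly invariant to
    per-antibody offsets). The fixed point — all row and column medians
    0 and all sums of squares at target — is the contract; the default
    50 iterations reaches it to well below 1e-6 on any non-degenerate
    matrix.

    Returns the polished matrix and a per-iteration convergence log
    (max |median| and max relative SS deviation, rows and columns).
    """
    cfg = cfg or PreprocessConfig()
    if matrix.stage != "log2_averaged":
        raise PreprocessError("iterative_median_polish requires stage 'log2_averaged'")
    X = matrix.values.to_numpy(dtype=float).copy()
    n_rows, n_cols = X.shape
    if (np.ptp(X, axis=1) == 0).any():
        bad = matrix.values.index[np.ptp(X, axis=1) == 0][0]
        raise PreprocessError(f"constant row {bad!r}: cannot normalize")
    if (np.ptp(X, axis=0) == 0).any():
        bad = matrix.values.columns[np.ptp(X, axis=0) == 0][0]
        raise PreprocessError(f"constant column {bad!r}: cannot normalize")

    deltas = []
    it = 0
    while True:
        X -= np.median(X, axis=1, keepdims=True)
        row_rms = np.sqrt((X**2).sum(axis=1, keepdims=True) / n_cols)
        if (row_rms == 0).any():
            bad = matrix.values.index[int(np.argmin(row_rms))]
            raise PreprocessError(f"zero-variance row {bad!r} during normalization")
        X /= row_rms
        X -= np.median(X, axis=0, keepdims=True)
        col_rms = np.sqrt((X**2).sum(axis=0) / n_rows)
        if (col_rms == 0).any():
            bad = matrix.values.columns[int(np.argmin(col_rms))]
            raise PreprocessError(f"zero-variance column {bad!r} during normalization")
        X /= col_rms
        it += 1
        deltas.append(
            {
                "iteration": it,
                "max_abs_row_median": float(np.abs(np.median(X, axis=1)).max()),
                "max_abs_col_median": float(np.abs(np.median(X, axis=0)).max()),
                "max_rel_row_ss_dev": float(np.abs((X**2).sum(axis=1) / n_cols - 1).max()),
                "max_rel_col_ss_dev": float(np.abs((X**2).sum(axis=0) / n_rows - 1).max()),
            }
        )
        dev = max(deltas[-1][k] for k in ("max_abs_row_median", "max_abs_col_median", "max_rel_row_ss_dev", "max_rel_col_ss_dev"))
        if it >= cfg.polish_iterations and (dev <= cfg.polish_tol or it >= 20 * cfg.polish_iterations):
            break
    out = pd.DataFrame(X, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, stage="polished"), pd.DataFrame(deltas)


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each antibody row to mean 0, SD 1 (population SD) across samples."""
    if matrix.stage != "polished":
        raise PreprocessError("zscore_rows requires stage 'polished'")
    X = matrix.values.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = matrix.values.index[sd == 0][0]
        raise PreprocessError(f"zero-SD row {bad!r}: cannot Z-score")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    out = pd.DataFrame(Z, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, stage="zscored")


def preprocess_cohort(
    spots: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Run the full preprocessing chain on a raw spot table.

    Returns the Z-scored antibody x sample matrix and a QC dictionary
    (control antibodies removed, ND fractions, dropped antibodies,
    polish convergence log).
    """
    cfg = cfg or PreprocessConfig()
    net = subtract_background(spots, cfg)
    mat = to_replicate_matrix(net)
    controls: list[str] = []
    if cfg.control_antibodies:
        mat, controls = drop_control_antibodies(mat, cfg.control_antibodies)
    mat, nd_log = filter_antibodies(mat, cfg)
    mat = replace_nd(mat, cfg)
    mat = log2_replicate_average(mat)
    mat, polish_log = iterative_median_polish(mat, cfg)
    mat = zscore_rows(mat)
    qc = {
        "n_input_antibodies": int(nd_log.shape[0]) + len(controls),
        "control_antibodies_removed": controls,
        "dropped_antibodies": {
            str(a): float(f)
            for a, f in nd_log.loc[nd_log["dropped"], "nd_frac"].items()
        },
        "n_analyzed_antibodies": int(mat.values.shape[0]),
        "nd_fractions": {str(a): float(f) for a, f in nd_log["nd_frac"].items()},
        "polish_convergence": polish_log.iloc[-1].to_dict(),
    }
    return mat, qc


def pca_confounders(
    matrix: ExpressionMatrix,
    meta: pd.DataFrame,
    n_components: int = 5,
    categorical: Sequence[str] = ("group", "center", "sex"),
    continuous: Sequence[str] = ("age", "mmse"),
) -> dict:
    """Principal components of the Z-scored matrix and covariate screens.

    Samples are observations, proteins features. Components are computed
    by SVD with a fixed sign convention (the largest-magnitude loading of
    each component is positive), so results are deterministic. Each of
    the first ``n_components`` scores is screened against every covariate
    in the metadata: Kruskal-Wallis for categorical covariates, Spearman
    for continuous ones.

    Returns a dict with ``scores`` (samples x components), ``varexp``
    (variance-explained fractions) and ``assoc_p`` (component x covariate
    p-values).
    """
    if matrix.stage != "zscored":
        raise PreprocessError("pca_confounders requires stage 'zscored'")
    X = matrix.values.to_numpy(dtype=float).T  # samples x proteins
    if n_components > min(X.shape):
        raise PreprocessError(
            f"n_components={n_components} exceeds min(n_samples, n_proteins)={min(X.shape)}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components],
        index=matrix.sample_ids,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    varexp = (S**2 / (S**2).sum())[:n_components]

    meta = meta.set_index("sample_id").loc[matrix.sample_ids]
    assoc: dict[str, dict[str, float]] = {}
    for pc in scores.columns:
        assoc[pc] = {}
        for cov in categorical:
            if cov not in meta.columns:
                continue
            groups = [
                scores.loc[idx, pc].to_numpy()
                for _, idx in meta.groupby(cov, dropna=True).groups.items()
            ]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                assoc[pc][cov] = np.nan
                continue
            assoc[pc][cov] = float(stats.kruskal(*groups).pvalue)
        for cov in continuous:
            if cov not in meta.columns:
                continue
            vals = pd.to_numeric(meta[cov], errors="coerce")
            ok = vals.notna()
            if ok.sum() < 3 or vals[ok].nunique() < 2:
                assoc[pc][cov] = np.nan
                continue
            assoc[pc][cov] = float(stats.spearmanr(scores.loc[ok.to_numpy(), pc], vals[ok]).pvalue)
    return {
        "scores": scores,
        "varexp": pd.Series(varexp, index=scores.columns),
        "assoc_p": pd.DataFrame(assoc).T,
    }
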