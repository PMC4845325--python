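"""Pipeline orchestration.

Ties the stages into the full workflow: (optional) simulation ->
preprocessing -> {differential, trait correlation, differential
co-expression} -> cross-disease comparison, with every stage output
written to disk and digested into a reproducible run report.

The single global seed is expanded into independent per-stage streams
(SeedSequence spawning), so toggling one stage never perturbs another
stage's randomness.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from signalome import io
from signalome.preprocess import PreprocessConfig, preprocess_cohort
from signalome.differential import differential_results, classify_specificity
from signalome.trait import trait_results
from signalome.diffcoexpr import (
    condition_correlations,
    profile_correlations,
    cluster_profiles,
    semantic_validation,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for a full run."""

    out_dir: Path
    spots: Path | None = None
    meta: Path | None = None
    seed: int = 0
    simulate: bool = False
    run_differential: bool = True
    run_trait: bool = True
    run_diffcoexpr: bool = True
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    group_col: str = "group"
    trait_col: str = "mmse"
    n_perm_differential: int = 10_000
    n_perm_trait: int = 1000
    alpha_q: float = 0.05
    k_clusters: int = 8
    r_threshold: float = 0.35
    sim_matrix: Path | None = None
    sim_params: dict = field(default_factory=dict)  # forwarded to SimulationConfig

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        for key in ("out_dir", "spots", "meta", "sim_matrix"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(preprocess=pp, **raw)


_STAGE_STREAMS = ("simulate", "differential", "trait", "diffcoexpr")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent per-stage random streams from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGE_STREAMS, children)}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run report (also written to ``out_dir/report.json``):
    per-stage output digests, parameter echo, wall time and warnings.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = stage_rngs(cfg.seed)
    report: dict = {"stages": {}, "warnings": [], "seed": cfg.seed}
    t0 = time.time()

    def record(stage: str, files: dict[str, Path]) -> None:
        report["stages"][stage] = {name: _digest(p) for name, p in files.items()}

    try:
        if cfg.simulate:
            from signalome.synthetic import SimulationConfig, simulate_cohort

            params = {"seed": int(rngs["simulate"].integers(2**31)), **cfg.sim_params}
            sim_cfg = SimulationConfig(**params)
            cohort = simulate_cohort(sim_cfg)
            spots_path, meta_path = out / "spots.tsv", out / "meta.csv"
            io.write_spot_table(cohort.spots, spots_path)
            io.write_metadata(cohort.meta, meta_path)
            io.write_json(cohort.truth.to_dict(), out / "truth.json")
            record("simulate", {"spots": spots_path, "meta": meta_path, "truth": out / "truth.json"})
        else:
            if cfg.spots is None or cfg.meta is None:
                raise PipelineError("spots and meta files are required unless simulate=true")
            spots_path, meta_path = Path(cfg.spots), Path(cfg.meta)

        spots = io.read_spot_table(spots_path)
        meta = io.read_metadata(meta_path)
    except Exception as exc:
        raise PipelineError(f"stage 'input': {exc}") from exc

    try:
        matrix, qc = preprocess_cohort(spots, cfg.preprocess)
        mat_path = out / "zscored_matrix.tsv"
        io.write_matrix(matrix.values, mat_path)
        io.write_json(qc, out / "preprocess_qc.json")
        record("preprocess", {"matrix": mat_path, "qc": out / "preprocess_qc.json"})
    except Exception as exc:
        raise PipelineError(f"stage 'preprocess': {exc}") from exc

    labels = meta.set_index("sample_id")[cfg.group_col]

    if cfg.run_differential:
        try:
            res = differential_results(
                matrix,
                labels,
                n_perm=cfg.n_perm_differential,
                seed=rngs["differential"],
                alpha_q=cfg.alpha_q,
            )
            path = out / "differential.tsv"
            res.to_csv(path, sep="\t", float_format="%.8g")
            record("differential", {"results": path})
        except Exception as exc:
            raise PipelineError(f"stage 'differential': {exc}") from exc

    if cfg.run_trait:
        try:
            trait = meta.set_index("sample_id")[cfg.trait_col]
            res = trait_results(matrix, trait, n_perm=cfg.n_perm_trait, seed=rngs["trait"])
            path = out / "trait.tsv"
            res.to_csv(path, sep="\t", float_format="%.8g")
            record("trait", {"results": path})
        except Exception as exc:
            raise PipelineError(f"stage 'trait': {exc}") from exc

    if cfg.run_diffcoexpr:
        try:
            mats = condition_correlations(matrix, labels)
            R = profile_correlations(mats.d)
            clusters = cluster_profiles(R, k=cfg.k_clusters)
            files = {}
            for name, df in (("c_ctrl", mats.c_ctrl), ("c_dis", mats.c_dis), ("d", mats.d), ("r", R)):
                p = out / f"{name}_matrix.tsv"
                io.write_matrix(df, p, index_name="protein_id")
                files[name] = p
            ctab = pd.DataFrame(
                {
                    "protein_id": clusters.labels.index,
                    "cluster": clusters.labels.to_numpy(),
                    "leaf_position": [clusters.leaf_order.index(p) for p in clusters.labels.index],
                }
            )
            cpath = out / "clusters.tsv"
            ctab.to_csv(cpath, sep="\t", index=False)
            files["clusters"] = cpath
            if cfg.sim_matrix is not None:
                S = io.read_similarity_matrix(cfg.sim_matrix).loc[R.index, R.columns]
                val = semantic_validation(
                    R, S, r_threshold=cfg.r_threshold, seed=rngs["diffcoexpr"]
                )
                io.write_json(val, out / "semantic_validation.json")
                files["semantic_validation"] = out / "semantic_validation.json"
            record("diffcoexpr", files)
        except Exception as exc:
            raise PipelineError(f"stage 'diffcoexpr': {exc}") from exc

    report["wall_time_s"] = round(time.time() - t0, 3)
    report["params"] = {
        "n_perm_differential": cfg.n_perm_differential,
        "n_perm_trait": cfg.n_perm_trait,
        "alpha_q": cfg.alpha_q,
        "k_clusters": cfg.k_clusters,
        "r_threshold": cfg.r_threshold,
        "nd_margin": cfg.preprocess.nd_margin,
        "max_nd_frac": cfg.preprocess.max_nd_frac,
        "polish_iterations": cfg.preprocess.polish_iterations,
    }
    io.write_json(report, out / "report.json")
    return report


def compare_diseases(res_a: pd.DataFrame, res_b: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Cross-disease comparison of two differential result tables."""
    comp = classify_specificity(res_a, res_b, alpha=alpha)
    return {
        "counts": comp.counts().to_dict(),
        "n_a": comp.n_a,
        "n_b": comp.n_b,
        "n_overlap": comp.n_overlap,
        "n_concordant": comp.n_concordant,
        "universe": comp.universe,
        "hypergeom_p": comp.hypergeom_p,
        "binomial_p": comp.binomial_p,
        "table": comp.table,
    }
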