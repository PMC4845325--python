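"""Synthetic antibody-microarray cohorts with known ground truth.

Generates spot-level data with the statistical structure the analysis
stages assume: log-normal-ish intensities with replicate noise, local
background, non-detect censoring through the background margin rule,
a minority of proteins with mean shifts between groups, block
co-expression that differs between conditions (Gaussian copula, so the
rank-correlation structure survives any monotone intensity mapping), an
integer 0-30 cognition trait tied to a protein subset, and a second
disease cohort sharing a directional signature with the first.

Every generator is a deterministic function of its configuration and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SimulationError(ValueError):
    pass


@dataclass
class ModuleSpec:
    """A block of proteins with equicorrelated latents, per condition."""

    size: int
    r_within_ctrl: float
    r_within_dis: float


@dataclass
class TraitSpec:
    """Cognition-trait model: integer 0-30, linked to a protein subset.

    The linked proteins share a latent cognition factor: each linked
    protein's latent is sqrt(loading) * factor + sqrt(1 - loading) *
    independent noise, and the trait is

        round(clip(intercept + slope * mean(linked latents) + noise, 0, 30))

    with ``missing_frac`` of samples masked (scores not recorded). At
    the defaults each linked protein has R^2 ~ 0.25 with the trait.
    """

    n_linked: int = 40
    loading: float = 0.35
    slope: float = 5.8
    noise_sd: float = 2.0
    missing_frac: float = 0.30
    intercept: float = 22.0


@dataclass
class NoiseSpec:
    """Spot-level noise: multiplicative replicate noise and background.

    Protein base abundances are drawn uniformly on a log2 range well
    above the mean background so detection failures come from the
    censoring mechanism, not from the bulk of the signal.
    """

    replicate_cv: float = 0.15
    background_mean: float = 100.0
    background_cv: float = 0.30
    base_log2_min: float = 10.0
    base_log2_max: float = 14.0


@dataclass
class SecondDiseaseSpec:
    """Second cohort sharing a directional signature with the first."""

    n_samples: int = 47
    shared_fraction: float = 0.5
    own_fraction: float = 0.3


@dataclass
class SimulationConfig:
    """Study conditions for a two-group plasma-array cohort.

    Defaults mirror a ~582-antibody, 47-disease / 52-control design with
    triplicate/quadruplicate printing, a 50-protein differential
    signature of one latent SD, two 30-protein co-expression modules
    rewired between conditions, and 10% non-detect censoring.
    """

    n_proteins: int = 582
    n_ctrl: int = 52
    n_dis: int = 47
    triplicate_fraction: float = 474 / 593
    n_differential: int = 50
    effect_size: float = 1.0
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [ModuleSpec(30, 0.0, 0.6), ModuleSpec(30, 0.6, 0.0)]
    )
    trait: TraitSpec = field(default_factory=TraitSpec)
    censor_quantile: float = 0.10
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    second_disease: SecondDiseaseSpec = field(default_factory=SecondDiseaseSpec)
    n_control_antibodies: int = 0
    n_low_signal: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        # plain dicts (e.g. from a YAML config) are promoted to spec objects
        self.modules = [ModuleSpec(**m) if isinstance(m, dict) else m for m in self.modules]
        if isinstance(self.trait, dict):
            self.trait = TraitSpec(**self.trait)
        if isinstance(self.noise, dict):
            self.noise = NoiseSpec(**self.noise)
        if isinstance(self.second_disease, dict):
            self.second_disease = SecondDiseaseSpec(**self.second_disease)
        if sum(m.size for m in self.modules) > self.n_proteins:
            raise SimulationError("module sizes exceed n_proteins")
        for m in self.modules:
            if not (-1 < m.r_within_ctrl < 1 and -1 < m.r_within_dis < 1):
                raise SimulationError(f"module correlation out of (-1,1): {m}")
        if not 0 <= self.censor_quantile < 1:
            raise SimulationError("censor_quantile must be in [0,1)")
        free = self.n_proteins - sum(m.size for m in self.modules) - self.n_low_signal
        if self.n_differential + self.trait.n_linked > free:
            raise SimulationError(
                "differential + trait-linked budget exceeds the proteins outside "
                f"modules and low-signal set ({free} free)"
            )
        if not 0 <= self.trait.loading < 1:
            raise SimulationError("trait loading must be in [0,1)")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    differential: dict[str, int]  # antibody_id -> direction (+1/-1)
    trait_linked: list[str]
    module_membership: dict[str, int]  # antibody_id -> module index (1-based)
    rewired_pairs: list[tuple[str, str]]
    low_signal: list[str]
    second_disease_shared: dict[str, int] = field(default_factory=dict)
    second_disease_own: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "differential": self.differential,
            "trait_linked": self.trait_linked,
            "module_membership": self.module_membership,
            "rewired_pairs": [list(p) for p in self.rewired_pairs],
            "low_signal": self.low_signal,
            "second_disease_shared": self.second_disease_shared,
            "second_disease_own": self.second_disease_own,
        }


@dataclass
class Cohort:
    """A simulated cohort: spot table, metadata, truth, and latents."""

    spots: pd.DataFrame
    meta: pd.DataFrame
    truth: GroundTruth
    latent: pd.DataFrame  # proteins x samples, SD units (with shifts applied)
    config: SimulationConfig
    base_log2: np.ndarray | None = None  # per-antibody abundance, log2 units
    rep_counts: np.ndarray | None = None


def gaussian_copula_spearman(r: float) -> float:
    """Spearman correlation implied by a Gaussian copula with Pearson r."""
    return 6.0 / np.pi * np.arcsin(r / 2.0)


def _module_chol(size: int, r: float) -> np.ndarray:
    sigma = np.full((size, size), r)
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise SimulationError(f"module block (size={size}, r={r}) not positive definite") from exc


def _draw_latent(
    rng: np.random.Generator, cfg: SimulationConfig, n_samples: int, condition: str
) -> np.ndarray:
    """Latent protein x sample matrix with the condition's block correlation."""
    L = rng.standard_normal((cfg.n_proteins, n_samples))
    start = 0
    for mod in cfg.modules:
        r = mod.r_within_ctrl if condition == "control" else mod.r_within_dis
        block = slice(start, start + mod.size)
        if r != 0.0:
            chol = _module_chol(mod.size, r)
            L[block] = chol @ L[block]
        start += mod.size
    return L


def _antibody_ids(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    signal = [f"AB{i + 1:04d}" for i in range(cfg.n_proteins)]
    controls = [f"CTRL{i + 1:03d}" for i in range(cfg.n_control_antibodies)]
    return signal, controls


def _replicate_counts(cfg: SimulationConfig, n_antibodies: int, rng: np.random.Generator) -> np.ndarray:
    """3 or 4 replicates per antibody (two physical array types)."""
    n_trip = int(round(cfg.triplicate_fraction * n_antibodies))
    reps = np.full(n_antibodies, 4, dtype=int)
    reps[:n_trip] = 3
    return reps


def _spots_from_latent(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    latent: np.ndarray,
    base_log2: np.ndarray,
    sample_ids: list[str],
    antibody_ids: list[str],
    rep_counts: np.ndarray,
    low_signal_mask: np.ndarray,
) -> pd.DataFrame:
    """Map latents to spot-level foreground/background intensities.

    Intensity per (antibody, sample) is 2**(base + latent); replicate
    foregrounds get multiplicative log-normal noise at the configured
    CV; backgrounds are log-normal around ``background_mean``. Pairs
    whose intensity falls below the antibody's censor quantile have
    their replicate backgrounds inflated above the foreground so the
    downstream 10%-above-background rule flags them ND — the real code
    path produces the non-detects, not a mask.
    """
    n_prot, n_samp = latent.shape
    base = base_log2.copy()
    base[low_signal_mask] = np.log2(max(cfg.noise.background_mean, 2.0)) - 4.0
    intensity = 2.0 ** (base[:, None] + latent)

    if cfg.censor_quantile > 0:
        thresh = np.quantile(intensity, cfg.censor_quantile, axis=1, keepdims=True)
        censor = intensity < thresh
    else:
        censor = np.zeros_like(intensity, dtype=bool)
    censor |= low_signal_mask[:, None]

    sigma_rep = np.sqrt(np.log1p(cfg.noise.replicate_cv**2))
    sigma_bg = np.sqrt(np.log1p(cfg.noise.background_cv**2))
    mu_bg = np.log(cfg.noise.background_mean) - sigma_bg**2 / 2.0

    rows_ab, rows_sample, rows_rep, rows_fg, rows_bg = [], [], [], [], []
    max_rep = int(rep_counts.max())
    # draw all replicate noise at once: (n_prot, n_samp, max_rep)
    noise = np.exp(rng.normal(0.0, sigma_rep, size=(n_prot, n_samp, max_rep)))
    fg_all = intensity[:, :, None] * noise
    bg_all = np.exp(rng.normal(mu_bg, sigma_bg, size=(n_prot, n_samp, max_rep)))
    # censored pairs: background raised above every replicate foreground
    fg_max = fg_all.max(axis=2)
    bg_all = np.where(censor[:, :, None], fg_max[:, :, None] * 1.3, bg_all)

    for r in range(max_rep):
        has_rep = rep_counts > r
        idx_prot = np.where(has_rep)[0]
        n_rows = idx_prot.size * n_samp
        rows_ab.append(np.repeat(np.array(antibody_ids, dtype=object)[idx_prot], n_samp))
        rows_sample.append(np.tile(np.array(sample_ids, dtype=object), idx_prot.size))
        rows_rep.append(np.full(n_rows, r + 1, dtype=int))
        rows_fg.append(fg_all[idx_prot, :, r].ravel())
        rows_bg.append(bg_all[idx_prot, :, r].ravel())

    spots = pd.DataFrame(
        {
            "array_id": np.concatenate(rows_sample),
            "antibody_id": np.concatenate(rows_ab),
            "replicate_index": np.concatenate(rows_rep),
            "foreground": np.round(np.concatenate(rows_fg), 3),
            "background": np.round(np.concatenate(rows_bg), 3),
        }
    )
    return spots.sort_values(["array_id", "antibody_id", "replicate_index"], kind="mergesort").reset_index(
        drop=True
    )


def simulate_trait(
    latent: np.ndarray,
    linked_rows: np.ndarray,
    spec: TraitSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer 0-30 trait driven by the mean of the linked latents.

    Returns a float vector with NaN for masked (missing) samples.
    """
    signal = latent[linked_rows].mean(axis=0) if linked_rows.size else np.zeros(latent.shape[1])
    raw = spec.intercept + spec.slope * signal + rng.normal(0.0, spec.noise_sd, size=latent.shape[1])
    trait = np.clip(np.round(raw), 0, 30).astype(float)
    n = trait.size
    n_missing = int(round(spec.missing_frac * n))
    if n_missing:
        trait[rng.choice(n, size=n_missing, replace=False)] = np.nan
    return trait


def simulate_cohort(cfg: SimulationConfig | None = None) -> Cohort:
    """Simulate a two-group cohort at spot level with known ground truth.

    Control and disease latents are drawn from multivariate Gaussians
    whose block correlation differs per ``cfg.modules`` (Gaussian
    copula: the Spearman structure is inherited monotonically by the
    intensities). Differential proteins get a +/- effect_size mean shift
    in the disease group. Latents are mapped to positive intensities,
    replicate foregrounds and backgrounds are drawn, and low-intensity
    pairs are censored through the background-margin rule.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    signal_ids, control_ids = _antibody_ids(cfg)
    all_ids = signal_ids + control_ids
    n_all = len(all_ids)

    # planted structure lives outside the co-expression modules; the
    # low-signal antibodies (dropped by QC) are excluded from the budget
    module_total = sum(m.size for m in cfg.modules)
    free = np.arange(module_total, cfg.n_proteins)
    low_rows = rng.choice(free, size=cfg.n_low_signal, replace=False) if cfg.n_low_signal else np.array([], dtype=int)
    eligible = np.setdiff1d(free, low_rows)
    picked = rng.choice(eligible, size=cfg.n_differential + cfg.trait.n_linked, replace=False)
    diff_rows = picked[: cfg.n_differential]
    trait_rows = picked[cfg.n_differential :]
    directions = rng.choice([-1, 1], size=cfg.n_differential)

    L_ctrl = _draw_latent(rng, cfg, cfg.n_ctrl, "control")
    L_dis = _draw_latent(rng, cfg, cfg.n_dis, "disease")

    ctrl_ids = [f"C{i + 1:03d}" for i in range(cfg.n_ctrl)]
    dis_ids = [f"D{i + 1:03d}" for i in range(cfg.n_dis)]
    sample_ids = ctrl_ids + dis_ids
    latent = np.hstack([L_ctrl, L_dis])

    # shared cognition factor across the trait-linked proteins
    g = rng.standard_normal(latent.shape[1])
    w = cfg.trait.loading
    latent[trait_rows] = np.sqrt(w) * g + np.sqrt(1.0 - w) * latent[trait_rows]
    latent[diff_rows[:, None], np.arange(cfg.n_ctrl, latent.shape[1])] += (
        directions[:, None] * cfg.effect_size
    )

    # control antibodies ride along with ordinary signal, no planted structure
    if cfg.n_control_antibodies:
        extra = rng.standard_normal((cfg.n_control_antibodies, latent.shape[1]))
        latent_all = np.vstack([latent, extra])
    else:
        latent_all = latent
    base_log2 = rng.uniform(cfg.noise.base_log2_min, cfg.noise.base_log2_max, size=n_all)
    low_mask = np.zeros(n_all, dtype=bool)
    low_mask[low_rows] = True
    rep_counts = _replicate_counts(cfg, n_all, rng)

    spots = _spots_from_latent(
        rng, cfg, latent_all, base_log2, sample_ids, all_ids, rep_counts, low_mask
    )

    trait = simulate_trait(latent, trait_rows, cfg.trait, rng)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["control"] * cfg.n_ctrl + ["disease"] * cfg.n_dis,
            "center": rng.choice(["UCSF", "Mayo"], size=len(sample_ids)),
            "age": np.clip(np.round(rng.normal(72, 8, size=len(sample_ids))), 50, 95).astype(int),
            "sex": rng.choice(["F", "M"], size=len(sample_ids)),
            "mmse": trait,
        }
    )

    membership: dict[str, int] = {}
    rewired: list[tuple[str, str]] = []
    start = 0
    for mi, mod in enumerate(cfg.modules, start=1):
        ids = signal_ids[start : start + mod.size]
        for a in ids:
            membership[a] = mi
        if mod.r_within_ctrl != mod.r_within_dis:
            rewired.extend((ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids)))
        start += mod.size

    truth = GroundTruth(
        differential={signal_ids[r]: int(d) for r, d in zip(diff_rows, directions)},
        trait_linked=[signal_ids[r] for r in sorted(trait_rows)],
        module_membership=membership,
        rewired_pairs=rewired,
        low_signal=[signal_ids[r] for r in sorted(low_rows)],
    )
    latent_df = pd.DataFrame(latent, index=signal_ids, columns=sample_ids)
    return Cohort(
        spots=spots,
        meta=meta,
        truth=truth,
        latent=latent_df,
        config=cfg,
        base_log2=base_log2,
        rep_counts=rep_counts,
    )


def simulate_second_disease(cfg: SimulationConfig, first: Cohort) -> Cohort:
    """Second disease cohort sharing the first cohort's controls.

    Re-uses the control samples (spots and all) and draws a new disease
    group in which ``shared_fraction`` of the first cohort's
    differential proteins are shifted in the SAME direction, and an
    additional ``own_fraction`` of the differential budget — disjoint
    proteins — are shifted independently. Quadrant classification of the
    two result sets should recover the shared proteins as "general" and
    the rest per construction.
    """
    sd = cfg.second_disease
    if sd.shared_fraction + sd.own_fraction > 1.0 + 1e-9:
        raise SimulationError("shared_fraction + own_fraction must be <= 1")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]).generate_state(1)[0])
    signal_ids, _ = _antibody_ids(cfg)

    diff_a = list(first.truth.differential.items())
    n_shared = int(round(sd.shared_fraction * len(diff_a)))
    n_own = int(round(sd.own_fraction * len(diff_a)))
    shared_idx = rng.choice(len(diff_a), size=n_shared, replace=False)
    shared = {diff_a[i][0]: diff_a[i][1] for i in shared_idx}
    pool = [a for a in signal_ids if a not in first.truth.differential and a not in first.truth.low_signal]
    own_ids = rng.choice(len(pool), size=n_own, replace=False)
    own = {pool[i]: int(d) for i, d in zip(own_ids, rng.choice([-1, 1], size=n_own))}

    row_of = {a: i for i, a in enumerate(signal_ids)}
    L_b = _draw_latent(rng, cfg, sd.n_samples, "control")
    for a, d in {**shared, **own}.items():
        L_b[row_of[a]] += d * cfg.effect_size

    b_ids = [f"B{i + 1:03d}" for i in range(sd.n_samples)]
    n_all = cfg.n_proteins + cfg.n_control_antibodies
    if cfg.n_control_antibodies:
        latent_all = np.vstack([L_b, rng.standard_normal((cfg.n_control_antibodies, sd.n_samples))])
    else:
        latent_all = L_b
    # same arrays, same antibodies: abundance and print layout carry over
    base_log2 = first.base_log2
    rep_counts = first.rep_counts
    low_mask = np.zeros(n_all, dtype=bool)
    low_mask[[row_of[a] for a in first.truth.low_signal]] = True
    all_ids = signal_ids + [f"CTRL{i + 1:03d}" for i in range(cfg.n_control_antibodies)]
    spots_b = _spots_from_latent(rng, cfg, latent_all, base_log2, b_ids, all_ids, rep_counts, low_mask)

    ctrl_mask = first.meta["group"] == "control"
    ctrl_ids = list(first.meta.loc[ctrl_mask, "sample_id"])
    spots = pd.concat(
        [first.spots[first.spots["array_id"].isin(ctrl_ids)], spots_b], ignore_index=True
    )
    meta_b = pd.DataFrame(
        {
            "sample_id": b_ids,
            "group": "disease",
            "center": rng.choice(["UCSF", "Mayo"], size=sd.n_samples),
            "age": np.clip(np.round(rng.normal(68, 8, size=sd.n_samples)), 50, 95).astype(int),
            "sex": rng.choice(["F", "M"], size=sd.n_samples),
            "mmse": np.nan,
        }
    )
    meta = pd.concat([first.meta[ctrl_mask], meta_b], ignore_index=True)
    truth = GroundTruth(
        differential={**shared, **own},
        trait_linked=[],
        module_membership=first.truth.module_membership,
        rewired_pairs=[],
        low_signal=list(first.truth.low_signal),
        second_disease_shared=shared,
        second_disease_own=own,
    )
    latent_df = pd.DataFrame(
        np.hstack([first.latent.loc[signal_ids, ctrl_ids].to_numpy(), L_b]),
        index=signal_ids,
        columns=ctrl_ids + b_ids,
    )
    return Cohort(spots=spots, meta=meta, truth=truth, latent=latent_df, config=cfg)


def simulate_gene_pvalues(
    n_genes: int,
    enriched_ids: list[str] | None = None,
    beta_a: float = 0.2,
    beta_b: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gene-level p-value sample for the KS enrichment stage.

    Genes listed in ``enriched_ids`` draw p ~ Beta(beta_a, beta_b)
    (concentrated near 0 at the defaults); all others draw
    p ~ Uniform(0, 1]. Returns a DataFrame with columns gene, p.
    """
    if beta_a <= 0 or beta_b <= 0:
        raise SimulationError("beta parameters must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    enriched = set(enriched_ids or [])
    unknown = enriched - set(genes)
    if unknown:
        raise SimulationError(f"enriched ids not in gene universe: {sorted(unknown)[:5]}")
    p = 1.0 - rng.random(n_genes)  # (0, 1]
    if enriched:
        mask = np.array([g in enriched for g in genes])
        p[mask] = np.clip(rng.beta(beta_a, beta_b, size=int(mask.sum())), 1e-300, 1.0)
    return pd.DataFrame({"gene": genes, "p": p})
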