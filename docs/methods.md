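# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic-data tests do and do not demonstrate about real data.

## Preprocessing

Input is a long-format spot table: one row per printed spot with its
foreground mean and local background median (the pipeline starts at
spot summary statistics; image quantification is out of scope).

**Background and non-detects.** For each (array, antibody) replicate
group the local background *B* is the median of the replicate
backgrounds, and each replicate's net signal is `foreground − B`. A spot
is non-detectable (ND) when its foreground is less than `(1 +
nd_margin)·B`; the default margin of 0.10 means "less than 10% above
background". Both thresholds are strict inequalities: a spot exactly 10%
above background is detected, an antibody with exactly 55% ND spots is
retained. When *B* = 0 the ratio rule is degenerate; such a spot is ND
iff its foreground is zero. ND fractions for the exclusion rule are
counted at replicate level across all arrays (each measured spot counts
once); a sample-level convention is available via `nd_frac_level`.

**ND imputation.** Each ND replicate is replaced by the greatest of:
half the minimum detected net value among that antibody's replicates in
the same sample; half the minimum detected net value of that antibody
anywhere (the fallback when the whole sample is ND); and a floor of 1
intensity unit. Imputed values are therefore positive, below the
detected range, and never below the floor; detected values are never
touched.

**Transform and averaging.** Replicate values are log2-transformed and
then averaged per (antibody, sample) — the mean of logs, not the log of
means, so a single high replicate cannot dominate.

**Iterative median polish.** Each round applies row median-centering,
row sum-of-squares normalization, column median-centering, column
sum-of-squares normalization. The sum-of-squares target is the vector
length, i.e. every row and column ends with root-mean-square 1 (the
target is a free constant; RMS 1 makes the polished scale comparable
across matrix shapes). Rows are processed before columns so that a
constant offset on a protein row is removed before it can leak into the
column statistics — this makes the output exactly invariant to
per-protein additive offsets, which is the property one wants from a
centering step. The contract is the fixed point (all medians 0, all
sums of squares on target, to 1e-6), not the path: 50 rounds are always
run, and extra rounds (capped at 20×) are appended in the rare cases —
small matrices with slow geometric convergence — where 50 does not yet
reach 1e-8. At the study scale of 582 × 99 the deviation after 50
rounds is already ~1e-14.

**Z-scoring** is per antibody row with the population-SD convention,
giving every protein mean 0 / SD 1 across samples — the scale the
downstream t-tests and correlation stages assume. Zero-variance rows
are an error here, not silently dropped.

**PCA confounder screen.** Components are computed by SVD on the
centered sample × protein matrix with a fixed sign convention (the
largest-magnitude loading of each component is positive), so results
are machine-independent. Scores are screened against categorical
covariates by Kruskal–Wallis and continuous ones by Spearman; the
output is a component × covariate p-value table, left to the analyst's
judgment rather than an automatic correction (no batch correction is
applied anywhere — the design assumes samples processed in one batch).

## Differential protein levels

The statistic is an unpaired two-tailed pooled-variance t (Welch
available via `flavor="welch"`); significance comes from class-label
permutations with the original group sizes. The permutation p-value
uses an add-one pseudocount, `p_corr = (1 + #{|t*| ≥ |t_obs|}) /
(n_perm + 1)`, so it is never zero — a deliberate deviation from
tooling that reports 0, since a permutation p of 0 is not statistically
meaningful. One shared permutation set is used for all proteins: this
makes a 582-protein run reproducible from a single seed and fast
(matrix products against a permutation indicator matrix), at the price
of weak dependence between protein p-values; per-protein independent
sets are available via `shared_permutations=False`. Permutations are
drawn in sorted-sample-id space, so reordering the input columns leaves
every p-value bit-identical. For small cohorts `exhaustive=True`
enumerates all label splits and returns the exact permutation p.

**q-values** follow the direct approach: pi0 is estimated on the grid
λ = 0.05…0.95 as `#{p > λ} / (m(1 − λ))`, extrapolated to λ → 1 with a
cubic smoothing spline, and clipped to (1/m, 1]; sorted q-values are
the step-down minima of `pi0·m·p_(i)/i`. For fewer than 100 p-values
the grid estimates are too noisy and pi0 falls back to 1 (equivalent to
Benjamini–Hochberg) — underestimating pi0 on small panels is
anticonservative, and conservatism is the right failure mode for an
FDR estimate.

**Cross-disease comparison.** Proteins are classified at strict p <
0.05 in each disease: significant in both with the same direction =
"general"; in one only = disease-specific; in both with opposite
directions = "discordant", kept as its own bucket rather than silently
dropped (the class exists by construction even if rare in practice).
Overlap significance is the hypergeometric upper tail P(X ≥ overlap);
directional concordance among overlapping hits is the Binomial(n, ½)
upper tail — 39 concordant of 39 gives 0.5³⁹ ≈ 1.8 × 10⁻¹².

## Trait correlation

Spearman rank correlation (average ranks for ties) of each protein
against the trait over pairwise-complete samples; samples without a
trait value are excluded per protein–trait pair and `n_used` is
reported. The analytic p_rho uses the t approximation
`t = rho·sqrt((n−2)/(1−rho²))`. The permutation p_perm permutes trait
values over the usable samples (one shared set, drawn in sorted-id
space) and compares |rho*| two-sidedly — the two-sided form matches
reporting both positive and negative correlates. p_perm is kept as the
literal count / n_perm, so 0 is possible (a perfect monotone
association can never be beaten by a permutation); the add-one variant
is opt-in. Both groups are pooled for the correlation by default, with
a group filter available, since trait scores exist in both groups.

## Differential co-expression

Per condition, the all-pairs Spearman matrix is computed; the
differential matrix D = C_dis − C_ctrl captures each pair's correlation
change (symmetric, zero diagonal, entries in [−2, 2]). The profile
correlation R[i,j] is the Pearson correlation between rows i and j of D
over the columns excluding i and j: the self-pair columns are
structurally constrained (diagonal zeros and the shared entry D[i,j])
and would bias R upward. It is computed in closed form from row sums,
so the leave-two-out definition costs O(n²) rather than O(n³). Pearson
(not Spearman) on the profiles is the default because profiles are
already on a common correlation scale; a rank variant would discard
the magnitude of rewiring.

Clustering is average-linkage agglomeration on 1 − R, cut to k flat
clusters (k = 8 by default; no automatic k selection is attempted).
Leaves are ordered by an exact dynamic program that minimizes the total
distance between adjacent leaves over all 2^(n−1) dendrogram-consistent
orders, with ties broken toward input order. The DP is implemented in
the package (O(n³), ~0.3 s at n = 582) and is verified against
exhaustive enumeration in the tests; the scipy implementation of the
same ordering was found to return non-optimal (though tree-consistent)
orders on a quarter of random small instances and is not used.

**Semantic validation** takes an externally supplied pairwise
similarity matrix S (entries in [0, 1]; no ontology access happens in
the package), selects the unordered pairs with R > 0.35, and compares
their median similarity against medians of equally many pairs drawn
uniformly without replacement; the p-value uses the add-one pseudocount.
Uniform pair draws match a "by chance" null; a degree-preserving null
is a possible refinement, not implemented.

**A structural caveat found during development:** if the protein
universe consists of exactly two complementary rewired modules and
nothing else, the two modules' differential profiles become *positively*
collinear after centering (each reads "module A down, module B up"), and
no profile-correlation method can separate them at k = 2. With the
modules embedded among unaffected background proteins — the realistic
regime — separation is essentially perfect. The recovery tests
therefore embed two 30-protein modules among 60 background proteins and
cut at k = 3 (background forms its own cluster).

## Enrichment statistics

**EASE score:** the one-sided Fisher exact (hypergeometric upper-tail)
enrichment p computed after removing one gene from the query∩annotation
cell — `P(X ≥ hits − 1)` with the margins unchanged, and p = 1 whenever
hits ≤ 1. This is always ≥ the classical Fisher p, penalizing
categories supported by one or two genes. Identifiers are uppercased,
stripped and deduplicated before any set arithmetic.

**KS p-value enrichment:** a one-sample KS test of observed p-values
against Uniform(0,1) (the expected distribution when no gene is
associated), or a two-sample KS when an explicit expected sample is
given; D is the supremum ECDF gap.

**Chi-square hit rate:** the observed number of annotated proteins in a
hit list versus the expectation `list_size · hits_total / total` from
the background rate, as a 2-cell goodness-of-fit without continuity
correction (the expected-value construction is explicitly rate-based,
which the goodness-of-fit form matches better than a 2×2 independence
test; the 2×2 form and Yates correction are available as options). An
expected cell below 1 is an error recommending an exact test.

## Synthetic cohorts

The generator emulates the data regime the pipeline targets: ~582
antibodies × ~100 samples in two groups, triplicate printing for ~80%
of antibodies and quadruplicate for the rest (two physical array
types), log-normal-ish intensities, and ND censoring.

- **Latent layer.** Per condition, protein latents are multivariate
  Gaussian with block-equicorrelated modules whose within-module r can
  differ between conditions (the rewiring signal). Because every
  downstream correlation is rank-based and levels are Z-scored, only
  the copula matters: the implied Spearman correlation is
  (6/π)·arcsin(r/2), and the generated ranks match it to ±0.05 at
  n = 200 in the tests. Differential proteins get a ±Δ mean shift
  (default Δ = 1 latent SD on 50 of 582 proteins) in the disease group.
  Planted differential and trait proteins are drawn from outside the
  modules so the two kinds of structure remain separable.
- **Intensity layer.** Latents map to intensities as
  `2^(base + latent)` with per-antibody base abundances uniform on
  log2 [10, 14] — well above the mean background of 100 units, so
  detectability is governed by the censoring mechanism, not by the bulk
  of the signal. Replicate foregrounds get multiplicative log-normal
  noise (CV 0.15); backgrounds are log-normal (CV 0.30).
- **ND censoring** inflates the replicate backgrounds of the
  (antibody, sample) pairs in the lowest `censor_quantile` (default
  10%) of each antibody's intensity distribution, so the actual
  10%-above-background rule — not a mask — produces the NDs, and the
  spot-level ND fraction tracks the quantile to ±0.02. "Low-signal"
  antibodies (for QC accounting scenarios) sit 4 log2 units below
  background and are ND everywhere.
- **Trait.** Linked proteins share a latent cognition factor with
  loading 0.35; the trait is `round(clip(22 + 5.8·mean(linked latents)
  + N(0, 2²), 0, 30))` with 30% of scores missing. At these defaults
  each linked protein has R² ≈ 0.25 with the trait. The shared factor
  is essential: if the trait were driven by the mean of *independent*
  linked proteins, each protein's correlation with it would be bounded
  by 1/√n_linked ≈ 0.16 and no per-protein recovery target near
  R² = 0.25 would be attainable — correlated trait-linked proteins are
  also the biologically plausible regime (they sit in shared pathways).
  The trait is independent of disease status by default so that trait
  recovery and differential power can be assessed without confounding.
- **Second disease** reuses the first cohort's control samples, base
  abundances and print layout, and draws a new disease group in which
  half of the first signature (by default) is shifted in the same
  direction and a disjoint 30% of the budget is shifted independently —
  the regime where quadrant classification should label shared proteins
  "general".

**What passing tests show and what they do not.** The generator's
marginals are clean log-normals with exchangeable samples; real plasma
arrays have heavier tails, antibody cross-reactivity, plate-position
effects and center-dependent handling differences, none of which are
simulated. Calibration and recovery results on synthetic cohorts
therefore validate the *statistical machinery* (type-I control, FDR
control, power at the design effect size, structure recovery), not the
biology of any particular cohort.

## Numerical conventions and edge cases

- All randomness flows through `numpy.random.Generator`; every public
  operation takes a seed or generator, and the pipeline expands one
  global seed into independent per-stage streams so toggling one stage
  never perturbs another.
- Permutation draws happen in sorted-sample-id space: results are
  invariant to input column order.
- Degenerate inputs (constant rows, zero-variance profiles, empty
  groups, all-ND panels) raise errors naming the offender; nothing is
  silently dropped or NaN-filled.
- Matrix TSVs are written with `%.17g` and read with round-trip float
  parsing, so write∘read is bit-exact.
- Problem sizes in the test and acceptance runs (500–1000 proteins,
  20–50 replicates, 1000–2000 permutations) are chosen to estimate each
  rate to comfortably better than its tolerance; the full 10,000/1,000
  permutation defaults remain the analysis defaults.

## Known limitations

- No covariate-adjusted differential models (by design: the protein
  stage uses none); confounding is screened, not corrected.
- The EASE/KS/chi-square stages consume caller-supplied gene sets,
  p-value samples and similarity matrices; no ontology or database
  retrieval is included.
- pi0 estimation falls back to 1 below 100 p-values; q-values on small
  panels are BH-conservative.
- `semantic_validation` draws uniform pair nulls; hub proteins with
  many high-R partners are not degree-matched.
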