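"""Enrichment and validation statistics.

EASE-score gene-set enrichment (conservative modified Fisher exact
test), Kolmogorov-Smirnov comparison of an observed p-value distribution
against its expectation, and the chi-square hit-rate test used to
compare a hit list's annotation rate against a background rate.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy import stats


class EnrichError(ValueError):
    pass


def normalize_gene_set(genes: Iterable[str]) -> frozenset[str]:
    """Uppercase, strip whitespace, drop empties, deduplicate."""
    return frozenset(g.strip().upper() for g in genes if g and g.strip())


def ease_score(query: Iterable[str], annotation: Iterable[str], background: Iterable[str]) -> float:
    """EASE-score enrichment p-value of an annotation in a query set.

    A conservative variant of the one-sided Fisher exact test: one gene
    is removed from the query-annotation overlap before computing the
    hypergeometric upper tail, which penalizes categories supported by
    very few genes. With N = |background|, K = |annotation in background|,
    n = |query| and h = |query in annotation|:

        p = P(X >= h - 1),  X ~ Hypergeom(N, K, n)

    and p = 1 whenever h <= 1 (removing the hit empties the cell).
    """
    query = normalize_gene_set(query)
    annotation = normalize_gene_set(annotation)
    background = normalize_gene_set(background)
    if not query <= background:
        extra = sorted(query - background)
        raise EnrichError(f"query genes outside background: {extra[:5]}")
    anno_in_bg = annotation & background
    hits = len(query & anno_in_bg)
    if hits <= 1:
        return 1.0
    return float(stats.hypergeom.sf(hits - 2, len(background), len(anno_in_bg), len(query)))


def fisher_exact_enrichment(
    query: Iterable[str], annotation: Iterable[str], background: Iterable[str]
) -> float:
    """Classical one-sided Fisher exact enrichment p (no EASE penalty)."""
    query = normalize_gene_set(query)
    annotation = normalize_gene_set(annotation)
    background = normalize_gene_set(background)
    if not query <= background:
        raise EnrichError("query genes outside background")
    anno_in_bg = annotation & background
    hits = len(query & anno_in_bg)
    return float(stats.hypergeom.sf(hits - 1, len(background), len(anno_in_bg), len(query)))


def ks_pvalue_enrichment(
    observed: np.ndarray, expected: np.ndarray | str = "uniform"
) -> tuple[float, float]:
    """KS comparison of an observed p-value distribution with its expectation.

    With ``expected="uniform"`` runs a one-sample KS test of the observed
    p-values against Uniform(0, 1) — the null distribution of p-values
    when no gene is associated. Passing an array runs the two-sample KS
    test instead. Returns (D, p) where D is the supremum ECDF gap.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size == 0:
        raise EnrichError("empty observed sample")
    if (obs <= 0).any() or (obs > 1).any():
        raise EnrichError("observed p-values must lie in (0, 1]")
    if isinstance(expected, str):
        if expected != "uniform":
            raise EnrichError(f"unknown expected distribution {expected!r}")
        res = stats.kstest(obs, "uniform")
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.size == 0:
            raise EnrichError("empty expected sample")
        res = stats.ks_2samp(obs, exp)
    return float(res.statistic), float(res.pvalue)


def chi2_hit_rate(
    hits_in_list: int,
    list_size: int,
    hits_total: int,
    total: int,
    form: str = "goodness_of_fit",
    continuity: bool = False,
) -> tuple[float, float]:
    """Chi-square test of a hit list's annotation rate against background.

    Compares the observed number of annotated proteins in a hit list
    against the expectation ``list_size * hits_total / total`` derived
    from the background rate. The default is a 2-cell goodness-of-fit
    without continuity correction; ``form="independence"`` runs the 2x2
    contingency chi-square on (in-list vs not) x (hit vs not) instead.

    Returns (chi2, p).
    """
    if not (0 <= hits_in_list <= list_size <= total and hits_in_list <= hits_total <= total):
        raise EnrichError(
            f"inconsistent counts: {hits_in_list}/{list_size} hits in list, "
            f"{hits_total}/{total} in background"
        )
    if form == "goodness_of_fit":
        expected_hits = list_size * hits_total / total
        expected = np.array([expected_hits, list_size - expected_hits])
        if (expected < 1).any():
            raise EnrichError(
                f"expected cell {expected.min():.3f} < 1: use an exact test instead"
            )
        observed = np.array([hits_in_list, list_size - hits_in_list], dtype=float)
        diff = np.abs(observed - expected)
        if continuity:
            diff = np.maximum(diff - 0.5, 0.0)
        chi2 = float((diff**2 / expected).sum())
        return chi2, float(stats.chi2.sf(chi2, df=1))
    if form == "independence":
        table = np.array(
            [
                [hits_in_list, list_size - hits_in_list],
                [hits_total - hits_in_list, (total - list_size) - (hits_total - hits_in_list)],
            ]
        )
        if (table < 0).any():
            raise EnrichError("inconsistent 2x2 table")
        chi2, p, _, exp = stats.chi2_contingency(table, correction=continuity)
        if (exp < 1).any():
            raise EnrichError("expected cell < 1: use an exact test instead")
        return float(chi2), float(p)
    raise EnrichError(f"unknown form {form!r}")
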