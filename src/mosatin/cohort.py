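"""Exact cohort-level statistics.

Substitution spectra and the modal-class binomial test, Clopper-Pearson
exact intervals, Fisher 2x2 tests, the five-lesion minimum-p beta
combination for gene significance, Benjamini-Hochberg FDR, the germline
candidate filter, and the hypermutator / expression-class flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._stats import binom_tail, log_binom_tail
from .io import SUBSTITUTION_CLASSES, GenomicVariant

logger = logging.getLogger(__name__)

_PYRIMIDINE_COLLAPSE = {
    ("C", "A"): "C>A", ("C", "G"): "C>G", ("C", "T"): "C>T",
    ("T", "A"): "T>A", ("T", "C"): "T>C", ("T", "G"): "T>G",
    ("G", "T"): "C>A", ("G", "C"): "C>G", ("G", "A"): "C>T",
    ("A", "T"): "T>A", ("A", "G"): "T>C", ("A", "C"): "T>G",
}

LESION_TYPES = ("snv", "het_deletion", "fusion", "cnloh", "amplification")


@dataclass
class SpectrumSummary:
    """Per-sample 6-class substitution tally (pyrimidine-collapsed)."""

    sample_id: str
    class_counts: np.ndarray
    modal_class: str | None  # None on a tie or an empty sample

    def __post_init__(self) -> None:
        self.class_counts = np.asarray(self.class_counts, dtype=float)
        if self.class_counts.shape != (6,):
            raise ValueError("need exactly 6 substitution classes")

    @property
    def total(self) -> float:
        return float(self.class_counts.sum())

    @property
    def relative(self) -> np.ndarray:
        t = self.total
        return self.class_counts / t if t > 0 else np.zeros(6)


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-collapsed class of a single-base substitution."""
    try:
        return _PYRIMIDINE_COLLAPSE[(ref, alt)]
    except KeyError:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}") from None


def spectrum(sample_id: str, variants: Sequence[GenomicVariant]) -> SpectrumSummary:
    """6-class substitution spectrum of one sample's SNVs.

    Ties for the modal class are reported as no modal class (with a
    warning), as are empty samples.
    """
    counts = np.zeros(6)
    for v in variants:
        if not v.is_snv:
            continue
        counts[SUBSTITUTION_CLASSES.index(substitution_class(v.ref_allele, v.alt_allele))] += 1
    if counts.sum() == 0:
        modal = None
    else:
        top = counts.max()
        winners = [c for c, n in zip(SUBSTITUTION_CLASSES, counts) if n == top]
        if len(winners) > 1:
            logger.warning("sample %s: modal substitution class tied (%s)", sample_id, winners)
            modal = None
        else:
            modal = winners[0]
    return SpectrumSummary(sample_id=sample_id, class_counts=counts, modal_class=modal)


def modal_count(
    spectra: Sequence[SpectrumSummary], target_class: str = "C>T"
) -> tuple[int, int]:
    """(k, n): samples whose modal class is ``target_class``, out of the
    non-empty un-tied samples."""
    eligible = [s for s in spectra if s.total > 0]
    n_excluded = len(spectra) - len(eligible)
    if n_excluded:
        logger.warning("modal_count: excluded %d empty samples", n_excluded)
    tied = [s for s in eligible if s.modal_class is None]
    if tied:
        logger.warning("modal_count: excluded %d tied samples", len(tied))
        eligible = [s for s in eligible if s.modal_class is not None]
    k = sum(s.modal_class == target_class for s in eligible)
    return k, len(eligible)


def exact_binomial_test(k: int, n: int, p0: float, tail: str = "upper") -> float:
    """Exact binomial tail probability, computed log-safely.

    ``upper``: P(X >= k); ``lower``: P(X <= k); ``two_sided``: the exact
    two-sided p summing outcomes no more probable than k.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 <= p0 <= 1:
        raise ValueError(f"p0 must lie in [0, 1], got {p0}")
    if tail in ("upper", "lower"):
        return binom_tail(k, n, p0, tail)
    if tail == "two_sided":
        return float(stats.binomtest(k, n, p0).pvalue)
    raise ValueError(f"unknown tail {tail!r}")


def log10_exact_binomial_test(k: int, n: int, p0: float, tail: str = "upper") -> float:
    """log10 of the upper/lower exact binomial tail (safe far below 1e-300)."""
    return log_binom_tail(k, n, p0, tail) / np.log(10)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval via beta
    quantiles; lower = 0 at k = 0 and upper = 1 at k = n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    a = (1.0 - conf) / 2.0
    lower = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lower, upper


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum).

    A zero margin makes the table degenerate and p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def combine_lesion_pvalues(p: Sequence[float], n_lesions: int = 5) -> float:
    """Overall gene p from per-lesion p-values: the CDF of the minimum of
    ``n_lesions`` independent U(0,1) draws, 1 - (1 - min p)^n."""
    p = np.asarray(p, dtype=float)
    if p.size != n_lesions:
        raise ValueError(f"expected {n_lesions} per-lesion p-values, got {p.size}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = float(p.min())
    # -expm1(n*log1p(-m)) keeps precision for tiny m
    return float(-np.expm1(n_lesions * np.log1p(-m))) if m < 1 else 1.0


def fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneLesionResult:
    gene: str
    p_per_lesion: np.ndarray  # in LESION_TYPES order
    p_overall: float
    q: float | None = None


def gene_significance(
    per_gene: Mapping[str, Sequence[float]]
) -> list[GeneLesionResult]:
    """Combine five per-lesion p-values per gene and attach BH q-values."""
    genes = sorted(per_gene)
    results = [
        GeneLesionResult(
            gene=g,
            p_per_lesion=np.asarray(per_gene[g], dtype=float),
            p_overall=combine_lesion_pvalues(per_gene[g]),
        )
        for g in genes
    ]
    qs = fdr([r.p_overall for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# germline candidate filter

@dataclass
class GermlineCandidate:
    variant: GenomicVariant
    passes: bool
    failed_rules: list[str]
    needs_review: bool = False  # missense lacking a REVEL score


def germline_filter(
    variants: Sequence[GenomicVariant],
    min_vaf: float = 0.2,
    min_coverage: int = 20,
    max_maf: float = 0.001,
    min_revel: float = 0.5,
    gene_allowlist: Sequence[str] | None = None,
) -> list[GermlineCandidate]:
    """Apply the germline candidate rules, recording failures by name.

    Rules, in order: normal VAF >= 0.2; normal coverage > 20; population
    MAF < 0.001 or absent; REVEL > 0.5 for missense variants.  A missense
    variant without a REVEL score is flagged for manual review rather than
    auto-failed.  An optional gene allow-list restricts candidates to a
    curated panel.
    """
    allow = set(gene_allowlist) if gene_allowlist is not None else None
    out = []
    for v in variants:
        failed: list[str] = []
        review = False
        if allow is not None and (v.gene is None or v.gene not in allow):
            failed.append("gene_panel")
        if v.normal_vaf < min_vaf:
            failed.append("vaf")
        if v.normal_depth <= min_coverage:
            failed.append("coverage")
        if v.population_maf is not None and v.population_maf >= max_maf:
            failed.append("maf")
        if v.variant_class == "missense":
            if v.revel_score is None:
                failed.append("revel_not_evaluable")
                review = True
            elif v.revel_score <= min_revel:
                failed.append("revel")
        out.append(
            GermlineCandidate(
                variant=v, passes=not failed, failed_rules=failed, needs_review=review
            )
        )
    return out


def hypermutator_flag(burdens: Mapping[str, float], n_sd: float = 2.0) -> list[str]:
    """Samples whose mutation burden exceeds mean + 2 sd (sample sd, n-1)."""
    if len(burdens) < 3:
        raise ValueError("need at least 3 samples to define a burden distribution")
    vals = np.asarray(list(burdens.values()), dtype=float)
    threshold = vals.mean() + n_sd * vals.std(ddof=1)
    return sorted(s for s, b in burdens.items() if b > threshold)


def expression_class(fpkm: float, threshold: float = 5.0) -> str:
    """'high' iff FPKM strictly exceeds the threshold (default 5), else 'low'."""
    if fpkm < 0:
        raise ValueError(f"FPKM must be non-negative, got {fpkm}")
    return "high" if fpkm > threshold else "low"
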