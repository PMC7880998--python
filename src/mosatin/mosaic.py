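"""Mosaicism versus tumor-in-normal contamination versus inheritance.

For each candidate variant, the allele counts observed in the matched
normal sample are tested against two exact binomial nulls:

* contamination — the success probability is the expected VAF e under pure
  tumor-in-normal contamination at level c, which depends on the local
  copy-number state of the variant (e = c/(2-c) for one-copy loss with LOH,
  e = c for copy-neutral LOH, e = c/2 for diploid loci);
* inheritance — e = 0.5, a germline heterozygous variant.

The contamination test is upper-tailed (mosaicism adds mutant reads above
e); the inheritance test is lower-tailed (a mosaic fraction sits below a
het germline VAF).  A variant rejecting both nulls after Bonferroni
correction at alpha (default 0.01) is called mosaic.  Tail probabilities
are accumulated in log space so values like 1e-40 survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._stats import binom_tail, log_binom_tail
from .io import GenomicVariant

logger = logging.getLogger(__name__)

LOCAL_STATES = ("het_loss", "cnloh", "diploid")
VERDICTS = ("mosaic", "germline", "contamination_consistent", "indeterminate")


def expected_vaf_under_contamination(c: float, local_state: str) -> float:
    """Expected normal-sample VAF under contamination at cell fraction c.

    het_loss: one mutant copy among c*1 + (1-c)*2 copies -> c/(2-c).
    cnloh: two mutant copies in contaminating cells -> c.
    diploid: heterozygous in contaminating cells -> c/2 (an extension for
    loci outside LOH regions, so the test is total).
    """
    if not 0 <= c <= 1:
        raise ValueError(f"contamination must lie in [0, 1], got {c}")
    if local_state == "het_loss":
        return c / (2.0 - c)
    if local_state == "cnloh":
        return c
    if local_state == "diploid":
        return c / 2.0
    raise ValueError(f"unknown local state {local_state!r}")


def contamination_test(x: int, n: int, e: float) -> float:
    """Upper-tail exact binomial p-value P(X >= x | n, e), log-safe."""
    return binom_tail(x, n, e, "upper")


def inheritance_test(x: int, n: int, e: float = 0.5) -> float:
    """Lower-tail exact binomial p-value P(X <= x | n, e=0.5), log-safe."""
    return binom_tail(x, n, e, "lower")


def log10_contamination_test(x: int, n: int, e: float) -> float:
    return log_binom_tail(x, n, e, "upper") / np.log(10)


def log10_inheritance_test(x: int, n: int, e: float = 0.5) -> float:
    return log_binom_tail(x, n, e, "lower") / np.log(10)


@dataclass
class MosaicCandidate:
    """A variant with its local copy-number state and contamination null."""

    variant: GenomicVariant
    local_state: str
    c_used: float
    e_contam: float | None = None

    def __post_init__(self) -> None:
        if self.local_state not in LOCAL_STATES:
            raise ValueError(f"unknown local state {self.local_state!r}")
        if self.e_contam is None:
            self.e_contam = expected_vaf_under_contamination(self.c_used, self.local_state)


@dataclass
class MosaicismResult:
    candidate: MosaicCandidate
    p_contam: float
    p_inherit: float
    log10_p_contam: float
    log10_p_inherit: float
    alpha: float
    n_tests: int
    verdict: str

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.n_tests


def _verdict(p_contam: float, p_inherit: float, threshold: float) -> str:
    reject_contam = p_contam < threshold
    reject_inherit = p_inherit < threshold
    if reject_contam and reject_inherit:
        return "mosaic"
    if reject_contam and not reject_inherit:
        return "germline"
    if reject_inherit and not reject_contam:
        return "contamination_consistent"
    return "indeterminate"


def classify(
    candidates: Sequence[MosaicCandidate],
    alpha: float = 0.01,
    family: str = "per_run",
    two_sided: bool = False,
) -> list[MosaicismResult]:
    """Run both binomial tests per candidate and call verdicts.

    Bonferroni family size n_tests is the number of candidates in the run
    (``per_run``, default) or within each sample (``per_sample``).  With
    ``two_sided`` both tests use the two-sided exact binomial p-value
    instead of the directional defaults.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if family not in ("per_run", "per_sample"):
        raise ValueError(f"unknown Bonferroni family {family!r}")
    if not candidates:
        return []

    if family == "per_run":
        sizes = {None: len(candidates)}
        key = lambda cand: None  # noqa: E731
    else:
        key = lambda cand: cand.variant.sample_id  # noqa: E731
        sizes = {}
        for cand in candidates:
            sizes[key(cand)] = sizes.get(key(cand), 0) + 1

    out = []
    for cand in candidates:
        x, n = cand.variant.normal_alt, cand.variant.normal_depth
        if two_sided:
            p_c = stats.binomtest(x, n, cand.e_contam).pvalue
            p_i = stats.binomtest(x, n, 0.5).pvalue
            l10_c, l10_i = np.log10(max(p_c, 5e-324)), np.log10(max(p_i, 5e-324))
        else:
            p_c = contamination_test(x, n, cand.e_contam)
            p_i = inheritance_test(x, n)
            l10_c = log10_contamination_test(x, n, cand.e_contam)
            l10_i = log10_inheritance_test(x, n)
        n_tests = sizes[key(cand)]
        out.append(
            MosaicismResult(
                candidate=cand,
                p_contam=p_c,
                p_inherit=p_i,
                log10_p_contam=l10_c,
                log10_p_inherit=l10_i,
                alpha=alpha,
                n_tests=n_tests,
                verdict=_verdict(p_c, p_i, alpha / n_tests),
            )
        )
    return out


def normal_only_rule(variant: GenomicVariant, clinical_support: bool = False) -> str:
    """Classification when only a normal sample exists.

    Normal VAF >= 0.2 -> germline; VAF < 0.2 with supportive clinical
    history -> mosaic; otherwise indeterminate.
    """
    if variant.normal_depth <= 0:
        raise ValueError("normal depth must be positive")
    if variant.normal_vaf >= 0.2:
        return "germline"
    return "mosaic" if clinical_support else "indeterminate"


class MosaicismScreen:
    """Mosaicism screen over a set of candidate variants.

    Parameters
    ----------
    candidates : sequence of MosaicCandidate
        Variants with their local copy-number state and the contamination
        level c (cell-fraction scale enters via the state formulas).
    alpha : float
        Familywise significance level before Bonferroni division.
    family : {"per_run", "per_sample"}
    two_sided : bool
        Replace the directional defaults with two-sided tests.
    """

    def __init__(
        self,
        candidates: Sequence[MosaicCandidate],
        alpha: float = 0.01,
        family: str = "per_run",
        two_sided: bool = False,
    ) -> None:
        self.candidates = list(candidates)
        self.alpha = alpha
        self.family = family
        self.two_sided = two_sided

    def fit(self) -> "MosaicismScreenResults":
        results = classify(
            self.candidates, alpha=self.alpha, family=self.family, two_sided=self.two_sided
        )
        return MosaicismScreenResults(model=self, results=results)


@dataclass
class MosaicismScreenResults:
    model: MosaicismScreen
    results: list[MosaicismResult]

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            v = r.candidate.variant
            rows.append(
                {
                    "sample_id": v.sample_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "gene": v.gene,
                    "local_state": r.candidate.local_state,
                    "x": v.normal_alt,
                    "n": v.normal_depth,
                    "normal_vaf": v.normal_vaf,
                    "e_contam": r.candidate.e_contam,
                    "p_contam": r.p_contam,
                    "p_inherit": r.p_inherit,
                    "log10_p_contam": r.log10_p_contam,
                    "log10_p_inherit": r.log10_p_inherit,
                    "adjusted_alpha": r.adjusted_alpha,
                    "verdict": r.verdict,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        counts = {v: 0 for v in VERDICTS}
        for r in self.results:
            counts[r.verdict] += 1
        lines = [
            "Mosaicism screen",
            "=" * 38,
            f"candidates                {len(self.results)}",
            f"alpha / family            {self.model.alpha} / {self.model.family}",
        ]
        lines += [f"{k:<26}{n}" for k, n in counts.items()]
        return "\n".join(lines)
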