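"""Tumor purity and tumor-in-normal contamination estimation.

Purity f is estimated two ways and the maximum taken:

* from somatic VAFs — a 1-D Gaussian mixture is fitted to tumor allele
  fractions, and the highest-mean cluster centred under 0.5 (mean u) gives
  f = 2u, the diploid heterozygous reading of the clonal VAF peak;
* from copy-number/LOH segments — the heterozygous-loss segment of largest
  |log ratio| gives f = 2 - 2^(log_ratio + 1), and the copy-neutral-LOH
  segment of largest allelic imbalance AI = |BAF - 0.5| gives f = 2 AI.

Diploid clonal markers are somatic variants whose tumor VAF lies in
(0.8 * f/2, 0.6) and which overlap no non-diploid segment.  Summing their
mutant reads (M) and depths (T) in the *normal* sample yields the
contamination level c = M/T (the literal convention), or, read as a
fraction of contaminating tumor cells, c = 2 M/T (``cell_fraction``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .io import CopyNumberSegment, GenomicVariant

logger = logging.getLogger(__name__)

CONVENTIONS = ("literal_MT", "cell_fraction")


class InsufficientDataError(ValueError):
    """Too few observations to fit the requested estimator."""


@dataclass
class VafClusterModel:
    """A fitted 1-D Gaussian mixture over somatic VAFs."""

    n_components: int
    means: np.ndarray
    weights: np.ndarray
    assignments: np.ndarray
    u: float | None

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")
        if self.u is not None and not (0 <= self.u < 0.5):
            raise ValueError(f"u must lie in [0, 0.5), got {self.u}")


@dataclass
class PurityEstimate:
    f_snv: float | None
    f_cnv: float | None
    f: float
    source: str


@dataclass
class ContaminationEstimate:
    """c inferred from diploid clonal markers in the normal sample."""

    c: float
    M: int
    T: int
    n_markers: int
    convention: str = "literal_MT"

    @property
    def cell_fraction(self) -> float:
        """c expressed as the contaminating tumor-cell fraction."""
        if self.convention == "cell_fraction":
            return self.c
        return min(1.0, 2.0 * self.c)


def cluster_vafs(
    vafs: Sequence[float],
    max_components: int = 5,
    seed: int = 0,
    min_bic_evidence: float = 10.0,
) -> VafClusterModel:
    """Fit 1-D Gaussian mixtures for 1..max_components components, pick by BIC.

    A more complex mixture replaces a simpler one only when it improves BIC
    by at least ``min_bic_evidence`` (10 = very strong evidence on the
    Kass-Raftery scale); plain argmin-BIC tends to split a single skewed
    read-count peak into two overlapping components, which would bias the
    clonal-peak mean upward.

    u is the mean of the highest-mean component with centre under 0.5;
    absent (None, with a warning) when every component sits at >= 0.5.
    """
    x = np.asarray(vafs, dtype=float).reshape(-1, 1)
    if x.size < 5:
        raise InsufficientDataError(f"need >= 5 VAFs to cluster, got {x.size}")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("VAFs must lie in [0, 1]")

    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        if k > x.size:
            break
        # tied (equal) variance: the 1-D analogue of mclust's "E" model.
        # Component-specific variances let the mixture fit narrow spikes on
        # the read-count lattice of fixed-depth VAFs, splitting one clonal
        # peak into several components.
        with warnings.catch_warnings():
            # degenerate inputs (all VAFs identical) legitimately collapse
            # k-means initial clusters; the k=1 model then wins on BIC
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm = GaussianMixture(
                n_components=k,
                covariance_type="tied",
                reg_covar=1e-6,
                n_init=3,
                init_params="kmeans",
                random_state=seed,
            ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - (min_bic_evidence if best is not None else 0.0):
            best_bic, best = bic, gm

    means = best.means_.ravel()
    sub = means[means < 0.5]
    u = float(sub.max()) if sub.size else None
    if u is None:
        logger.warning("no VAF cluster centred under 0.5; u unavailable")
    return VafClusterModel(
        n_components=best.n_components,
        means=means,
        weights=best.weights_.ravel(),
        assignments=best.predict(x),
        u=u,
    )


def purity_from_snv(model: VafClusterModel) -> float | None:
    """f = 2u from the clonal VAF peak; None when u is unavailable."""
    if model.u is None:
        return None
    return float(np.clip(2.0 * model.u, 0.0, 1.0))


def purity_from_segments(
    segments: Sequence[CopyNumberSegment],
) -> tuple[float, str] | None:
    """Purity from the most extreme LOH evidence.

    Among het-loss segments the one with maximum |log_ratio| gives
    f = 2 - 2^(log_ratio + 1); among CN-LOH segments the one with maximum
    AI gives f = 2 AI.  Returns (max of the candidates, source), or None
    when no eligible segment exists.  Estimates are clipped to [0, 1]
    (noisy log ratios can otherwise exceed it).
    """
    f_loss = None
    loss = [s for s in segments if s.state == "het_loss"]
    if loss:
        seg = max(loss, key=lambda s: abs(s.log_ratio))
        f_loss = float(np.clip(2.0 - 2.0 ** (seg.log_ratio + 1.0), 0.0, 1.0))
    f_cnloh = None
    cnloh = [s for s in segments if s.state == "cnloh" and s.baf is not None]
    if cnloh:
        seg = max(cnloh, key=lambda s: s.allelic_imbalance)
        f_cnloh = float(np.clip(2.0 * seg.allelic_imbalance, 0.0, 1.0))

    if f_loss is None and f_cnloh is None:
        return None
    if f_cnloh is None or (f_loss is not None and f_loss >= f_cnloh):
        return f_loss, "het_loss"
    return f_cnloh, "cnloh"


def final_purity(f_snv: float | None, f_cnv: float | None, cnv_source: str = "cnv") -> PurityEstimate:
    """Final purity = max of the SNV- and CNV/LOH-based candidates."""
    if f_snv is None and f_cnv is None:
        raise InsufficientDataError(
            "no purity estimate available from VAFs or segments; supply purity manually"
        )
    if f_snv is None:
        f, source = f_cnv, cnv_source
    elif f_cnv is None:
        f, source = f_snv, "snv"
    else:
        f, source = max(f_snv, f_cnv), "max_of_both"
    return PurityEstimate(f_snv=f_snv, f_cnv=f_cnv, f=float(np.clip(f, 0, 1)), source=source)


def select_diploid_clonal(
    variants: Sequence[GenomicVariant],
    segments: Sequence[CopyNumberSegment],
    f: float,
    upper: float = 0.6,
    clonal_fraction: float = 0.8,
) -> list[GenomicVariant]:
    """Diploid clonal markers: tumor VAF in (0.8 * f/2, 0.6), outside
    non-diploid segments.

    The VAF window follows the rule VAF > f*0.5*80% and VAF < 0.6; the
    segment veto tightens it, since the diploid label presumes diploidy.
    """
    if not (0 < f <= 1):
        raise ValueError(f"purity must lie in (0, 1], got {f}")
    lo = clonal_fraction * f * 0.5
    non_diploid = [s for s in segments if s.state != "diploid"]
    kept = []
    for v in variants:
        if not (lo < v.tumor_vaf < upper):
            continue
        if any(s.contains(v.chrom, v.pos) for s in non_diploid):
            continue
        kept.append(v)
    if not kept:
        logger.warning(
            "no diploid clonal markers in VAF window (%.3f, %.3f); "
            "contamination estimation unavailable",
            lo,
            upper,
        )
    return kept


def estimate_contamination(
    markers: Sequence[GenomicVariant], convention: str = "literal_MT"
) -> ContaminationEstimate:
    """c from summed normal-sample mutant reads (M) and depths (T).

    literal_MT: c = M/T.  cell_fraction: c = min(1, 2 M/T) — M/T measures
    about half the contaminating cell fraction because the markers are
    heterozygous in the contaminating tumor cells.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if not markers:
        raise InsufficientDataError("no diploid clonal markers")
    M = int(sum(v.normal_alt for v in markers))
    T = int(sum(v.normal_depth for v in markers))
    if T == 0:
        raise ValueError("total normal depth of markers is zero")
    ratio = M / T
    c = ratio if convention == "literal_MT" else min(1.0, 2.0 * ratio)
    return ContaminationEstimate(c=c, M=M, T=T, n_markers=len(markers), convention=convention)


# ---------------------------------------------------------------------------
# model / results presentation

class PurityContaminationModel:
    """Joint purity and tumor-in-normal contamination estimator for one
    tumor/normal pair.

    Parameters
    ----------
    variants : sequence of GenomicVariant
        Somatic SNVs/indels of the pair, with tumor and normal depths.
    segments : sequence of CopyNumberSegment, optional
        Copy-number/LOH segments of the tumor.
    convention : {"literal_MT", "cell_fraction"}
        How the marker ratio M/T is reported as c.
    max_components, seed
        Mixture-fit settings for the VAF clustering.

    Examples
    --------
    >>> model = PurityContaminationModel(variants, segments)
    >>> res = model.fit()
    >>> res.purity.f, res.contamination.c
    """

    def __init__(
        self,
        variants: Sequence[GenomicVariant],
        segments: Sequence[CopyNumberSegment] = (),
        convention: str = "literal_MT",
        max_components: int = 5,
        seed: int = 0,
    ) -> None:
        self.variants = list(variants)
        self.segments = list(segments)
        self.convention = convention
        self.max_components = max_components
        self.seed = seed

    def fit(self) -> "PurityContaminationResults":
        cluster = None
        f_snv = None
        try:
            cluster = cluster_vafs(
                [v.tumor_vaf for v in self.variants],
                max_components=self.max_components,
                seed=self.seed,
            )
            f_snv = purity_from_snv(cluster)
        except InsufficientDataError:
            logger.warning("too few somatic VAFs for clustering; SNV purity unavailable")

        seg_est = purity_from_segments(self.segments)
        f_cnv, cnv_source = (seg_est if seg_est is not None else (None, "cnv"))
        purity = final_purity(f_snv, f_cnv, cnv_source=cnv_source)

        markers = select_diploid_clonal(self.variants, self.segments, purity.f)
        contamination = (
            estimate_contamination(markers, self.convention) if markers else None
        )
        return PurityContaminationResults(
            model=self,
            cluster=cluster,
            purity=purity,
            markers=markers,
            contamination=contamination,
        )


@dataclass
class PurityContaminationResults:
    """Fitted purity/contamination parameters with their evidence."""

    model: PurityContaminationModel
    cluster: VafClusterModel | None
    purity: PurityEstimate
    markers: list[GenomicVariant]
    contamination: ContaminationEstimate | None

    def to_dict(self) -> dict:
        d = {
            "n_variants": len(self.model.variants),
            "n_segments": len(self.model.segments),
            "f": self.purity.f,
            "f_snv": self.purity.f_snv,
            "f_cnv": self.purity.f_cnv,
            "purity_source": self.purity.source,
            "u": self.cluster.u if self.cluster else None,
            "cluster_means": (
                sorted(float(m) for m in self.cluster.means) if self.cluster else None
            ),
            "n_markers": len(self.markers),
        }
        if self.contamination is not None:
            d.update(
                c=self.contamination.c,
                M=self.contamination.M,
                T=self.contamination.T,
                convention=self.contamination.convention,
            )
        else:
            d.update(c=None, M=None, T=None, convention=self.model.convention)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def summary(self) -> str:
        d = self.to_dict()
        lines = [
            "Purity / tumor-in-normal contamination",
            "=" * 44,
            f"somatic variants          {d['n_variants']}",
            f"CN/LOH segments           {d['n_segments']}",
            f"clonal VAF peak u         {_fmt(d['u'])}",
            f"purity f (SNV)            {_fmt(d['f_snv'])}",
            f"purity f (CNV/LOH)        {_fmt(d['f_cnv'])}",
            f"final purity f            {d['f']:.4f}  [{d['purity_source']}]",
            f"diploid clonal markers    {d['n_markers']}",
            f"contamination c           {_fmt(d['c'])}  ({d['convention']})",
        ]
        if self.contamination is not None:
            lines.append(
                f"  M / T                   {self.contamination.M} / {self.contamination.T}"
            )
        return "\n".join(lines)


def _fmt(x: float | None) -> str:
    return "n/a" if x is None else f"{x:.4f}"
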