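"""Synthetic paired tumor/normal cohorts with known ground truth.

Generates allele counts, copy-number segments and signature-mixture
catalogs from the same generative assumptions the estimators invert, so
every stage of the pipeline can be validated without external data.

For a diploid heterozygous somatic SNV in a tumor of purity f, the
expected tumor VAF is f/2; inside planned segments the state-specific
dosages apply (f/(2-f) for one-copy loss with the mutation on the retained
copy, f for CN-LOH with the mutant allele duplicated).  The matched normal
is contaminated by tumor cells at cell fraction c, contributing an
expected VAF of c/2 (diploid), c/(2-c) (het loss) or c (CN-LOH); designated
mosaic loci add mosaic_fraction/2 on top.  Allele counts are binomial at
the configured depths (optionally Poisson-distributed depths and
beta-binomial overdispersion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CHANNEL_LABELS, Catalog96, CopyNumberSegment, GenomicVariant, SignatureSet

_STATE_TUMOR_VAF = {
    "diploid": lambda f: f / 2.0,
    "het_loss": lambda f: f / (2.0 - f),
    "cnloh": lambda f: f,
}
_STATE_CONTAM_VAF = {
    "diploid": lambda c: c / 2.0,
    "het_loss": lambda c: c / (2.0 - c),
    "cnloh": lambda c: c,
}


@dataclass
class MosaicPlan:
    """A designated mosaic locus: position, constitutional mosaic fraction,
    and the local copy-number state it must sit in."""

    pos: int
    mosaic_fraction: float
    local_state: str = "diploid"


@dataclass
class SimulationConfig:
    """Generating parameters of one synthetic tumor/normal pair.

    ``contamination`` is the ground-truth contaminating tumor *cell
    fraction* in the normal sample; the literal marker ratio M/T the
    estimator measures is about half of it at diploid loci.
    """

    seed: int = 0
    sample_id: str = "SIM"
    purity: float = 0.8
    contamination: float = 0.0
    n_snvs: int = 200
    tumor_depth: int = 100
    normal_depth: int = 500
    depth_model: str = "fixed"  # or "poisson"
    allele_noise: str = "binomial"  # or "beta_binomial"
    overdispersion_rho: float = 0.01
    chrom: str = "1"
    mosaic_variants: list[MosaicPlan] = field(default_factory=list)
    segment_plan: list[CopyNumberSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")
        if not 0 <= self.contamination <= 1:
            raise ValueError("contamination must lie in [0, 1]")
        for m in self.mosaic_variants:
            if not 0 <= m.mosaic_fraction <= 1:
                raise ValueError("mosaic fractions must lie in [0, 1]")
            state = self._local_state(m.pos)
            if state != m.local_state:
                raise ValueError(
                    f"mosaic locus at {m.pos} declared {m.local_state} but lies in a "
                    f"{state} region"
                )

    def _local_state(self, pos: int) -> str:
        for seg in self.segment_plan:
            if seg.contains(self.chrom, pos):
                return seg.state
        return "diploid"


def _draw_counts(rng: np.random.Generator, n: int, depth: int, p: float, config: SimulationConfig):
    """(alt, total) count vectors under the configured depth/noise models."""
    if config.depth_model == "poisson":
        totals = rng.poisson(depth, size=n)
        totals = np.maximum(totals, 1)
    elif config.depth_model == "fixed":
        totals = np.full(n, depth, dtype=int)
    else:
        raise ValueError(f"unknown depth model {config.depth_model!r}")
    p = min(max(p, 0.0), 1.0)
    if config.allele_noise == "binomial":
        alts = rng.binomial(totals, p)
    elif config.allele_noise == "beta_binomial":
        rho = config.overdispersion_rho
        if p in (0.0, 1.0) or rho <= 0:
            alts = rng.binomial(totals, p)
        else:
            a = p * (1 - rho) / rho
            b = (1 - p) * (1 - rho) / rho
            alts = rng.binomial(totals, rng.beta(a, b, size=n))
    else:
        raise ValueError(f"unknown allele noise {config.allele_noise!r}")
    return alts, totals


def simulate_pair(
    config: SimulationConfig,
) -> tuple[list[GenomicVariant], list[CopyNumberSegment], dict]:
    """One tumor/normal pair: somatic variants, segments, and truth record.

    Deterministic given the config (the seed lives inside it).  The truth
    record carries every generating parameter plus the per-variant
    expected VAFs and the positions of planted mosaic loci.
    """
    rng = np.random.default_rng(config.seed)
    f, c = config.purity, config.contamination

    mosaic_pos = {m.pos for m in config.mosaic_variants}
    positions = []
    pos = 1000
    while len(positions) < config.n_snvs:
        pos += int(rng.integers(500, 5000))
        if pos not in mosaic_pos:
            positions.append(pos)
    variants: list[GenomicVariant] = []
    truth_variants = []

    def _emit(pos: int, mosaic_fraction: float = 0.0) -> None:
        state = config._local_state(pos)
        e_tumor = _STATE_TUMOR_VAF[state](f)
        e_normal = _STATE_CONTAM_VAF[state](c) + mosaic_fraction / 2.0
        t_alt, t_tot = _draw_counts(rng, 1, config.tumor_depth, e_tumor, config)
        n_alt, n_tot = _draw_counts(rng, 1, config.normal_depth, e_normal, config)
        variants.append(
            GenomicVariant(
                sample_id=config.sample_id,
                chrom=config.chrom,
                pos=pos,
                ref_allele="C",
                alt_allele="T",
                tumor_alt=int(t_alt[0]),
                tumor_depth=int(t_tot[0]),
                normal_alt=int(n_alt[0]),
                normal_depth=int(n_tot[0]),
            )
        )
        truth_variants.append(
            {
                "pos": pos,
                "local_state": state,
                "expected_tumor_vaf": e_tumor,
                "expected_normal_vaf": e_normal,
                "mosaic_fraction": mosaic_fraction,
            }
        )

    for pos in positions:
        _emit(pos)
    for plan in config.mosaic_variants:
        _emit(plan.pos, plan.mosaic_fraction)

    truth = {
        "sample_id": config.sample_id,
        "purity": f,
        "contamination_cell_fraction": c,
        "contamination_literal_MT_diploid": c / 2.0,
        "seed": config.seed,
        "n_snvs": config.n_snvs,
        "mosaic_positions": sorted(mosaic_pos),
        "variants": truth_variants,
    }
    return variants, list(config.segment_plan), truth


def simulate_catalog(
    signatures: SignatureSet,
    exposures: Sequence[float],
    seed: int = 0,
    sample_id: str = "SIM",
    assay: str = "wgs",
) -> tuple[Catalog96, np.ndarray, np.ndarray]:
    """Draw a catalog from a signature mixture.

    Each of sum(exposures) mutations picks signature k with probability
    s_k / sum(s) and then a channel from P_{c,k}.  Returns the catalog,
    the per-mutation channel indices, and the per-mutation true causal
    signature indices (for attribution benchmarking).
    """
    s = np.asarray(exposures, dtype=float)
    if (s < 0).any() or s.sum() <= 0:
        raise ValueError("exposures must be non-negative with positive sum")
    if s.size != len(signatures.names):
        raise ValueError("one exposure per signature required")
    rng = np.random.default_rng(seed)
    n = int(round(s.sum()))
    sig_idx = rng.choice(s.size, size=n, p=s / s.sum())
    channels = np.empty(n, dtype=int)
    for k in range(s.size):
        mask = sig_idx == k
        if mask.any():
            channels[mask] = rng.choice(96, size=int(mask.sum()), p=signatures.probs[k])
    counts = np.bincount(channels, minlength=96).astype(float)
    return (
        Catalog96(sample_id=sample_id, counts=counts, assay=assay),
        channels,
        sig_idx,
    )


def simulate_spectra(
    n_samples: int, n_mutations: int = 100, dominance: float = 0.8, seed: int = 0
) -> np.ndarray:
    """Per-sample 6-class substitution counts with a C>T weight of
    ``dominance`` and the remaining mass uniform over the other classes."""
    if not 0 <= dominance <= 1:
        raise ValueError("dominance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.full(6, (1.0 - dominance) / 5.0)
    p[2] = dominance  # C>T position in the canonical class order
    return rng.multinomial(n_mutations, p, size=n_samples)
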