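"""Reading and writing the formats the pipeline touches.

Variant tables (VCF or flat TSV), copy-number segment tables (SEG-like TSV),
fixed signature-probability matrices (96-row TSV), and the trinucleotide
machinery that turns single-base substitutions into SBS-96 channel indices
and per-sample mutation catalogs.

Coordinate conventions: variants are 1-based (VCF); segments are 1-based,
inclusive on both ends (SEG). VAF is alt_count / total_depth at the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Pyrimidine-centred substitution classes, in conventional (COSMIC-style)
#: order: substitution major, then 5' context, then 3' context, A<C<G<T.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: The 96 channel labels like "A[C>T]G", in canonical order.
CHANNEL_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "silent", "other")
SEGMENT_STATES = ("diploid", "het_loss", "cnloh", "amplification")


class ParseError(ValueError):
    """A malformed input file; the message names the offending line/label."""


@dataclass
class GenomicVariant:
    """One substitution or indel with per-sample allele depths.

    ``pos`` is 1-based. Depth fields count reads in the tumor and matched
    normal sample respectively; VAFs are alt/depth.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    tumor_alt: int
    tumor_depth: int
    normal_alt: int
    normal_depth: int
    gene: str | None = None
    variant_class: str = "other"
    revel_score: float | None = None
    population_maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")
        if self.tumor_alt > self.tumor_depth:
            raise ValueError(
                f"tumor_alt {self.tumor_alt} exceeds tumor_depth {self.tumor_depth}"
            )
        if self.normal_alt > self.normal_depth:
            raise ValueError(
                f"normal_alt {self.normal_alt} exceeds normal_depth {self.normal_depth}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _BASES
            and self.alt_allele in _BASES
        )

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else float("nan")

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else float("nan")


@dataclass
class CopyNumberSegment:
    """A genomic interval with log2 coverage ratio, BAF and LOH state.

    ``start``/``end`` are 1-based and inclusive. ``log_ratio`` is the log2
    tumor/normal coverage ratio; ``baf`` the B-allele fraction of germline
    het SNPs within the segment.
    """

    chrom: str
    start: int
    end: int
    log_ratio: float
    baf: float | None = None
    state: str = "diploid"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.state not in SEGMENT_STATES:
            raise ValueError(f"unknown segment state {self.state!r}")
        if self.state == "cnloh" and self.baf is None:
            raise ValueError("cnloh segment requires a B-allele fraction")

    @property
    def allelic_imbalance(self) -> float | None:
        """AI = |BAF - 0.5|, or None when no BAF is available."""
        return None if self.baf is None else abs(self.baf - 0.5)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class MutationChannel:
    """A pyrimidine-centred SBS-96 channel: substitution plus flanking bases."""

    substitution: str
    fivep: str
    threep: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTION_CLASSES:
            raise ValueError(f"bad substitution {self.substitution!r}")
        if self.fivep not in _BASES or self.threep not in _BASES:
            raise ValueError("flanking bases must be one of ACGT")

    @property
    def label(self) -> str:
        return f"{self.fivep}[{self.substitution}]{self.threep}"

    @property
    def index(self) -> int:
        return _CHANNEL_INDEX[self.label]

    @classmethod
    def from_label(cls, label: str) -> "MutationChannel":
        if label not in _CHANNEL_INDEX:
            raise ParseError(f"unknown channel label {label!r}")
        return cls(substitution=label[2:5], fivep=label[0], threep=label[6])


@dataclass
class Catalog96:
    """Per-sample counts of SNVs over the 96 trinucleotide channels."""

    sample_id: str
    counts: np.ndarray
    assay: str = "wgs"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")
        if self.assay not in ("wgs", "wes"):
            raise ValueError(f"unknown assay {self.assay!r}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureSet:
    """A fixed K x 96 signature-probability matrix (rows sum to 1)."""

    names: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.names), 96):
            raise ValueError("probs must be K x 96 with K = len(names)")
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            bad = [self.names[i] for i in np.nonzero(off)[0]]
            logger.warning("renormalising signature rows not summing to 1: %s", bad)
            self.probs = self.probs / sums[:, None]

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        idx = [self.names.index(n) for n in names]
        return SignatureSet(names=list(names), probs=self.probs[idx].copy())


# ---------------------------------------------------------------------------
# trinucleotide channel assignment

def _reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _context(reference, chrom: str, pos: int) -> str:
    """Upper-case trinucleotide centred on 1-based ``pos``.

    ``reference`` may be a pyfaidx.Fasta (or any mapping of contig name to a
    sliceable sequence) holding the genome.
    """
    contig = reference[chrom]
    tri = str(contig[pos - 2 : pos + 1]).upper()
    if len(tri) != 3:
        raise ValueError(f"context for {chrom}:{pos} runs off the contig")
    return tri


def trinucleotide_channel(variant: GenomicVariant, reference) -> MutationChannel | None:
    """SBS-96 channel of a single-base substitution.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand. Returns None (with a warning) when the flanking
    context contains N; raises for non-SNV input.
    """
    if not variant.is_snv:
        raise ValueError(
            f"trinucleotide channel undefined for non-SNV "
            f"{variant.ref_allele}>{variant.alt_allele} at {variant.chrom}:{variant.pos}"
        )
    tri = _context(reference, variant.chrom, variant.pos)
    if tri[1] != variant.ref_allele:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"variant ref {variant.ref_allele}, genome {tri[1]}"
        )
    alt = variant.alt_allele
    if "N" in tri:
        logger.warning(
            "excluding %s:%d: N in trinucleotide context %s", variant.chrom, variant.pos, tri
        )
        return None
    if tri[1] in ("G", "A"):  # purine reference: flip strand
        tri = _reverse_complement(tri)
        alt = _COMPLEMENT[alt]
    return MutationChannel(substitution=f"{tri[1]}>{alt}", fivep=tri[0], threep=tri[2])


def build_catalog(
    variants: Iterable[GenomicVariant], reference, assay: str = "wgs"
) -> Catalog96:
    """SBS-96 catalog of one sample's SNVs.

    Non-SNVs and N-context SNVs are excluded (counted in the log). All
    variants must share a sample_id; an empty input yields an all-zero
    catalog for sample id "".
    """
    counts = np.zeros(96)
    sample_ids = set()
    n_skipped = 0
    for v in variants:
        sample_ids.add(v.sample_id)
        if not v.is_snv:
            n_skipped += 1
            continue
        ch = trinucleotide_channel(v, reference)
        if ch is None:
            n_skipped += 1
            continue
        counts[ch.index] += 1
    if len(sample_ids) > 1:
        raise ValueError(f"variants span multiple samples: {sorted(sample_ids)}")
    if n_skipped:
        logger.info("build_catalog: excluded %d non-SNV/N-context variants", n_skipped)
    return Catalog96(sample_id=next(iter(sample_ids), ""), counts=counts, assay=assay)


# ---------------------------------------------------------------------------
# variant tables

_TSV_COLUMNS = [f.name for f in fields(GenomicVariant)]


def read_variants(
    path: str | Path,
    format: str | None = None,
    tumor_sample: str | None = None,
    normal_sample: str | None = None,
) -> list[GenomicVariant]:
    """Read a variant table from VCF or flat TSV.

    For VCF, per-sample AD fields must be present for the tumor and normal
    columns (defaulting to the first and second sample); multi-allelic
    records are split into one record per ALT. Records lacking depths are
    rejected and counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "vcf":
        return _read_vcf(path, tumor_sample, normal_sample)
    if format == "tsv":
        return _read_variant_tsv(path)
    raise ValueError(f"unknown variant format {format!r}")


def _read_vcf(
    path: Path, tumor_sample: str | None, normal_sample: str | None
) -> list[GenomicVariant]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ParseError(f"{path}: VCF needs tumor and normal sample columns")
    t_idx = samples.index(tumor_sample) if tumor_sample else 0
    n_idx = samples.index(normal_sample) if normal_sample else 1

    out: list[GenomicVariant] = []
    n_rejected = 0
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            n_rejected += len(rec.ALT)
            continue
        ref_t, ref_n = int(ad[t_idx][0]), int(ad[n_idx][0])
        gene = rec.INFO.get("GENE")
        vclass = rec.INFO.get("VCLASS", "other")
        revel = rec.INFO.get("REVEL")
        maf = rec.INFO.get("MAF")
        for ai, alt in enumerate(rec.ALT, start=1):
            alt_t, alt_n = int(ad[t_idx][ai]), int(ad[n_idx][ai])
            if min(alt_t, alt_n) < 0:  # cyvcf2 encodes missing AD as negative
                n_rejected += 1
                continue
            out.append(
                GenomicVariant(
                    sample_id=samples[t_idx],
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    tumor_alt=alt_t,
                    tumor_depth=ref_t + sum(max(int(a), 0) for a in ad[t_idx][1:]),
                    normal_alt=alt_n,
                    normal_depth=ref_n + sum(max(int(a), 0) for a in ad[n_idx][1:]),
                    gene=gene,
                    variant_class=str(vclass) if vclass else "other",
                    revel_score=float(revel) if revel is not None else None,
                    population_maf=float(maf) if maf is not None else None,
                )
            )
    if n_rejected:
        logger.warning("%s: rejected %d records lacking allele depths", path, n_rejected)
    return out


def _read_variant_tsv(path: Path) -> list[GenomicVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(_TSV_COLUMNS[:9]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                GenomicVariant(
                    sample_id=str(row.sample_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref_allele=str(row.ref_allele),
                    alt_allele=str(row.alt_allele),
                    tumor_alt=int(row.tumor_alt),
                    tumor_depth=int(row.tumor_depth),
                    normal_alt=int(row.normal_alt),
                    normal_depth=int(row.normal_depth),
                    gene=None if pd.isna(getattr(row, "gene", None)) else str(row.gene),
                    variant_class=(
                        "other"
                        if pd.isna(getattr(row, "variant_class", None))
                        else str(row.variant_class)
                    ),
                    revel_score=(
                        None
                        if pd.isna(getattr(row, "revel_score", None))
                        else float(row.revel_score)
                    ),
                    population_maf=(
                        None
                        if pd.isna(getattr(row, "population_maf", None))
                        else float(row.population_maf)
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def write_variants(variants: Sequence[GenomicVariant], path: str | Path) -> None:
    """Write variants as a flat TSV (the documented column schema)."""
    df = pd.DataFrame([{c: getattr(v, c) for c in _TSV_COLUMNS} for v in variants])
    if df.empty:
        df = pd.DataFrame(columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# segments and signature matrices

def infer_segment_state(
    log_ratio: float,
    baf: float | None,
    het_loss_log_ratio: float = -0.3,
    cnloh_ai: float = 0.1,
) -> str:
    """Threshold-based state call when the input file carries none."""
    if log_ratio < het_loss_log_ratio:
        return "het_loss"
    if log_ratio > -het_loss_log_ratio:
        return "amplification" if log_ratio > 0.3 else "diploid"
    if baf is not None and abs(baf - 0.5) > cnloh_ai:
        return "cnloh"
    return "diploid"


def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read a SEG-like TSV: chrom, start, end, log_ratio[, baf][, state]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "log_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing segment columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        baf = getattr(row, "baf", None)
        baf = None if baf is None or pd.isna(baf) else float(baf)
        state = getattr(row, "state", None)
        if state is None or pd.isna(state):
            state = infer_segment_state(float(row.log_ratio), baf)
        try:
            out.append(
                CopyNumberSegment(
                    chrom=str(row.chrom),
                    start=int(row.start),
                    end=int(row.end),
                    log_ratio=float(row.log_ratio),
                    baf=baf,
                    state=str(state),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return out


def write_segments(segments: Sequence[CopyNumberSegment], path: str | Path) -> None:
    cols = ["chrom", "start", "end", "log_ratio", "baf", "state"]
    df = pd.DataFrame([{c: getattr(s, c) for c in cols} for s in segments], columns=cols)
    df.to_csv(path, sep="\t", index=False)


def read_signature_matrix(path: str | Path) -> SignatureSet:
    """Read a 96 x K signature matrix TSV.

    The first column holds channel labels like ``A[C>T]G``; remaining
    columns are signatures. Rows may appear in any order — they are
    reordered by label onto the canonical channel order. Columns not
    summing to 1 (within 1e-6) are renormalised with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    labels = df[label_col].astype(str).tolist()
    for lab in labels:
        if lab not in _CHANNEL_INDEX:
            raise ParseError(f"{path}: unknown channel label {lab!r}")
    if len(set(labels)) != 96:
        raise ParseError(f"{path}: expected 96 unique channel labels, got {len(set(labels))}")
    df = df.set_index(label_col).reindex(CHANNEL_LABELS)
    names = [str(c) for c in df.columns]
    probs = df.to_numpy(dtype=float).T  # K x 96
    sums = probs.sum(axis=1)
    off = np.abs(sums - 1.0) > 1e-6
    if off.any():
        logger.warning(
            "%s: renormalising signature columns not summing to 1: %s",
            path,
            [names[i] for i in np.nonzero(off)[0]],
        )
    return SignatureSet(names=names, probs=probs)


def write_signature_matrix(signatures: SignatureSet, path: str | Path) -> None:
    df = pd.DataFrame(
        signatures.probs.T, index=list(CHANNEL_LABELS), columns=signatures.names
    )
    df.index.name = "channel"
    df.to_csv(path, sep="\t")


def write_catalogs(catalogs: Sequence[Catalog96], path: str | Path) -> None:
    """Samples x 96 catalog matrix TSV."""
    df = pd.DataFrame(
        [c.counts for c in catalogs],
        index=[c.sample_id for c in catalogs],
        columns=list(CHANNEL_LABELS),
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_catalogs(path: str | Path, assay: str = "wgs") -> list[Catalog96]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(CHANNEL_LABELS):
        df = df.reindex(columns=list(CHANNEL_LABELS))
        if df.isna().any().any():
            raise ParseError(f"{path}: catalog columns do not cover the 96 channels")
    return [
        Catalog96(sample_id=str(ix), counts=row.to_numpy(dtype=float), assay=assay)
        for ix, row in df.iterrows()
    ]
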