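"""Fixed-signature refitting and per-mutation attribution.

A sample's SBS-96 catalog is explained as a non-negative combination of
fixed signature profiles P_{c,k} (each a probability distribution over the
96 trinucleotide channels).  Exposures s_k are fitted by non-negative least
squares and rescaled so that sum(s_k) equals the catalog total, i.e. s_k is
the number of SNVs attributed to signature k.

Which signatures a sample carries is decided by greedy forward selection on
reconstruction cosine similarity: a signature enters only if adding it
(with a full refit) raises the cosine between catalog and reconstruction by
at least ``min_cosine_increase`` (default 0.02).  Cohort-level pruning
removes signatures never reaching ``cohort_threshold`` (default 150)
mutations in any single sample, and per-sample QC excludes catalogs with
fewer than 30 SNVs or a reconstruction cosine below 0.9.

Given fitted exposures, the probability that a particular mutation m at
channel c arose from signature i is

    P(i | m) = s_i P_{c,i} / sum_k s_k P_{c,k}

with the sum running over the sample's detected signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .io import Catalog96, MutationChannel, SignatureSet

logger = logging.getLogger(__name__)


@dataclass
class ExposureVector:
    """Per-sample signature strengths (in numbers of SNVs)."""

    sample_id: str
    detected: list[str]
    s: np.ndarray
    reconstruction_cosine: float | None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (len(self.detected),):
            raise ValueError("one exposure per detected signature required")
        if (self.s < -1e-9).any():
            raise ValueError("exposures must be non-negative")

    @property
    def total(self) -> float:
        return float(self.s.sum())

    def exposure(self, name: str) -> float:
        return float(self.s[self.detected.index(name)]) if name in self.detected else 0.0


@dataclass
class AttributionResult:
    """Posterior probability per detected signature for one mutation."""

    channel: MutationChannel
    posterior: dict[str, float]
    defined: bool

    def best(self) -> tuple[str, float] | None:
        if not self.defined:
            return None
        name = max(self.posterior, key=self.posterior.get)
        return name, self.posterior[name]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def refit_exposures(
    catalog: Catalog96, signatures: SignatureSet, active: Sequence[str]
) -> ExposureVector:
    """Non-negative least-squares fit of the catalog to the active signatures.

    Exposures are rescaled so they sum to the catalog total; the
    reconstruction cosine compares the catalog with its fitted
    reconstruction (None for an all-zero catalog).
    """
    if not active:
        raise ValueError("active signature set must be non-empty")
    sub = signatures.subset(active)
    A = sub.probs.T  # 96 x k
    y = catalog.counts
    total = y.sum()
    if total == 0:
        return ExposureVector(
            sample_id=catalog.sample_id,
            detected=list(active),
            s=np.zeros(len(active)),
            reconstruction_cosine=None,
        )
    s, _ = nnls(A, y)
    if s.sum() > 0:
        s = s * (total / s.sum())
    recon = A @ s
    return ExposureVector(
        sample_id=catalog.sample_id,
        detected=list(active),
        s=s,
        reconstruction_cosine=_cosine(y, recon),
    )


def forward_select(
    catalog: Catalog96,
    signatures: SignatureSet,
    min_cosine_increase: float = 0.02,
) -> ExposureVector:
    """Greedy forward selection of signatures by reconstruction cosine.

    Starting from the empty set, repeatedly add the candidate whose
    inclusion (with refit) most increases the reconstruction cosine; stop
    when the best increase falls below ``min_cosine_increase``.  Ties are
    broken by signature name.  Returns the refit on the selected set; an
    empty set (with warning) if no signature clears the first step.
    """
    if catalog.total == 0:
        raise ValueError("cannot select signatures for an empty catalog")
    selected: list[str] = []
    current_cos = 0.0
    remaining = sorted(signatures.names)
    best_fit: ExposureVector | None = None

    while remaining:
        best_gain, best_name, best_candidate = -np.inf, None, None
        for name in remaining:
            fit = refit_exposures(catalog, signatures, selected + [name])
            gain = fit.reconstruction_cosine - current_cos
            if gain > best_gain + 1e-12:
                best_gain, best_name, best_candidate = gain, name, fit
        if best_gain < min_cosine_increase:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current_cos = best_candidate.reconstruction_cosine
        best_fit = best_candidate

    if best_fit is None:
        logger.warning(
            "no signature raises reconstruction cosine by >= %.3f for sample %s",
            min_cosine_increase,
            catalog.sample_id,
        )
        return ExposureVector(
            sample_id=catalog.sample_id, detected=[], s=np.zeros(0), reconstruction_cosine=None
        )
    return best_fit


def cohort_prefilter(
    exposures: Sequence[ExposureVector], threshold: float = 150
) -> list[str]:
    """Signatures reaching > threshold mutations in at least one sample.

    Signatures never exceeding the threshold anywhere in the cohort are
    judged likely spurious and dropped; final per-sample fits should be
    re-run restricted to the retained set.
    """
    best: dict[str, float] = {}
    for ev in exposures:
        for name, s in zip(ev.detected, ev.s):
            best[name] = max(best.get(name, 0.0), float(s))
    return sorted(name for name, m in best.items() if m > threshold)


@dataclass
class QCDecision:
    usable: bool
    reason: str | None = None


def sample_qc(
    catalog: Catalog96,
    fit: ExposureVector,
    min_snvs: int = 30,
    min_reconstruction: float = 0.9,
) -> QCDecision:
    """Exclude catalogs too small or too poorly reconstructed.

    Fewer than ``min_snvs`` SNVs excludes any assay; a reconstruction
    cosine below ``min_reconstruction`` excludes exome samples.
    """
    if catalog.total < min_snvs:
        return QCDecision(usable=False, reason="low_count")
    if (
        catalog.assay == "wes"
        and fit.reconstruction_cosine is not None
        and fit.reconstruction_cosine < min_reconstruction
    ):
        return QCDecision(usable=False, reason="poor_reconstruction")
    return QCDecision(usable=True)


def attribute(
    channel: MutationChannel, exposures: ExposureVector, signatures: SignatureSet
) -> AttributionResult:
    """Posterior P(i|m) = s_i P_{c,i} / sum_k s_k P_{c,k} over detected
    signatures; flagged undefined when no detected signature has mass on
    the channel."""
    if exposures.total <= 0:
        raise ValueError("attribution requires positive total exposure")
    sub = signatures.subset(exposures.detected)
    mass = exposures.s * sub.probs[:, channel.index]
    denom = mass.sum()
    if denom <= 0:
        return AttributionResult(
            channel=channel,
            posterior={name: float("nan") for name in exposures.detected},
            defined=False,
        )
    post = mass / denom
    return AttributionResult(
        channel=channel,
        posterior={name: float(p) for name, p in zip(exposures.detected, post)},
        defined=True,
    )


# ---------------------------------------------------------------------------
# model / results presentation

class SignatureRefitModel:
    """Cohort signature refit with per-sample selection, cohort pruning and QC.

    Parameters
    ----------
    catalogs : sequence of Catalog96
        One SBS-96 catalog per sample.
    signatures : SignatureSet
        The candidate signature profiles.
    min_cosine_increase : float
        Required reconstruction-cosine gain for a signature to enter a
        sample (default 0.02).
    cohort_threshold : float
        Minimum single-sample exposure (in mutations) a signature must
        reach somewhere in the cohort to survive pruning (default 150).
    min_snvs, min_reconstruction
        Per-sample QC thresholds (defaults 30 SNVs, cosine 0.9 for exomes).
    """

    def __init__(
        self,
        catalogs: Sequence[Catalog96],
        signatures: SignatureSet,
        min_cosine_increase: float = 0.02,
        cohort_threshold: float = 150,
        min_snvs: int = 30,
        min_reconstruction: float = 0.9,
    ) -> None:
        self.catalogs = list(catalogs)
        self.signatures = signatures
        self.min_cosine_increase = min_cosine_increase
        self.cohort_threshold = cohort_threshold
        self.min_snvs = min_snvs
        self.min_reconstruction = min_reconstruction

    def fit(self) -> "SignatureRefitResults":
        # pass 1: per-sample forward selection over all candidates
        first_pass = [
            forward_select(c, self.signatures, self.min_cosine_increase)
            for c in self.catalogs
            if c.total > 0
        ]
        retained = cohort_prefilter(first_pass, self.cohort_threshold)
        fits: dict[str, ExposureVector] = {}
        qc: dict[str, QCDecision] = {}
        for catalog in self.catalogs:
            if catalog.total == 0 or not retained:
                fit = ExposureVector(
                    sample_id=catalog.sample_id,
                    detected=[],
                    s=np.zeros(0),
                    reconstruction_cosine=None,
                )
            else:
                # pass 2: forward selection restricted to the retained set
                fit = forward_select(
                    catalog, self.signatures.subset(retained), self.min_cosine_increase
                )
            fits[catalog.sample_id] = fit
            qc[catalog.sample_id] = sample_qc(
                catalog, fit, self.min_snvs, self.min_reconstruction
            )
        return SignatureRefitResults(model=self, retained=retained, exposures=fits, qc=qc)


@dataclass
class SignatureRefitResults:
    model: SignatureRefitModel
    retained: list[str]
    exposures: dict[str, ExposureVector]
    qc: dict[str, QCDecision]

    def attribute(self, sample_id: str, channel: MutationChannel) -> AttributionResult:
        return attribute(channel, self.exposures[sample_id], self.model.signatures)

    def to_frame(self):
        import pandas as pd

        names = self.retained
        rows = []
        for sid, ev in self.exposures.items():
            row = {"sample_id": sid}
            row.update({n: ev.exposure(n) for n in names})
            row["reconstruction_cosine"] = ev.reconstruction_cosine
            row["usable"] = self.qc[sid].usable
            row["qc_reason"] = self.qc[sid].reason
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_usable = sum(d.usable for d in self.qc.values())
        lines = [
            "Signature refit",
            "=" * 38,
            f"samples                   {len(self.exposures)}",
            f"usable after QC           {n_usable}",
            f"retained signatures       {', '.join(self.retained) or '(none)'}",
        ]
        for sid, ev in self.exposures.items():
            cos = "n/a" if ev.reconstruction_cosine is None else f"{ev.reconstruction_cosine:.3f}"
            parts = ", ".join(
                f"{n}={s:.0f}" for n, s in zip(ev.detected, ev.s) if s > 0.5
            )
            lines.append(f"  {sid}: cosine {cos}; {parts or 'no exposure'}")
        return "\n".join(lines)
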