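import numpy as np
import pytest

from mosatin.io import GenomicVariant, SignatureSet


@pytest.fixture
def reference():
    """A tiny in-memory genome: mapping of contig name to sequence string."""
    return {
        "1": "TTACAGGCGTACGTANATTTCCGGA",
        "2": "GGGCCCAAATTT",
    }


def make_variant(**kw) -> GenomicVariant:
    base = dict(
        sample_id="S1",
        chrom="1",
        pos=4,
        ref_allele="C",
        alt_allele="T",
        tumor_alt=40,
        tumor_depth=100,
        normal_alt=0,
        normal_depth=100,
    )
    base.update(kw)
    return GenomicVariant(**base)


@pytest.fixture
def disjoint_signatures():
    """Two signatures with disjoint channel support (exact-fit cases)."""
    pa = np.zeros(96)
    pa[:16] = 1 / 16
    pb = np.zeros(96)
    pb[48:64] = 1 / 16
    return SignatureSet(names=["sigA", "sigB"], probs=np.vstack([pa, pb]))


@pytest.fixture
def cosmic_like_signatures():
    """Four sparse, partially overlapping signature profiles.

    Built deterministically; mimics the peaked shape of real SBS
    signatures without copying any published matrix.
    """
    rng = np.random.default_rng(20210212)
    probs = []
    for k in range(4):
        p = rng.dirichlet(np.full(96, 0.08))
        probs.append(p)
    return SignatureSet(names=[f"S{k+1}" for k in range(4)], probs=np.vstack(probs))
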