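"""Signature refitting, forward selection, QC and per-mutation attribution."""

import itertools

import numpy as np
import pytest

from mosatin.io import Catalog96, MutationChannel, SignatureSet, CHANNEL_LABELS
from mosatin.signatures import (
    ExposureVector,
    SignatureRefitModel,
    attribute,
    cohort_prefilter,
    forward_select,
    refit_exposures,
    sample_qc,
)
from mosatin.simulate import simulate_catalog


def catalog_from(counts, sample_id="S", assay="wgs"):
    return Catalog96(sample_id=sample_id, counts=np.asarray(counts, float), assay=assay)


class TestRefit:
    def test_exact_single_signature(self, disjoint_signatures):
        cat = catalog_from(500 * disjoint_signatures.probs[0])
        ev = refit_exposures(cat, disjoint_signatures, ["sigA"])
        assert ev.s[0] == pytest.approx(500, abs=1e-9)
        assert ev.reconstruction_cosine == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_mixture_recovered_exactly(self, disjoint_signatures):
        cat = catalog_from(
            300 * disjoint_signatures.probs[0] + 700 * disjoint_signatures.probs[1]
        )
        ev = refit_exposures(cat, disjoint_signatures, ["sigA", "sigB"])
        np.testing.assert_allclose(ev.s, [300, 700], atol=1e-9)
        # independent oracle: unconstrained least squares (interior solution)
        A = disjoint_signatures.probs.T
        s_ls, *_ = np.linalg.lstsq(A, cat.counts, rcond=None)
        np.testing.assert_allclose(ev.s, s_ls, atol=1e-6)

    def test_wrong_signature_gives_near_zero_cosine(self, disjoint_signatures):
        cat = catalog_from(500 * disjoint_signatures.probs[1])
        ev = refit_exposures(cat, disjoint_signatures, ["sigA"])
        assert ev.reconstruction_cosine == pytest.approx(0.0, abs=1e-9)

    def test_exposures_sum_to_catalog_total(self, cosmic_like_signatures):
        rng = np.random.default_rng(0)
        cat = catalog_from(rng.integers(0, 50, 96))
        ev = refit_exposures(cat, cosmic_like_signatures, cosmic_like_signatures.names)
        assert ev.total == pytest.approx(cat.total, abs=0.5)

    def test_matches_grid_oracle_on_toy_problem(self):
        """NNLS refit agrees with a brute-force grid search on a tiny
        3-signature problem."""
        probs = np.zeros((3, 96))
        probs[0, :4] = [0.4, 0.3, 0.2, 0.1]
        probs[1, 2:6] = [0.1, 0.2, 0.3, 0.4]
        probs[2, 4:8] = 0.25
        sigs = SignatureSet(names=["a", "b", "c"], probs=probs)
        true = np.array([30.0, 50.0, 20.0])
        cat = catalog_from(true @ sigs.probs)
        ev = refit_exposures(cat, sigs, ["a", "b", "c"])

        A = sigs.probs.T
        best, best_rss = None, np.inf
        for s in itertools.product(range(0, 101, 2), repeat=3):
            rss = np.sum((A @ np.array(s, float) - cat.counts) ** 2)
            if rss < best_rss:
                best, best_rss = np.array(s, float), rss
        np.testing.assert_allclose(ev.s, best, atol=2.0)  # grid step is 2
        np.testing.assert_allclose(ev.s, true, atol=1e-6)

    def test_zero_catalog(self, disjoint_signatures):
        ev = refit_exposures(catalog_from(np.zeros(96)), disjoint_signatures, ["sigA"])
        assert ev.total == 0
        assert ev.reconstruction_cosine is None


class TestForwardSelect:
    def test_exact_catalog_detected_in_one_step(self, disjoint_signatures):
        cat = catalog_from(400 * disjoint_signatures.probs[0])
        ev = forward_select(cat, disjoint_signatures)
        assert ev.detected == ["sigA"]
        assert ev.reconstruction_cosine == pytest.approx(1.0, abs=1e-12)

    def test_single_generating_signature_detected(self, cosmic_like_signatures):
        cat, _, _ = simulate_catalog(
            cosmic_like_signatures, [1000, 0, 0, 0], seed=5
        )
        ev = forward_select(cat, cosmic_like_signatures)
        assert "S1" in ev.detected
        assert ev.exposure("S1") > 900

    def test_two_component_mixture_exposures_within_sampling_error(
        self, cosmic_like_signatures
    ):
        n, w = 2000, 0.7
        cat, _, _ = simulate_catalog(
            cosmic_like_signatures, [w * n, (1 - w) * n, 0, 0], seed=9
        )
        ev = forward_select(cat, cosmic_like_signatures)
        assert {"S1", "S2"} <= set(ev.detected)
        bound = 3 * np.sqrt(n * w * (1 - w))
        assert abs(ev.exposure("S1") - w * n) < bound
        assert abs(ev.exposure("S2") - (1 - w) * n) < bound

    def test_cosine_nondecreasing_across_iterations(self, cosmic_like_signatures):
        cat, _, _ = simulate_catalog(
            cosmic_like_signatures, [500, 300, 200, 0], seed=3
        )
        # with threshold 0 the greedy path visits a nondecreasing cosine sequence
        ev = forward_select(cat, cosmic_like_signatures, min_cosine_increase=0.0)
        prev = 0.0
        for i in range(1, len(ev.detected) + 1):
            fit = refit_exposures(cat, cosmic_like_signatures, ev.detected[:i])
            assert fit.reconstruction_cosine >= prev - 1e-12
            prev = fit.reconstruction_cosine

    def test_no_signature_clears_threshold(self, disjoint_signatures):
        # catalog orthogonal to both signatures
        counts = np.zeros(96)
        counts[90:96] = 50
        ev = forward_select(catalog_from(counts), disjoint_signatures)
        assert ev.detected == []

    def test_empty_catalog_rejected(self, disjoint_signatures):
        with pytest.raises(ValueError):
            forward_select(catalog_from(np.zeros(96)), disjoint_signatures)


class TestCohortRules:
    def test_prefilter_150_rule(self):
        evs = [
            ExposureVector("a", ["x", "y"], np.array([120.0, 200.0]), 0.99),
            ExposureVector("b", ["x"], np.array([90.0]), 0.99),
        ]
        assert cohort_prefilter(evs) == ["y"]

    def test_prefilter_empty_cohort(self):
        assert cohort_prefilter([]) == []

    def test_qc_low_count(self):
        cat = catalog_from(np.r_[np.full(5, 5.0), np.zeros(91)], assay="wes")
        d = sample_qc(cat, ExposureVector("s", [], np.zeros(0), None))
        assert (d.usable, d.reason) == (False, "low_count")

    def test_qc_poor_reconstruction_exome(self):
        cat = catalog_from(np.full(96, 2.0), assay="wes")
        d = sample_qc(cat, ExposureVector("s", ["x"], np.array([192.0]), 0.85))
        assert (d.usable, d.reason) == (False, "poor_reconstruction")

    def test_qc_good_genome_usable(self):
        cat = catalog_from(np.full(96, 60.0), assay="wgs")
        d = sample_qc(cat, ExposureVector("s", ["x"], np.array([5760.0]), 0.95))
        assert d.usable


class TestAttribution:
    def test_single_signature_probability_one(self, disjoint_signatures):
        ev = ExposureVector("s", ["sigA"], np.array([100.0]), 1.0)
        ch = MutationChannel.from_label(CHANNEL_LABELS[0])
        res = attribute(ch, ev, disjoint_signatures)
        assert res.posterior["sigA"] == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        probs = np.vstack(
            [np.r_[0.02, np.full(95, 0.98 / 95)], np.r_[0.01, np.full(95, 0.99 / 95)]]
        )
        sigs = SignatureSet(names=["a", "b"], probs=probs)
        ev = ExposureVector("s", ["a", "b"], np.array([100.0, 300.0]), 1.0)
        res = attribute(MutationChannel.from_label(CHANNEL_LABELS[0]), ev, sigs)
        # s_a P_a / (s_a P_a + s_b P_b) = 2 / (2 + 3); renormalised rows keep the ratio
        assert res.posterior["a"] == pytest.approx(0.4)
        assert res.posterior["b"] == pytest.approx(0.6)

    def test_identical_signatures_split_evenly(self):
        probs = np.tile(np.full(96, 1 / 96), (2, 1))
        sigs = SignatureSet(names=["a", "b"], probs=probs)
        ev = ExposureVector("s", ["a", "b"], np.array([50.0, 50.0]), 1.0)
        res = attribute(MutationChannel.from_label(CHANNEL_LABELS[10]), ev, sigs)
        assert res.posterior["a"] == pytest.approx(0.5)

    def test_undefined_when_no_mass_on_channel(self, disjoint_signatures):
        ev = ExposureVector("s", ["sigA"], np.array([100.0]), 1.0)
        ch = MutationChannel.from_label(CHANNEL_LABELS[95])  # outside sigA support
        res = attribute(ch, ev, disjoint_signatures)
        assert not res.defined

    def test_posteriors_sum_to_one_and_permutation_equivariant(
        self, cosmic_like_signatures
    ):
        ev = ExposureVector(
            "s", list(cosmic_like_signatures.names), np.array([10.0, 20.0, 30.0, 40.0]), 1.0
        )
        perm = [2, 0, 3, 1]
        sigs_perm = SignatureSet(
            names=[cosmic_like_signatures.names[i] for i in perm],
            probs=cosmic_like_signatures.probs[perm],
        )
        ev_perm = ExposureVector(
            "s", list(sigs_perm.names), np.array([30.0, 10.0, 40.0, 20.0]), 1.0
        )
        for label in CHANNEL_LABELS[::7]:
            ch = MutationChannel.from_label(label)
            res = attribute(ch, ev, cosmic_like_signatures)
            if res.defined:
                assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-9)
                res_p = attribute(ch, ev_perm, sigs_perm)
                for name in res.posterior:
                    assert res_p.posterior[name] == pytest.approx(res.posterior[name])


class TestRefitModel:
    def test_cohort_pipeline_prunes_and_refits(self, cosmic_like_signatures):
        cats = [
            simulate_catalog(cosmic_like_signatures, [800, 400, 0, 0], seed=1,
                             sample_id="P1")[0],
            simulate_catalog(cosmic_like_signatures, [0, 600, 0, 0], seed=2,
                             sample_id="P2")[0],
        ]
        res = SignatureRefitModel(cats, cosmic_like_signatures).fit()
        assert {"S1", "S2"} <= set(res.retained)
        # S3/S4 never exceed 150 mutations anywhere: pruned
        assert "S3" not in res.retained and "S4" not in res.retained
        df = res.to_frame()
        assert set(df.sample_id) == {"P1", "P2"}
        assert df.usable.all()
        assert "retained signatures" in res.summary()

    def test_attribution_through_results(self, cosmic_like_signatures):
        cat, channels, _ = simulate_catalog(
            cosmic_like_signatures, [1000, 500, 0, 0], seed=4, sample_id="P1"
        )
        res = SignatureRefitModel([cat], cosmic_like_signatures).fit()
        ch = MutationChannel.from_label(CHANNEL_LABELS[int(channels[0])])
        att = res.attribute("P1", ch)
        if att.defined:
            assert sum(att.posterior.values()) == pytest.approx(1.0, abs=1e-9)
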