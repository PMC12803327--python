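"""Raw and split-half corrected DVC: arithmetic, recovery, symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dvcorr import (
    ClassPair,
    DecisionVariableCorrelation,
    DVSeries,
    EmbeddingConfig,
    Representation,
    SDTObserverPair,
    StimulusSet,
    correct_attenuation,
    dvc_between,
    dvc_matrix,
    embed_representation,
    raw_pair_dvc,
    simulate_latent_dvs,
    split_half_dvc,
)
from .conftest import PAIR_AB, make_embedded_pair


def _series(dv, classes, observer="o1"):
    dv = np.asarray(dv, float)
    classes = np.asarray(classes, str)
    ids = np.array([f"i{j}" for j in range(dv.size)])
    return DVSeries(observer, PAIR_AB, ids, dv, classes, sign_convention="b")


class TestRawPairDVC:
    def test_identical_series_is_one(self):
        s = _series([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert raw_pair_dvc(s, s) == (1.0, 1.0)

    def test_sign_flip_is_minus_one(self):
        s1 = _series([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        s2 = _series([-1, -2, -3, -4, -5, -6], ["a"] * 3 + ["b"] * 3)
        r = raw_pair_dvc(s1, s2)
        np.testing.assert_allclose(r, (-1.0, -1.0))

    def test_hand_computed_example(self):
        # class a: (1,2,3) vs (2,4,6) -> 1; class b: (1,2,4) vs (1,3,4) -> 39/42
        s1 = _series([1, 2, 3, 1, 2, 4], ["a"] * 3 + ["b"] * 3)
        s2 = _series([2, 4, 6, 1, 3, 4], ["a"] * 3 + ["b"] * 3)
        r = raw_pair_dvc(s1, s2)
        np.testing.assert_allclose(r, (1.0, 39.0 / 42.0), atol=1e-12)

    def test_trial_mismatch_rejected(self):
        s1 = _series([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        s2 = _series([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        s2.stimulus_id = s2.stimulus_id[::-1].copy()
        with pytest.raises(ValueError, match="different trials"):
            raw_pair_dvc(s1, s2)

    def test_zero_variance_rejected(self):
        s1 = _series([1, 1, 1, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        s2 = _series([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="zero variance"):
            raw_pair_dvc(s1, s2)

    @settings(max_examples=30, deadline=None)
    @given(
        shift=st.floats(-100, 100, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_invariant_to_positive_affine_rescaling(self, shift, scale):
        """Pearson invariance: shifting or positively scaling DVs changes nothing."""
        rng = np.random.default_rng(0)
        dv1 = rng.standard_normal(20)
        dv2 = dv1 + rng.standard_normal(20)
        classes = ["a"] * 10 + ["b"] * 10
        base = raw_pair_dvc(_series(dv1, classes), _series(dv2, classes))
        moved = raw_pair_dvc(
            _series(dv1, classes), _series(dv2 * scale + shift, classes)
        )
        np.testing.assert_allclose(moved, base, atol=1e-12)


class TestCorrectAttenuation:
    def test_fixed_input_arithmetic(self):
        r_cross, r_self, corrected, flags = correct_attenuation(
            np.full(4, 0.4), 0.64, 0.64
        )
        np.testing.assert_allclose(r_cross, 0.4)
        np.testing.assert_allclose(r_self, 0.64)
        np.testing.assert_allclose(corrected, 0.625)
        assert flags == ()

    def test_low_reliability_yields_missing(self):
        _, r_self, corrected, flags = correct_attenuation(
            np.full(4, 0.1), 0.04, 0.8
        )
        assert np.isnan(corrected) and np.isnan(r_self)
        assert "low_reliability" in flags

    def test_sign_disagreement_flagged(self):
        *_, flags = correct_attenuation(np.array([0.4, 0.4, -0.4, 0.4]), 0.5, 0.5)
        assert "cross_sign_disagreement" in flags

    def test_corrected_above_one_flagged_not_clipped(self):
        _, _, corrected, flags = correct_attenuation(np.full(4, 0.6), 0.5, 0.5)
        np.testing.assert_allclose(corrected, 1.2)
        assert "exceeds_unity" in flags


class TestSplitHalfDVC:
    def test_self_comparison_raw_is_exactly_one(self):
        """Identical full-feature DVs correlate at exactly 1, whatever the
        noise level; the corrected value is only meaningful for noise that
        is independent between the observers."""
        rep1, _, stim, _, _ = make_embedded_pair(0.5, 300, noise_sd=0.5, seed=1)
        p = split_half_dvc(rep1, rep1, stim, PAIR_AB, n_splits=3, seed=2)
        np.testing.assert_allclose(p.raw, 1.0, atol=1e-10)

    def test_copy_without_independent_noise_is_unity(self):
        """An exact copy of a near-noiseless observer: raw and corrected 1."""
        rep1, _, stim, _, _ = make_embedded_pair(0.5, 300, noise_sd=1e-4, seed=3)
        rep2 = Representation("copy", rep1.matrix.copy())
        p = split_half_dvc(rep1, rep2, stim, PAIR_AB, n_splits=3, seed=4)
        np.testing.assert_allclose(p.raw, 1.0, atol=0.02)
        np.testing.assert_allclose(p.corrected, 1.0, atol=0.02)

    def test_attenuation_recovery_monte_carlo(self):
        """Noise attenuates raw DVC; the split-half ratio undoes it.

        Latent correlation 0.6 embedded with noise giving split-half
        reliability near 0.5: raw comes out near rho times the full-DV
        reliability, corrected near rho.
        """
        rep1, rep2, stim, _, _ = make_embedded_pair(
            0.6, 1000, noise_sd=np.sqrt(0.5), seed=5
        )
        p = split_half_dvc(rep1, rep2, stim, PAIR_AB, n_splits=10, seed=6)
        assert abs(np.mean(p.corrected) - 0.6) < 0.05
        # half reliability ~ 1/(1+2*0.5) = 0.5; full-DV reliability is its
        # Spearman-Brown step-up ~ 2/3, so raw ~ 0.6 * 2/3 = 0.4
        assert abs(np.mean(p.raw) - 0.4) < 0.05
        assert np.all((p.r_self_1 > 0.4) & (p.r_self_1 < 0.6))

    def test_pure_noise_reliability_reported_missing(self):
        rng = np.random.default_rng(7)
        stim = StimulusSet(
            np.array([f"i{j}" for j in range(80)]),
            np.repeat(["a", "b"], 40),
        )
        # tiny class separation, overwhelming independent noise
        sig = np.where(stim.class_label == "b", 0.01, -0.01)
        r1 = Representation("n1", sig[:, None] * np.ones(16) + rng.standard_normal((80, 16)) * 10)
        r2 = Representation("n2", sig[:, None] * np.ones(16) + rng.standard_normal((80, 16)) * 10)
        p = split_half_dvc(r1, r2, stim, PAIR_AB, n_splits=4, seed=8)
        assert np.isnan(p.corrected).all()
        assert all("low_reliability" in p.flags[c] for c in p.classes)
        assert np.isfinite(p.raw).all()  # raw still reported

    def test_pooled_mode_single_value(self):
        rep1, rep2, stim, _, _ = make_embedded_pair(0.5, 200, seed=9)
        p = split_half_dvc(rep1, rep2, stim, PAIR_AB, n_splits=2, seed=10,
                           mode="pooled")
        assert p.classes == ("pooled",)
        assert p.raw.shape == (1,)


class TestDVCBetween:
    def test_two_classes_give_two_values(self):
        rep1, rep2, stim, _, _ = make_embedded_pair(0.5, 200, seed=11)
        res = dvc_between(rep1, rep2, stim, n_splits=2, seed=12)
        assert len(res.pair_values) == 1
        assert res.n_values == 2
        np.testing.assert_allclose(
            res.mean_raw, np.mean(res.pair_values[0].raw)
        )

    def test_eight_classes_give_28_pairs_56_values(self):
        rng = np.random.default_rng(13)
        n_per, n_feat = 40, 16
        classes = [f"c{j}" for j in range(8)]
        labels = np.repeat(classes, n_per)
        ids = np.array([f"i{j}" for j in range(8 * n_per)])
        stim = StimulusSet(ids, labels)
        # class-specific mean patterns plus noise, shared across observers
        means = {c: rng.standard_normal(n_feat) * 2 for c in classes}
        base = np.array([means[c] for c in labels])
        shared = rng.standard_normal((8 * n_per, n_feat))
        r1 = Representation("o1", base + shared + rng.standard_normal((8 * n_per, n_feat)))
        r2 = Representation("o2", base + shared + rng.standard_normal((8 * n_per, n_feat)))
        res = dvc_between(r1, r2, stim, n_splits=2, seed=14)
        assert len(res.pair_values) == 28
        assert res.n_values == 56

    def test_symmetric_in_observer_order(self):
        rep1, rep2, stim, _, _ = make_embedded_pair(0.4, 300, seed=15)
        a = dvc_between(rep1, rep2, stim, n_splits=3, seed=16)
        b = dvc_between(rep2, rep1, stim, n_splits=3, seed=16)
        assert a.mean_raw == b.mean_raw
        assert a.mean_corrected == b.mean_corrected

    def test_model_results_roundtrip(self, tmp_path):
        """The model class reproduces the functional API and summarises."""
        from dvcorr.data import save_observer

        rep1, rep2, stim, _, _ = make_embedded_pair(0.5, 200, seed=17)
        save_observer(stim, rep1, tmp_path / "m1.csv", tmp_path / "l1.csv")
        save_observer(stim, rep2, tmp_path / "m2.csv", tmp_path / "l2.csv")
        model = DecisionVariableCorrelation.from_files(
            tmp_path / "m1.csv", tmp_path / "l1.csv",
            tmp_path / "m2.csv", tmp_path / "l2.csv",
            n_splits=2,
        )
        res = model.fit(seed=18)
        direct = dvc_between(rep1, rep2, stim, n_splits=2, seed=18)
        # observer ids differ (file stems) so split seeds differ; compare raw,
        # which does not depend on the splits
        np.testing.assert_allclose(res.mean_raw, direct.mean_raw, atol=1e-12)
        text = res.summary()
        assert "Mean corrected DVC" in text
        table = res.pair_table()
        assert set(table["class"]) == {"a", "b"}


class TestDVCMatrix:
    def _observers(self, n_obs, rho_latent, seed):
        cfg = SDTObserverPair(rho=1.0, d_prime=2.0, n_trials_per_class=200,
                              seed=seed)
        dv1, dv2, stim = simulate_latent_dvs(cfg)
        reps = []
        for i in range(n_obs):
            reps.append(
                embed_representation(
                    dv1, EmbeddingConfig(32, signal_axis_seed=50 + i,
                                         noise_sd=0.3),
                    seed=100 + i, observer_id=f"obs{i}",
                )
            )
        return stim, reps

    def test_identical_latents_give_near_unit_entries(self):
        stim, reps = self._observers(3, 1.0, seed=19)
        m = dvc_matrix(reps, stim, n_splits=3, seed=20)
        off = m.corrected.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=0.05)
        np.testing.assert_allclose(np.diag(m.raw), 1.0)

    def test_symmetry_and_dissimilarity_complement(self):
        stim, reps = self._observers(3, 1.0, seed=21)
        m = dvc_matrix(reps, stim, n_splits=2, seed=22)
        np.testing.assert_array_equal(m.raw.to_numpy(), m.raw.to_numpy().T)
        np.testing.assert_allclose(
            (m.raw + m.dissimilarity_raw).to_numpy(), 1.0
        )

    def test_independent_latents_give_near_zero_raw(self):
        cfg = SDTObserverPair(rho=0.0, d_prime=2.0, n_trials_per_class=1000,
                              seed=23)
        dv1, dv2, stim = simulate_latent_dvs(cfg)
        r1 = embed_representation(dv1, EmbeddingConfig(32, 1, 0.5), seed=2,
                                  observer_id="o1")
        r2 = embed_representation(dv2, EmbeddingConfig(32, 3, 0.5), seed=4,
                                  observer_id="o2")
        m = dvc_matrix([r1, r2], stim, n_splits=2, seed=24)
        assert abs(m.raw.loc["o1", "o2"]) < 0.05

    def test_duplicate_observer_ids_rejected(self):
        stim, reps = self._observers(2, 1.0, seed=25)
        reps[1].observer_id = reps[0].observer_id
        with pytest.raises(ValueError, match="duplicate"):
            dvc_matrix(reps, stim)
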