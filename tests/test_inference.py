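"""Surrogates, behavior regression, rotation scans, epochs, ROC, subspace."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import interbrain as ib
from .conftest import random_dyad


class TestSurrogate:
    def _check_preserved(self, activity, seed=0):
        sur = ib.generate_surrogate(activity, seed=seed)
        pair = ib.decompose_pair(sur.activity)
        assert abs(
            ib.interbrain_correlation(*sur.activity.values) - sur.original_correlation
        ) < 1e-10
        assert np.var(pair.mean) == pytest.approx(sur.original_var_mean, abs=1e-10)
        assert np.var(pair.diff) == pytest.approx(
            sur.original_var_diff, rel=1e-10, abs=1e-14
        )
        return sur

    def test_preserves_invariants_on_random_input(self, rng):
        self._check_preserved(random_dyad(rng, n_bins=600))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_preservation_property_sweep(self, seed):
        r = np.random.default_rng(seed)
        self._check_preserved(random_dyad(r, n_bins=300), seed=seed)

    def test_surrogate_difference_is_slower(self, one_chamber_session):
        original = ib.decompose_pair(one_chamber_session.activity)
        sur = self._check_preserved(one_chamber_session.activity, seed=3)
        spair = ib.decompose_pair(sur.activity)
        dt = original.dt
        c_orig = ib.spectral_summary(original.diff, dt).centroid_hz
        c_sur = ib.spectral_summary(spair.diff, dt).centroid_hz
        assert c_sur < c_orig

    def test_mean_component_unchanged(self, one_chamber_session):
        sur = ib.generate_surrogate(one_chamber_session.activity, seed=1)
        orig = ib.decompose_pair(one_chamber_session.activity)
        new = ib.decompose_pair(sur.activity)
        np.testing.assert_allclose(new.mean, orig.mean, atol=1e-12)

    def test_collinear_components_rejected(self):
        t = np.arange(300) * 2.5
        base = np.sin(2 * np.pi * t / 700.0)
        activity = ib.ActivityTimeSeries(
            times=t, values=np.vstack([3.0 * base, base]),
            subject_ids=("a", "b"),
        )
        with pytest.raises(ValueError, match="collinear"):
            ib.generate_surrogate(activity, seed=0)


class TestRegression:
    def _behavior(self, labels1, labels2):
        labels = np.array([labels1, labels2], dtype=object)
        return ib.BehaviorSequence(
            times=np.arange(len(labels1)) * 2.5, labels=labels,
            subject_ids=("b1", "b2"),
        )

    def test_pure_indicator_activity_removed(self):
        lab1 = ["resting"] * 5 + ["probing"] * 5
        beh = self._behavior(lab1, ["fighting"] * 10)
        indicator = (np.array(lab1, dtype=object) == "resting").astype(float)
        resid = ib.regress_out_behavior(2.0 * indicator, beh)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_residual_orthogonal_to_indicators(self, rng):
        labels = np.array(ib.DEFAULT_BEHAVIORS, dtype=object)
        beh = self._behavior(
            labels[rng.integers(0, 11, 200)], labels[rng.integers(0, 11, 200)]
        )
        y = rng.standard_normal(200)
        resid = ib.regress_out_behavior(y, beh)
        for i in range(2):
            for name in ib.DEFAULT_BEHAVIORS:
                col = (beh.labels[i] == name).astype(float)
                if col.any():
                    assert abs(resid @ col) / np.linalg.norm(col) < 1e-8

    def test_random_activity_variance_roughly_preserved(self, rng):
        labels = np.array(ib.DEFAULT_BEHAVIORS, dtype=object)
        beh = self._behavior(
            labels[rng.integers(0, 11, 2000)], labels[rng.integers(0, 11, 2000)]
        )
        y = rng.standard_normal(2000)
        resid = ib.regress_out_behavior(y, beh)
        # at most ~21 fitted dof out of 2000 samples
        assert np.var(resid) > 0.95 * np.var(y)


class TestRotationScan:
    def test_one_chamber_curve_shape(self, one_chamber_session):
        df = ib.correlation_vs_rotation(
            one_chamber_session.activity, one_chamber_session.behavior,
            angles_deg=np.arange(0.0, 91.0, 5.0),
        )
        raw = df.correlation_raw.to_numpy()
        assert df.angle_deg[np.argmax(raw)] <= 10.0
        # sign change bracketing 45 degrees
        sign_change = np.where(np.diff(np.sign(raw)))[0]
        assert len(sign_change) == 1
        crossing = df.angle_deg[sign_change[0]]
        assert 35.0 <= crossing <= 50.0
        reg = df.correlation_regressed.to_numpy()
        reg_change = np.where(np.diff(np.sign(reg)))[0]
        assert abs(df.angle_deg[reg_change[0]] - crossing) <= 5.0

    def test_two_chamber_curve_flat(self, two_chamber_config, two_chamber_chain):
        means = []
        for seed in range(20):
            sess = ib.simulate_session(two_chamber_config, two_chamber_chain, seed=seed)
            df = ib.correlation_vs_rotation(sess.activity)
            means.append(df.correlation_raw.to_numpy())
        assert np.abs(np.mean(means, axis=0)).max() < 0.1


class TestRemoveCoordinatedEpochs:
    def _session(self, labels1, labels2, values=None):
        n = len(labels1)
        labels = np.array([labels1, labels2], dtype=object)
        beh = ib.BehaviorSequence(
            times=np.arange(n) * 2.5, labels=labels, subject_ids=("b1", "b2"))
        if values is None:
            values = np.random.default_rng(0).standard_normal((2, n))
        act = ib.ActivityTimeSeries(
            times=np.arange(n) * 2.5, values=values, subject_ids=("b1", "b2"))
        return act, beh

    def test_no_coordination_identity(self):
        act, beh = self._session(["resting"] * 6, ["probing"] * 6)
        kept, corr, n = ib.remove_coordinated_epochs(act, beh)
        assert n == 6
        np.testing.assert_array_equal(kept, act.values)

    def test_full_coordination_error(self):
        act, beh = self._session(["resting"] * 6, ["resting"] * 6)
        with pytest.raises(ValueError, match="remain"):
            ib.remove_coordinated_epochs(act, beh)

    def test_hand_filtered_six_bins(self):
        values = np.arange(12.0).reshape(2, 6)
        act, beh = self._session(
            ["resting"] * 3 + ["probing", "mating", "resting"],
            ["resting"] * 3 + ["resting", "probing", "fighting"],
            values=values,
        )
        kept, corr, n = ib.remove_coordinated_epochs(act, beh)
        assert n == 3
        np.testing.assert_array_equal(kept, values[:, 3:])
        assert corr == pytest.approx(1.0)  # both halves linear in bin index

    def test_idempotent(self, one_chamber_session):
        sess = one_chamber_session
        kept, corr, n = ib.remove_coordinated_epochs(sess.activity, sess.behavior)
        keep_mask = sess.behavior.labels[0] != sess.behavior.labels[1]
        sub_beh = ib.BehaviorSequence(
            times=np.arange(n) * 2.5,
            labels=sess.behavior.labels[:, keep_mask],
            subject_ids=("b1", "b2"),
        )
        sub_act = ib.ActivityTimeSeries(
            times=np.arange(n) * 2.5, values=kept, subject_ids=("b1", "b2"))
        kept2, corr2, n2 = ib.remove_coordinated_epochs(sub_act, sub_beh)
        assert n2 == n and corr2 == pytest.approx(corr)


class TestDiscriminationAUC:
    def test_perfect_separation(self):
        resid = np.array([0.0, 0, 0, 1, 1, 1] * 2)
        labels = np.array(["resting"] * 6 + ["probing"] * 6, dtype=object)
        resid = np.concatenate([np.zeros(6), np.ones(6)])
        auc, na, nb = ib.behavior_discrimination_auc(
            resid, labels, ("resting", "probing"))
        assert auc == 1.0 and na == nb == 6

    def test_identical_distributions_half(self):
        resid = np.tile([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        labels = np.array(["resting"] * 5 + ["probing"] * 5, dtype=object)
        auc, _, _ = ib.behavior_discrimination_auc(resid, labels, ("resting", "probing"))
        assert auc == 0.5

    def test_hand_rank_example(self):
        resid = np.array([1.0, 2, 3, 2, 3, 4])
        labels = np.array(["resting"] * 3 + ["probing"] * 3, dtype=object)
        auc, _, _ = ib.behavior_discrimination_auc(
            resid, labels, ("resting", "probing"), min_count=3)
        assert auc == pytest.approx(7 / 9)

    def test_monotone_transform_invariance(self, rng):
        resid = rng.standard_normal(40)
        labels = np.array(["resting"] * 20 + ["probing"] * 20, dtype=object)
        a1, _, _ = ib.behavior_discrimination_auc(resid, labels, ("resting", "probing"))
        a2, _, _ = ib.behavior_discrimination_auc(
            np.exp(3.0 * resid), labels, ("resting", "probing"))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_insufficient_counts_error(self):
        resid = np.zeros(6)
        labels = np.array(["resting"] * 4 + ["probing"] * 2, dtype=object)
        with pytest.raises(ValueError, match=">= 5"):
            ib.behavior_discrimination_auc(resid, labels, ("resting", "probing"))


class TestDifferenceSubspace:
    def _group(self, values):
        return ib.ActivityTimeSeries(
            times=np.arange(values.shape[1]) * 2.5, values=values,
            subject_ids=tuple(f"bat{i}" for i in range(values.shape[0])),
        )

    def test_identical_subjects_zero_difference_variance(self, rng):
        base = rng.standard_normal(500)
        stats = ib.difference_subspace_stats(
            self._group(np.tile(base, (4, 1))), n_directions=50, seed=0)
        assert stats.diff_variance_avg == pytest.approx(0.0, abs=1e-10)

    def test_directions_unit_norm_orthogonal_to_ones(self, rng):
        from interbrain.inference import _random_difference_directions
        dirs = _random_difference_directions(5, 200, rng)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(dirs @ np.ones(5), 0.0, atol=1e-12)

    def test_requires_three_subjects(self, rng):
        with pytest.raises(ValueError, match="n >= 3"):
            ib.difference_subspace_stats(random_dyad(rng))

    def test_total_variance_partition(self, rng):
        values = rng.standard_normal((4, 400))
        stats = ib.difference_subspace_stats(self._group(values), n_directions=10, seed=0)
        total = np.var(values, axis=1).sum()
        assert stats.mean_variance + 3 * stats.diff_variance_avg == pytest.approx(total, rel=1e-10)
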