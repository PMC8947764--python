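"""Coupling matrix, behavioral modulation, and the linear dynamics."""

import numpy as np
import pytest

import interbrain as ib
from interbrain.neural_dynamics import ModulationSeries, moving_average


def _const_modulation(bd_vec, n_bins=240, dt=2.5, bn=None):
    bd = np.tile(np.asarray(bd_vec, float)[:, None], (1, n_bins))
    bn_arr = np.zeros_like(bd) if bn is None else bn
    return ModulationSeries(times=np.arange(n_bins) * dt, bd=bd, bn=bn_arr)


class TestCouplingMatrix:
    def test_two_subject_matrix_and_eigenvalues(self):
        c = ib.build_coupling_matrix(ib.CouplingSpec(cs=1.0, ci=0.4, n=2))
        np.testing.assert_allclose(c, [[-1.0, 0.4], [0.4, -1.0]])
        w = np.sort(np.linalg.eigvalsh(c))
        np.testing.assert_allclose(w, [-1.4, -0.6], atol=1e-12)

    def test_uncoupled_is_negative_identity(self):
        c = ib.build_coupling_matrix(ib.CouplingSpec(cs=1.0, ci=0.0, n=2))
        np.testing.assert_allclose(c, -np.eye(2))

    def test_four_subject_eigenstructure(self):
        spec = ib.CouplingSpec(cs=1.0, ci=0.1, n=4)
        c = ib.build_coupling_matrix(spec)
        ones = np.ones(4)
        np.testing.assert_allclose(c @ ones, -0.7 * ones, atol=1e-12)
        v = np.array([1.0, -1.0, 0.0, 0.0])
        np.testing.assert_allclose(c @ v, -1.1 * v, atol=1e-12)

    def test_stability_constraint(self):
        with pytest.raises(ValueError, match="CI < CS"):
            ib.CouplingSpec(cs=1.0, ci=0.4, n=4)


class TestModulation:
    def _behavior(self, pairs):
        labels = np.array(list(zip(*pairs)), dtype=object)
        return ib.BehaviorSequence(
            times=np.arange(len(pairs)) * 2.5, labels=labels,
            subject_ids=("bat1", "bat2"),
        )

    def test_resting_pair_one_chamber_level(self):
        beh = self._behavior([("resting", "resting")] * 3)
        mod = ib.modulation_from_behavior(
            beh, ib.ModulationMap(sigma_n=0.0), rng=0
        )
        np.testing.assert_allclose(mod.bd, 0.078, atol=1e-12)
        np.testing.assert_allclose(mod.bn, 0.0)

    def test_mixed_behaviors_levels(self):
        beh = self._behavior([("resting", "fighting")] * 2)
        mod = ib.modulation_from_behavior(beh, ib.ModulationMap(sigma_n=0.0), rng=0)
        np.testing.assert_allclose(mod.bd[:, 0], [0.078, 0.275], atol=1e-12)

    def test_noise_standard_deviation(self):
        beh = self._behavior([("resting", "resting")] * 50_000)
        mod = ib.modulation_from_behavior(beh, ib.ModulationMap(sigma_n=0.15), rng=3)
        assert mod.bn.std() == pytest.approx(0.15, abs=0.003)

    def test_unmapped_behavior_error(self):
        beh = self._behavior([("resting", "probing")] * 2)
        with pytest.raises(ValueError, match="probing"):
            ib.modulation_from_behavior(
                beh, ib.ModulationMap(levels={"resting": 0.1}), rng=0
            )


class TestFixedPoint:
    C = np.array([[-1.0, 0.4], [0.4, -1.0]])

    def test_symmetric_input(self):
        a = ib.fixed_point(self.C, np.array([0.078, 0.078]))
        np.testing.assert_allclose(a, [0.13, 0.13], atol=1e-12)

    def test_asymmetric_input_hand_solve(self):
        a = ib.fixed_point(self.C, np.array([0.078, 0.275]))
        np.testing.assert_allclose(a, [0.188 / 0.84, 0.3062 / 0.84], atol=1e-10)

    def test_zero_input(self):
        np.testing.assert_allclose(ib.fixed_point(self.C, np.zeros(2)), 0.0)

    def test_residual_is_zero(self):
        bd0 = np.array([0.2, 0.31])
        a = ib.fixed_point(self.C, bd0)
        np.testing.assert_allclose(self.C @ a + bd0, 0.0, atol=1e-12)


class TestSimulateDynamics:
    SPEC = ib.CouplingSpec(cs=1.0, ci=0.4, tau=15.0, n=2)

    def test_constant_modulation_stays_at_fixed_point(self):
        mod = _const_modulation([0.1, 0.25])
        out = ib.simulate_dynamics(self.SPEC, mod)
        a_star = ib.fixed_point(ib.build_coupling_matrix(self.SPEC), mod.bd[:, 0])
        assert np.abs(out.values - a_star[:, None]).max() < 1e-8

    def test_uncoupled_step_response_time_constant(self):
        spec = ib.CouplingSpec(cs=1.0, ci=0.0, tau=15.0, n=2)
        n = 240
        bd = np.zeros((2, n))
        bd[0, 40:] = 1.0  # step for subject 1 only
        mod = ModulationSeries(times=np.arange(n) * 2.5, bd=np.zeros((2, n)), bn=bd)
        out = ib.simulate_dynamics(spec, mod)
        assert np.abs(out.values[1]).max() < 1e-12  # subject 2 untouched
        # fit exponential approach a(t) = 1 - exp(-t/tc) after the step
        t = out.times[41:140] - out.times[41]
        y = out.values[0, 41:140]
        tc = np.polyfit(t, np.log(1.0 - y), 1)[0]
        assert -1.0 / tc == pytest.approx(15.0, rel=0.02)

    @pytest.mark.parametrize(
        "direction,expected_tc", [((1.0, 1.0), 25.0), ((1.0, -1.0), 15.0 / 1.4)]
    )
    def test_impulse_decay_along_eigendirections(self, direction, expected_tc):
        n = 200
        mod = _const_modulation([0.0, 0.0], n_bins=n)
        c = ib.build_coupling_matrix(self.SPEC)
        a0 = np.asarray(direction, float)
        # start from a displaced state by faking bd(0) whose fixed point is a0
        mod.bd[:, 0] = -(c @ a0)
        mod.bd[:, 1:] = 0.0
        out = ib.simulate_dynamics(self.SPEC, mod)
        proj = a0 @ out.values / (a0 @ a0)
        # skip the first bin (bd ramps to zero within it), fit the pure decay
        t = out.times[1:80] - out.times[1]
        tc = -1.0 / np.polyfit(t, np.log(np.abs(proj[1:80])), 1)[0]
        assert tc == pytest.approx(expected_tc, rel=0.02)

    def test_exact_matches_adaptive_rk(self, one_chamber_session):
        short = ModulationSeries(
            times=one_chamber_session.modulation.times[:400],
            bd=one_chamber_session.modulation.bd[:, :400],
            bn=one_chamber_session.modulation.bn[:, :400],
        )
        exact = ib.simulate_dynamics(self.SPEC, short, method="exact")
        rk = ib.simulate_dynamics(self.SPEC, short, method="rk45")
        assert np.abs(exact.values - rk.values).max() < 1e-6

    def test_superposition(self, rng):
        n = 150
        t = np.arange(n) * 2.5
        b1 = rng.standard_normal((2, n))
        b2 = rng.standard_normal((2, n))
        def run(b):
            mod = ModulationSeries(times=t, bd=np.zeros((2, n)), bn=b)
            return ib.simulate_dynamics(self.SPEC, mod).values
        lhs = run(b1 + b2)
        rhs = run(b1) + run(b2)
        assert np.abs(lhs - rhs).max() < 1e-8

    def test_zero_drive_decays_to_zero(self):
        n = 400
        mod = _const_modulation([0.0, 0.0], n_bins=n)
        mod.bd[:, 0] = [0.5, -0.2]
        mod.bd[:, 1:] = 0.0
        out = ib.simulate_dynamics(self.SPEC, mod)
        assert np.abs(out.values[:, -1]).max() < 1e-8

    def test_eigen_decoupling_of_full_session(self, one_chamber_session):
        # projections onto (1,1)/sqrt2-normalized mean/difference directions
        # must satisfy the two scalar equations driven by the projected b
        sess = one_chamber_session
        b = sess.modulation.b
        bd = sess.modulation.bd
        t = sess.modulation.times
        for sign, lam_cs in (((1, 1), 0.6), ((1, -1), 1.4)):
            w = np.asarray(sign, float) / 2.0  # component = (a1 +/- a2)/2
            proj_b = w @ b
            proj_bd = w @ bd
            scalar_spec = ib.CouplingSpec(cs=lam_cs, ci=0.0, tau=15.0, n=2)
            mod = ModulationSeries(
                times=t,
                bd=np.vstack([proj_bd, proj_bd]),
                bn=np.vstack([proj_b - proj_bd, proj_b - proj_bd]),
            )
            scalar = ib.simulate_dynamics(scalar_spec, mod).values[0]
            direct = w @ sess.activity.values
            assert np.abs(scalar - direct).max() < 1e-5


class TestGroupModulation:
    def test_degenerate_constant(self):
        mod = ib.generate_group_modulation(3, 600.0, bstd=0.0, sigma_n=0.0, rng=0)
        np.testing.assert_allclose(mod.b, 0.2, atol=1e-12)

    def test_smoothing_reduces_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.2, 3.5, 2400)
        assert np.var(moving_average(x, 1200)) < np.var(x)

    def test_subjects_uncorrelated(self):
        corrs = []
        for seed in range(50):
            mod = ib.generate_group_modulation(2, 6000.0, rng=seed)
            corrs.append(np.corrcoef(mod.b)[0, 1])
        assert abs(np.mean(corrs)) < 0.1

    def test_invalid_window(self):
        with pytest.raises(ValueError, match="window"):
            ib.generate_group_modulation(2, 600.0, smoothing_window=0, rng=0)


def test_session_reproducibility(one_chamber_config, one_chamber_chain):
    s1 = ib.simulate_session(one_chamber_config, one_chamber_chain, seed=5)
    s2 = ib.simulate_session(one_chamber_config, one_chamber_chain, seed=5)
    assert (s1.behavior.labels == s2.behavior.labels).all()
    np.testing.assert_array_equal(s1.modulation.b, s2.modulation.b)
    np.testing.assert_array_equal(s1.activity.values, s2.activity.values)


def test_one_chamber_session_variance_ratio_above_one(one_chamber_session):
    pair = ib.decompose_pair(one_chamber_session.activity)
    assert pair.variance_ratio > 1.0
    assert pair.centroid_ratio() < 1.0
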