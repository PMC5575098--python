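"""Rigid base-pair chains: step geometry, composition, closure, persistence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnacyclize.chain_mc import (
    BasePairFrame,
    FlexibilityModel,
    build_chain,
    closure_observables,
    draw_hinge_mask,
    estimate_persistence_length,
    sample_step,
    step_decay_factor,
    step_transform,
)
from dnacyclize.params_io import OpeningProfile

angles = st.floats(-40.0, 40.0, allow_nan=False)


class TestStepTransform:
    def test_zero_step_translates_along_normal(self):
        R, t = step_transform([0, 0, 0, 0, 0, 3.4])
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, [0, 0, 3.4], atol=1e-12)

    def test_ten_turns_of_36_degrees_close_a_turn(self):
        chain = build_chain(np.tile([0, 0, 36.0, 0, 0, 3.4], (10, 1)))
        np.testing.assert_allclose(chain.triads[-1], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(chain.origins[-1], [0, 0, 34.0], atol=1e-12)

    def test_small_angle_bend_magnitude(self):
        R, _ = step_transform([5.0, 3.0, 0, 0, 0, 3.4])
        # normal-normal angle equals hypot(tilt, roll) for this construction
        bend = np.degrees(np.arccos(np.clip(R[2, 2], -1, 1)))
        assert bend == pytest.approx(np.hypot(5.0, 3.0), rel=1e-9)

    def test_pure_twist_rotates_about_normal(self):
        R, _ = step_transform([0, 0, 34.3, 0, 0, 3.4])
        np.testing.assert_allclose(R[:, 2], [0, 0, 1], atol=1e-12)
        assert R[0, 0] == pytest.approx(np.cos(np.radians(34.3)))

    @given(angles, angles, angles)
    def test_rotation_is_proper_orthonormal(self, tilt, roll, twist):
        R, _ = step_transform([tilt, roll, twist, 0.1, -0.2, 3.4])
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)


class TestBuildChain:
    def test_straight_fixture_end_to_end(self):
        steps = np.tile([0, 0, 34.3, 0, 0, 3.4], (100, 1))
        chain = build_chain(steps)
        r, cosg, _ = closure_observables(chain)
        assert r == pytest.approx(340.0, rel=1e-12)
        assert cosg == pytest.approx(1.0, abs=1e-12)

    def test_inverse_composition_recovers_start(self, rng):
        steps = rng.normal(0, 5, (50, 6))
        steps[:, 5] = 3.4
        chain = build_chain(steps)
        # walk back: apply inverse transforms in reverse order
        T = chain.triads[-1].copy()
        o = chain.origins[-1].copy()
        for s in reversed(range(50)):
            R, t = step_transform(steps[s])
            T = T @ R.T
            o = o - T @ t
        np.testing.assert_allclose(T, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(o, np.zeros(3), atol=1e-9)

    def test_orthonormality_drift_bounded(self, rng):
        steps = rng.normal(0, 6, (10_000, 6))
        steps[:, 5] = 3.4
        chain = build_chain(steps)
        T = chain.triads[-1]
        assert np.abs(T.T @ T - np.eye(3)).max() < 1e-8

    def test_frame_accessor_validates(self):
        chain = build_chain(np.tile([0, 0, 34.3, 0, 0, 3.4], (5, 1)))
        frame = chain.frame(3)
        assert isinstance(frame, BasePairFrame)


class TestClosureObservables:
    def test_perfectly_closed_chain(self):
        chain = build_chain(np.tile([0, 0, 36.0, 0, 0, 0.0], (10, 1)))
        r, cosg, cosp = closure_observables(chain)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert cosg == pytest.approx(1.0)
        assert cosp == pytest.approx(1.0)

    def test_planar_circle_fixture(self):
        n = 120
        steps = np.tile([0, 360.0 / n, 0, 0, 0, 3.4], (n, 1))
        r, cosg, _ = closure_observables(build_chain(steps))
        assert r < 3.4
        assert cosg == pytest.approx(1.0, abs=1e-9)

    def test_cos_values_bounded(self, rng):
        steps = rng.normal(0, 30, (40, 6))
        steps[:, 5] = 3.4
        r, cosg, cosp = closure_observables(build_chain(steps))
        assert r >= 0 and -1 <= cosg <= 1 and -1 <= cosp <= 1


class TestHingeMask:
    def test_degenerate_profiles(self, rng):
        zeros = draw_hinge_mask(OpeningProfile(np.zeros(20)), rng)
        ones = draw_hinge_mask(OpeningProfile(np.ones(20)), rng)
        assert not zeros.any() and ones.all()

    def test_binomial_rate(self):
        rng = np.random.default_rng(99)
        profile = OpeningProfile(np.full(10, 0.3))
        draws = np.array([draw_hinge_mask(profile, rng) for _ in range(10_000)])
        frac = draws.mean()
        se = np.sqrt(0.3 * 0.7 / draws.size)
        assert abs(frac - 0.3) < 3 * se


class TestSampleStep:
    def test_zero_rms_returns_equilibrium(self, rng):
        flex = FlexibilityModel(duplex=(0, 0, 0))
        theta0 = [1.0, 2.0, 34.3, 0.1, -0.1, 3.4]
        np.testing.assert_array_equal(sample_step(theta0, flex, False, rng), theta0)

    def test_displacements_never_fluctuate(self, rng):
        flex = FlexibilityModel()
        draws = np.array(
            [sample_step([0, 0, 34.3, 0.3, -0.2, 3.4], flex, False, rng) for _ in range(50)]
        )
        np.testing.assert_array_equal(draws[:, 3:], np.tile([0.3, -0.2, 3.4], (50, 1)))

    @pytest.mark.parametrize(
        "single_strand,column,expected_sd",
        [(False, 0, 4.84), (False, 2, 4.09), (True, 2, 27.96), (True, 0, 30.08)],
    )
    def test_sampled_rms_matches_state(self, single_strand, column, expected_sd):
        rng = np.random.default_rng(2024 + column)
        flex = FlexibilityModel()
        n = 100_000
        draws = np.empty((n, 6))
        for i in range(n):
            draws[i] = sample_step([0, 0, 34.3, 0, 0, 3.4], flex, single_strand, rng)
        sd = draws[:, column].std(ddof=1)
        se = expected_sd / np.sqrt(2 * (n - 1))
        assert abs(sd - expected_sd) < 3 * se


class TestPersistenceLength:
    def test_single_strand_state_is_a_few_bp(self):
        fit = estimate_persistence_length(
            None, n_chains=3_000, chain_length=40, seed=5, state="single_strand"
        )
        assert 2.0 < fit.lp_bp < 5.0

    def test_rigid_limit_flagged(self):
        flex = FlexibilityModel(duplex=(0, 0, 0))
        fit = estimate_persistence_length(None, flex, n_chains=10, chain_length=50, seed=0)
        assert fit.rigid and np.isinf(fit.lp_bp)
        assert np.all(fit.correlation == 1.0)

    def test_trinucleotide_table_path_needs_and_uses_a_sequence(self, straight_table, short_seq):
        with pytest.raises(ValueError, match="sequence"):
            estimate_persistence_length(straight_table, n_chains=10, chain_length=20)
        fit = estimate_persistence_length(
            straight_table, n_chains=300, chain_length=200, seed=3, seq=short_seq
        )
        assert 100 < fit.lp_bp < 190

    def test_bootstrap_interval_brackets_estimate(self):
        fit = estimate_persistence_length(None, n_chains=400, chain_length=300, seed=8)
        assert fit.ci_low < fit.lp_bp < fit.ci_high

    def test_hinge_states_differ_by_flexibility_only(self):
        # conditional bend width: masked (open) sites must fluctuate with the
        # single-strand RMS, unmasked ones with the duplex RMS
        rng = np.random.default_rng(31)
        flex = FlexibilityModel()
        profile = OpeningProfile(np.array([1.0, 0.0] * 10))
        mask = draw_hinge_mask(profile, rng)
        assert mask.tolist() == [True, False] * 10
        n = 20_000
        bends_open = np.array(
            [sample_step([0, 0, 0, 0, 0, 3.4], flex, True, rng)[:2] for _ in range(n)]
        )
        bends_ds = np.array(
            [sample_step([0, 0, 0, 0, 0, 3.4], flex, False, rng)[:2] for _ in range(n)]
        )
        for arr, sd in ((bends_open, 30.08), (bends_ds, 4.84)):
            got = arr.std(ddof=1)
            assert abs(got - sd) < 4 * sd / np.sqrt(2 * arr.size)


def test_step_decay_factor_small_angle_limit():
    # E[cos G] ~ 1 - (sd_t^2 + sd_r^2)/2 for small angles, so -1/ln matches
    # the closed form 2/(sd_t^2 + sd_r^2) within a fraction of a percent
    lam = step_decay_factor(4.84, 4.84)
    lp = -1.0 / np.log(lam)
    closed = 2.0 / (2 * np.deg2rad(4.84) ** 2)
    assert lp == pytest.approx(closed, rel=5e-3)
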