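"""Closure counting, estimator normalization, coupling and reproducibility."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnacyclize.chain_mc import FlexibilityModel
from dnacyclize.jfactor import (
    ClosureThresholds,
    CyclizationCounts,
    accumulate_counts,
    estimate_jfactor,
    free_energy_equivalent,
    jfactor_from_counts,
    shimada_yamakawa_j,
    torsion_free_j,
)
from dnacyclize.params_io import AVOGADRO, DNASequence, OpeningProfile


class TestAccumulateCounts:
    def test_perfect_closure_counts_through_all_gates(self):
        counts = accumulate_counts([(0.0, 1.0, 1.0)])
        assert counts == CyclizationCounts(1, 1, 1, 1)

    def test_distance_gate_is_first(self):
        counts = accumulate_counts([(100.0, 1.0, 1.0)])
        assert counts == CyclizationCounts(1, 0, 0, 0)

    def test_alignment_without_contact_never_counted(self, rng):
        r = rng.uniform(50, 500, 1000)  # all fail the r gate
        cosg = np.ones(1000)
        cosp = np.ones(1000)
        counts = accumulate_counts((r, cosg, cosp))
        assert counts.n_r == counts.n_gamma == counts.n_phi == 0

    def test_order_independence(self, rng):
        r = rng.uniform(0, 60, 500)
        cosg = rng.uniform(-1, 1, 500)
        cosp = rng.uniform(-1, 1, 500)
        a = accumulate_counts((r, cosg, cosp))
        perm = rng.permutation(500)
        b = accumulate_counts((r[perm], cosg[perm], cosp[perm]))
        assert a == b

    @given(st.integers(0, 2**32 - 1))
    def test_nesting_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        counts = accumulate_counts(
            (rng.uniform(0, 60, n), rng.uniform(-1, 1, n), rng.uniform(-1, 1, n))
        )
        assert counts.n_total >= counts.n_r >= counts.n_gamma >= counts.n_phi >= 0

    def test_widening_thresholds_is_monotone(self, rng):
        obs = (rng.uniform(0, 60, 2000), rng.uniform(-1, 1, 2000), rng.uniform(-1, 1, 2000))
        tight = accumulate_counts(obs, ClosureThresholds(20.0, 0.9, 0.9))
        loose = accumulate_counts(obs, ClosureThresholds(40.0, 0.8, 0.8))
        assert loose.n_r >= tight.n_r


class TestJFactorFromCounts:
    def test_no_closed_chain_gives_zero_flagged(self):
        est = jfactor_from_counts(CyclizationCounts(1000, 10, 2, 0))
        assert est.j == 0.0 and est.insufficient_sampling

    def test_gamma_estimates_uniform_density(self):
        # isotropic normals: cos(gamma) uniform on [-1, 1], so the expected
        # pass fraction is (1 - 0.86)/2 = 0.07 and Gamma_hat -> 0.5
        rng = np.random.default_rng(7)
        n = 200_000
        counts = accumulate_counts(
            (np.zeros(n), rng.uniform(-1, 1, n), rng.uniform(-1, 1, n))
        )
        frac = counts.n_gamma / counts.n_r
        se = np.sqrt(0.07 * 0.93 / n)
        assert abs(frac - 0.07) < 3 * se
        gamma_hat = (counts.n_gamma / counts.n_r) / (1 - 0.86)
        assert gamma_hat == pytest.approx(0.5, rel=0.05)

    def test_w_density_recovered_from_uniform_ball(self):
        # points uniform in a ball of radius R: W_hat must report the known
        # density n/( (4/3) pi R^3 ) regardless of the counting radius r_c
        rng = np.random.default_rng(11)
        n = 400_000
        radius = 60.0
        r = radius * rng.random(n) ** (1.0 / 3.0)
        density_per_l = 1.0 / ((4.0 / 3.0) * np.pi * radius**3 * 1e-27)
        for rc in (20.0, 40.0):
            thr = ClosureThresholds(r_c=rc)
            counts = accumulate_counts((r, np.ones(n), np.ones(n)), thr)
            v_c = (4.0 / 3.0) * np.pi * rc**3 * 1e-27
            w_hat = counts.n_r / n / v_c
            assert w_hat == pytest.approx(density_per_l, rel=0.02)

    def test_ideal_chain_limit_recovers_jacobson_stockmayer(self):
        # uniform orientations and torsional register: J must equal W(0)/N_A
        rng = np.random.default_rng(3)
        n = 500_000
        radius = 90.0
        r = radius * rng.random(n) ** (1.0 / 3.0)
        cosg = rng.uniform(-1, 1, n)
        cosp = np.cos(rng.uniform(-np.pi, np.pi, n))  # uniform torsional register
        thr = ClosureThresholds()
        est = jfactor_from_counts(accumulate_counts((r, cosg, cosp), thr), thr)
        w0 = (1.0 / ((4.0 / 3.0) * np.pi * radius**3 * 1e-27))
        assert est.j == pytest.approx(w0 / AVOGADRO, rel=0.25)

    def test_stderr_positive_when_sampled(self):
        est = jfactor_from_counts(CyclizationCounts(10_000, 500, 100, 20))
        assert est.j > 0 and est.stderr > 0
        assert est.stderr / est.j == pytest.approx(
            np.sqrt((1 / 500 - 1 / 10_000) + (1 / 100 - 1 / 500) + (1 / 20 - 1 / 100)),
            rel=1e-9,
        )

    def test_empty_total_rejected(self):
        with pytest.raises(ValueError):
            jfactor_from_counts(CyclizationCounts(0, 0, 0, 0))


class TestEstimateJFactor:
    def test_coupling_degeneracy_zero_profile_equals_pure_model(self, seq63, straight_table):
        est_none = estimate_jfactor(seq63, straight_table, n_chains=30_000, seed=17)
        est_zero = estimate_jfactor(
            seq63, straight_table,
            profile=OpeningProfile(np.zeros(63), source="synthetic"),
            n_chains=30_000, seed=17,
        )
        assert est_none.counts == est_zero.counts
        assert est_none.j == est_zero.j
        assert est_none.mode == "cso" and est_zero.mode == "cso_epbd"

    def test_all_open_profile_equals_single_strand_statistics(self, seq63, straight_table):
        # p = 1 everywhere must be bit-identical to a model whose duplex
        # widths are the single-strand ones
        ones = estimate_jfactor(
            seq63, straight_table,
            profile=OpeningProfile(np.ones(63), source="synthetic"),
            n_chains=30_000, seed=23,
        )
        ss_as_duplex = FlexibilityModel(duplex=(30.08, 30.08, 27.96))
        ss = estimate_jfactor(
            seq63, straight_table, flex=ss_as_duplex, n_chains=30_000, seed=23,
        )
        assert ones.counts == ss.counts

    def test_seed_determinism(self, seq63, straight_table):
        a = estimate_jfactor(seq63, straight_table, n_chains=20_000, seed=5)
        b = estimate_jfactor(seq63, straight_table, n_chains=20_000, seed=5)
        assert a.counts == b.counts and a.j == b.j

    def test_merge_equivalence_across_chunked_workers(self, seq63, straight_table):
        prof = OpeningProfile(np.full(63, 0.4), source="synthetic")
        whole = estimate_jfactor(
            seq63, straight_table, profile=prof, n_chains=30_000, seed=77,
            chunk_size=10_000,
        )
        parts = [
            estimate_jfactor(
                seq63, straight_table, profile=prof, n_chains=10_000, seed=77,
                chunk_size=10_000, chunk_index_start=k,
            )
            for k in range(3)
        ]
        merged = parts[0].counts + parts[1].counts + parts[2].counts
        assert merged == whole.counts

    def test_mismatch_annotation_forces_coupled_mode(self, straight_table):
        seq = DNASequence("mm", "ACGTACGTACGT", frozenset({6}))
        est = estimate_jfactor(seq, straight_table, n_chains=1_000, seed=1)
        assert est.mode == "cso_epbd"

    def test_profile_length_checked(self, seq63, straight_table):
        with pytest.raises(ValueError, match="length"):
            estimate_jfactor(
                seq63, straight_table,
                profile=OpeningProfile(np.zeros(10)), n_chains=100,
            )


class TestFreeEnergyEquivalent:
    def test_fully_open_profile_costs_nothing(self):
        g, mean, n_inf = free_energy_equivalent(OpeningProfile(np.ones(5)))
        assert np.all(g == 0.0) and mean == 0.0 and n_inf == 0

    def test_logarithm_identity(self):
        prof = OpeningProfile(np.array([np.exp(-10.0)]))
        g, mean, _ = free_energy_equivalent(prof)
        assert g[0] == pytest.approx(10.0) and mean == pytest.approx(10.0)

    def test_zero_probability_sites_excluded(self):
        prof = OpeningProfile(np.array([0.0, np.exp(-2.0), 1.0]))
        g, mean, n_inf = free_energy_equivalent(prof)
        assert np.isinf(g[0]) and n_inf == 1
        assert mean == pytest.approx(1.0)  # mean of {2, 0}


def test_shimada_yamakawa_peak_location_and_scale():
    # the closed form peaks near nu ~ 3.4 persistence lengths and its peak
    # value for lp = 140 bp sits in the 1e-8..1e-7 mol/L decade
    lp = 140.0
    grid = np.arange(200, 1200, 10)
    j = np.array([shimada_yamakawa_j(n, lp) for n in grid])
    n_peak = grid[np.argmax(j)]
    assert 2.8 < n_peak / lp < 4.0
    assert 1e-8 < j.max() < 1e-6
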