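"""Association statistics: oracles, worked examples, invariants, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizstate import (
    AssociationResult,
    circ_linear_rank_corr,
    duration_phase_test,
    duration_vs_time,
    fdr_correct,
    occurrence_vs_time,
    plv,
    plv_occurrence_test,
)


def brute_force_auc(x, y):
    """P(X > Y) + 0.5 P(X = Y) by pair enumeration."""
    wins = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    return wins / (len(x) * len(y))


class TestOccurrenceVsTime:
    def test_perfect_separation(self):
        auc, _ = occurrence_vs_time([4, 5, 6], [1, 2, 3])
        assert auc == 1.0

    def test_identical_groups(self):
        auc, p = occurrence_vs_time([1, 2, 3], [1, 2, 3])
        assert auc == 0.5

    def test_interleaved_hand_example(self):
        # pairs (1,2)(1,4)(3,2)(3,4): one win of four
        auc, _ = occurrence_vs_time([1, 3], [2, 4])
        assert auc == 0.25

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            occurrence_vs_time([], [1, 2])

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_auc_equals_pair_enumeration(self, data):
        x = data.draw(st.lists(st.integers(0, 20), min_size=1, max_size=15))
        y = data.draw(st.lists(st.integers(0, 20), min_size=1, max_size=15))
        auc, _ = occurrence_vs_time(x, y)
        assert auc == pytest.approx(brute_force_auc(x, y), abs=1e-12)


class TestDurationVsTime:
    def test_monotone_increasing(self):
        rho, _ = duration_vs_time([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = duration_vs_time([5, 4, 3, 2, 1], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # durations {3,1,2} vs times {1,2,3}: Spearman rho = -0.5
        rho = np.corrcoef([3, 1, 2], [1, 2, 3])[0, 1]  # ranks equal the values
        assert rho == pytest.approx(-0.5)
        from scipy.stats import spearmanr

        assert spearmanr([3, 1, 2], [1, 2, 3]).statistic == pytest.approx(-0.5)

    def test_constant_durations_flagged(self):
        with pytest.raises(ValueError):
            duration_vs_time([2, 2, 2, 2, 2], [1, 2, 3, 4, 5])


class TestPLV:
    def test_equal_phases(self):
        r = plv([0.3] * 7)
        assert r.R == pytest.approx(1.0)
        assert r.psi == pytest.approx(0.3)

    def test_antipodal_cancellation(self):
        assert plv([0.0, np.pi]).R == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        r = plv([0.0, np.pi / 2])
        assert r.R == pytest.approx(np.sqrt(2) / 2)
        assert r.psi == pytest.approx(np.pi / 4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            plv([])

    def test_matches_complex_mean_oracle(self, rng):
        for _ in range(200):
            phi = rng.uniform(-np.pi, np.pi, rng.integers(1, 40))
            z = np.mean(np.exp(-1j * phi))
            r = plv(phi)
            assert abs(r.R - abs(z)) < 1e-12
            assert np.angle(np.exp(1j * (r.psi + np.angle(z)))) == pytest.approx(0, abs=1e-12)

    @given(
        st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=30),
        st.floats(-np.pi, np.pi),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rotation_invariance(self, phases, c):
        a, b = plv(phases), plv(np.asarray(phases) + c)
        assert b.R == pytest.approx(a.R, abs=1e-9)


class TestPLVPermutationTest:
    def test_full_subset_gives_unit_pvalue(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 30)
        r_obs, d_r, p = plv_occurrence_test(phi, phi, n_perm=200, seed=0)
        assert d_r == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_addone_rule_floor(self, rng):
        # strongly locked subset of a uniform sample: p hits the add-one floor
        phi_all = rng.uniform(-np.pi, np.pi, 300)
        phi_with = rng.vonmises(0.0, 50.0, 60)
        phi_all[:60] = phi_with
        _, _, p = plv_occurrence_test(phi_with, phi_all, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_subset_larger_than_population_rejected(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 10)
        with pytest.raises(ValueError):
            plv_occurrence_test(phi, phi[:5])

    def test_too_few_seizures_rejected(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 10)
        with pytest.raises(ValueError):
            plv_occurrence_test(phi[:2], phi)


class TestCircularLinearD:
    def test_strong_coupling(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 200)
        D = circ_linear_rank_corr(np.cos(phi), phi)
        assert D >= 0.9

    def test_independent_small(self, rng):
        hits = 0
        for _ in range(100):
            phi = rng.uniform(-np.pi, np.pi, 200)
            d = rng.lognormal(2.7, 0.5, 200)
            hits += circ_linear_rank_corr(d, phi) < 0.05
        assert hits >= 95

    def test_duplicated_dataset_invariance(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 50)
        d = rng.lognormal(2.7, 0.5, 50)
        D1 = circ_linear_rank_corr(d, phi)
        D2 = circ_linear_rank_corr(np.tile(d, 2), np.tile(phi, 2))
        assert D2 == pytest.approx(D1, abs=1e-12)

    def test_constant_durations_flagged(self, rng):
        with pytest.raises(ValueError):
            circ_linear_rank_corr(np.ones(20), rng.uniform(-np.pi, np.pi, 20))

    def test_zero_permutations_rejected(self, rng):
        phi = rng.uniform(-np.pi, np.pi, 20)
        with pytest.raises(ValueError):
            duration_phase_test(rng.random(20), phi, n_perm=0)

    def test_shuffle_null_matches_loop_oracle(self, rng):
        """Vectorised shuffle distribution agrees with a per-shuffle loop."""
        phi = rng.uniform(-np.pi, np.pi, 40)
        d = rng.lognormal(2.7, 0.5, 40)
        D_obs, p_vec = duration_phase_test(d, phi, n_perm=500, seed=9)
        loop_rng = np.random.default_rng(7)
        null = [
            circ_linear_rank_corr(loop_rng.permutation(d), phi) for _ in range(500)
        ]
        p_loop = (np.sum(np.asarray(null) >= D_obs) + 1) / 501
        assert abs(p_vec - p_loop) < 0.08  # same null distribution, different draws


def independent_bh(pvals, alpha):
    """Reference BH step-up, written directly from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        reject[order[: kmax + 1]] = True
    return reject


def _results(pvals):
    return [
        AssociationResult("p", i, "occurrence", "t", "AUC", 0.5, None, p, "rank-sum")
        for i, p in enumerate(pvals)
    ]


class TestFDR:
    def test_hand_worked_example(self):
        out = fdr_correct(_results([0.01, 0.02, 0.03, 0.04]), alpha=0.05)
        assert all(r.fdr_significant for r in out)

    def test_single_raw_threshold(self):
        out = fdr_correct(_results([0.049]))
        assert out[0].fdr_significant

    def test_all_ones_none_significant(self):
        out = fdr_correct(_results([1.0, 1.0, 1.0]))
        assert not any(r.fdr_significant for r in out)

    def test_excluded_results_left_out_of_family(self):
        res = _results([0.01, 0.5])
        res[1].excluded = True
        out = fdr_correct(res)
        assert out[0].fdr_significant and out[1].p_adj is None

    def test_matches_independent_step_up(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            got = np.array(
                [r.fdr_significant for r in fdr_correct(_results(p), alpha=0.05)]
            )
            assert np.array_equal(got, independent_bh(p, 0.05))
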