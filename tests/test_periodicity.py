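import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal, stats

from netosc.errors import InputError, InsufficientDataError
from netosc.periodicity import (ALGORITHMS, ConsensusSet, autocorr_score, bh_fdr,
                                call_periodic, consensus_from_sets,
                                estimate_period_phase, periodicity_statistics,
                                periodogram_power, permutation_indices,
                                permutation_pvalue, template_rank_score)
from netosc.synthgen import (ExperimentDesign, SynchronyModel,
                             constitutive_gene_models, periodic_gene_models,
                             simulate_experiment)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Brute-force step-up definition: q(i) = min_{j: p_j >= p_i ranked} p_(j)*m/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos in range(m):
        i = order[rank_pos]
        q[i] = min(min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0)
    return q


def exact_perm_pvalue(statistic, series, times):
    """Full enumeration over all orderings of the series."""
    series = np.asarray(series, float)
    obs = statistic(series, times)
    perms = list(itertools.permutations(range(series.size)))
    count = sum(statistic(series[list(p)], times) >= obs for p in perms)
    return count / len(perms), len(perms)


# ---------------------------------------------------------------------------
# periodogram
# ---------------------------------------------------------------------------

class TestPeriodogram:
    times = np.arange(0.0, 301.0, 20.0)

    def test_pure_cosine_peaks_at_true_period(self):
        grid = np.arange(40.0, 241.0, 10.0)
        y = np.cos(2 * np.pi * self.times / 60.0)
        power = periodogram_power(y, self.times, grid)
        assert grid[np.argmax(power)] == 60.0

    def test_constant_series_zero_power(self):
        grid = np.arange(40.0, 241.0, 10.0)
        power = periodogram_power(np.full(self.times.shape, 3.0), self.times, grid)
        assert np.all(power <= 1e-10)

    def test_time_reversal_symmetry(self):
        grid = np.arange(40.0, 241.0, 10.0)
        rng = np.random.default_rng(0)
        y = np.cos(2 * np.pi * self.times / 70.0) + 0.2 * rng.normal(size=self.times.size)
        p1 = periodogram_power(y, self.times, grid)
        p2 = periodogram_power(y[::-1], self.times, grid)
        assert np.allclose(p1, p2, atol=1e-9)

    def test_matches_scipy_lombscargle(self):
        # independent route: scipy's implementation, same normalization
        rng = np.random.default_rng(1)
        times = np.delete(self.times, [3, 7])  # uneven sampling
        y = np.cos(2 * np.pi * times / 80.0) + 0.3 * rng.normal(size=times.size)
        grid = np.arange(45.0, 200.0, 7.0)
        ours = periodogram_power(y, times, grid)
        yc = y - y.mean()
        theirs = signal.lombscargle(times, yc, 2 * np.pi / grid, normalize=True)
        assert np.allclose(ours, theirs, rtol=1e-8, atol=1e-10)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            periodogram_power([1, 2, 3], [0, 1, 2], [2.0])

    def test_grid_outside_range_rejected(self):
        with pytest.raises(InputError):
            periodogram_power(np.ones(16), self.times, [10.0])


class TestAutocorr:
    def test_exact_period_lag_gives_one(self):
        y = np.tile([1.0, 5.0, 2.0, 0.5], 4)
        assert autocorr_score(y, 4) == pytest.approx(1.0)

    def test_antiphase_gives_minus_one(self):
        t = np.arange(16.0)
        y = np.cos(2 * np.pi * t / 8.0)
        assert autocorr_score(y, 4) == pytest.approx(-1.0)

    def test_white_noise_scores_center_on_zero(self):
        rng = np.random.default_rng(3)
        scores = [autocorr_score(rng.normal(size=16), 4) for _ in range(300)]
        scores = np.asarray(scores)
        assert np.all(np.abs(scores) < 1.0)
        assert abs(np.mean(scores)) < 0.1

    def test_zero_variance_segment_is_zero(self):
        y = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 3.0])
        assert autocorr_score(y, 2) == 0.0

    def test_bad_lag_rejected(self):
        with pytest.raises(InputError):
            autocorr_score(np.ones(5), 5)


class TestTemplateRank:
    times = np.arange(0.0, 301.0, 20.0)

    def test_sampled_template_scores_one(self):
        y = np.cos(2 * np.pi * (self.times / 100.0 - 0.25))
        phase_grid = np.arange(8) / 8.0
        assert template_rank_score(y, self.times, 100.0, phase_grid) == pytest.approx(1.0)

    def test_negated_template_matches_antiphase(self):
        # period 137 is incommensurate with the sampling, so all template
        # values are distinct and rank comparisons are exact
        y = -np.cos(2 * np.pi * self.times / 137.0)
        phase_grid = np.arange(8) / 8.0  # contains 0.5, the antiphase
        assert template_rank_score(y, self.times, 137.0, phase_grid) == pytest.approx(1.0)

    def test_kendall_tau_three_pair_enumeration(self):
        # [1,3,2] vs [1,2,3]: pairs (1,3)+(1,2) concordant, (3,2) discordant
        tau = stats.kendalltau([1, 3, 2], [1, 2, 3]).statistic
        assert tau == pytest.approx(1.0 / 3.0)

    def test_monotone_distortion_invariance(self):
        y = np.cos(2 * np.pi * self.times / 140.0)
        s1 = template_rank_score(y, self.times, 140.0)
        s2 = template_rank_score(np.exp(3.0 * y), self.times, 140.0)
        assert s1 == pytest.approx(s2)

    def test_batch_tau_matches_scipy(self):
        # the fast consensus path computes tau-b from sign matrices; check it
        # against scipy's kendalltau on random data
        from netosc.periodicity import _ScoringContext
        rng = np.random.default_rng(5)
        grid = np.array([60.0, 100.0])
        ctx = _ScoringContext(self.times, grid, n_phases=4)
        for _ in range(10):
            y = rng.normal(size=self.times.size)
            fast = ctx.template(y[None, :])[0]
            slow = max(stats.kendalltau(y, tmpl).statistic for tmpl in ctx.templates)
            assert fast == pytest.approx(slow, abs=1e-5)  # tie-break term is 1e-6


# ---------------------------------------------------------------------------
# permutation p-values
# ---------------------------------------------------------------------------

class TestPermutationPvalue:
    times = np.arange(0.0, 181.0, 20.0)  # 10 points

    def test_constant_series_p_one(self):
        stat = lambda s, t: float(np.ptp(s[:3]))
        p = permutation_pvalue(stat, np.full(10, 2.0), self.times, n_perm=99, seed=0)
        assert p == 1.0

    def test_matches_full_enumeration_on_five_points(self):
        series = np.array([0.3, 1.7, 0.9, 2.5, 0.1])
        times = np.arange(5.0)
        stat = lambda s, t: float(s[0] - s[-1])
        frac, n = exact_perm_pvalue(stat, series, times)
        perms = np.array(list(itertools.permutations(range(5))))
        p = permutation_pvalue(stat, series, times, permutations=perms)
        assert n == 120
        # add-one on both sides: identity permutation is included in perms
        assert p == pytest.approx((1 + frac * n) / (n + 1))

    def test_pvalue_floor(self):
        stat = lambda s, t: float(np.corrcoef(s, np.cos(t / 30.0))[0, 1])
        rng = np.random.default_rng(2)
        y = np.cos(self.times / 30.0)
        p = permutation_pvalue(stat, y, self.times, n_perm=99, seed=1)
        assert p >= 1.0 / 100.0
        assert p == pytest.approx(1.0 / 100.0)

    def test_deterministic_given_seed(self):
        stat = lambda s, t: float(s @ np.sin(t))
        y = np.random.default_rng(0).normal(size=10)
        p1 = permutation_pvalue(stat, y, self.times, n_perm=199, seed=5)
        p2 = permutation_pvalue(stat, y, self.times, n_perm=199, seed=5)
        assert p1 == p2


class TestBH:
    def test_equal_spacing_collapses_to_max(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(InputError):
            bh_fdr([1.5])

    @given(st.lists(st.integers(1, 20).map(lambda i: i * 0.05),
                    min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle(self, p):
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=2, max_size=8),
           st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, p, rnd):
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        q = bh_fdr(p)
        q_shuffled = bh_fdr([p[i] for i in idx])
        assert np.allclose([q[i] for i in idx], q_shuffled, atol=1e-12)


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

class TestConsensus:
    def test_set_intersection_example(self):
        per_alg = {"a": {"A", "B", "C"}, "b": {"B", "C"}, "c": {"C"}}
        cons = consensus_from_sets(per_alg, alpha=0.05)
        assert cons.gene_ids == {"C"}

    def test_removing_algorithm_never_shrinks(self):
        per_alg = {"a": {"A", "B", "C"}, "b": {"B", "C"}, "c": {"C"}}
        full = consensus_from_sets(per_alg, 0.05).gene_ids
        for drop in per_alg:
            reduced = {k: v for k, v in per_alg.items() if k != drop}
            assert full <= consensus_from_sets(reduced, 0.05).gene_ids

    def test_invariant_enforced_by_type(self):
        with pytest.raises(InputError):
            ConsensusSet(gene_ids={"A"}, per_algorithm={"a": {"B"}}, alpha=0.05)

    def test_consensus_subset_of_each_algorithm(self, small_matrix):
        calls, cons = call_periodic(small_matrix, n_perm=199, seed=0)
        for genes in cons.per_algorithm.values():
            assert cons.gene_ids <= genes

    def test_fast_path_matches_generic_permutation_pvalue(self, sync_default):
        # dual route: the vectorized per-gene p-values must equal the generic
        # permutation_pvalue applied to the shared scoring callables with the
        # same permutations
        models = periodic_gene_models(2, seed=8) + constitutive_gene_models(2, seed=9)
        design = ExperimentDesign(condition="WT", dt=20.0, total_time=360.0,
                                  noise_cv=0.1, seed=3)
        mat = simulate_experiment(models, sync_default, design)
        n_perm, seed = 99, 11
        calls, _ = call_periodic(mat, alpha=0.05, n_perm=n_perm, seed=seed)
        grid = None
        from netosc.periodicity import DEFAULT_PERIOD_GRID
        dt = 20.0
        span = mat.times[-1] - mat.times[0]
        grid = DEFAULT_PERIOD_GRID[(DEFAULT_PERIOD_GRID >= 2 * dt)
                                   & (DEFAULT_PERIOD_GRID <= span)]
        scorers = periodicity_statistics(mat.times, grid)
        by_key = {(c.gene_id, c.algorithm): c for c in calls}
        for gi, gene in enumerate(mat.gene_ids):
            perms = permutation_indices(mat.times.size, n_perm, [seed, gi])
            for alg, fn in scorers.items():
                expected = permutation_pvalue(fn, mat.values[gi], mat.times,
                                              permutations=perms)
                assert by_key[(gene, alg)].p_value == pytest.approx(expected)

    def test_detection_on_mixed_panel(self, sync_default):
        # known ground truth: periodic vs flat genes
        n_per, n_flat = 100, 400
        models = periodic_gene_models(n_per, seed=1) + constitutive_gene_models(
            n_flat, seed=2)
        design = ExperimentDesign(condition="WT", dt=20.0, total_time=360.0,
                                  noise_cv=0.1, seed=4)
        mat = simulate_experiment(models, sync_default, design)
        _, cons = call_periodic(mat, alpha=0.05, n_perm=999, seed=0)
        truth = {m.gene_id for m in models[:n_per]}
        called = cons.gene_ids
        fdp = len(called - truth) / max(len(called), 1)
        sensitivity = len(called & truth) / n_per
        assert fdp <= 0.10
        assert sensitivity >= 0.80

    def test_alpha_zero_empty_consensus(self, small_matrix):
        _, cons = call_periodic(small_matrix, alpha=0.0, n_perm=99, seed=0)
        assert cons.gene_ids == set()


# ---------------------------------------------------------------------------
# period / phase estimation
# ---------------------------------------------------------------------------

class TestEstimatePeriodPhase:
    times = np.arange(0.0, 361.0, 20.0)

    def test_offgrid_period_recovered_within_5min(self):
        y = 2.0 + np.cos(2 * np.pi * self.times / 70.0)
        est = estimate_period_phase(y, self.times)
        assert abs(est.period - 70.0) <= 5.0

    def test_exact_grid_node_recovery(self):
        y = 1.0 + np.cos(2 * np.pi * self.times / 90.0)
        est = estimate_period_phase(y, self.times)
        assert est.period == pytest.approx(90.0, abs=1.0)
        assert not est.boundary

    def test_identical_series_identical_estimates(self):
        rng = np.random.default_rng(6)
        y = 2.0 + np.cos(2 * np.pi * self.times / 100.0) + 0.1 * rng.normal(
            size=self.times.size)
        e1 = estimate_period_phase(y, self.times)
        e2 = estimate_period_phase(y.copy(), self.times)
        assert (e1.period, e1.peak_time, e1.power) == (e2.period, e2.peak_time,
                                                       e2.power)

    def test_peak_time_matches_cosine_phase(self):
        y = 1.0 + np.cos(2 * np.pi * (self.times - 30.0) / 100.0)
        est = estimate_period_phase(y, self.times)
        assert est.peak_time == pytest.approx(30.0, abs=2.0)
        assert 0.0 <= est.peak_time < est.period

    def test_boundary_flag(self):
        y = np.cos(2 * np.pi * self.times / 240.0)
        est = estimate_period_phase(y, self.times,
                                    period_grid=np.array([40.0, 50.0, 60.0]))
        assert est.boundary
        assert est.period in (40.0, 60.0)
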