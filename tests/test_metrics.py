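"""Allocation, transition, visit, null-model, and time-course analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_log
from patchforage.agents import AgentSpec, SessionConfig, run_session
from patchforage.metrics import (
    QUALITY_RANK,
    continuous_push_rate,
    ipi_distribution,
    normalize_metric,
    null_model,
    perblock_spearman,
    push_fraction,
    quality_rank_spearman,
    return_times,
    segment_visits,
    stay_times,
    timeresolved_spearman,
    transition_matrix,
    windowed_push_fraction,
)
from patchforage.schedules import PatchId, Variant

F, M, S = PatchId.FAST, PatchId.MED, PatchId.SLOW


class TestPushFraction:
    def test_direct_count(self):
        log = make_log([1, 2, 3, 4], ["fast", "fast", "med", "slow"])
        fr = push_fraction(log)
        assert (fr[F], fr[M], fr[S]) == (0.5, 0.25, 0.25)

    def test_single_patch_boundary(self):
        fr = push_fraction(make_log([1, 2], ["fast", "fast"]))
        assert (fr[F], fr[M], fr[S]) == (1.0, 0.0, 0.0)

    def test_fractions_sum_to_one_and_ignore_order(self):
        a = push_fraction(make_log([1, 2, 3], ["fast", "med", "slow"]))
        b = push_fraction(make_log([1, 2, 3], ["slow", "fast", "med"]))
        assert a == b
        assert sum(a.values()) == pytest.approx(1.0)

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            push_fraction(make_log([], []))


class TestQualityRankSpearman:
    def test_perfectly_ordered_blocks_hit_tie_ceiling(self):
        blocks = [{F: 0.5 + 0.01 * b, M: 0.3, S: 0.2 - 0.01 * b} for b in range(5)]
        res = quality_rank_spearman(blocks)
        # repeated ranks cap rho below 1; ordering is otherwise perfect
        assert res.rho > 0.9
        assert res.n == 15

    def test_rank_independent_fractions_give_null_rho(self, rng):
        blocks = []
        for _ in range(10_000):
            f = rng.dirichlet([1, 1, 1])
            blocks.append({F: f[0], M: f[1], S: f[2]})
        res = quality_rank_spearman(blocks)
        assert abs(res.rho) < 0.03

    def test_observation_count_three_per_block(self):
        blocks = [{F: 0.5, M: 0.3, S: 0.2}] * 199
        assert quality_rank_spearman(blocks).n == 597

    def test_constant_fractions_flagged(self):
        res = quality_rank_spearman([{F: 1 / 3, M: 1 / 3, S: 1 / 3}] * 4)
        assert np.isnan(res.rho)

    def test_perblock_exact_permutation_p(self):
        rho, p = perblock_spearman({F: 0.6, M: 0.3, S: 0.1})
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 3)  # identity and reversal of 6 orderings


class TestIPI:
    def test_successive_differences_and_median(self):
        log = make_log([1, 2, 4], ["fast", "fast", "fast"])
        res = ipi_distribution(log, F)
        np.testing.assert_array_equal(res.intervals, [1, 2])
        assert res.median == 1.5

    def test_intervening_other_patch_does_not_break_pairs(self):
        log = make_log([1, 2, 4], ["fast", "med", "fast"])
        np.testing.assert_array_equal(ipi_distribution(log, F).intervals, [3])
        ipi_global = ipi_distribution(log, per_patch=False)
        np.testing.assert_array_equal(ipi_global.intervals, [1, 2])

    def test_single_push_empty(self):
        res = ipi_distribution(make_log([1], ["fast"]), F)
        assert res.intervals.size == 0
        assert np.isnan(res.median)


class TestTransitions:
    def test_hand_counted_five_push_example(self):
        log = make_log([1, 2, 3, 4, 5], ["fast", "fast", "med", "fast", "slow"])
        tm = transition_matrix(log)
        np.testing.assert_allclose(tm.probs[0], [1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(tm.probs[1], [1, 0, 0])
        assert tm.counts.sum() == 4
        # only one transition out of med/slow, and it goes to fast
        assert tm.p_to_fast_given_not_fast == 1.0

    def test_deterministic_alternation(self):
        log = make_log(range(1, 7), ["fast", "med"] * 3)
        tm = transition_matrix(log)
        assert tm.prob(F, M) == 1.0
        assert tm.prob(M, F) == 1.0

    def test_uniform_labels_give_uniform_rows(self, rng):
        n = 100_000
        labels = np.array(["fast", "med", "slow"])[rng.integers(0, 3, n)]
        log = make_log(np.arange(n, dtype=float), labels)
        tm = transition_matrix(log)
        se = 3 * np.sqrt((1 / 3) * (2 / 3) / (n / 3))
        np.testing.assert_allclose(tm.probs, 1 / 3, atol=se)

    def test_rows_sum_to_one_where_defined(self):
        log = make_log([1, 2, 3], ["fast", "med", "fast"])
        tm = transition_matrix(log)
        sums = np.nansum(tm.probs, axis=1)
        assert sums[0] == pytest.approx(1.0)


class TestVisits:
    def test_maximal_runs_including_ends(self):
        log = make_log([1, 3, 5, 6, 9], ["fast", "fast", "med", "med", "fast"])
        v = segment_visits(log)
        assert [(x.patch, x.t_first, x.t_last, x.n_pushes) for x in v] == [
            (F, 1, 3, 2),
            (M, 5, 6, 2),
            (F, 9, 9, 1),
        ]

    def test_single_push_zero_length_visit(self):
        v = segment_visits(make_log([2], ["med"]))
        assert len(v) == 1 and v[0].t_first == v[0].t_last

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["fast", "med", "slow"]), min_size=1, max_size=15),
           st.lists(st.sampled_from(["fast", "med", "slow"]), min_size=1, max_size=15))
    def test_concatenation_locality(self, a, b):
        if a[-1] == b[0]:
            b = b[:]
            b[0] = {"fast": "med", "med": "slow", "slow": "fast"}[b[0]]
        ta = list(map(float, range(1, len(a) + 1)))
        tb = [len(a) + 1.0 + i for i in range(len(b))]
        whole = segment_visits(make_log(ta + tb, a + b))
        parts = segment_visits(make_log(ta, a)) + segment_visits(make_log(tb, b))
        assert whole == parts

    def test_stay_times_formula_and_zero_retention(self):
        log = make_log([10, 12, 15, 20], ["fast", "fast", "fast", "med"])
        st_ = stay_times(segment_visits(log))
        np.testing.assert_array_equal(st_[F], [5.0])
        np.testing.assert_array_equal(st_[M], [0.0])

    def test_return_time_gap(self):
        log = make_log([10, 15, 40, 41], ["fast", "fast", "fast", "med"])
        # one visit only: no return
        assert return_times(segment_visits(log))[F].size == 0
        log2 = make_log([10, 15, 20, 40], ["fast", "fast", "med", "fast"])
        np.testing.assert_array_equal(return_times(segment_visits(log2))[F], [25.0])

    def test_alternating_visits_one_return_each(self):
        log = make_log([1, 2, 3, 4], ["fast", "med", "fast", "med"])
        rt = return_times(segment_visits(log))
        assert rt[F].size == 1 and rt[M].size == 1
        assert all(np.all(v > 0) for v in rt.values() if v.size)


class TestNullModel:
    def test_surrogate_duration_and_labels(self, rng):
        log = make_log(np.arange(0, 200, 2.0), ["fast", "med", "slow", "fast"] * 25)
        null = null_model(log, 200, rng)
        total_visits = sum(null.stay_n.values())
        # uniform labels: roughly equal visit counts per patch
        counts = np.array([null.stay_n[p] for p in PatchId])
        assert counts.min() > 0.8 * counts.mean()
        assert total_visits > 0

    def test_bad_rep_count_rejected(self, rng):
        log = make_log([1, 2], ["fast", "med"])
        with pytest.raises(ValueError):
            null_model(log, 0, rng)

    def test_normalization_identity_and_division(self):
        real = {F: 10.0, M: 5.0, S: 1.0}
        null = {F: 5.0, M: 5.0, S: 2.0}
        out = normalize_metric(real, null)
        assert (out[F], out[M], out[S]) == (2.0, 1.0, 0.5)

    def test_time_rescaling_invariance(self):
        times = np.cumsum(np.random.default_rng(3).exponential(2.0, 120))
        labels = np.array(["fast", "med", "slow"])[
            np.random.default_rng(4).integers(0, 3, 120)
        ]
        ratios = []
        for c in (1.0, 10.0):
            log = make_log(times * c, labels)
            st_ = stay_times(segment_visits(log))
            null = null_model(log, 300, np.random.default_rng(99))
            real = {p: float(np.mean(st_[p])) for p in PatchId}
            ratios.append(normalize_metric(real, null.mean_stay))
        for p in PatchId:
            assert ratios[0][p] == pytest.approx(ratios[1][p], rel=1e-9)


class TestContinuousPushRate:
    def test_piecewise_rates_from_hand_example(self):
        log = make_log([0.0, 2.0, 2.5], ["fast", "fast", "fast"])
        grid, series = continuous_push_rate(log, window=1e-9, grid_step=0.25)
        mean_rate = 2 / 2.5
        # r = 0.5 on [0,2), 2.0 on [2,2.5)
        assert series[0] == pytest.approx(0.5 / mean_rate)
        assert series[np.searchsorted(grid, 2.0)] == pytest.approx(2.0 / mean_rate)

    def test_periodic_pushes_normalize_to_unity(self):
        log = make_log(np.arange(0, 100, 2.0), ["fast"] * 50)
        _, series = continuous_push_rate(log, window=10.0)
        np.testing.assert_allclose(series, 1.0)

    def test_duplicate_timestamps_clipped_with_warning(self):
        log = make_log([0.0, 1.0, 2.0], ["fast", "fast", "fast"])
        log.events.loc[1, "t_s"] = 0.0  # force duplicate after validation
        with pytest.warns(UserWarning):
            continuous_push_rate(log)


class TestTimeCourses:
    def test_single_patch_fraction_is_one(self):
        log = make_log(np.arange(0, 300, 5.0), ["fast"] * 60)
        tc = windowed_push_fraction([log], window=60, step=10)
        np.testing.assert_allclose(tc.mean[:, 0], 1.0)
        np.testing.assert_allclose(np.nansum(tc.mean, axis=1), 1.0)

    def test_stationary_random_agent_near_uniform(self):
        logs = [
            run_session(
                SessionConfig(variant=Variant.EXPONENTIAL, kappa=1.0, seed=70 + b),
                AgentSpec("random"),
            )
            for b in range(12)
        ]
        tc = windowed_push_fraction(logs, window=120, step=30)
        assert np.nanmax(np.abs(tc.mean - 1 / 3)) < 0.12
        rho = timeresolved_spearman(logs, window=120, step=30)
        assert abs(np.nanmean(rho.mean)) < 0.25

    def test_perfectly_ordered_blocks_give_unit_course(self):
        logs = []
        for b in range(3):
            times = np.arange(0, 300, 1.0)
            labels = (["fast"] * 3 + ["med"] * 2 + ["slow"]) * 50
            logs.append(make_log(times, labels[: len(times)]))
        tc = timeresolved_spearman(logs, window=60, step=20)
        np.testing.assert_allclose(tc.mean, 1.0)

    def test_quality_ranks(self):
        assert (QUALITY_RANK[S], QUALITY_RANK[M], QUALITY_RANK[F]) == (1, 2, 3)
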