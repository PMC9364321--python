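"""Benchmark machinery: regression metrics, thresholds, enrichment factors,
de novo objectives, the budget ledger and trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockbench import benchmarks as bm
from dockbench import docking as dk
from dockbench import fixtures as fx
from dockbench.models import OracleRanker, RandomRanker


class TestRegressionMetrics:
    def test_perfect_fit(self):
        m = bm.regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r2 == 1.0 and m.mse == 0.0 and m.mae == 0.0

    def test_constant_mean_prediction_r2_zero(self):
        y = [1.0, 2.0, 3.0]
        m = bm.regression_metrics(y, [2.0, 2.0, 2.0])
        assert m.r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        m = bm.regression_metrics([0, 1, 2], [0, 1, 1])
        assert m.mse == pytest.approx(1 / 3)
        assert m.mae == pytest.approx(1 / 3)
        assert m.r2 == pytest.approx(0.5)

    def test_zero_variance_reported(self):
        m = bm.regression_metrics([2.0, 2.0], [1.0, 3.0])
        assert m.r2 is None and m.mse == 1.0


class TestScoreThreshold:
    def test_first_order_statistic_of_1000(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=1000)
        assert bm.score_threshold(scores, 0.1) == np.sort(scores)[0]

    def test_all_equal(self):
        assert bm.score_threshold([3.3] * 17) == 3.3

    @pytest.mark.parametrize("percentile", [0.1, 1.0, 10.0, 50.0])
    def test_against_sort_oracle(self, percentile):
        rng = np.random.default_rng(7)
        for n in (10, 137, 1000):
            scores = rng.normal(size=n)
            expected = np.sort(scores)[max(1, math.ceil(percentile / 100 * n)) - 1]
            assert bm.score_threshold(scores, percentile) == expected

    def test_published_constants_served_from_config(self):
        assert bm.SCREENING_THRESHOLDS == {"KIT": -10.7, "PARP1": -12.1, "PGR": -10.1}


class TestEnrichmentFactor:
    def test_maximum_possible(self):
        assert bm.enrichment_factor(5000, 5000, 1e-3) == pytest.approx(1000.0)

    def test_zero_actives(self):
        assert bm.enrichment_factor(5000, 0, 1e-3) == 0.0

    def test_ten_fold(self):
        assert bm.enrichment_factor(5000, 50, 1e-3) == pytest.approx(10.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=1, max_value=10000),
           st.integers(min_value=0, max_value=10000))
    def test_whole_library_ef_is_one(self, n, k):
        """Selecting the entire library gives EF exactly 1."""
        k = min(k, n)
        if k == 0:
            return
        assert bm.enrichment_factor(n, k, base_rate=k / n) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bm.enrichment_factor(0, 0, 0.5)
        with pytest.raises(ValueError):
            bm.enrichment_factor(10, 2, 0.0)


class TestQedPenalty:
    def test_extremes(self):
        assert bm.qed_penalty(0.0) == 10.0
        assert bm.qed_penalty(1.0) == 0.0

    @pytest.mark.parametrize("qed,expected", [(0.75, 2.5), (0.5, 5.0), (0.25, 7.5)])
    def test_linear_interior(self, qed, expected):
        assert bm.qed_penalty(qed) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bm.qed_penalty(1.2)


class TestObjectiveValue:
    def test_f2_zero_penalty(self):
        spec = bm.ObjectiveSpec(bm.ObjectiveKind.F2)
        assert bm.objective_value(spec, {"F2": -10.0}, 1.0) == -10.0

    def test_ppar_worst_of_three(self):
        spec = bm.ObjectiveSpec(bm.ObjectiveKind.PROMISCUOUS_PPAR)
        scores = {"PPARA": -10.0, "PPARD": -9.0, "PPARG": -8.0}
        assert bm.objective_value(spec, scores, 1.0) == -8.0

    def test_jak2_anchored_selectivity(self):
        spec = bm.ObjectiveSpec(bm.ObjectiveKind.SELECTIVE_JAK2)
        # LCK worse than the anchor: the anchor value -8.1 is used
        value = bm.objective_value(spec, {"JAK2": -10.0, "LCK": -7.0}, 1.0)
        assert value == pytest.approx(-10.0 - (-8.1))

    def test_jak2_off_target_penalized_below_anchor(self):
        spec = bm.ObjectiveSpec(bm.ObjectiveKind.SELECTIVE_JAK2)
        value = bm.objective_value(spec, {"JAK2": -10.0, "LCK": -9.0}, 1.0)
        assert value == pytest.approx(-10.0 - (-9.0))

    def test_missing_target_score(self):
        spec = bm.ObjectiveSpec(bm.ObjectiveKind.PROMISCUOUS_PPAR)
        with pytest.raises(KeyError):
            bm.objective_value(spec, {"PPARA": -9.0}, 1.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-13, -4), st.floats(-13, -4), st.floats(-13, -4),
           st.floats(0, 1), st.floats(0.01, 2.0))
    def test_monotone_in_scores(self, s1, s2, s3, qed, delta):
        """Improving any constituent docking score never worsens the task."""
        f2 = bm.ObjectiveSpec(bm.ObjectiveKind.F2)
        assert (bm.objective_value(f2, {"F2": s1 - delta}, qed)
                <= bm.objective_value(f2, {"F2": s1}, qed))
        ppar = bm.ObjectiveSpec(bm.ObjectiveKind.PROMISCUOUS_PPAR)
        base = {"PPARA": s1, "PPARD": s2, "PPARG": s3}
        better = dict(base, PPARA=s1 - delta)
        assert bm.objective_value(ppar, better, qed) <= bm.objective_value(ppar, base, qed)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-8.0, -4.0), st.floats(-8.0, -4.0))
    def test_anchor_flat_region(self, lck_a, lck_b):
        """LCK scores above the anchor (-8.1) are interchangeable."""
        spec = bm.ObjectiveSpec(bm.ObjectiveKind.SELECTIVE_JAK2)
        va = bm.objective_value(spec, {"JAK2": -10.0, "LCK": lck_a}, 0.8)
        vb = bm.objective_value(spec, {"JAK2": -10.0, "LCK": lck_b}, 0.8)
        assert va == pytest.approx(vb)

    def test_constants_match_config(self):
        spec = bm.ObjectiveSpec(bm.ObjectiveKind.SELECTIVE_JAK2)
        assert spec.lck_anchor == -8.1
        assert spec.penalty_weight == 10
        assert bm.DEFAULT_BUDGET == 5000
        assert spec.targets == ("JAK2", "LCK")
        assert bm.ObjectiveSpec(bm.ObjectiveKind.PROMISCUOUS_PPAR).targets == (
            "PPARA", "PPARD", "PPARG")


class TestLedger:
    def test_budget_enforced(self):
        ledger = bm.EvaluationLedger(budget=3)
        for i in range(3):
            ledger.record(f"M{i}", float(i))
        with pytest.raises(bm.BudgetExhausted):
            ledger.record("M99", 0.0)

    def test_cache_hits_are_free(self):
        ledger = bm.EvaluationLedger(budget=2)
        ledger.record("CCO", -5.0)
        for _ in range(10):
            assert ledger.record("CCO", 123.0) == -5.0
        assert ledger.unique_calls == 1
        assert len(ledger.calls) == 11

    def test_call_count_non_decreasing(self):
        ledger = bm.EvaluationLedger(budget=10)
        counts = []
        for i in range(5):
            ledger.record(f"M{i}", float(-i))
            counts.append(len(ledger.calls))
        assert counts == sorted(counts)

    def test_failed_preparation_consumes_budget_with_inf(self):
        ledger = bm.EvaluationLedger(budget=2)
        value = ledger.evaluate("CC.Cl", lambda s: (_ for _ in ()).throw(ValueError()))
        assert value == math.inf
        assert ledger.unique_calls == 1


class TestTrajectory:
    def _ledger(self, values):
        ledger = bm.EvaluationLedger(budget=len(values))
        for i, v in enumerate(values):
            ledger.record(f"M{i}", v)
        return ledger

    def test_running_minimum(self):
        traj = bm.trajectory(self._ledger([3.0, 1.0, 2.0, 0.5]), k=1)
        assert traj == [3.0, 1.0, 1.0, 0.5]

    def test_missing_before_k_observations(self):
        traj = bm.trajectory(self._ledger(list(map(float, range(24)))), k=25)
        assert all(v is None for v in traj)

    def test_hand_example_k2(self):
        assert bm.trajectory(self._ledger([3.0, 1.0, 2.0]), k=2) == [None, 3.0, 2.0]

    def test_matches_prefix_sort_oracle(self):
        rng = np.random.default_rng(3)
        values = list(rng.normal(size=200))
        ledger = self._ledger(values)
        for k in (1, 5, 25):
            traj = bm.trajectory(ledger, k=k)
            for i in range(len(values)):
                prefix = sorted(values[:i + 1])
                expected = prefix[k - 1] if len(prefix) >= k else None
                assert traj[i] == expected

    def test_k_ordering_and_monotonicity(self):
        rng = np.random.default_rng(8)
        ledger = self._ledger(list(rng.normal(size=100)))
        t1, t5 = bm.trajectory(ledger, 1), bm.trajectory(ledger, 5)
        for a, b in zip(t1, t5):
            if b is not None:
                assert b >= a
        finite = [v for v in t1 if v is not None]
        assert finite == sorted(finite, reverse=True)


@pytest.fixture(scope="module")
def screen_setup(library_2000):
    lib = library_2000[:1000]
    matrix, targets = fx.generate_mock_targets(
        [fx.MockTargetSpec("KIT", seed=4)], lib)
    scores = matrix.frame["KIT"].to_numpy()
    threshold = bm.score_threshold(scores, percentile=10.0)
    return lib, targets["KIT"], scores, threshold


class TestRunScreen:

    def test_oracle_ranker_achieves_maximum_ef(self, screen_setup):
        lib, target, scores, threshold = screen_setup
        backend = dk.MockBackend()
        result = bm.run_screen(OracleRanker(backend, target), lib, target, backend,
                               top_k=100, threshold=threshold, base_rate=0.1)
        n_active_total = int((scores < threshold).sum())
        best_possible = bm.enrichment_factor(100, min(100, n_active_total), 0.1)
        assert result.ef == pytest.approx(best_possible)

    def test_random_ranker_ef_near_one(self, screen_setup):
        lib, target, scores, threshold = screen_setup
        backend = dk.MockBackend()
        efs = [bm.run_screen(RandomRanker(seed=s), lib, target, backend,
                             top_k=200, threshold=threshold, base_rate=0.1).ef
               for s in range(20)]
        assert 0.8 <= float(np.mean(efs)) <= 1.2

    def test_top_k_exceeding_library_rejected(self, screen_setup):
        lib, target, _, threshold = screen_setup
        with pytest.raises(ValueError):
            bm.run_screen(RandomRanker(), lib, target, dk.MockBackend(),
                          top_k=len(lib) + 1, threshold=threshold)

    def test_prep_rejected_molecules_excluded(self, screen_setup):
        lib, target, _, threshold = screen_setup
        corrupted = list(lib[:50]) + ["CC.Cl", "[CH3]"]
        result = bm.run_screen(RandomRanker(seed=1), corrupted, target,
                               dk.MockBackend(), top_k=len(corrupted),
                               threshold=threshold, base_rate=0.1)
        assert result.n_selected == 50
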