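import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhr_ttp import evaluation as ev
from fhr_ttp.preprocess import WindowSegment


def _trace(probs, label=0, approach="A1", gated=None, rid="r"):
    probs = np.asarray(probs, float)
    return ev.PredictionTrace(
        record_id=rid,
        approach=approach,
        window_probs=probs,
        window_end_min=15.0 + 5.0 * np.arange(probs.size),
        true_label=label,
        gated=gated,
    )


def brute_force_search(traces, fpr_target, gradient=0.0, start=1.0, step=0.001):
    """Literal grid descent: reference for the closed-form calibration."""
    labels = np.array([t.true_label for t in traces])
    n_neg = (labels == 0).sum()
    b = start
    while b > -1e-9:
        sched = ev.ThresholdSchedule(fpr_target, b, gradient)
        fp = sum(
            ev.decide_record(t, sched)[0] for t in traces if t.true_label == 0
        )
        if fp / n_neg >= fpr_target:
            return b
        b -= step
    return None


class TestDecideRecord:
    def test_negative_when_no_window_crosses(self):
        sched = ev.ThresholdSchedule(0.1, 0.8)
        assert ev.decide_record(_trace([0.2, 0.5, 0.79]), sched) == (0, None)

    def test_ttp_is_end_of_first_positive_window(self):
        sched = ev.ThresholdSchedule(0.1, 0.5)
        d, ttp = ev.decide_record(_trace([0.1, 0.6, 0.9]), sched)
        assert d == 1 and ttp == 20.0  # second window ends at 20 min

    def test_gated_window_cannot_fire(self):
        sched = ev.ThresholdSchedule(0.1, 0.5)
        t = _trace([0.9, 0.2, 0.6], gated=[True, False, False])
        d, ttp = ev.decide_record(t, sched)
        assert d == 1 and ttp == 25.0  # third window, first was gated

    def test_a2_schedule_lowers_bar_for_later_windows(self):
        sched = ev.ThresholdSchedule(0.1, 0.9, gradient_per_window=-0.1)
        # effective thresholds 0.8, 0.7, 0.6 for windows 1..3
        d, ttp = ev.decide_record(_trace([0.75, 0.65, 0.65], approach="A2"), sched)
        assert d == 1 and ttp == 25.0

    def test_decision_monotone_in_threshold(self):
        t = _trace([0.3, 0.7, 0.5])
        fired = [
            ev.decide_record(t, ev.ThresholdSchedule(0.1, b))[0]
            for b in np.linspace(0.0, 1.0, 21)
        ]
        assert np.all(np.diff(fired) <= 0)  # once negative, stays negative


class TestSearchThreshold:
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(5, 40),
        gradient=st.sampled_from([0.0, -0.02, -0.05]),
        fpr=st.sampled_from([0.05, 0.1, 0.2, 0.5]),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_brute_force_grid_descent(self, seed, n, gradient, fpr):
        rng = np.random.default_rng(seed)
        traces = [
            _trace(
                rng.uniform(0, 1, rng.integers(1, 10)),
                label=int(rng.uniform() < 0.3),
                rid=f"r{i}",
            )
            for i in range(n)
        ]
        if not any(t.true_label == 0 for t in traces):
            traces[0].true_label = 0
        start = 1.5 if gradient else 1.0
        approach = "A2" if gradient else "A1"
        expected = brute_force_search(traces, fpr, gradient, start)
        sched = ev.search_threshold(traces, fpr, approach=approach, gradient=gradient)
        assert sched.base_threshold == pytest.approx(expected, abs=1e-12)

    def test_achieved_fpr_within_one_grid_step_of_target(self):
        rng = np.random.default_rng(1)
        traces = [
            _trace(rng.uniform(0, 1, 10), label=0, rid=f"n{i}") for i in range(50)
        ]
        for fpr in ev.FPR_TARGETS:
            sched = ev.search_threshold(traces, fpr)
            got = np.mean(
                [ev.decide_record(t, sched)[0] for t in traces]
            )
            assert got >= fpr  # descent stops at first crossing
            above = ev.ThresholdSchedule(fpr, sched.base_threshold + ev.GRID_STEP)
            got_above = np.mean([ev.decide_record(t, above)[0] for t in traces])
            assert got_above < fpr  # one step up would miss the target

    def test_zero_gradient_a2_equals_a1_with_same_start(self):
        rng = np.random.default_rng(2)
        traces = [
            _trace(rng.uniform(0, 1, 8), label=0, rid=f"n{i}") for i in range(30)
        ]
        s1 = ev.search_threshold(traces, 0.1, approach="A1")
        s2 = ev.search_threshold(
            traces, 0.1, approach="A2", gradient=0.0, search_start=1.0
        )
        assert s2.base_threshold == pytest.approx(s1.base_threshold)

    def test_all_gated_normals_is_calibration_error(self):
        traces = [
            _trace([0.9, 0.9], label=0, gated=[True, True], rid=f"n{i}")
            for i in range(10)
        ]
        with pytest.raises(ev.CalibrationError):
            ev.search_threshold(traces, 0.2)

    def test_no_normals_rejected(self):
        with pytest.raises(ValueError):
            ev.search_threshold([_trace([0.5], label=1)], 0.1)


class TestGradientFit:
    def test_exact_affine_recovered(self):
        w = np.arange(1, 11)
        rows = np.stack([0.9 - 0.03 * w, 0.8 - 0.05 * w])
        grads = ev.fit_threshold_gradients(rows, fprs=(0.05, 0.10))
        assert grads[0.05] == pytest.approx(-0.03)
        assert grads[0.10] == pytest.approx(-0.05)

    def test_noisy_fit_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        w = np.arange(1, 11)
        row = 1.0 - 0.04 * w + rng.normal(0, 0.01, 10)
        grads = ev.fit_threshold_gradients(row[None, :], fprs=(0.05,))
        ref = sm.OLS(row, sm.add_constant(w)).fit().params[1]
        assert grads[0.05] == pytest.approx(ref, abs=1e-10)

    def test_single_length_rejected(self):
        with pytest.raises(ValueError):
            ev.fit_threshold_gradients(np.array([[0.5]]))


class TestSignalLossGating:
    def _segs(self, losses):
        out = []
        for i, loss in enumerate(losses):
            n = 225
            samples = np.full(n, 140.0)
            samples[: int(round(n * loss / 100))] = 0.0
            out.append(
                WindowSegment(
                    parent_id="r", start_min=5.0 * i, end_min=15 + 5.0 * i,
                    samples=samples, window_index=i + 1, rate=0.25,
                )
            )
        return out

    def test_exceeding_threshold_gates_and_zeroes(self):
        segs = self._segs([0, 40, 80])
        t = ev.gate_by_signal_loss(_trace([0.9, 0.9, 0.9]), segs, 50.0)
        np.testing.assert_array_equal(t.gated, [False, False, True])
        np.testing.assert_array_equal(t.window_probs, [0.9, 0.9, 0.0])

    def test_loss_exactly_at_threshold_kept(self):
        segs = self._segs([20.0])
        t = ev.gate_by_signal_loss(_trace([0.7]), segs, 20.0)
        assert not t.gated[0]

    def test_fully_gated_record_always_negative(self):
        segs = self._segs([90, 95])
        t = ev.gate_by_signal_loss(_trace([1.0, 1.0], label=1), segs, 50.0)
        assert ev.decide_record(t, ev.ThresholdSchedule(0.1, 0.0))[0] == 0

    def test_training_filter_keeps_at_or_below(self):
        segs = self._segs([0, 20, 40])
        kept = ev.filter_training_by_signal_loss(segs, 20.0)
        assert [s.window_index for s in kept] == [1, 2]

    def test_misaligned_segments_rejected(self):
        with pytest.raises(ValueError):
            ev.gate_by_signal_loss(_trace([0.5, 0.5]), self._segs([10]), 50.0)


class TestPooledMetrics:
    def test_tpr_example(self):
        d = np.array([1, 0, 1, 1, 0, 0])
        y = np.array([1, 1, 1, 0, 0, 0])
        assert ev.pooled_tpr(d, y) == pytest.approx(2 / 3)
        assert ev.pooled_fpr(d, y) == pytest.approx(1 / 3)

    def test_mean_ttp_includes_false_positives(self):
        d = np.array([1, 1, 0])
        assert ev.mean_ttp(d, [20.0, 40.0, None]) == pytest.approx(30.0)

    def test_empty_pools_rejected(self):
        with pytest.raises(ValueError):
            ev.pooled_tpr(np.array([0]), np.array([0]))
        with pytest.raises(ValueError):
            ev.mean_ttp(np.array([0, 0]), [None, None])


class TestMcNemar:
    def test_worked_example_exact_binomial(self):
        # 10 records only A correctly flags, 2 only B: p = 2*P(X<=2|n=12)
        y = np.ones(40, int)
        a = np.ones(40, int)
        b = np.ones(40, int)
        a[:2] = 0  # A misses 2, B catches them
        b[10:20] = 0  # B misses 10 that A catches
        table, p = ev.mcnemar_test(a, b, y)
        assert table[0, 1] == 10 and table[1, 0] == 2
        from scipy.stats import binom

        assert p == pytest.approx(2 * binom.cdf(2, 12, 0.5), abs=1e-9)
        assert p == pytest.approx(0.038574, abs=1e-5)

    def test_agrees_with_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = np.ones(30, int)
            a = rng.integers(0, 2, 30)
            b = rng.integers(0, 2, 30)
            table, p = ev.mcnemar_test(a, b, y)
            if table[0, 1] + table[1, 0] == 0:
                continue
            ref = sm_mcnemar(table, exact=True).pvalue
            assert p == pytest.approx(ref, abs=1e-9)

    def test_large_discordant_uses_chi_square(self):
        y = np.ones(100, int)
        a = np.ones(100, int)
        b = np.ones(100, int)
        b[:30] = 0  # 30 discordant, all favouring A
        _, p = ev.mcnemar_test(a, b, y)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf((30 - 1) ** 2 / 30, 1), abs=1e-12)

    def test_identical_methods_p_one(self):
        y = np.array([1, 1, 1, 0])
        d = np.array([1, 0, 1, 0])
        _, p = ev.mcnemar_test(d, d, y)
        assert p == 1.0

    def test_normals_are_ignored(self):
        y = np.array([1, 0, 0, 0])
        a = np.array([1, 1, 1, 1])
        b = np.array([1, 0, 0, 0])
        table, p = ev.mcnemar_test(a, b, y)
        assert table.sum() == 1 and p == 1.0


class TestApproachWindows:
    def _proc(self, minutes=60):
        from fhr_ttp.preprocess import ProcessedFHR

        return ProcessedFHR("p", np.full(int(minutes * 15), 140.0))

    def test_a1_sliding_a2_cumulative_a3_single(self):
        proc = self._proc(60)
        w1 = ev._windows_for_approach(proc, "A1")
        w2 = ev._windows_for_approach(proc, "A2")
        w3 = ev._windows_for_approach(proc, "A3")
        assert len(w1) == len(w2) == 10 and len(w3) == 1
        assert all(s.samples.size == 225 for s in w1)
        assert [s.samples.size for s in w2] == [225 + 75 * k for k in range(10)]
        assert w3[0].samples.size == 900 and w3[0].end_min == 60.0

    def test_unknown_approach_rejected(self):
        with pytest.raises(ValueError, match="approach"):
            ev._windows_for_approach(self._proc(), "A9")


class _OracleModel:
    """Deterministic stand-in classifier: probability = mean deficit below
    140 bpm, squashed to (0, 1). Compromised synthetic records (deeper
    decelerations) score higher without any training."""

    def predict(self, segments):
        out = []
        for s in segments:
            nz = s.samples[s.samples != 0]
            deficit = 0.0 if nz.size == 0 else max(0.0, 140.0 - nz.mean())
            out.append(1 - np.exp(-deficit / 4.0))
        return np.array(out)


@pytest.fixture(scope="module")
def cv_result(small_cohort):
    model = _OracleModel()
    return ev.run_cross_validation(
        small_cohort,
        model_factory=lambda s: model,
        train_fn=lambda m, segs, y, s: m,
        predict_fn=lambda m, segs: m.predict(segs),
        approach=("A1", "A2", "A3"),
        folds=3,
        repeats=2,
        seed=0,
    )


class TestCrossValidation:
    def test_returns_one_result_per_approach(self, cv_result):
        assert set(cv_result) == {"A1", "A2", "A3"}
        for res in cv_result.values():
            assert set(res.tpr_at_fpr) == set(ev.FPR_TARGETS)
            for v in res.tpr_at_fpr.values():
                assert 0.0 <= v <= 1.0

    def test_every_record_scored_exactly_once_per_repeat(self, cv_result, small_cohort):
        res = cv_result["A1"]
        n_labeled = sum(1 for r in small_cohort if r.ph is not None)
        assert len(res.record_ids) == n_labeled
        assert res.decisions[0.2].size == n_labeled
        # 2 repeats x full cohort of traces
        assert len(res.traces) == 2 * n_labeled

    def test_a3_ttp_equals_evaluation_length(self, cv_result):
        res = cv_result["A3"]
        for f, ttp in res.ttp_at_fpr.items():
            assert ttp == pytest.approx(60.0)

    def test_reproducible(self, small_cohort, cv_result):
        model = _OracleModel()
        again = ev.run_cross_validation(
            small_cohort,
            model_factory=lambda s: model,
            train_fn=lambda m, segs, y, s: m,
            predict_fn=lambda m, segs: m.predict(segs),
            approach="A1",
            folds=3,
            repeats=2,
            seed=0,
        )
        assert again.tpr_at_fpr == cv_result["A1"].tpr_at_fpr
        assert again.ttp_at_fpr == cv_result["A1"].ttp_at_fpr

    def test_too_few_compromised_rejected(self, small_cohort):
        normals = [r for r in small_cohort if r.ph is not None and not r.label.is_compromised]
        with pytest.raises(ValueError):
            ev.run_cross_validation(
                normals,
                model_factory=lambda s: None,
                train_fn=lambda m, segs, y, s: m,
                predict_fn=lambda m, segs: np.zeros(len(segs)),
                folds=5,
            )
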