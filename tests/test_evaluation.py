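"""Majority-vote fusion, confusion metrics, alarms, SOP/SPH, chance level."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preictal.evaluation import (
    classify_segment,
    mtpw_scan,
    postictal_drift_profile,
    raise_alarms,
    random_predictor_alarm_prob,
    random_predictor_pvalue,
    score_events,
    segment_metrics,
)
from preictal.io import SeizureEvent
from preictal.staging import Stage

PRE, INT, POST = Stage.PREICTAL, Stage.INTERICTAL, Stage.POSTICTAL


def oracle_segment_label(labels, n_classes):
    """Threshold rule re-derived by plain counting."""
    n = len(labels)
    n_pre = sum(1 for l in labels if l is PRE)
    if n_classes == 2:
        return PRE if n_pre > n / 2 else INT
    if n_pre > n / 3:
        return PRE
    n_post = sum(1 for l in labels if l is POST)
    n_int = sum(1 for l in labels if l is INT)
    return POST if n_post > n_int else INT


class TestClassifySegment:
    def test_over_half_rule(self):
        labels = [PRE] * 13 + [INT] * 11
        assert classify_segment(labels, 2) is PRE

    def test_exactly_half_is_interictal(self):
        labels = [PRE] * 12 + [INT] * 12
        assert classify_segment(labels, 2) is INT

    def test_third_rule_three_class(self):
        labels = [PRE] * 9 + [POST] * 10 + [INT] * 5
        assert classify_segment(labels, 3) is PRE  # 9 > 24/3

    def test_exactly_third_not_preictal(self):
        labels = [PRE] * 8 + [POST] * 10 + [INT] * 6
        assert classify_segment(labels, 3) is POST

    def test_remaining_tie_resolves_interictal(self):
        labels = [PRE] * 2 + [POST] * 5 + [INT] * 5
        assert classify_segment(labels, 3) is INT

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_segment([], 2)

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_exhaustive_enumeration_up_to_12(self, n_classes):
        """Agreement with an independent counting oracle for all multisets."""
        for n in range(1, 13):
            for n_pre in range(n + 1):
                for n_post in range(n - n_pre + 1):
                    labels = (
                        [PRE] * n_pre
                        + [POST] * n_post
                        + [INT] * (n - n_pre - n_post)
                    )
                    assert classify_segment(labels, n_classes) is (
                        oracle_segment_label(labels, n_classes)
                    )


class TestSegmentMetrics:
    def test_formulas(self):
        true = [PRE] * 10 + [INT] * 10
        pred = [PRE] * 9 + [INT] * 1 + [PRE] * 2 + [INT] * 8
        res = segment_metrics(true, pred)
        assert (res.TP, res.FN, res.FP, res.TN) == (9, 1, 2, 8)
        assert res.sensitivity == pytest.approx(0.90)
        assert res.specificity == pytest.approx(0.80)

    def test_all_correct(self):
        true = [PRE, INT, PRE, INT]
        res = segment_metrics(true, true)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_random_confusion_matches_recount(self, rng):
        true = [PRE if b else INT for b in rng.integers(0, 2, 500)]
        pred = [PRE if b else INT for b in rng.integers(0, 2, 500)]
        res = segment_metrics(true, pred)
        tp = sum(1 for t, p in zip(true, pred) if t is PRE and p is PRE)
        fp = sum(1 for t, p in zip(true, pred) if t is INT and p is PRE)
        assert (res.TP, res.FP) == (tp, fp)
        assert res.n == 500

    def test_three_class_per_class_tpr(self, rng):
        true = [PRE] * 4 + [POST] * 4 + [INT] * 4
        pred = [PRE] * 3 + [POST] + [POST] * 2 + [INT] * 2 + [INT] * 4
        res = segment_metrics(true, pred)
        assert res.per_class_tpr[PRE] == pytest.approx(0.75)
        assert res.per_class_tpr[POST] == pytest.approx(0.5)
        assert res.per_class_tpr[INT] == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            segment_metrics([PRE], [PRE, INT])


class TestMTPW:
    def test_perfect_predictions_flat_curve(self):
        true = [PRE] * 240 + [INT] * 240
        curve, mtpw = mtpw_scan(true, list(true))
        assert all(
            r.sensitivity == 1.0 and r.specificity == 1.0
            for r in curve.values()
        )
        assert mtpw == 5.0

    def test_binomial_closed_form_at_120s(self, rng):
        from scipy.stats import binom

        # i.i.d. per-sample accuracy 0.8 on both classes
        n_seg, k = 2000, 24
        true = [PRE] * (n_seg * k // 2) + [INT] * (n_seg * k // 2)
        flip = rng.random(len(true)) > 0.8
        pred = [
            (INT if t is PRE else PRE) if f else t
            for t, f in zip(true, flip)
        ]
        curve, _ = mtpw_scan(true, pred, window_lengths_s=[120.0])
        expect = binom.sf(12, 24, 0.8)  # P(X >= 13)
        se = math.sqrt(expect * (1 - expect) / (n_seg / 2))
        assert abs(curve[120.0].sensitivity - expect) < 4 * se

    def test_non_multiple_window_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            mtpw_scan([PRE] * 10, [PRE] * 10, window_lengths_s=[7.0])


def step_through_alarm_oracle(stream, n_win, frac, refractory_s, sample_s):
    """Literal re-execution of the alarm rule with Fraction arithmetic."""
    alarms = []
    last = None
    labels = []
    times = []
    for t, lab in stream:
        if times and t - times[-1] > sample_s + 1e-9:
            labels, times = [], []
        labels.append(lab)
        times.append(t)
        if len(labels) < n_win:
            continue
        window = labels[-n_win:]
        count = sum(1 for l in window if l is PRE)
        at = t + 2 * sample_s
        if Fraction(count, n_win) > Fraction(frac).limit_denominator(100) and (
            last is None or at - last >= refractory_s
        ):
            alarms.append(at)
            last = at
    return alarms


class TestAlarms:
    def make_stream(self, labels, start=0.0, step=5.0):
        return [(start + i * step, l) for i, l in enumerate(labels)]

    def test_strict_seventy_percent_boundary(self):
        base = [INT] * 36 + [PRE] * 84  # exactly 84/120 in final window
        assert raise_alarms(self.make_stream(base)) == []
        fires = [INT] * 35 + [PRE] * 85  # 85/120
        alarms = raise_alarms(self.make_stream(fires))
        assert len(alarms) == 1

    def test_refractory_deduplicates(self):
        # two supra-threshold epochs 20 min apart within a 50-min refractory
        labels = [PRE] * 120 + [INT] * 120 + [PRE] * 120
        alarms = raise_alarms(self.make_stream(labels), refractory_s=3000.0)
        assert len(alarms) == 1
        labels2 = [PRE] * 120 + [INT] * 120 + [PRE] * 480
        alarms2 = raise_alarms(self.make_stream(labels2), refractory_s=3000.0)
        assert len(alarms2) == 2
        assert alarms2[1].time_s - alarms2[0].time_s >= 3000.0

    def test_gap_resets_window(self):
        first = self.make_stream([PRE] * 100)
        second = [(1e6 + i * 5.0, PRE) for i in range(100)]
        assert raise_alarms(first + second) == []

    def test_short_stream_warns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert raise_alarms(self.make_stream([PRE] * 10)) == []

    def test_matches_step_through_oracle(self, rng):
        for trial in range(10):
            labels = [
                PRE if rng.random() < 0.72 else INT for _ in range(600)
            ]
            stream = self.make_stream(labels)
            got = [a.time_s for a in raise_alarms(stream)]
            want = step_through_alarm_oracle(stream, 120, 0.70, 3000.0, 5.0)
            assert got == pytest.approx(want)


def pairing_oracle(alarm_times, onsets, sop_s, sph_s):
    """Brute force over all alarm-seizure pairs."""
    correct_for = {
        t: [o for o in onsets if t + sph_s <= o < t + sph_s + sop_s]
        for t in alarm_times
    }
    predicted = {
        o
        for o in onsets
        if any(o in hits for hits in correct_for.values())
    }
    n_false = sum(1 for t in alarm_times if not correct_for[t])
    warn = {}
    for o in sorted(onsets):
        firsts = [t for t in sorted(alarm_times) if o in correct_for[t]]
        if firsts:
            warn[o] = o - firsts[0]
    return len(predicted), n_false, warn


class TestScoreEvents:
    def leading(self, *onsets, dur=60.0):
        return [SeizureEvent(o, o + dur, leading=True) for o in onsets]

    def test_alarm_forty_minutes_ahead_is_correct(self):
        from preictal.evaluation import AlarmEvent

        res = score_events(
            [AlarmEvent(0.0)], self.leading(2400.0), evaluated_hours=1.0
        )
        assert res.m == 1 and res.n_false_alarms == 0
        assert res.warning_times_s == [2400.0]

    def test_onset_within_sph_is_false_alarm(self):
        from preictal.evaluation import AlarmEvent

        res = score_events(
            [AlarmEvent(0.0)], self.leading(900.0), evaluated_hours=1.0
        )
        assert res.m == 0 and res.n_false_alarms == 1

    def test_sop_end_is_exclusive(self):
        from preictal.evaluation import AlarmEvent

        res = score_events(
            [AlarmEvent(0.0)], self.leading(3000.0), evaluated_hours=1.0
        )
        assert res.m == 0  # onset exactly at SPH+SOP

    def test_random_timelines_match_pairing_oracle(self, rng):
        from preictal.evaluation import AlarmEvent

        for trial in range(60):
            n_alarm = int(rng.integers(0, 6))
            n_seiz = int(rng.integers(1, 4))
            alarm_times = np.unique(rng.uniform(0, 20000, n_alarm)).tolist()
            onsets = []
            t = float(rng.uniform(3000, 8000))
            for _ in range(n_seiz):
                onsets.append(t)
                t += float(rng.uniform(500, 9000))
            res = score_events(
                [AlarmEvent(t) for t in alarm_times],
                self.leading(*onsets, dur=30.0),
                evaluated_hours=5.0,
            )
            m, n_false, warn = pairing_oracle(
                alarm_times, onsets, 1200.0, 1800.0
            )
            assert res.m == m
            assert res.n_false_alarms == n_false
            assert sorted(res.warning_times_s) == pytest.approx(
                sorted(warn.values())
            )
            # bookkeeping identity: every alarm is correct or false
            n_correct_alarms = sum(
                1
                for t in alarm_times
                if any(
                    t + 1800.0 <= o < t + 3000.0 for o in onsets
                )
            )
            assert n_correct_alarms + n_false == len(alarm_times)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            score_events([], [], sop_s=-5.0)
        with pytest.raises(ValueError):
            score_events([], [], evaluated_hours=-1.0)


class TestRandomPredictor:
    def test_alarm_prob_endpoints(self):
        assert random_predictor_alarm_prob(0.0, 1200.0) == 0.0
        assert random_predictor_alarm_prob(1e9, 1200.0) == pytest.approx(1.0)

    def test_alarm_prob_reference_value(self):
        # 1 - exp(-0.29/3), frozen from a 30-digit sympy evaluation
        assert random_predictor_alarm_prob(0.29, 1200.0) == pytest.approx(
            0.0921414247726354717885962340944, abs=1e-12
        )

    def test_identity_with_exponential(self):
        for fpr in (0.05, 0.29, 1.7):
            P = random_predictor_alarm_prob(fpr, 1200.0)
            assert P + math.exp(-fpr * 1200.0 / 3600.0) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_pvalue_trivial_cases(self):
        assert random_predictor_pvalue(0.3, 5, 0) == 1.0
        assert random_predictor_pvalue(0.5, 3, 2) == pytest.approx(0.5)

    def test_pvalue_equals_outcome_enumeration(self):
        """Exhaustive enumeration over all 2^M outcome vectors, M <= 10."""
        for P in np.linspace(0.0, 1.0, 11):
            for M in range(1, 11):
                for m in range(M + 1):
                    total = 0.0
                    for outcome in itertools.product((0, 1), repeat=M):
                        if sum(outcome) >= m:
                            prob = 1.0
                            for o in outcome:
                                prob *= P if o else (1.0 - P)
                            total += prob
                    assert random_predictor_pvalue(P, M, m) == pytest.approx(
                        total, abs=1e-12
                    )

    @given(
        P=st.floats(0.0, 1.0),
        M=st.integers(1, 20),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_pvalue_monotone(self, P, M, data):
        m = data.draw(st.integers(0, M))
        p = random_predictor_pvalue(P, M, m)
        assert 0.0 <= p <= 1.0
        if m > 0:
            assert p <= random_predictor_pvalue(P, M, m - 1) + 1e-12
        assert p <= random_predictor_pvalue(min(P + 0.05, 1.0), M, m) + 1e-12

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            random_predictor_pvalue(1.5, 3, 1)
        with pytest.raises(ValueError):
            random_predictor_pvalue(0.5, 3, 4)
        with pytest.raises(ValueError):
            random_predictor_alarm_prob(-0.1, 1200.0)


class TestPostictalDrift:
    def test_all_interictal_gives_zero(self):
        pairs = [(60.0 * i, INT) for i in range(100)]
        assert all(v == 0.0 for v in postictal_drift_profile(pairs).values())

    def test_fraction_per_bin(self):
        pairs = [(10.0 + i, PRE) for i in range(30)] + [
            (100.0 + i, INT) for i in range(90)
        ]
        prof = postictal_drift_profile(pairs)
        assert prof[0] == pytest.approx(30 / 120)

    def test_empty_bins_absent(self):
        pairs = [(10.0, PRE), (2 * 3600.0 + 5.0, INT)]
        prof = postictal_drift_profile(pairs)
        assert set(prof) == {0, 2}

    def test_recount_matches(self, rng):
        pairs = [
            (float(rng.uniform(0, 4 * 3600)), PRE if rng.random() < 0.4 else INT)
            for _ in range(500)
        ]
        prof = postictal_drift_profile(pairs)
        for b, frac in prof.items():
            inb = [l for t, l in pairs if int(t // 3600) == b]
            assert frac == pytest.approx(
                sum(1 for l in inb if l is PRE) / len(inb)
            )

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            postictal_drift_profile([(-1.0, PRE)])
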