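"""Segment- and event-level scoring of seizure predictions.

Segment level: per-sample labels are fused over fixed-length segments by a
majority rule — a segment is preictal when strictly more than half of its
5-s samples are preictal (binary task) or strictly more than one third
(three-class task) — and scored by sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP), with per-class true-positive rates in the
three-class mode.  The minimum time prediction window (MTPW) scan sweeps
the segment length from 5 to 150 s and reports where both metrics plateau.

Event level: an alarm is raised when strictly more than 70% of the samples
in a trailing 10-min window are labeled preictal.  An alarm at time t is
correct when a leading seizure starts inside ``[t+SPH, t+SPH+SOP)`` — the
seizure prediction horizon SPH (default 30 min) is reserved for
intervention and must stay seizure-free, the seizure occurrence period SOP
(default 20 min) is when the seizure must arrive.  Sensitivity is the
fraction of leading seizures with a correct alarm; the false prediction
rate (FPR) counts incorrect alarms per evaluated hour.  Chance performance
of an equally noisy random predictor is P = 1 - exp(-FPR * SOP), and the
probability of it predicting at least m of M seizures is the binomial tail
sum_{i>=m} C(M,i) P^i (1-P)^{M-i}; p < 0.05 declares the predictor better
than chance.
"""

from __future__ import annotations

import warnings
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import SeizureEvent
from .staging import Stage

__all__ = [
    "SegmentEvalResult",
    "AlarmEvent",
    "EventEvalResult",
    "classify_segment",
    "segment_metrics",
    "mtpw_scan",
    "raise_alarms",
    "score_events",
    "random_predictor_alarm_prob",
    "random_predictor_pvalue",
    "postictal_drift_profile",
]

_EPS = 1e-9


@dataclass
class SegmentEvalResult:
    """Confusion counts and rates with preictal as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int
    per_class_tpr: dict[Stage, float] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def sensitivity(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.TN + self.FP
        return self.TN / d if d else float("nan")


@dataclass(frozen=True)
class AlarmEvent:
    """A warning alarm raised at ``time_s`` on the subject timeline."""

    time_s: float
    window_frac: float = float("nan")


@dataclass
class EventEvalResult:
    """SOP/SPH-scored event-level outcome."""

    M: int
    m: int
    n_false_alarms: int
    evaluated_hours: float
    warning_times_s: list[float]
    sop_s: float
    sph_s: float

    @property
    def sensitivity(self) -> float:
        return self.m / self.M if self.M else float("nan")

    @property
    def fpr_per_hour(self) -> float:
        return (
            self.n_false_alarms / self.evaluated_hours
            if self.evaluated_hours > 0
            else float("nan")
        )

    @property
    def chance_alarm_prob(self) -> float:
        fpr = self.fpr_per_hour
        if np.isnan(fpr):
            return float("nan")
        return random_predictor_alarm_prob(fpr, self.sop_s)

    @property
    def chance_pvalue(self) -> float:
        P = self.chance_alarm_prob
        if np.isnan(P):
            return float("nan")
        return random_predictor_pvalue(P, self.M, self.m)


# ---------------------------------------------------------------------------
# segment level
# ---------------------------------------------------------------------------


def classify_segment(sample_labels: list[Stage], n_classes: int = 2) -> Stage:
    """Fuse the sample labels of one segment into a segment label.

    Binary task: preictal iff strictly more than half the samples are
    preictal, else interictal.  Three-class task: preictal iff strictly more
    than a third are preictal; otherwise the plurality of the remaining
    classes, ties resolving to interictal (the non-alarm class).
    """
    if not sample_labels:
        raise ValueError("empty segment")
    n = len(sample_labels)
    counts = Counter(sample_labels)
    n_pre = counts.get(Stage.PREICTAL, 0)
    if n_classes == 2:
        return Stage.PREICTAL if 2 * n_pre > n else Stage.INTERICTAL
    if n_classes != 3:
        raise ValueError("n_classes must be 2 or 3")
    if 3 * n_pre > n:
        return Stage.PREICTAL
    n_post = counts.get(Stage.POSTICTAL, 0)
    n_int = counts.get(Stage.INTERICTAL, 0)
    return Stage.POSTICTAL if n_post > n_int else Stage.INTERICTAL


def segment_metrics(
    true_labels: list[Stage],
    predicted_labels: list[Stage],
    positive: Stage = Stage.PREICTAL,
) -> SegmentEvalResult:
    """Confusion counts with ``positive`` (preictal) as the alarm class.

    In the three-class setting the binary sensitivity/specificity still
    treat preictal vs rest, and ``per_class_tpr`` additionally reports each
    stage's own true-positive rate.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label list length mismatch")
    tp = tn = fp = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if not isinstance(t, Stage) or not isinstance(p, Stage):
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        if t is positive:
            if p is positive:
                tp += 1
            else:
                fn += 1
        else:
            if p is positive:
                fp += 1
            else:
                tn += 1
    per_class: dict[Stage, float] = {}
    for stage in set(true_labels):
        idx = [i for i, t in enumerate(true_labels) if t is stage]
        per_class[stage] = sum(
            1 for i in idx if predicted_labels[i] is stage
        ) / len(idx)
    return SegmentEvalResult(TP=tp, TN=tn, FP=fp, FN=fn, per_class_tpr=per_class)


def _runs(values: list) -> list[tuple[int, int]]:
    """Half-open index runs of constant value."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i))
            start = i
    return runs


def mtpw_scan(
    true_labels: list[Stage],
    predicted_labels: list[Stage],
    window_lengths_s: list[float] | None = None,
    sample_s: float = 5.0,
    n_classes: int = 2,
    plateau_tol: float = 0.01,
) -> tuple[dict[float, SegmentEvalResult], float | None]:
    """Sweep the segment length and locate the minimum time prediction window.

    For each window length L the per-sample predictions are grouped into
    consecutive runs of L / 5 samples inside stretches of constant true
    stage (trailing remainders dropped), fused by :func:`classify_segment`
    and scored.  Returns the per-L results and the smallest L whose
    sensitivity and specificity are both within ``plateau_tol`` of their
    maxima over all larger L (the plateau onset); ``None`` when no L
    qualifies.
    """
    if window_lengths_s is None:
        window_lengths_s = [float(L) for L in range(5, 155, 5)]
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label list length mismatch")
    results: dict[float, SegmentEvalResult] = {}
    for L in window_lengths_s:
        k = L / sample_s
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"window length {L} s is not a multiple of {sample_s} s")
        k = int(round(k))
        seg_true: list[Stage] = []
        seg_pred: list[Stage] = []
        for a, b in _runs(true_labels):
            for s in range(a, b - k + 1, k):
                seg_true.append(true_labels[a])
                seg_pred.append(
                    classify_segment(predicted_labels[s : s + k], n_classes)
                )
        results[L] = segment_metrics(seg_true, seg_pred)

    Ls = sorted(results)
    mtpw = None
    for i, L in enumerate(Ls):
        tail = Ls[i:]
        max_sen = max(results[t].sensitivity for t in tail)
        max_spe = max(results[t].specificity for t in tail)
        if (
            results[L].sensitivity >= max_sen - plateau_tol
            and results[L].specificity >= max_spe - plateau_tol
        ):
            mtpw = L
            break
    return results, mtpw


# ---------------------------------------------------------------------------
# event level
# ---------------------------------------------------------------------------


def raise_alarms(
    stream: list[tuple[float, Stage]],
    window_min: float = 10.0,
    frac: float = 0.70,
    refractory_s: float = 3000.0,
    sample_s: float = 5.0,
) -> list[AlarmEvent]:
    """Raise warning alarms from a time-ordered label stream.

    ``stream`` holds ``(start_s, predicted_stage)`` per 5-s sample.  A
    trailing window of the last ``window_min`` minutes slides one sample at
    a time; an alarm fires when strictly more than ``frac`` of the samples
    in a full window are preictal.  After an alarm no further alarm fires
    until ``refractory_s`` has elapsed (default SPH+SOP = 50 min, so one
    alarm covers one prediction window).  A gap in the recording (step
    larger than the sample length) resets the window.  The alarm takes
    effect at the first sample boundary after the completing sample has
    been fully observed (one sample of actuation latency), so the largest
    achievable warning time is SPH + SOP minus one sample length —
    49.92 min at the defaults.
    """
    n_win = int(round(window_min * 60.0 / sample_s))
    if len(stream) < n_win:
        warnings.warn(
            f"stream of {len(stream)} samples is shorter than one "
            f"{window_min:g}-min window; no alarms possible",
            stacklevel=2,
        )
        return []
    alarms: list[AlarmEvent] = []
    window: deque[Stage] = deque(maxlen=n_win)
    n_pre = 0
    prev_t: float | None = None
    last_alarm = -np.inf
    for t, label in stream:
        if prev_t is not None and t - prev_t > sample_s + _EPS:
            window.clear()
            n_pre = 0
        prev_t = t
        if len(window) == n_win and window[0] is Stage.PREICTAL:
            n_pre -= 1
        window.append(label)
        if label is Stage.PREICTAL:
            n_pre += 1
        if len(window) < n_win:
            continue
        alarm_t = t + 2.0 * sample_s
        if n_pre > frac * n_win + _EPS and alarm_t - last_alarm >= refractory_s:
            alarms.append(AlarmEvent(alarm_t, n_pre / n_win))
            last_alarm = alarm_t
    return alarms


def score_events(
    alarms: list[AlarmEvent],
    seizures: list[SeizureEvent],
    sop_s: float = 1200.0,
    sph_s: float = 1800.0,
    evaluated_hours: float = 0.0,
) -> EventEvalResult:
    """Score alarms against leading seizure onsets under SOP/SPH.

    An alarm at t is correct iff some leading onset lies in
    ``[t+SPH, t+SPH+SOP)``; a seizure counts as predicted iff at least one
    alarm is correct for it; alarms correct for no seizure are false
    alarms.  ``evaluated_hours`` is the denominator of the false prediction
    rate (the evaluated non-ictal recording time).
    """
    if sop_s <= 0 or sph_s < 0:
        raise ValueError("need sop_s > 0 and sph_s >= 0")
    if evaluated_hours < 0:
        raise ValueError("evaluated_hours must be non-negative")
    leading = sorted(
        (ev for ev in seizures if ev.leading), key=lambda e: e.onset_s
    )
    times = sorted(a.time_s for a in alarms)
    if any(t1 - t0 <= 0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("alarms must be strictly increasing in time")
    predicted = [False] * len(leading)
    first_correct: list[float | None] = [None] * len(leading)
    n_false = 0
    for t in times:
        hit = False
        for j, ev in enumerate(leading):
            if t + sph_s <= ev.onset_s < t + sph_s + sop_s:
                hit = True
                predicted[j] = True
                if first_correct[j] is None:
                    first_correct[j] = t
        if not hit:
            n_false += 1
    warning_times = [
        ev.onset_s - t0
        for ev, t0 in zip(leading, first_correct)
        if t0 is not None
    ]
    return EventEvalResult(
        M=len(leading),
        m=sum(predicted),
        n_false_alarms=n_false,
        evaluated_hours=evaluated_hours,
        warning_times_s=warning_times,
        sop_s=sop_s,
        sph_s=sph_s,
    )


def random_predictor_alarm_prob(fpr_per_hour: float, sop_s: float) -> float:
    """Chance of an unspecific predictor alarming inside one SOP.

    ``P = 1 - exp(-FPR * SOP)`` with the SOP expressed in hours.
    """
    if fpr_per_hour < 0:
        raise ValueError("FPR must be non-negative")
    if sop_s <= 0:
        raise ValueError("SOP must be positive")
    return float(-np.expm1(-fpr_per_hour * sop_s / 3600.0))


def random_predictor_pvalue(P: float, M: int, m: int) -> float:
    """Chance of predicting at least m of M independent seizures.

    The upper binomial tail ``sum_{i>=m} C(M,i) P^i (1-P)^(M-i)``; values
    below 0.05 declare the predictor significantly better than chance.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P must be in [0, 1], got {P}")
    if not 0 <= m <= M:
        raise ValueError(f"need 0 <= m <= M, got m={m}, M={M}")
    if m == 0:
        return 1.0
    return float(stats.binom.sf(m - 1, M, P))


def postictal_drift_profile(
    labeled_offsets: list[tuple[float, Stage]],
    bin_s: float = 3600.0,
) -> dict[int, float]:
    """Fraction of samples predicted preictal per hour after seizure offset.

    ``labeled_offsets`` holds ``(seconds since the ictal offset, predicted
    stage)`` pairs.  Returns ``{bin index: fraction}``; bins without samples
    are absent rather than zero.
    """
    if any(t < 0 for t, _ in labeled_offsets):
        raise ValueError("time offsets must be non-negative")
    totals: Counter[int] = Counter()
    pre: Counter[int] = Counter()
    for t, label in labeled_offsets:
        b = int(t // bin_s)
        totals[b] += 1
        if label is Stage.PREICTAL:
            pre[b] += 1
    return {b: pre[b] / totals[b] for b in sorted(totals)}
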