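"""Stage labeling of the subject timeline around annotated seizures.

Each recorded second gets exactly one of five labels.  The ictal span is
the clinical annotation; the preictal hour precedes each *leading* seizure
(one occurring more than 60 min after the previous seizure's end); the
postictal hour follows every seizure offset; interictal time must keep a
5 h buffer after the previous seizure and a 3 h buffer before the next, to
avoid contaminating the baseline class; whatever recorded time fits none
of these is EXCLUDED.  On conflict the precedence is

    ICTAL > PREICTAL > POSTICTAL > EXCLUDED > INTERICTAL

so preictal data for a predictable seizure is never sacrificed to the
previous seizure's postictal window, while interictal purity is maximal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .io import SeizureEvent, sort_events

__all__ = [
    "Stage",
    "StageInterval",
    "StagingPolicy",
    "select_leading_seizures",
    "assign_stages",
    "stage_at",
    "intervals_to_tsv",
]


class Stage(str, Enum):
    PREICTAL = "preictal"
    ICTAL = "ictal"
    POSTICTAL = "postictal"
    INTERICTAL = "interictal"
    EXCLUDED = "excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Stages whose windows become classifier samples.
CLASSIFIABLE_STAGES = (Stage.PREICTAL, Stage.POSTICTAL, Stage.INTERICTAL)


@dataclass(frozen=True)
class StageInterval:
    """A half-open labeled span ``[start_s, end_s)`` on the subject timeline."""

    stage: Stage
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"empty or inverted interval [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StagingPolicy:
    """Durations (seconds) governing the stage layout.

    Defaults follow the standard scheme: leading-seizure gap 60 min,
    preictal and postictal 1 h, interictal buffers 5 h after / 3 h before
    a seizure.
    """

    leading_gap_s: float = 3600.0
    preictal_len_s: float = 3600.0
    postictal_len_s: float = 3600.0
    interictal_pre_buffer_s: float = 5 * 3600.0
    interictal_post_buffer_s: float = 3 * 3600.0

    def __post_init__(self) -> None:
        for name in (
            "leading_gap_s",
            "preictal_len_s",
            "postictal_len_s",
            "interictal_pre_buffer_s",
            "interictal_post_buffer_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.preictal_len_s > self.interictal_post_buffer_s:
            raise ValueError(
                "preictal_len_s may not exceed interictal_post_buffer_s "
                "(preictal and interictal time would overlap)"
            )


def _recorded_before(
    spans: list[tuple[float, float]], start: float, end: float
) -> float:
    """Recorded seconds inside ``[start, end)``."""
    total = 0.0
    for s, e in spans:
        total += max(0.0, min(e, end) - max(s, start))
    return total


def select_leading_seizures(
    events: list[SeizureEvent],
    policy: StagingPolicy = StagingPolicy(),
    recorded_spans: list[tuple[float, float]] | None = None,
) -> list[SeizureEvent]:
    """Flag leading seizures (the prediction targets).

    A seizure is leading iff its onset is more than ``leading_gap_s`` after
    the previous seizure's offset.  The subject's first seizure is leading
    iff a full preictal window before its onset is recorded, which requires
    ``recorded_spans``; without spans the first seizure is taken leading.
    Returns a new sorted list with ``leading`` set; the non-leading seizures
    are retained (they still carve ictal/postictal/excluded zones).
    """
    events = sort_events(events)
    out: list[SeizureEvent] = []
    for i, ev in enumerate(events):
        if i == 0:
            if recorded_spans is None:
                leading = True
            else:
                covered = _recorded_before(
                    recorded_spans, ev.onset_s - policy.preictal_len_s, ev.onset_s
                )
                leading = covered >= policy.preictal_len_s - 1e-9
        else:
            leading = ev.onset_s - events[i - 1].offset_s > policy.leading_gap_s
        out.append(replace(ev, leading=leading))
    return out


def stage_at(
    t: float,
    events: list[SeizureEvent],
    policy: StagingPolicy = StagingPolicy(),
) -> Stage:
    """Stage of a single timeline instant, by direct application of the rules.

    ``events`` must already carry leading flags.  This pointwise form is the
    definition; :func:`assign_stages` evaluates it piecewise over whole
    recordings.
    """
    for ev in events:
        if ev.onset_s <= t < ev.offset_s:
            return Stage.ICTAL
    for ev in events:
        if ev.leading and ev.onset_s - policy.preictal_len_s <= t < ev.onset_s:
            return Stage.PREICTAL
    for ev in events:
        if ev.offset_s <= t < ev.offset_s + policy.postictal_len_s:
            return Stage.POSTICTAL
    prev_off = max((ev.offset_s for ev in events if ev.offset_s <= t), default=None)
    next_on = min((ev.onset_s for ev in events if ev.onset_s > t), default=None)
    ok_prev = prev_off is None or t - prev_off >= policy.interictal_pre_buffer_s
    ok_next = next_on is None or next_on - t >= policy.interictal_post_buffer_s
    if ok_prev and ok_next:
        return Stage.INTERICTAL
    return Stage.EXCLUDED


def assign_stages(
    recorded_spans: list[tuple[float, float]],
    events: list[SeizureEvent],
    policy: StagingPolicy = StagingPolicy(),
) -> list[StageInterval]:
    """Tile the recorded timeline with stage intervals.

    ``recorded_spans`` are the half-open ``[start, end)`` spans actually on
    disk (gaps between records are simply absent and get no interval).
    ``events`` must be sorted, non-overlapping and carry leading flags (see
    :func:`select_leading_seizures`).  The output tiles every recorded
    second exactly once, with maximal merged runs of equal stage.
    """
    events = sort_events(events)
    spans = sorted(recorded_spans)
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 < e0 - 1e-9:
            raise ValueError("recorded spans overlap")
    if any(e <= s for s, e in spans):
        raise ValueError("empty recorded span")

    # Boundaries where the pointwise stage can change.
    cuts: set[float] = set()
    for s, e in spans:
        cuts.update((s, e))
    for ev in events:
        cuts.update(
            (
                ev.onset_s,
                ev.offset_s,
                ev.onset_s - policy.preictal_len_s,
                ev.offset_s + policy.postictal_len_s,
                ev.offset_s + policy.interictal_pre_buffer_s,
                ev.onset_s - policy.interictal_post_buffer_s,
            )
        )
    cut_list = sorted(cuts)

    out: list[StageInterval] = []
    for s, e in spans:
        inner = [s] + [c for c in cut_list if s < c < e] + [e]
        for a, b in zip(inner, inner[1:]):
            # midpoint: the stage is constant on the open segment, while the
            # boundary instant itself can satisfy a >= buffer condition that
            # fails everywhere else in the segment
            st = stage_at((a + b) / 2.0, events, policy)
            if out and out[-1].stage is st and abs(out[-1].end_s - a) < 1e-9:
                out[-1] = StageInterval(st, out[-1].start_s, b)
            else:
                out.append(StageInterval(st, a, b))
    return out


def intervals_to_tsv(intervals: list[StageInterval]) -> str:
    """BED-like TSV rendering (start, end, stage), one interval per line."""
    lines = ["start_s\tend_s\tstage"]
    for iv in intervals:
        lines.append(f"{iv.start_s:g}\t{iv.end_s:g}\t{iv.stage.value}")
    return "\n".join(lines)
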