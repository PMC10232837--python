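"""End-to-end orchestration: ingest -> stage -> filter -> segment -> train
-> predict -> segment/event evaluation -> report.

A single :class:`RunConfig` (loadable from YAML) holds every constant of
the method — window length, band, staging durations, alarm rule, SOP/SPH,
model settings, seeds — so a results bundle is reproducible from its
manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import (
    EventEvalResult,
    SegmentEvalResult,
    mtpw_scan,
    postictal_drift_profile,
    raise_alarms,
    score_events,
)
from .io import EEGRecording, SeizureEvent, load_subject
from .model import (
    ModelConfig,
    kfold_cv,
    loocv_by_seizure,
    predict_samples,
    split_first_k_seizures,
    train,
)
from .preprocessing import (
    BANDS,
    RejectionPolicy,
    Sample,
    balance_classes,
    bandpass_filter,
    segment_recording,
)
from .staging import (
    Stage,
    StagingPolicy,
    assign_stages,
    intervals_to_tsv,
    select_leading_seizures,
)
from .synthetic import SynthConfig, generate_subject_data

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run", "compare_bands"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SynthSpec:
    """Synthetic-subject layout for runs without on-disk data."""

    n_channels: int = 23
    n_seizures: int = 3
    gap_s: float = 9 * 3600.0
    lead_in_s: float = 4 * 3600.0
    tail_s: float = 6 * 3600.0
    ictal_len_s: float = 60.0
    band_power: dict = field(
        default_factory=lambda: {"preictal": {"gamma": 1.5}, "postictal": {"gamma": 1.25}}
    )
    artifact_rate_per_hour: float = 2.0


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    data_dir: str | None = None
    synth: SynthSpec | None = None
    channels: list[str] | None = None
    task: int = 2  # 2- or 3-class
    band: str = "gamma"
    window_s: float = 5.0
    segment_window_s: float = 120.0
    split: str = "loo_by_seizure"  # | first_k | kfold_segments
    first_k: int = 2
    # first_k training recipe: "all", "preictal+interictal" or
    # "postictal+interictal" (train on early postictal hours as the alarm
    # class; their predictions are mapped onto preictal)
    train_on: str = "all"
    kfold_k: int = 10
    policy: StagingPolicy = field(default_factory=StagingPolicy)
    rejection: RejectionPolicy = field(default_factory=RejectionPolicy)
    model: ModelConfig = field(default_factory=ModelConfig.reduced)
    sop_s: float = 1200.0
    sph_s: float = 1800.0
    alarm_window_min: float = 10.0
    alarm_frac: float = 0.70
    min_postictal_s: float = 600.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.task not in (2, 3):
            raise ValueError("task must be 2 or 3 (number of classes)")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.split not in ("loo_by_seizure", "first_k", "kfold_segments"):
            raise ValueError(f"unknown split mode {self.split!r}")
        if self.train_on not in (
            "all",
            "preictal+interictal",
            "postictal+interictal",
        ):
            raise ValueError(f"unknown train_on recipe {self.train_on!r}")
        if self.data_dir is None and self.synth is None:
            raise ValueError("either data_dir or synth must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "synth" in kw and kw["synth"] is not None:
            kw["synth"] = SynthSpec(**kw["synth"])
        if "policy" in kw:
            kw["policy"] = StagingPolicy(**kw["policy"])
        if "rejection" in kw:
            kw["rejection"] = RejectionPolicy(**kw["rejection"])
        if "model" in kw:
            m = dict(kw["model"])
            preset = m.pop("preset", None)
            kw["model"] = (
                ModelConfig.reduced(**m) if preset == "reduced" else ModelConfig(**m)
            )
        return cls(**kw)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["package_version"] = __version__
        return d


# ---------------------------------------------------------------------------


def _ingest(config: RunConfig):
    """Load or synthesize the subject: recordings, events, spans."""
    if config.data_dir is not None:
        recordings, events = load_subject(config.data_dir, config.channels)
        if not recordings:
            raise PipelineError("ingest: no readable records")
        return recordings, events
    spec = config.synth
    synth_cfg = SynthConfig(
        n_channels=spec.n_channels,
        band_power=spec.band_power,
        artifact_rate_per_hour=spec.artifact_rate_per_hour,
        seed=config.seed,
    )
    rec, events, _ = generate_subject_data(
        synth_cfg,
        n_seizures=spec.n_seizures,
        gap_s=spec.gap_s,
        ictal_len_s=spec.ictal_len_s,
        lead_in_s=spec.lead_in_s,
        tail_s=spec.tail_s,
        policy=config.policy,
    )
    return [rec], events


def _collect_samples(
    recordings: list[EEGRecording],
    intervals,
    config: RunConfig,
) -> tuple[list[Sample], int]:
    """Filter, window and artifact-screen every record.

    The EMG screen runs on the *raw* windows (broadband content is what
    betrays muscle artifact); surviving window positions are then cut from
    the band-filtered record.
    """
    from .preprocessing import _is_artifact  # deterministic screen

    samples: list[Sample] = []
    n_rej = 0
    for rec in recordings:
        raw_windows = segment_recording(rec, intervals, config.window_s)
        bad_keys = set()
        for w in raw_windows:
            if _is_artifact(w.data, config.rejection, rec.fs):
                bad_keys.add(w.key)
        n_rej += len(bad_keys)
        filt = bandpass_filter(rec, config.band)
        for w in segment_recording(filt, intervals, config.window_s, band=config.band):
            if w.key not in bad_keys:
                samples.append(w)
    samples.sort(key=lambda s: s.start_s)
    return samples, n_rej


def _seizure_offset_before(t: float, events: list[SeizureEvent]) -> float | None:
    offs = [ev.offset_s for ev in events if ev.offset_s <= t]
    return max(offs) if offs else None


def _evaluated_hours(test_samples: list[Sample], task: int, window_s: float) -> float:
    stages = (
        (Stage.INTERICTAL,) if task == 2 else (Stage.INTERICTAL, Stage.POSTICTAL)
    )
    n = sum(1 for s in test_samples if s.stage in stages)
    return n * window_s / 3600.0


def _model_config_for(config: RunConfig, samples: list[Sample]) -> ModelConfig:
    base = asdict(config.model)
    base["input_len"] = samples[0].data.shape[1]
    base["n_channels"] = samples[0].data.shape[0]
    base["n_classes"] = config.task
    base["seed"] = config.seed
    return ModelConfig(**base)


def run(config: RunConfig) -> dict:
    """Execute the full prediction method and return the results bundle."""
    t_start = time.time()
    stage_name = "ingest"
    try:
        recordings, events = _ingest(config)
        spans = [r.span for r in recordings]

        stage_name = "staging"
        events = select_leading_seizures(events, config.policy, spans)
        intervals = assign_stages(spans, events, config.policy)

        stage_name = "preprocessing"
        samples, n_rejected = _collect_samples(recordings, intervals, config)
        by_stage = {
            st.value: sum(1 for s in samples if s.stage is st)
            for st in (Stage.PREICTAL, Stage.INTERICTAL, Stage.POSTICTAL)
        }
        logger.info("samples per class after rejection: %s", by_stage)
        if config.task == 3:
            if by_stage["postictal"] * config.window_s < config.min_postictal_s:
                raise PipelineError(
                    "preprocessing: insufficient postictal data for the "
                    f"3-class task ({by_stage['postictal']} samples)"
                )
        task_stages = (
            (Stage.PREICTAL, Stage.INTERICTAL)
            if config.task == 2
            else (Stage.PREICTAL, Stage.INTERICTAL, Stage.POSTICTAL)
        )
        task_samples = [s for s in samples if s.stage in task_stages]
        postictal_samples = [s for s in samples if s.stage is Stage.POSTICTAL]

        stage_name = "train/predict"
        mcfg = _model_config_for(config, samples)
        results: dict = {
            "manifest": config.to_manifest(),
            "counts": {"per_class": by_stage, "rejected": n_rejected},
        }
        alarm_rows: list[tuple[float, float]] = []

        if config.split == "kfold_segments":
            folds = kfold_cv(
                balance_classes(task_samples, seed=config.seed),
                k=config.kfold_k,
                config=mcfg,
            )
            results["segment"] = {
                "per_fold": [_seg_dict(f) for f in folds],
                "mean_sensitivity": float(
                    np.mean([f.sensitivity for f in folds])
                ),
                "mean_specificity": float(
                    np.mean([f.specificity for f in folds])
                ),
            }
            results["event"] = None
        else:
            if config.split == "first_k":
                variant = config.train_on == "postictal+interictal"
                train_on = config.train_on
                if config.task == 2 and train_on == "all":
                    train_on = "preictal+interictal"
                train_set, test_set = split_first_k_seizures(
                    samples if variant else task_samples,
                    events,
                    k=config.first_k,
                    train_on=train_on,
                )
                test_set = [s for s in test_set if s.stage in task_stages]
                clf = train(balance_classes(train_set, seed=config.seed), mcfg)
                _, labels = predict_samples(clf, test_set)
                if variant:
                    # the postictal-trained alarm class stands in for preictal
                    labels = [
                        Stage.PREICTAL if l is Stage.POSTICTAL else l
                        for l in labels
                    ]
                pred_pairs = list(zip(test_set, labels))
                leading_events = [ev for ev in events if ev.leading][config.first_k :]
                models = [clf]
            else:  # loo_by_seizure
                loo = loocv_by_seizure(task_samples, events, mcfg)
                pred_pairs = []
                for rnd in loo:
                    pred_pairs.extend(zip(rnd.test_samples, rnd.labels))
                leading_events = [ev for ev in events if ev.leading]
                models = []
            pred_pairs.sort(key=lambda p: p[0].start_s)
            test_samples = [p[0] for p in pred_pairs]
            true_labels = [p[0].stage for p in pred_pairs]
            pred_labels = [p[1] for p in pred_pairs]

            stage_name = "segment evaluation"
            curve, mtpw = mtpw_scan(
                true_labels, pred_labels, n_classes=config.task
            )
            at = curve[config.segment_window_s]
            results["segment"] = {
                "window_s": config.segment_window_s,
                "sensitivity": at.sensitivity,
                "specificity": at.specificity,
                "per_class_tpr": {
                    k.value: v for k, v in at.per_class_tpr.items()
                },
                "confusion": _seg_dict(at),
                "mtpw_s": mtpw,
                "curve": {
                    str(int(L)): {
                        "sensitivity": r.sensitivity,
                        "specificity": r.specificity,
                    }
                    for L, r in curve.items()
                },
            }

            stage_name = "event evaluation"
            stream_stages = task_stages
            stream = [
                (s.start_s, lab)
                for s, lab in zip(test_samples, pred_labels)
                if s.stage in stream_stages
            ]
            alarms = raise_alarms(
                stream,
                window_min=config.alarm_window_min,
                frac=config.alarm_frac,
                refractory_s=config.sph_s + config.sop_s,
                sample_s=config.window_s,
            )
            alarm_rows = [(a.time_s, a.window_frac) for a in alarms]
            ev_hours = _evaluated_hours(test_samples, config.task, config.window_s)
            ev_res = score_events(
                alarms,
                leading_events,
                sop_s=config.sop_s,
                sph_s=config.sph_s,
                evaluated_hours=ev_hours,
            )
            results["event"] = _event_dict(ev_res)

            stage_name = "postictal drift"
            if postictal_samples and config.split == "first_k" and models:
                _, post_labels = predict_samples(models[0], postictal_samples)
                offsets = []
                for s, lab in zip(postictal_samples, post_labels):
                    off = _seizure_offset_before(s.start_s, events)
                    if off is not None:
                        offsets.append((s.start_s - off, lab))
                results["postictal_drift"] = postictal_drift_profile(offsets)
            elif config.task == 3:
                # drift is read off the LOO predictions directly
                offsets = []
                for s, lab in zip(test_samples, pred_labels):
                    if s.stage is Stage.POSTICTAL:
                        off = _seizure_offset_before(s.start_s, events)
                        if off is not None:
                            offsets.append((s.start_s - off, lab))
                results["postictal_drift"] = (
                    postictal_drift_profile(offsets) if offsets else {}
                )

        results["runtime_s"] = time.time() - t_start
        if config.output_dir:
            _write_bundle(config, results, intervals, alarm_rows)
        return results
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage_name}: {exc}") from exc


def _seg_dict(r: SegmentEvalResult) -> dict:
    return {
        "TP": r.TP,
        "TN": r.TN,
        "FP": r.FP,
        "FN": r.FN,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
    }


def _event_dict(r: EventEvalResult) -> dict:
    return {
        "M": r.M,
        "m": r.m,
        "sensitivity": r.sensitivity,
        "n_false_alarms": r.n_false_alarms,
        "evaluated_hours": r.evaluated_hours,
        "fpr_per_hour": r.fpr_per_hour,
        "warning_times_s": r.warning_times_s,
        "mean_warning_time_min": (
            float(np.mean(r.warning_times_s)) / 60.0 if r.warning_times_s else None
        ),
        "sop_s": r.sop_s,
        "sph_s": r.sph_s,
        "chance_alarm_prob": r.chance_alarm_prob,
        "chance_pvalue": r.chance_pvalue,
    }


def _write_bundle(config, results, intervals, alarm_rows) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(json.dumps(results, indent=2, default=str))
    (out / "manifest.json").write_text(
        json.dumps(config.to_manifest(), indent=2, default=str)
    )
    (out / "stage_intervals.tsv").write_text(intervals_to_tsv(intervals))
    lines = ["time_s,window_frac"] + [f"{t:g},{f:g}" for t, f in alarm_rows]
    (out / "alarms.csv").write_text("\n".join(lines))
    seg, ev = results.get("segment"), results.get("event")
    if seg and ev and "sensitivity" in seg:
        (out / "summary.csv").write_text(
            "segment_sensitivity,segment_specificity,event_sensitivity,"
            "fpr_per_hour,mean_warning_time_min,p_value\n"
            f"{seg['sensitivity']:g},{seg['specificity']:g},"
            f"{ev['sensitivity']:g},{ev['fpr_per_hour']:g},"
            f"{ev['mean_warning_time_min'] if ev['mean_warning_time_min'] is not None else ''},"
            f"{ev['chance_pvalue']:g}\n"
        )


def compare_bands(config: RunConfig) -> list[dict]:
    """Sample-level metrics of every band under identical seeds.

    Runs the 2-class train/predict once per band (delta..gamma) with shared
    staging, splits and seeds, returning one row per band.
    """
    base = dataclasses.replace(config, task=2)
    recordings, events = _ingest(base)
    spans = [r.span for r in recordings]
    events = select_leading_seizures(events, base.policy, spans)
    intervals = assign_stages(spans, events, base.policy)
    rows = []
    for band in BANDS:
        cfg = dataclasses.replace(base, band=band)
        samples, _ = _collect_samples(recordings, intervals, cfg)
        task_samples = [
            s for s in samples if s.stage in (Stage.PREICTAL, Stage.INTERICTAL)
        ]
        mcfg = _model_config_for(cfg, task_samples)
        loo = loocv_by_seizure(task_samples, events, mcfg)
        true_l, pred_l = [], []
        for rnd in loo:
            for s, lab in zip(rnd.test_samples, rnd.labels):
                true_l.append(s.stage)
                pred_l.append(lab)
        from .evaluation import segment_metrics

        res = segment_metrics(true_l, pred_l)
        rows.append(
            {
                "band": band,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "n_samples": res.n,
            }
        )
    return rows
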