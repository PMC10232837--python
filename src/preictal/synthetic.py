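"""Synthetic multichannel EEG with stage-dependent spectral structure.

The generator emulates the statistical premise the predictor exploits:
scalp EEG as per-channel 1/f^alpha background noise whose band-resolved
power changes with brain state — by default the gamma band (30-128 Hz) is
raised 1.5x during the preictal hour and 1.25x during the postictal hour
relative to interictal baseline.  Seizures themselves appear as
large-amplitude rhythmic bursts, and optional EMG-like artifacts are
injected as brief broadband (>60 Hz) high-amplitude transients so the
artifact screen has something to reject.

Construction: background noise x is generated per channel; for every band
with a stage-dependent multiplier the band component is extracted with the
package's own zero-phase FIR and rescaled inside each stage span by the
square root of the configured power multiplier, so measured band-power
ratios track the configuration directly.  Everything is driven by one
seeded generator; identical seeds give bit-identical signals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import EEGRecording, RecordInfo, SeizureEvent, write_edf, write_seizure_summary
from .preprocessing import BANDS, bandpass_filter
from .staging import (
    Stage,
    StageInterval,
    StagingPolicy,
    assign_stages,
    select_leading_seizures,
)

__all__ = ["SynthConfig", "generate_recording", "generate_subject_data", "generate_subject"]


def _default_band_power() -> dict[str, dict[str, float]]:
    return {
        "preictal": {"gamma": 1.5},
        "postictal": {"gamma": 1.25},
    }


@dataclass
class SynthConfig:
    """Knobs of the synthetic EEG generator.

    ``band_power`` maps stage name -> band name -> power multiplier
    relative to interictal baseline.  ``schedule`` (for
    :func:`generate_recording`) is an explicit list of ``(stage name,
    duration_s)`` spans.  Artifact bursts arrive as a Poisson process at
    ``artifact_rate_per_hour`` with uniform amplitude/duration draws.
    """

    n_channels: int = 23
    fs: float = 256.0
    schedule: list[tuple[str, float]] | None = None
    band_power: dict[str, dict[str, float]] = field(default_factory=_default_band_power)
    noise_alpha: float = 1.0
    background_rms_uv: float = 30.0
    ictal_burst_uv: float = 300.0
    ictal_burst_hz: float = 5.0
    artifact_rate_per_hour: float = 2.0
    artifact_amp_uv: tuple[float, float] = (600.0, 2000.0)
    artifact_dur_s: tuple[float, float] = (0.2, 1.0)
    preictal_ramp_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.fs <= 0:
            raise ValueError("need n_channels >= 1 and fs > 0")
        for stage, bands in self.band_power.items():
            Stage(stage)  # validates the name
            for band, mult in bands.items():
                if band not in BANDS:
                    raise ValueError(f"unknown band {band!r}")
                if mult <= 0:
                    raise ValueError(f"multiplier for {stage}/{band} must be > 0")
        if self.schedule is not None:
            for stage, dur in self.schedule:
                Stage(stage)
                if dur <= 0:
                    raise ValueError(f"non-positive duration for {stage}")
                if abs(dur * self.fs - round(dur * self.fs)) > 1e-6:
                    raise ValueError(
                        f"duration {dur} s does not give an integer sample count"
                    )


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, alpha: float) -> np.ndarray:
    """Per-channel 1/f^alpha noise, unit variance, float32."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    shaping[0] = 0.0
    out = np.empty((n_ch, n), dtype=np.float32)
    for c in range(n_ch):  # per channel to bound memory
        spec = np.fft.rfft(rng.standard_normal(n))
        x = np.fft.irfft(spec * shaping, n=n)
        out[c] = (x / x.std()).astype(np.float32)
    return out


def _signal_from_intervals(
    intervals: list[StageInterval],
    config: SynthConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    fs = config.fs
    total_s = intervals[-1].end_s
    n = int(round(total_s * fs))
    x = _pink_noise(rng, config.n_channels, n, config.noise_alpha)
    x *= config.background_rms_uv

    # stage-dependent band power: rescale each shaped band inside its spans
    shaped_bands = sorted(
        {b for bands in config.band_power.values() for b in bands}
    )
    if shaped_bands:
        rec = EEGRecording(x, fs, [f"ch{i}" for i in range(config.n_channels)])
        comps = {b: bandpass_filter(rec, BANDS[b]).signal for b in shaped_bands}
        for iv in intervals:
            gains = config.band_power.get(iv.stage.value, {})
            i0 = int(round(iv.start_s * fs))
            i1 = int(round(iv.end_s * fs))
            for b, mult in gains.items():
                if mult == 1.0:
                    continue
                # preictal changes build up gradually rather than switching
                # on at the stage boundary
                if iv.stage is Stage.PREICTAL and config.preictal_ramp_s > 0:
                    tt = np.arange(i1 - i0, dtype=np.float32) / np.float32(fs)
                    frac = np.minimum(tt / np.float32(config.preictal_ramp_s), 1.0)
                    gain = np.sqrt(1.0 + (mult - 1.0) * frac).astype(np.float32)
                else:
                    gain = np.float32(np.sqrt(mult))
                x[:, i0:i1] += (gain - 1.0) * comps[b][:, i0:i1].astype(np.float32)

    # ictal spans: large rhythmic bursts
    t = np.arange(n, dtype=np.float32) / fs
    for iv in intervals:
        if iv.stage is not Stage.ICTAL:
            continue
        i0 = int(round(iv.start_s * fs))
        i1 = int(round(iv.end_s * fs))
        env = np.hanning(i1 - i0).astype(np.float32)
        phases = rng.uniform(0, 2 * np.pi, size=config.n_channels).astype(np.float32)
        burst = np.sin(
            2 * np.pi * config.ictal_burst_hz * t[i0:i1][None, :] + phases[:, None]
        )
        x[:, i0:i1] += config.ictal_burst_uv * env[None, :] * burst.astype(np.float32)

    # EMG-like broadband (>60 Hz) high-amplitude artifacts
    if config.artifact_rate_per_hour > 0:
        hours = total_s / 3600.0
        n_art = rng.poisson(config.artifact_rate_per_hour * hours)
        for _ in range(n_art):
            dur = rng.uniform(*config.artifact_dur_s)
            amp = rng.uniform(*config.artifact_amp_uv)
            start = rng.uniform(0, total_s - dur)
            i0 = int(round(start * fs))
            i1 = min(i0 + int(round(dur * fs)), n)
            m = i1 - i0
            if m < 8:
                continue
            burst = rng.standard_normal((config.n_channels, m))
            spec = np.fft.rfft(burst, axis=1)
            freqs = np.fft.rfftfreq(m, d=1.0 / fs)
            spec[:, freqs < 60.0] = 0.0
            burst = np.fft.irfft(spec, n=m, axis=1)
            burst /= np.max(np.abs(burst)) + 1e-12
            env = np.hanning(m)
            x[:, i0:i1] += (amp * env[None, :] * burst).astype(np.float32)
    return x


def _intervals_from_schedule(schedule: list[tuple[str, float]]) -> list[StageInterval]:
    out = []
    t = 0.0
    for stage, dur in schedule:
        out.append(StageInterval(Stage(stage), t, t + dur))
        t += dur
    return out


def generate_recording(
    config: SynthConfig,
) -> tuple[EEGRecording, list[SeizureEvent], list[StageInterval]]:
    """Generate one continuous recording from an explicit stage schedule.

    Returns the recording, the seizures implied by the schedule's ictal
    spans, and the ground-truth stage intervals.  Deterministic given
    ``config.seed``.
    """
    if config.schedule is None:
        raise ValueError("config.schedule is required for generate_recording")
    intervals = _intervals_from_schedule(config.schedule)
    rng = np.random.default_rng(config.seed)
    x = _signal_from_intervals(intervals, config, rng)
    events = [
        SeizureEvent(iv.start_s, iv.end_s)
        for iv in intervals
        if iv.stage is Stage.ICTAL
    ]
    labels = [f"SYN{i + 1:02d}-REF" for i in range(config.n_channels)]
    rec = EEGRecording(x, config.fs, labels, t0=0.0, record_id="synth_01")
    return rec, events, intervals


def generate_subject_data(
    config: SynthConfig,
    n_seizures: int,
    gap_s: float | list[float],
    ictal_len_s: float = 60.0,
    lead_in_s: float = 4 * 3600.0,
    tail_s: float = 6 * 3600.0,
    policy: StagingPolicy = StagingPolicy(),
) -> tuple[EEGRecording, list[SeizureEvent], list[StageInterval]]:
    """Generate a whole synthetic subject from a seizure layout.

    ``gap_s`` is the offset-to-onset spacing between consecutive seizures
    (a scalar or one value per gap); ``lead_in_s`` of recording precedes
    the first onset and ``tail_s`` follows the last offset.  Ground-truth
    stages come from the package's own staging rules applied to the layout,
    and the stage-dependent band shaping follows those stages, so the
    generated subject is exactly self-consistent with the pipeline.
    """
    if n_seizures < 1:
        raise ValueError("need at least one seizure")
    gaps = [gap_s] * (n_seizures - 1) if np.isscalar(gap_s) else list(gap_s)
    if len(gaps) != n_seizures - 1:
        raise ValueError(f"need {n_seizures - 1} gaps, got {len(gaps)}")
    if n_seizures > 1 and not any(
        g > policy.interictal_pre_buffer_s + policy.interictal_post_buffer_s
        for g in gaps
    ):
        warnings.warn(
            "no inter-seizure gap exceeds the interictal buffers; the subject "
            "will contain no interictal data between seizures",
            stacklevel=2,
        )
    events = []
    t = lead_in_s
    for i in range(n_seizures):
        events.append(SeizureEvent(t, t + ictal_len_s))
        if i < n_seizures - 1:
            t = t + ictal_len_s + gaps[i]
    total = events[-1].offset_s + tail_s
    spans = [(0.0, total)]
    events = select_leading_seizures(events, policy, spans)
    intervals = assign_stages(spans, events, policy)
    rng = np.random.default_rng(config.seed)
    x = _signal_from_intervals(intervals, config, rng)
    labels = [f"SYN{i + 1:02d}-REF" for i in range(config.n_channels)]
    rec = EEGRecording(x, config.fs, labels, t0=0.0, record_id="synth_01")
    return rec, events, intervals


def generate_subject(
    config: SynthConfig,
    n_seizures: int,
    gap_s: float | list[float],
    out_dir,
    record_len_s: float = 3600.0,
    subject_id: str = "syn01",
    **layout_kwargs,
) -> Path:
    """Write a complete synthetic subject directory to disk.

    Emits one EDF file per ``record_len_s`` chunk, a CHB-MIT-dialect
    ``<subject>-summary.txt``, and a ``ground_truth.json`` with the true
    stage intervals.  The staging module applied to the written files
    recovers the ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec, events, intervals = generate_subject_data(
        config, n_seizures, gap_s, **layout_kwargs
    )
    n_per = int(round(record_len_s * config.fs))
    infos: list[RecordInfo] = []
    k = 0
    i0 = 0
    while i0 < rec.n_samples:
        i1 = min(i0 + n_per, rec.n_samples)
        k += 1
        rid = f"{subject_id}_{k:02d}"
        start_s = i0 / config.fs
        end_s = i1 / config.fs
        chunk = EEGRecording(
            rec.signal[:, i0:i1], config.fs, rec.channel_labels, start_s, rid
        )
        write_edf(chunk, [], out_dir / f"{rid}.edf")
        evs = [
            e for e in events if start_s <= e.onset_s < end_s
        ]
        infos.append(RecordInfo(rid, start_s, end_s, evs))
        i0 = i1
    (out_dir / f"{subject_id}-summary.txt").write_text(
        write_seizure_summary(infos, config.fs)
    )
    (out_dir / "ground_truth.json").write_text(
        json.dumps(
            {
                "intervals": [
                    [iv.stage.value, iv.start_s, iv.end_s] for iv in intervals
                ],
                "seizures": [
                    [e.onset_s, e.offset_s, e.leading] for e in events
                ],
            },
            indent=2,
        )
    )
    return out_dir
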