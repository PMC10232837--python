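"""Band-pass filtering, 5-s windowing, EMG rejection and class balancing.

The five standard EEG bands are delta (0-4 Hz), theta (4-8 Hz), alpha
(8-13 Hz), beta (13-30 Hz) and gamma (30-128 Hz).  Filters are linear-phase
windowed-sinc (Hamming) FIRs applied forward-backward to the continuous
record, so each channel keeps its length and acquires zero net phase shift;
filtering precedes windowing to avoid edge artifacts inside 5-s samples.

The gamma band's nominal 128 Hz upper edge coincides with Nyquist at the
usual 256 Hz sampling rate; it is realized as a 30-127.5 Hz passband with
2 Hz transitions.  The delta band is a 4 Hz low-pass applied after
per-channel mean removal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import EEGRecording
from .staging import CLASSIFIABLE_STAGES, Stage, StageInterval

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "BANDS",
    "Sample",
    "RejectionPolicy",
    "bandpass_filter",
    "segment_recording",
    "reject_emg_artifacts",
    "balance_classes",
]


@dataclass(frozen=True)
class BandSpec:
    """One EEG frequency band, edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges [{self.low_hz}, {self.high_hz}]")


BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
    "gamma": BandSpec("gamma", 30.0, 128.0),
}


@dataclass
class Sample:
    """One fixed-length multichannel window, the classifier's prediction unit."""

    data: np.ndarray  # channels x (window_s * fs), microvolts
    stage: Stage
    start_s: float
    record_id: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("sample data must be channels x time")
        if not np.isfinite(self.data).all():
            raise ValueError("sample data must be finite")
        if self.stage not in CLASSIFIABLE_STAGES:
            raise ValueError(f"stage {self.stage} cannot form a classifier sample")

    @property
    def key(self) -> tuple[str, float]:
        return (self.record_id, self.start_s)


def _design_fir(band: BandSpec, fs: float, transition_hz: float = 2.0) -> np.ndarray:
    """Hamming windowed-sinc kernel for one band at sampling rate ``fs``."""
    nyq = fs / 2.0
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length, symmetric
    if band.high_hz > nyq:
        raise ValueError(
            f"band {band.name}: upper edge {band.high_hz} Hz is beyond the "
            f"Nyquist frequency {nyq} Hz at fs={fs}"
        )
    # an edge exactly at Nyquist (gamma at 256 Hz) is pulled just inside
    high = min(band.high_hz, nyq - transition_hz / 4.0)
    if band.low_hz <= 0:
        if high >= nyq:
            raise ValueError(f"band {band.name}: upper edge {high} Hz >= Nyquist {nyq} Hz")
        return sps.firwin(numtaps, high, fs=fs, window="hamming", pass_zero=True)
    if band.low_hz >= nyq:
        raise ValueError(f"band {band.name}: lower edge >= Nyquist at fs={fs}")
    return sps.firwin(
        numtaps, [band.low_hz, high], fs=fs, window="hamming", pass_zero=False
    )


def bandpass_filter(
    recording: EEGRecording, band: BandSpec | str, transition_hz: float = 2.0
) -> EEGRecording:
    """Zero-phase FIR band-pass of a continuous recording.

    The symmetric kernel ``h`` is applied forward and backward, realized as
    one overlap-add convolution with ``h * reverse(h)`` centered on the
    record ('same' mode), so the output has the input's length and zero net
    phase shift and the magnitude response is |H|^2.  For the delta band the
    per-channel mean is removed first and a 4 Hz low-pass applied.
    """
    if isinstance(band, str):
        band = BANDS[band]
    h = _design_fir(band, recording.fs, transition_hz)
    if recording.n_samples < 3 * len(h):
        raise ValueError(
            f"record {recording.record_id or '<unnamed>'} shorter than 3x filter "
            f"length ({recording.n_samples} < {3 * len(h)} samples)"
        )
    h2 = np.convolve(h, h[::-1])  # zero-phase squared response
    out = np.empty_like(recording.signal)
    for c in range(recording.n_channels):  # per channel to bound memory
        x = np.asarray(recording.signal[c], dtype=np.float64)
        if band.low_hz <= 0:
            x = x - x.mean()
        out[c] = sps.oaconvolve(x, h2, mode="same")
    return replace(recording, signal=out)


def segment_recording(
    recording: EEGRecording,
    stage_intervals: list[StageInterval],
    window_s: float = 5.0,
    band: str = "",
) -> list[Sample]:
    """Cut a recording into non-overlapping stage-pure windows.

    Windows of ``window_s`` tile each preictal/postictal/interictal interval
    from its start; a window is emitted only if it lies entirely inside one
    such interval and inside the recording; trailing remainders and
    straddling windows are dropped.  Ictal and excluded time yields no
    samples.
    """
    npts = window_s * recording.fs
    if abs(npts - round(npts)) > 1e-9:
        raise ValueError(f"window_s * fs = {npts} is not an integer")
    npts = int(round(npts))
    rec_start, rec_end = recording.span
    samples: list[Sample] = []
    for iv in stage_intervals:
        if iv.stage not in CLASSIFIABLE_STAGES:
            continue
        lo = max(iv.start_s, rec_start)
        hi = min(iv.end_s, rec_end)
        # tile from the interval's own start so counts are floor(L / window_s)
        k0 = int(np.ceil((lo - iv.start_s) / window_s - 1e-9))
        t = iv.start_s + k0 * window_s
        while t + window_s <= hi + 1e-9:
            i0 = int(round((t - rec_start) * recording.fs))
            samples.append(
                Sample(
                    data=recording.signal[:, i0 : i0 + npts],
                    stage=iv.stage,
                    start_s=t,
                    record_id=recording.record_id,
                    band=band,
                )
            )
            t += window_s
    return samples


@dataclass(frozen=True)
class RejectionPolicy:
    """Deterministic EMG-artifact screen.

    A sample is rejected iff any channel's peak absolute amplitude exceeds
    ``amp_max_uv`` or the fraction of its broadband power above
    ``hf_cut_hz`` exceeds ``hf_frac``.  The screen is meant for raw
    (unfiltered) windows; on a band-limited copy the high-frequency rule is
    uninformative.
    """

    amp_max_uv: float = 500.0
    hf_frac: float = 0.85
    hf_cut_hz: float = 60.0


def reject_emg_artifacts(
    samples: list[Sample],
    policy: RejectionPolicy = RejectionPolicy(),
    fs: float = 256.0,
) -> tuple[list[Sample], int]:
    """Split samples into (kept, n_rejected) under the EMG screen."""
    kept: list[Sample] = []
    n_rej = 0
    for s in samples:
        if _is_artifact(s.data, policy, fs):
            n_rej += 1
        else:
            kept.append(s)
    return kept, n_rej


def _is_artifact(data: np.ndarray, policy: RejectionPolicy, fs: float) -> bool:
    if np.max(np.abs(data)) > policy.amp_max_uv:
        return True
    freqs = np.fft.rfftfreq(data.shape[1], d=1.0 / fs)
    power = np.abs(np.fft.rfft(data, axis=1)) ** 2
    total = power.sum(axis=1)
    hf = power[:, freqs > policy.hf_cut_hz].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, hf / total, 0.0)
    return bool(np.any(frac > policy.hf_frac))


def balance_classes(
    samples: list[Sample], seed: int | np.random.Generator = 0
) -> list[Sample]:
    """Undersample the interictal majority to the smallest minority class.

    Interictal samples are drawn uniformly without replacement down to the
    size of the smallest non-interictal class present (preictal for the
    binary task; min(preictal, postictal) for three classes); other classes
    are untouched.  If interictal is already the minority everything is kept
    with a warning.  Deterministic given ``seed``.  Output preserves time
    order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inter = [s for s in samples if s.stage is Stage.INTERICTAL]
    minority_counts = [
        sum(1 for s in samples if s.stage is st)
        for st in (Stage.PREICTAL, Stage.POSTICTAL)
        if any(s.stage is st for s in samples)
    ]
    if not minority_counts:
        return list(samples)
    target = min(minority_counts)
    if len(inter) < target:
        warnings.warn(
            f"only {len(inter)} interictal samples for target {target}; keeping all",
            stacklevel=2,
        )
        return list(samples)
    keep_idx = set(rng.choice(len(inter), size=target, replace=False).tolist())
    kept_inter = {id(s) for i, s in enumerate(inter) if i in keep_idx}
    return [
        s
        for s in samples
        if s.stage is not Stage.INTERICTAL or id(s) in kept_inter
    ]
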