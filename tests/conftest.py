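"""Shared fixtures: tiny in-memory recordings and labeled sample lists."""

from __future__ import annotations

import numpy as np
import pytest

from preictal.io import EEGRecording
from preictal.preprocessing import Sample
from preictal.staging import Stage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def recording_factory(rng):
    """Build a small noise recording: factory(n_channels, duration_s, fs)."""

    def make(n_channels=4, duration_s=10.0, fs=256.0, amp=50.0, t0=0.0, record_id="rec"):
        n = int(round(duration_s * fs))
        sig = rng.normal(0.0, amp, size=(n_channels, n))
        labels = [f"CH{i + 1}-REF" for i in range(n_channels)]
        return EEGRecording(sig, fs, labels, t0=t0, record_id=record_id)

    return make


@pytest.fixture
def sample_factory(rng):
    """Labeled Sample lists with a controllable class amplitude contrast.

    factory(counts={stage: n}, ...) produces windows of gaussian noise whose
    per-stage amplitude scale implements a separable (or null) problem.
    """

    def make(
        counts: dict[Stage, int],
        n_channels=3,
        n_points=64,
        scale={Stage.PREICTAL: 2.0},
        base_amp=10.0,
        start_s=0.0,
        step_s=5.0,
    ):
        out = []
        t = start_s
        order = []
        for stage, n in counts.items():
            order += [stage] * n
        for stage in order:
            amp = base_amp * scale.get(stage, 1.0)
            data = rng.normal(0.0, amp, size=(n_channels, n_points))
            out.append(Sample(data=data, stage=stage, start_s=t, record_id="rec"))
            t += step_s
        return out

    return make
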