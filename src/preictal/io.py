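"""Reading and writing continuous EEG recordings and seizure annotations.

Recordings are exchanged as 16-bit EDF files; seizure annotations as the
plain-text per-subject summary dialect used by the CHB-MIT scalp EEG
database (``File Name`` / ``File Start Time`` / ``Seizure N Start Time``
stanzas).  All times inside the package live on a single per-subject
monotonic timeline, in seconds, with half-open intervals ``[start, end)``
and ``t0 = 0`` at the start of the subject's first record.  Gaps between
records are represented explicitly, never silently concatenated.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "SeizureEvent",
    "RecordInfo",
    "EDFError",
    "SummaryParseError",
    "read_edf",
    "write_edf",
    "write_edf_raw",
    "parse_seizure_summary",
    "write_seizure_summary",
    "load_subject",
    "check_timeline",
]


class EDFError(ValueError):
    """Malformed, unreadable or unwritable EDF content."""


class SummaryParseError(ValueError):
    """Seizure-summary text that does not follow the expected grammar."""


@dataclass
class EEGRecording:
    """A continuous multichannel EEG record.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Bipolar montage names, one per signal row.
    t0 : float
        Absolute start time in seconds on the subject timeline.
    record_id : str
        Identifier of the record (typically the EDF file stem).
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if np.isnan(self.signal).any():
            raise ValueError("signal contains NaN after ingestion")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def span(self) -> tuple[float, float]:
        """Half-open ``[t0, t0 + duration)`` interval on the subject timeline."""
        return (self.t0, self.t0 + self.duration_s)


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated seizure, in seconds on the subject timeline."""

    onset_s: float
    offset_s: float
    leading: bool = False

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"seizure offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )


@dataclass
class RecordInfo:
    """Summary-file metadata for one record on the subject timeline."""

    record_id: str
    start_s: float
    end_s: float
    events: list[SeizureEvent] = field(default_factory=list)


def sort_events(events: list[SeizureEvent]) -> list[SeizureEvent]:
    """Return events sorted by onset, raising if any pair overlaps."""
    out = sorted(events, key=lambda e: e.onset_s)
    for prev, nxt in zip(out, out[1:]):
        if nxt.onset_s < prev.offset_s:
            raise ValueError(
                f"overlapping seizures: [{prev.onset_s}, {prev.offset_s}) and "
                f"[{nxt.onset_s}, {nxt.offset_s})"
            )
    return out


# ---------------------------------------------------------------------------
# EDF writing
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics rather than corrupting the header
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf_raw(
    path,
    signals: list[np.ndarray],
    samples_per_record: list[int],
    record_duration_s: float,
    channel_labels: list[str],
    phys_min: float,
    phys_max: float,
    start_clock_s: float = 0.0,
) -> None:
    """Low-level EDF writer: one physical range, arbitrary per-channel rates.

    ``signals[i]`` holds channel *i* as a 1-D microvolt array whose length
    must be ``n_records * samples_per_record[i]``.  Exists mainly so tests
    can construct files (e.g. with inconsistent per-channel rates) that the
    high-level API refuses to emit.
    """
    ns = len(signals)
    if ns != len(channel_labels) or ns != len(samples_per_record):
        raise EDFError("signals, labels and samples_per_record lengths differ")
    n_records_f = len(signals[0]) / samples_per_record[0]
    n_records = int(round(n_records_f))
    for sig, spr in zip(signals, samples_per_record):
        if len(sig) != n_records * spr:
            raise EDFError("signal length is not n_records * samples_per_record")
    peak = max(float(np.max(np.abs(s))) if s.size else 0.0 for s in signals)
    if peak > max(abs(phys_min), abs(phys_max)):
        raise EDFError(
            f"signal amplitude {peak:g} uV exceeds EDF physical range "
            f"[{phys_min:g}, {phys_max:g}] uV"
        )

    clock = int(round(start_clock_s)) % 86400
    t = _dt.timedelta(seconds=clock)
    hh, rem = divmod(t.seconds, 3600)
    mm, ss = divmod(rem, 60)

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X X", 80),
            _edf_field("01.01.00", 8),
            _edf_field(f"{hh:02d}.{mm:02d}.{ss:02d}", 8),
            _edf_field(256 + ns * 256, 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(f"{record_duration_s:g}", 8),
            _edf_field(ns, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_edf_field(lbl, 16) for lbl in channel_labels),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_min:g}", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{phys_max:g}", 8) for _ in range(ns)),
            b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in range(ns)),
            b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(spr, 8) for spr in samples_per_record),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = [
        np.clip(
            np.round((np.asarray(sig, dtype=np.float64) - phys_min) * scale)
            + _EDF_DIG_MIN,
            _EDF_DIG_MIN,
            _EDF_DIG_MAX,
        ).astype("<i2")
        for sig in signals
    ]

    path = Path(path)
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(per_signal)
            for rec in range(n_records):
                for sig, spr in zip(digital, samples_per_record):
                    fh.write(sig[rec * spr : (rec + 1) * spr].tobytes())
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise EDFError(f"cannot write EDF to {path}: {exc}") from exc


def write_edf(
    recording: EEGRecording,
    events: list[SeizureEvent] | None,
    path,
    phys_range: tuple[float, float] = (-5000.0, 5000.0),
) -> Path:
    """Write a recording as a 16-bit EDF file.

    Uses 1-second data records when the sample count divides evenly by
    ``fs``, otherwise a single record spanning the whole signal.  Values are
    quantized onto the 16-bit grid of ``phys_range`` (microvolts); a signal
    exceeding that range is an error.  Seizure ``events`` are not embedded in
    the EDF (plain EDF has no annotation channel); pass them to
    :func:`write_seizure_summary` alongside.
    """
    phys_min, phys_max = phys_range
    n = recording.n_samples
    fs_int = int(round(recording.fs))
    if abs(recording.fs - fs_int) < 1e-9 and n % fs_int == 0:
        spr, dur = fs_int, 1.0
    else:
        spr, dur = n, n / recording.fs
    write_edf_raw(
        path,
        [np.ascontiguousarray(ch) for ch in recording.signal],
        [spr] * recording.n_channels,
        dur,
        recording.channel_labels,
        phys_min,
        phys_max,
        start_clock_s=recording.t0,
    )
    return Path(path)


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------


def _scan_edf_rates(path: Path) -> None:
    """Reject EDF files whose ordinary channels disagree on sampling rate.

    mne upsamples mixed-rate channels instead of erring, which would hide a
    genuinely inconsistent file, so the per-signal ``samples per record``
    header fields are checked up front.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFError(f"{path}: truncated EDF header")
        try:
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EDFError(f"{path}: unreadable signal count field") from exc
        per = fh.read(ns * 256)
    if len(per) < ns * 256:
        raise EDFError(f"{path}: truncated per-signal header")
    labels = [per[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip() for i in range(ns)]
    spr_off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = []
    for i in range(ns):
        raw = per[spr_off + i * 8 : spr_off + (i + 1) * 8].decode("ascii", "replace").strip()
        try:
            rates.append(int(raw))
        except ValueError as exc:
            raise EDFError(f"{path}: bad samples-per-record field {raw!r}") from exc
    ordinary = {r for lbl, r in zip(labels, rates) if lbl != "EDF Annotations"}
    if len(ordinary) > 1:
        raise EDFError(
            f"{path}: inconsistent per-channel sampling rates "
            f"(samples per record: {sorted(ordinary)})"
        )


def read_edf(path, channel_selection: list[str] | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    ``channel_selection`` selects and orders channels by label; a requested
    label missing from the file is an error.  ``t0`` is set to 0; callers
    holding a summary file should place the record on the subject timeline
    themselves (see :func:`load_subject`).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    _scan_edf_rates(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise EDFError(f"{path}: not a readable EDF file ({exc})") from exc

    labels = list(raw.ch_names)
    if channel_selection is not None:
        missing = [c for c in channel_selection if c not in labels]
        if missing:
            raise EDFError(f"{path}: requested channels not present: {missing}")
        raw = raw.pick(channel_selection)
        labels = list(raw.ch_names)
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(
        signal=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        t0=0.0,
        record_id=path.stem,
    )


# ---------------------------------------------------------------------------
# CHB-MIT-style seizure summary files
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"^(\d+):(\d{1,2}):(\d{1,2})$")


def _clock_to_seconds(text: str, line_no: int) -> int:
    m = _TIME_RE.match(text.strip())
    if not m:
        raise SummaryParseError(f"line {line_no}: bad clock time {text!r}")
    h, mi, s = (int(g) for g in m.groups())
    return h * 3600 + mi * 60 + s


def parse_seizure_summary(text: str) -> dict[str, RecordInfo]:
    """Parse CHB-MIT-dialect summary text into per-record metadata.

    Records are placed on the subject timeline: ``t0 = 0`` at the start of
    the first record, wall-clock gaps between records preserved, and a start
    clock earlier than the previous record's end is taken as a day rollover
    (+24 h).  Seizure times, given in seconds from the start of their record,
    are converted to subject-timeline seconds.
    """
    records: dict[str, RecordInfo] = {}
    lines = text.splitlines()
    i = 0
    origin: int | None = None
    prev_end_clock = -1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        m = re.match(r"^File Name:\s*(\S+)", line)
        if not m:
            continue
        record_id = Path(m.group(1)).stem
        stanza: dict[str, str] = {}
        seiz: list[tuple[int, float | None, float | None]] = []
        while i < len(lines):
            ln = lines[i].strip()
            if ln.startswith("File Name:"):
                break
            i += 1
            if not ln:
                continue
            sm = re.match(
                r"^Seizure\s*(\d*)\s*(Start|End) Time:\s*([\d.]+)\s*sec", ln
            )
            if sm:
                idx = int(sm.group(1) or len(seiz) + (sm.group(2) == "End"))
                t = float(sm.group(3))
                entry = next((e for e in seiz if e[0] == idx), None)
                if entry is None:
                    seiz.append((idx, None, None))
                    entry = seiz[-1]
                j = seiz.index(entry)
                if sm.group(2) == "Start":
                    seiz[j] = (idx, t, entry[2])
                else:
                    seiz[j] = (idx, entry[1], t)
                continue
            km = re.match(r"^([^:]+):\s*(.*)$", ln)
            if km:
                stanza[km.group(1).strip()] = km.group(2).strip()

        for key in ("File Start Time", "File End Time"):
            if key not in stanza:
                raise SummaryParseError(f"record {record_id}: missing '{key}'")
        start_clock = _clock_to_seconds(stanza["File Start Time"], i)
        end_clock = _clock_to_seconds(stanza["File End Time"], i)
        while start_clock < prev_end_clock:
            start_clock += 86400
        while end_clock < start_clock:
            end_clock += 86400
        prev_end_clock = end_clock
        if origin is None:
            origin = start_clock
        start_s = float(start_clock - origin)
        end_s = float(end_clock - origin)
        duration = end_s - start_s

        n_declared = stanza.get("Number of Seizures in File")
        if n_declared is not None and int(n_declared) != len(seiz):
            raise SummaryParseError(
                f"record {record_id}: declares {n_declared} seizures, "
                f"stanza lists {len(seiz)}"
            )
        events = []
        for idx, s, e in sorted(seiz):
            if s is None or e is None:
                raise SummaryParseError(
                    f"record {record_id}: seizure {idx} missing start or end time"
                )
            if e <= s:
                raise SummaryParseError(
                    f"record {record_id}: seizure {idx} end ({e}) <= start ({s})"
                )
            if e > duration + 1e-9:
                raise SummaryParseError(
                    f"record {record_id}: seizure {idx} extends past record end "
                    f"({e} s > {duration:g} s)"
                )
            events.append(SeizureEvent(start_s + s, start_s + e))
        if record_id in records:
            raise SummaryParseError(f"duplicate record id {record_id}")
        records[record_id] = RecordInfo(record_id, start_s, end_s, events)
    return records


def write_seizure_summary(records: list[RecordInfo], fs: float = 256.0) -> str:
    """Render per-record metadata as CHB-MIT-dialect summary text.

    ``records`` carry subject-timeline times; seizure times are emitted
    relative to their record's start, clock stamps as monotone H:MM:SS.
    """

    def clock(t: float) -> str:
        t = int(round(t))
        h, rem = divmod(t, 3600)
        m, s = divmod(rem, 60)
        return f"{h:02d}:{m:02d}:{s:02d}"

    out = [
        f"Data Sampling Rate: {fs:g} Hz",
        "*" * 30,
        "",
    ]
    for rec in records:
        out.append(f"File Name: {rec.record_id}.edf")
        out.append(f"File Start Time: {clock(rec.start_s)}")
        out.append(f"File End Time: {clock(rec.end_s)}")
        out.append(f"Number of Seizures in File: {len(rec.events)}")
        for k, ev in enumerate(sorted(rec.events, key=lambda e: e.onset_s), 1):
            out.append(
                f"Seizure {k} Start Time: {ev.onset_s - rec.start_s:g} seconds"
            )
            out.append(
                f"Seizure {k} End Time: {ev.offset_s - rec.start_s:g} seconds"
            )
        out.append("")
    return "\n".join(out)


def check_timeline(recordings: list[EEGRecording]) -> None:
    """Assert one subject's records form a monotone non-overlapping timeline."""
    spans = sorted((r.span for r in recordings), key=lambda s: s[0])
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 < e0 - 1e-9:
            raise ValueError(
                f"records overlap on the subject timeline: [{s0}, {e0}) and [{s1}, {e1})"
            )


def load_subject(
    directory,
    channel_selection: list[str] | None = None,
) -> tuple[list[EEGRecording], list[SeizureEvent]]:
    """Load all records of one subject directory (EDFs + ``*-summary.txt``).

    Records listed in the summary but missing any requested channel are
    skipped with a warning (the classifier needs a fixed channel set), per
    the channel-mismatch policy.  Returns records with ``t0`` set from the
    summary, and the subject's merged, sorted seizure list.
    """
    directory = Path(directory)
    summaries = sorted(directory.glob("*-summary.txt"))
    if not summaries:
        raise FileNotFoundError(f"no *-summary.txt in {directory}")
    info = parse_seizure_summary(summaries[0].read_text())
    recordings: list[EEGRecording] = []
    events: list[SeizureEvent] = []
    for record_id, rec in info.items():
        edf_path = directory / f"{record_id}.edf"
        try:
            recording = read_edf(edf_path, channel_selection)
        except (EDFError, FileNotFoundError) as exc:
            warnings.warn(f"skipping record {record_id}: {exc}", stacklevel=2)
            continue
        recording = replace_t0(recording, rec.start_s)
        recordings.append(recording)
        events.extend(rec.events)
    check_timeline(recordings)
    return recordings, sort_events(events)


def replace_t0(recording: EEGRecording, t0: float) -> EEGRecording:
    """Copy of *recording* repositioned at ``t0`` on the subject timeline."""
    return replace(recording, t0=t0)
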