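"""Waveform/beat input, windowing, pulse-peak detection and heart-rate series.

Units are seconds for time and BPM for heart rate throughout. Windows are
half-open ``[k*w, (k+1)*w)``; a trailing partial window is dropped.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.signal import find_peaks

__all__ = [
    "WaveformRecord",
    "BeatSeries",
    "BeatParseError",
    "InsufficientBeatsError",
    "read_beat_csv",
    "read_waveform_csv",
    "read_wfdb",
    "resample",
    "segment_windows",
    "windows_to_beat_series",
    "detect_peaks_simple",
    "compute_heart_rates",
    "write_windows_csv",
]


class BeatParseError(ValueError):
    """Malformed beat/waveform CSV content."""


class InsufficientBeatsError(ValueError):
    """Fewer beats than the operation requires."""


@dataclass(frozen=True)
class WaveformRecord:
    """A single-channel PPG waveform sampled uniformly at ``fs`` Hz."""

    samples: NDArray[np.float64]
    fs: float
    start_time: float = 0.0
    channel_name: str = "ppg"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> NDArray[np.float64]:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BeatSeries:
    """Pulse-peak times for one window plus the derived HR series.

    ``hr[i] = 60 / (peak_times[i+1] - peak_times[i])`` exactly; its length is
    ``len(peak_times) - 1`` (empty when fewer than two peaks were detected).
    """

    peak_times: NDArray[np.float64]
    window_id: int = 0
    hr: NDArray[np.float64] = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.peak_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("peak_times must be 1-D")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("peak_times must be strictly increasing")
        hr = 60.0 / np.diff(times) if times.size >= 2 else np.empty(0)
        object.__setattr__(self, "peak_times", times)
        object.__setattr__(self, "hr", hr)

    @property
    def n_beats(self) -> int:
        return int(self.peak_times.size)


def read_beat_csv(path: str | Path) -> NDArray[np.float64]:
    """Read one peak time (seconds) per row; a single header row is skipped.

    Raises :class:`BeatParseError` naming the offending line for malformed
    rows and ``ValueError`` for non-monotone timestamps.
    """
    path = Path(path)
    times: list[float] = []
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not row[0].strip():
                continue
            cell = row[0].strip()
            try:
                times.append(float(cell))
            except ValueError:
                if lineno == 1:  # tolerate a header row only
                    continue
                raise BeatParseError(
                    f"{path}: line {lineno}: cannot parse {cell!r} as a peak time"
                ) from None
    arr = np.asarray(times, dtype=float)
    if arr.size >= 2 and not np.all(np.diff(arr) > 0):
        bad = int(np.argmax(np.diff(arr) <= 0))
        raise ValueError(
            f"{path}: peak times must be strictly increasing "
            f"(violation between entries {bad} and {bad + 1})"
        )
    return arr


def read_waveform_csv(path: str | Path, fs: float | None = None) -> WaveformRecord:
    """Read a ``t,ppg`` CSV into a :class:`WaveformRecord`.

    ``fs`` is inferred from the time column when not given; the time grid must
    be uniform to within 1%.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "t" not in cols or "ppg" not in cols:
        raise BeatParseError(f"{path}: expected columns 't,ppg', got {list(df.columns)}")
    t = df[cols["t"]].to_numpy(dtype=float)
    x = df[cols["ppg"]].to_numpy(dtype=float)
    if t.size < 2:
        raise BeatParseError(f"{path}: waveform needs at least two samples")
    dt = np.diff(t)
    if fs is None:
        if np.ptp(dt) > 0.01 * np.median(dt):
            raise BeatParseError(f"{path}: non-uniform sampling; pass fs explicitly")
        fs = 1.0 / float(np.median(dt))
    return WaveformRecord(samples=x, fs=float(fs), start_time=float(t[0]))


def read_wfdb(record_name: str | Path, channel: int = 0) -> WaveformRecord:
    """Read one channel of a WFDB record (requires the optional ``wfdb`` package)."""
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "WFDB support requires the optional 'wfdb' package "
            "(pip install ectopy[wfdb]); CSV input needs no extras"
        ) from exc
    rec = wfdb.rdrecord(str(record_name), channels=[channel])  # pragma: no cover
    return WaveformRecord(  # pragma: no cover
        samples=np.asarray(rec.p_signal[:, 0], dtype=float),
        fs=float(rec.fs),
        channel_name=str(rec.sig_name[0]),
    )


def resample(record: WaveformRecord, fs_new: float) -> WaveformRecord:
    """Linear-interpolation resampling (e.g. 128 Hz down to 50 Hz)."""
    if not fs_new > 0:
        raise ValueError("fs_new must be positive")
    t_old = record.times
    t_new = np.arange(record.start_time, record.start_time + record.duration, 1.0 / fs_new)
    return WaveformRecord(
        samples=np.interp(t_new, t_old, record.samples),
        fs=float(fs_new),
        start_time=record.start_time,
        channel_name=record.channel_name,
    )


def segment_windows(
    record: WaveformRecord | ArrayLike, window_s: float = 30.0
) -> list[WaveformRecord] | list[NDArray[np.float64]]:
    """Cut into consecutive, non-overlapping ``[k*w, (k+1)*w)`` windows.

    Accepts either a :class:`WaveformRecord` (sliced by sample count) or a
    sequence of peak times (grouped by ``floor(t / w)``).  A trailing window
    not fully covered by the data is dropped; empty input gives ``[]``.
    """
    if not window_s > 0:
        raise ValueError("window_s must be positive")
    if isinstance(record, WaveformRecord):
        per = int(round(window_s * record.fs))
        n_win = record.samples.size // per
        return [
            WaveformRecord(
                samples=record.samples[k * per : (k + 1) * per],
                fs=record.fs,
                start_time=record.start_time + k * window_s,
                channel_name=record.channel_name,
            )
            for k in range(n_win)
        ]
    times = np.asarray(record, dtype=float)
    if times.size == 0:
        return []
    n_win = int(times[-1] // window_s)
    idx = np.floor(times / window_s).astype(int)
    return [times[idx == k] for k in range(n_win)]


def windows_to_beat_series(
    peak_times: ArrayLike, window_s: float = 30.0
) -> list[BeatSeries]:
    """Segment a peak-time list and wrap each window as a :class:`BeatSeries`."""
    return [
        BeatSeries(peak_times=w, window_id=k)
        for k, w in enumerate(segment_windows(np.asarray(peak_times, dtype=float), window_s))
    ]


def detect_peaks_simple(
    record: WaveformRecord, refractory_s: float = 0.25
) -> NDArray[np.float64]:
    """Local-maximum pulse-peak detector with a 0.25-s refractory period.

    A deliberately simple stand-in exposed behind this interface so that an
    external detector can be substituted.  Deterministic for fixed input; a
    flat signal yields an empty peak list plus a warning.
    """
    if record.fs < 25:
        raise ValueError(f"sampling rate too low for peak detection: {record.fs} Hz")
    if record.duration < 2.0:
        raise ValueError("signal must be at least 2 s long")
    x = record.samples
    if np.ptp(x) == 0:
        warnings.warn("flat signal: no pulse peaks detected", stacklevel=2)
        return np.empty(0)
    distance = max(1, int(round(refractory_s * record.fs)))
    prominence = 0.25 * float(np.std(x))
    idx, _ = find_peaks(x, distance=distance, prominence=prominence)
    return record.start_time + idx / record.fs


def compute_heart_rates(peak_times: ArrayLike) -> NDArray[np.float64]:
    """``hr[i] = 60 / (peak_times[i+1] - peak_times[i])`` in BPM."""
    times = np.asarray(peak_times, dtype=float)
    if times.size < 2:
        raise InsufficientBeatsError("need at least 2 peaks to compute heart rates")
    ibis = np.diff(times)
    if np.any(ibis <= 0):
        raise ValueError("peak times must be strictly increasing")
    return 60.0 / ibis


def write_windows_csv(windows: Sequence[BeatSeries], path: str | Path) -> None:
    """Serialize per-window beat series as ``window_id,peak_time`` rows."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["window_id", "peak_time"])
        for w in windows:
            for t in w.peak_times:
                writer.writerow([w.window_id, f"{t:.6f}"])
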