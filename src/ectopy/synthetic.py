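"""Synthetic beat sequences and PPG waveforms for NSR, AF and periodic ectopy.

Ectopy is modelled at the interval level: a repeating cycle of
``normals_per_cycle`` normal intervals at ``base_hr``, one premature
(coupling) interval at ``base_hr + coupling_delta`` and one compensatory
pause interval at ``base_hr - pause_delta``.  With zero jitter the quadrant
trajectory of each preset reproduces its published pattern exactly (up to
cycle phase); see :data:`PRESETS`.

AF intervals are i.i.d. with HR uniform on
``[base_hr - 30, base_hr + 40]`` — a deliberately crude broad-dispersion
model whose only validated property is a low zero-quadrant ratio.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.typing import NDArray

from .classifier import RhythmLabel
from .signal_io import BeatSeries, WaveformRecord

__all__ = [
    "RHYTHMS",
    "RhythmSpec",
    "PRESETS",
    "EXPECTED_CYCLES",
    "LabelledWindow",
    "generate_ibis",
    "preset_for",
    "render_ppg",
    "generate_cohort",
]

RHYTHMS = ("NSR", "AF", "BIGEMINY", "TRIGEMINY", "QUADRIGEMINY")

#: Default number of plain normal intervals per ectopy cycle.  Bigeminy
#: alternates coupling/pause with no plain interval in between; trigeminy
#: and quadrigeminy insert one and two.
_DEFAULT_NORMALS = {"BIGEMINY": 0, "TRIGEMINY": 1, "QUADRIGEMINY": 2}


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of one generated rhythm window (seeded, bit-reproducible)."""

    rhythm: str
    base_hr: float = 70.0
    coupling_delta: float = 0.0
    pause_delta: float = 0.0
    jitter_sd: float = 0.0
    duration: float = 30.0
    seed: Optional[int] = None
    normals_per_cycle: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rhythm not in RHYTHMS:
            raise ValueError(f"unknown rhythm {self.rhythm!r}; expected one of {RHYTHMS}")
        if not 30.0 <= self.base_hr <= 220.0:
            raise ValueError(f"base_hr must lie in [30, 220] BPM, got {self.base_hr}")
        if self.jitter_sd < 0 or self.coupling_delta < 0 or self.pause_delta < 0:
            raise ValueError("jitter_sd, coupling_delta and pause_delta must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.normals_per_cycle is not None and self.normals_per_cycle < 0:
            raise ValueError("normals_per_cycle must be >= 0")
        if self.is_ectopy and self.base_hr - self.pause_delta <= 0:
            raise ValueError(
                "non-physiological spec: pause interval HR "
                f"{self.base_hr - self.pause_delta} BPM <= 0"
            )

    @property
    def is_ectopy(self) -> bool:
        return self.rhythm in _DEFAULT_NORMALS

    @property
    def cycle_hrs(self) -> Optional[list[float]]:
        """Noise-free HR cycle for ectopy rhythms, ``None`` otherwise."""
        if not self.is_ectopy:
            return None
        k = (
            self.normals_per_cycle
            if self.normals_per_cycle is not None
            else _DEFAULT_NORMALS[self.rhythm]
        )
        return [self.base_hr] * k + [
            self.base_hr + self.coupling_delta,
            self.base_hr - self.pause_delta,
        ]


#: Preset table reproducing the six published trajectory-pattern rows.
#: Fast-HR trigeminy/quadrigeminy override normals_per_cycle so the
#: zero-jitter trajectory cycle equals the printed pattern (ledgered).
PRESETS: dict[tuple[str, str], RhythmSpec] = {
    ("BIGEMINY", "normal"): RhythmSpec(
        "BIGEMINY", base_hr=75, coupling_delta=25, pause_delta=25
    ),
    ("BIGEMINY", "fast"): RhythmSpec(
        "BIGEMINY", base_hr=110, coupling_delta=2, pause_delta=2
    ),
    ("TRIGEMINY", "normal"): RhythmSpec(
        "TRIGEMINY", base_hr=60, coupling_delta=40, pause_delta=3
    ),
    ("TRIGEMINY", "fast"): RhythmSpec(
        "TRIGEMINY", base_hr=110, coupling_delta=25, pause_delta=25, normals_per_cycle=0
    ),
    ("QUADRIGEMINY", "normal"): RhythmSpec(
        "QUADRIGEMINY", base_hr=60, coupling_delta=40, pause_delta=3
    ),
    ("QUADRIGEMINY", "fast"): RhythmSpec(
        "QUADRIGEMINY", base_hr=100, coupling_delta=3, pause_delta=20, normals_per_cycle=1
    ),
}

#: Published zero-jitter trajectory cycle per preset (one period each).
EXPECTED_CYCLES: dict[tuple[str, str], tuple[int, ...]] = {
    ("BIGEMINY", "normal"): (2, 4),
    ("BIGEMINY", "fast"): (0,),
    ("TRIGEMINY", "normal"): (1, 2, 3),
    ("TRIGEMINY", "fast"): (2, 4),
    ("QUADRIGEMINY", "normal"): (1, 2, 3, 0),
    ("QUADRIGEMINY", "fast"): (6, 4, 5),
}


def preset_for(rhythm_name: str, rate_class: str | None = None) -> RhythmSpec:
    """Look up a published-pattern preset by row name.

    Accepts either two arguments (``"bigeminy", "fast"``) or a single
    Table-style string such as ``"Bigeminy (Fast HR)"``.
    """
    text = rhythm_name if rate_class is None else f"{rhythm_name} {rate_class}"
    tokens = re.sub(r"[^a-z]+", " ", text.lower()).split()
    rhythm = next((r for r in _DEFAULT_NORMALS if r.lower() in tokens), None)
    if rhythm is None:
        raise ValueError(f"unknown rhythm row: {rhythm_name!r}")
    rate = "fast" if "fast" in tokens else "normal"
    return PRESETS[(rhythm, rate)]


def _interval_hrs(spec: RhythmSpec, n: int, rng: np.random.Generator) -> NDArray[np.float64]:
    """Per-interval HR draws (BPM) for ``n`` intervals."""
    if spec.rhythm == "AF":
        lo = max(spec.base_hr - 30.0, 20.0)
        hi = spec.base_hr + 40.0
        return rng.uniform(lo, hi, size=n)
    if spec.rhythm == "NSR":
        base = np.full(n, spec.base_hr)
    else:
        cycle = np.asarray(spec.cycle_hrs)
        base = np.tile(cycle, n // cycle.size + 1)[:n]
    if spec.jitter_sd > 0:
        base = base + rng.normal(0.0, spec.jitter_sd, size=n)
    return np.maximum(base, 1.0)  # guard against extreme jitter draws


def generate_ibis(spec: RhythmSpec) -> NDArray[np.float64]:
    """Generate peak times (seconds) covering ``spec.duration``.

    The first peak is at t=0; beats are appended until the cumulative time
    reaches the duration, so the last peak lands within one interval past it.
    """
    rng = np.random.default_rng(spec.seed)
    min_hr = 20.0 if spec.rhythm == "AF" else min(spec.cycle_hrs or [spec.base_hr])
    # generous upper bound on the number of intervals needed
    n = int(np.ceil(spec.duration * (spec.base_hr + 80.0) / 60.0)) + 8
    while True:
        hrs = _interval_hrs(spec, n, rng)
        times = np.concatenate(([0.0], np.cumsum(60.0 / hrs)))
        if times[-1] >= spec.duration:
            break
        n *= 2  # pragma: no cover - bound above is already generous
    stop = int(np.searchsorted(times, spec.duration))
    return times[: stop + 1]


def render_ppg(
    peak_times: Sequence[float],
    fs: float = 50.0,
    pulse_width: float = 0.30,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> WaveformRecord:
    """Render peaks as a sum of Gaussian pulses plus optional white noise.

    The method consumes only peak times, so waveform realism is a non-goal;
    each pulse is a unit-amplitude bump centred on its beat.
    """
    if fs < 25:
        raise ValueError(f"fs must be >= 25 Hz, got {fs}")
    peaks = np.asarray(peak_times, dtype=float)
    duration = (peaks[-1] if peaks.size else 0.0) + 1.0
    t = np.arange(0.0, duration, 1.0 / fs)
    x = np.zeros_like(t)
    sigma = pulse_width / 2.0
    if peaks.size and np.min(np.diff(peaks), initial=np.inf) < 2.0 * sigma:
        warnings.warn("pulses overlap substantially at this rate", stacklevel=2)
    for p in peaks:
        lo = int(np.searchsorted(t, p - 4 * sigma))
        hi = int(np.searchsorted(t, p + 4 * sigma))
        x[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - p) / sigma) ** 2)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=x.size)
    return WaveformRecord(samples=x, fs=fs, channel_name="synthetic-ppg")


@dataclass(frozen=True)
class LabelledWindow:
    """One generated 30-s window with its ground truth attached."""

    window_id: int
    class_name: str
    truth: RhythmLabel
    beats: BeatSeries
    spec: RhythmSpec


def _spec_for_class(name: str, rng: np.random.Generator, jitter_sd: float | None) -> RhythmSpec:
    key = name.strip().lower()
    if key == "nsr":
        spec = RhythmSpec(
            "NSR",
            base_hr=float(rng.uniform(55.0, 90.0)),
            jitter_sd=2.0,
        )
    elif key == "af":
        spec = RhythmSpec("AF", base_hr=float(rng.uniform(70.0, 100.0)))
    else:
        spec = preset_for(name)
    if jitter_sd is not None and spec.rhythm != "AF":
        spec = replace(spec, jitter_sd=jitter_sd)
    return spec


def generate_cohort(
    n_windows: int,
    classes: Sequence[str],
    seed: Optional[int] = None,
    duration: float = 30.0,
    jitter_sd: float | None = None,
) -> list[LabelledWindow]:
    """Reproducible labelled set of ``n_windows`` windows per class.

    Class names are ``"NSR"``, ``"AF"`` or any preset row name accepted by
    :func:`preset_for` (e.g. ``"trigeminy normal"``).  ``jitter_sd``, when
    given, overrides the preset jitter for non-AF classes.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    windows: list[LabelledWindow] = []
    wid = 0
    for name in classes:
        for _ in range(n_windows):
            spec = _spec_for_class(name, rng, jitter_sd)
            spec = replace(
                spec, duration=duration, seed=int(rng.integers(0, 2**32))
            )
            times = generate_ibis(spec)
            beats = BeatSeries(peak_times=times[times < duration], window_id=wid)
            truth = (
                RhythmLabel.NSR
                if spec.rhythm == "NSR"
                else RhythmLabel.AF
                if spec.rhythm == "AF"
                else RhythmLabel.PACPVC
            )
            windows.append(
                LabelledWindow(
                    window_id=wid, class_name=name, truth=truth, beats=beats, spec=spec
                )
            )
            wid += 1
    return windows


def write_ground_truth(windows: Sequence[LabelledWindow], path: str | Path) -> None:
    """Sidecar JSON with the spec and truth label of every window."""
    payload = [
        {
            "window_id": w.window_id,
            "class_name": w.class_name,
            "truth": w.truth.value,
            "spec": asdict(w.spec),
        }
        for w in windows
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
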