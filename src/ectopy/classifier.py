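"""Per-window rhythm decisions: the AF-routed and non-AF-routed algorithms.

Both algorithms first look for at least ``min_kites`` repeated kite patterns
with tightly clustered angles (vector resemblance); the non-AF algorithm
additionally checks bigeminy '2-4'/'4-2' pairs and the broken-kite edge
families before falling back to the zero-quadrant ratio and the
outside-cross count.

The edge-family branch carries one amendment over the printed pseudocode
(rule "D1"): a family participates only when its minimum pair count exceeds
``min_edge_pairs_exclusive`` — otherwise a window with no patterns at all
would have every std forced to 0 and be called PAC/PVC vacuously.  The
branch trace of every decision is recorded in ``rule_fired``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from numpy.typing import ArrayLike

from .patterns import ClassifierConfig, WindowFeatures, extract_features
from .poincare import QuadrantGeometry, trajectory_of, zero_quadrant_ratio
from .signal_io import BeatSeries

__all__ = [
    "RhythmLabel",
    "WindowDecision",
    "classify_af_window",
    "classify_nonaf_window",
    "classify_window",
    "classify_recording",
]


class RhythmLabel(str, Enum):
    """Per-window rhythm decision."""

    NSR = "NSR"
    AF = "AF"
    PACPVC = "PACPVC"
    UNDETERMINED = "UNDETERMINED"

    def __str__(self) -> str:  # plain value in CSV/JSON output
        return self.value


@dataclass(frozen=True)
class WindowDecision:
    """A labelled window plus the feature vector and the branch that fired."""

    window_id: int
    label: RhythmLabel
    features: Optional[WindowFeatures]
    rule_fired: str

    def __post_init__(self) -> None:
        if not self.rule_fired:
            raise ValueError("rule_fired must be non-empty")


def _effective_kite_stds(f: WindowFeatures) -> tuple[float, float]:
    # lines 3-8 of both algorithms: a single (or absent) kite has no spread
    std123 = 0.0 if f.n123 <= 1 else f.std123
    std645 = 0.0 if f.n645 <= 1 else f.std645
    return std123, std645


def _alg1(f: WindowFeatures, cfg: ClassifierConfig) -> tuple[RhythmLabel, str]:
    t = cfg.std_angle_max
    if f.n123 + f.n645 >= cfg.min_kites:
        std123, std645 = _effective_kite_stds(f)
        if std123 <= t and std645 <= t:
            return RhythmLabel.PACPVC, "alg1:9-10"
        if f.rzero < cfg.rzero_af:
            return RhythmLabel.AF, "alg1:12-13"
        return RhythmLabel.NSR, "alg1:14-15"
    if f.rzero < cfg.rzero_nsr:
        return RhythmLabel.AF, "alg1:19-20"
    return RhythmLabel.NSR, "alg1:21-22"


def _alg2(f: WindowFeatures, cfg: ClassifierConfig) -> tuple[RhythmLabel, str]:
    t = cfg.std_angle_max
    if f.n123 + f.n645 >= cfg.min_kites:
        std123, std645 = _effective_kite_stds(f)
        if std123 <= t and std645 <= t:
            return RhythmLabel.PACPVC, "alg2:9-10"
        return RhythmLabel.AF, "alg2:11-12"
    if min(f.n24, f.n42) >= cfg.min_bigeminy_pairs and f.std24 <= t and f.std42 <= t:
        return RhythmLabel.PACPVC, "alg2:16-17"
    # Edge families for broken kites; D1: only families with min pair-count
    # strictly above the threshold participate.
    participating: list[float] = []
    if min(f.n64, f.n45) > cfg.min_edge_pairs_exclusive:
        participating += [f.std64, f.std45]
    if min(f.n12, f.n23) > cfg.min_edge_pairs_exclusive:
        participating += [f.std12, f.std23]
    if participating and max(participating) <= t:
        return RhythmLabel.PACPVC, "alg2:20-27(D1)"
    if f.rzero < cfg.rzero_nsr or f.noutside >= cfg.outside_min_af:
        return RhythmLabel.AF, "alg2:29-30"
    return RhythmLabel.NSR, "alg2:31-32"


def classify_af_window(
    f: WindowFeatures, cfg: ClassifierConfig | None = None
) -> RhythmLabel:
    """Decide a window that the upstream detector labelled AF (Algorithm 1)."""
    return _alg1(f, cfg or ClassifierConfig())[0]


def classify_nonaf_window(
    f: WindowFeatures, cfg: ClassifierConfig | None = None
) -> RhythmLabel:
    """Decide a window that the upstream detector labelled non-AF (Algorithm 2)."""
    return _alg2(f, cfg or ClassifierConfig())[0]


def classify_window(
    hr: ArrayLike,
    prior_af: Optional[bool],
    geom: QuadrantGeometry | None = None,
    cfg: ClassifierConfig | None = None,
    window_id: int = 0,
) -> WindowDecision:
    """Extract features and dispatch on the routing bit.

    ``prior_af=None`` engages the non-normative irregularity stub
    (rzero < rzero_nsr routes to the AF-window algorithm); windows with
    fewer than ``cfg.min_beats`` beats are UNDETERMINED.
    """
    geom = geom or QuadrantGeometry()
    cfg = cfg or ClassifierConfig()
    hr = np.asarray(hr, dtype=float)
    n_beats = hr.size + 1 if hr.size else 0
    if n_beats < cfg.min_beats:
        return WindowDecision(
            window_id=window_id,
            label=RhythmLabel.UNDETERMINED,
            features=None,
            rule_fired=f"gate:min-beats({n_beats}<{cfg.min_beats})",
        )
    features = extract_features(hr, geom, cfg)
    route_note = ""
    if prior_af is None:
        prior_af = zero_quadrant_ratio(trajectory_of(hr, geom)) < cfg.rzero_nsr
        route_note = f"route=stub(rzero<{cfg.rzero_nsr}->{'AF' if prior_af else 'nonAF'});"
    label, rule = (_alg1 if prior_af else _alg2)(features, cfg)
    return WindowDecision(
        window_id=window_id, label=label, features=features, rule_fired=route_note + rule
    )


def classify_recording(
    windows: Sequence[BeatSeries],
    prior_labels: Optional[Sequence[bool]] = None,
    geom: QuadrantGeometry | None = None,
    cfg: ClassifierConfig | None = None,
) -> list[WindowDecision]:
    """Independent per-window decisions over a whole recording."""
    if prior_labels is not None and len(prior_labels) != len(windows):
        raise ValueError(
            f"prior_labels length {len(prior_labels)} does not match "
            f"{len(windows)} windows"
        )
    decisions = []
    for i, w in enumerate(windows):
        prior = None if prior_labels is None else bool(prior_labels[i])
        decisions.append(
            classify_window(w.hr, prior, geom=geom, cfg=cfg, window_id=w.window_id)
        )
    return decisions
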