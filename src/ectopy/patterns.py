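"""Trajectory pattern mining and vector-angle resemblance statistics.

Periodic ectopy traces the same kite ('1-2-3' up, '6-4-5' down) or bigeminy
edge ('2-4'/'4-2') over and over in the Poincaré plane, so the angles of the
repeated displacement vectors cluster tightly; AF wanders, so they do not.
The per-window feature vector collects pattern counts, angle standard
deviations, the zero-quadrant ratio and the outside-cross count — everything
the window classifiers consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike

from .poincare import (
    PoincarePoint,
    QuadrantGeometry,
    count_outside_cross,
    poincare_points,
    trajectory_of,
    zero_quadrant_ratio,
)

__all__ = [
    "KITE_KINDS",
    "EDGE_KINDS",
    "PatternInstance",
    "WindowFeatures",
    "ClassifierConfig",
    "slope_angle",
    "included_angle",
    "find_kites",
    "find_edges",
    "angle_std",
    "extract_features",
]

#: Kite kinds -> quadrant triples (upward and downward kites).
KITE_KINDS: dict[str, tuple[int, int, int]] = {"1-2-3": (1, 2, 3), "6-4-5": (6, 4, 5)}
#: Edge kinds -> consecutive quadrant pairs.
EDGE_KINDS: dict[str, tuple[int, int]] = {
    "2-4": (2, 4),
    "4-2": (4, 2),
    "1-2": (1, 2),
    "2-3": (2, 3),
    "6-4": (6, 4),
    "4-5": (4, 5),
}


@dataclass(frozen=True)
class PatternInstance:
    """One occurrence of a kite or edge pattern in a trajectory.

    ``angle`` is the included angle in [0, 180] for 3-point kites and the
    slope angle in (−180, 180] for 2-point edges, in degrees.
    """

    kind: str
    start_index: int
    angle: float

    def __post_init__(self) -> None:
        if self.kind not in KITE_KINDS and self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown pattern kind: {self.kind!r}")
        if not math.isfinite(self.angle):
            raise ValueError("pattern angle must be finite")


@dataclass(frozen=True)
class WindowFeatures:
    """All Algorithm-1/2 inputs for one 30-s window."""

    n123: int = 0
    n645: int = 0
    n24: int = 0
    n42: int = 0
    n12: int = 0
    n23: int = 0
    n64: int = 0
    n45: int = 0
    std123: float = 0.0
    std645: float = 0.0
    std24: float = 0.0
    std42: float = 0.0
    std12: float = 0.0
    std23: float = 0.0
    std64: float = 0.0
    std45: float = 0.0
    rzero: float = 1.0
    noutside: int = 0

    def __post_init__(self) -> None:
        for name in ("n123", "n645", "n24", "n42", "n12", "n23", "n64", "n45", "noutside"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("std123", "std645", "std24", "std42", "std12", "std23", "std64", "std45"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.rzero <= 1.0:
            raise ValueError(f"rzero must lie in [0, 1], got {self.rzero}")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ClassifierConfig:
    """Every numeric threshold of Algorithms 1 and 2 plus window gating.

    Defaults are the published values: 10° angle-SD ceiling, rzero 0.13 / 0.5,
    5 outside-cross points, 3 kite repetitions, 5 bigeminy pairs, and the
    strict "> 3 pairs" edge-family requirement.
    """

    std_angle_max: float = 10.0
    rzero_af: float = 0.13
    rzero_nsr: float = 0.5
    outside_min_af: int = 5
    min_kites: int = 3
    min_bigeminy_pairs: int = 5
    min_edge_pairs_exclusive: int = 3
    min_beats: int = 10

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierConfig":
        """Load thresholds from YAML; unknown keys are rejected."""
        import yaml

        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with Path(path).open("w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


def slope_angle(p_from: PoincarePoint, p_to: PoincarePoint) -> float:
    """Four-quadrant arctangent of the displacement, degrees in (−180, 180]."""
    dx = p_to.x - p_from.x
    dy = p_to.y - p_from.y
    if dx == 0 and dy == 0:
        raise ValueError("slope angle is undefined for identical points")
    angle = math.degrees(math.atan2(dy, dx))
    return 180.0 if angle == -180.0 else angle


def included_angle(p_a: PoincarePoint, p_b: PoincarePoint, p_c: PoincarePoint) -> float:
    """Angle in [0, 180] between displacements a→b and b→c, degrees."""
    v1 = (p_b.x - p_a.x, p_b.y - p_a.y)
    v2 = (p_c.x - p_b.x, p_c.y - p_b.y)
    n1 = math.hypot(*v1)
    n2 = math.hypot(*v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("included angle is undefined for coincident points")
    cosang = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def find_kites(
    traj: ArrayLike, points: Sequence[PoincarePoint], kind: str
) -> list[PatternInstance]:
    """Greedy left-to-right, non-overlapping exact matches of a kite triple."""
    if kind not in KITE_KINDS:
        raise ValueError(f"unknown kite kind: {kind!r}")
    traj = np.asarray(traj)
    if traj.size != len(points):
        raise ValueError("trajectory and points must be aligned")
    pattern = KITE_KINDS[kind]
    out: list[PatternInstance] = []
    i = 0
    while i + 3 <= traj.size:
        if tuple(traj[i : i + 3]) == pattern:
            angle = included_angle(points[i], points[i + 1], points[i + 2])
            out.append(PatternInstance(kind=kind, start_index=i, angle=angle))
            i += 3
        else:
            i += 1
    return out


def find_edges(
    traj: ArrayLike, points: Sequence[PoincarePoint], kind: str
) -> list[PatternInstance]:
    """Every consecutive trajectory pair matching the kind (no gaps)."""
    if kind not in EDGE_KINDS:
        raise ValueError(f"unknown edge kind: {kind!r}")
    traj = np.asarray(traj)
    if traj.size != len(points):
        raise ValueError("trajectory and points must be aligned")
    pattern = EDGE_KINDS[kind]
    out: list[PatternInstance] = []
    for i in range(traj.size - 1):
        if (traj[i], traj[i + 1]) == pattern:
            angle = slope_angle(points[i], points[i + 1])
            out.append(PatternInstance(kind=kind, start_index=i, angle=angle))
    return out


def angle_std(angles: Sequence[float]) -> float:
    """Sample standard deviation (ddof=1) of angles in degrees; 0 for n ≤ 1."""
    if len(angles) <= 1:
        return 0.0
    return float(np.std(np.asarray(angles, dtype=float), ddof=1))


def extract_features(
    hr: ArrayLike,
    geom: QuadrantGeometry | None = None,
    config: ClassifierConfig | None = None,  # noqa: ARG001 - part of the stable signature
) -> WindowFeatures:
    """Assemble the full per-window feature vector from an HR series."""
    geom = geom or QuadrantGeometry()
    points = poincare_points(hr)
    traj = trajectory_of(hr, geom)

    counts: dict[str, int] = {}
    stds: dict[str, float] = {}
    for kind, finder in (("1-2-3", find_kites), ("6-4-5", find_kites)):
        instances = finder(traj, points, kind)
        key = kind.replace("-", "")
        counts[f"n{key}"] = len(instances)
        stds[f"std{key}"] = angle_std([inst.angle for inst in instances])
    for kind in EDGE_KINDS:
        instances = find_edges(traj, points, kind)
        key = kind.replace("-", "")
        counts[f"n{key}"] = len(instances)
        stds[f"std{key}"] = angle_std([inst.angle for inst in instances])

    return WindowFeatures(
        **counts,
        **stds,
        rzero=zero_quadrant_ratio(traj),
        noutside=count_outside_cross(traj),
    )
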