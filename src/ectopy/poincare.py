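"""Nine-quadrant Poincaré geometry over successive heart-rate differences.

Each beat triple (HR_{n-1}, HR_n, HR_{n+1}) maps to one plane point with
``x = HR_{n+1} - HR_n`` (current beat to next) and ``y = HR_n - HR_{n-1}``
(previous beat to current); positive means speeding up.  The plane is split
into a central "zero" square of half-width 5 BPM, four axis-aligned arms and
four corners:

            y
      2  |  5  |  7
     ----+-----+----
      6  |  0  |  1    x
     ----+-----+----
      8  |  3  |  4

The union of quadrants {0, 1, 3, 5, 6} is the "cross" demarcation; points in
{2, 4, 7, 8} lie outside it.  Boundaries at ±zero_half_width are closed
(|Δ| ≤ 5 counts as small); magnitudes beyond the ±half_range plotting field
still classify into the outermost region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .signal_io import InsufficientBeatsError

__all__ = [
    "QuadrantGeometry",
    "PoincarePoint",
    "OUTSIDE_CROSS",
    "CROSS_QUADRANTS",
    "poincare_points",
    "classify_quadrant",
    "trajectory_of",
    "zero_quadrant_ratio",
    "count_outside_cross",
    "export_trajectory_csv",
    "plot_trajectory",
]

#: Quadrants covered by the cross demarcation (center plus the four arms).
CROSS_QUADRANTS = frozenset({0, 1, 3, 5, 6})
#: Corner quadrants, i.e. points outside the cross demarcation.
OUTSIDE_CROSS = frozenset({2, 4, 7, 8})


@dataclass(frozen=True)
class QuadrantGeometry:
    """Plane geometry constants: ±half_range field, ±zero_half_width center."""

    half_range: float = 80.0
    zero_half_width: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.zero_half_width < self.half_range:
            raise ValueError(
                "require 0 < zero_half_width < half_range, got "
                f"{self.zero_half_width} / {self.half_range}"
            )

    @property
    def arm_length(self) -> float:
        """Long side of the arm quadrants: half_range − zero_half_width."""
        return self.half_range - self.zero_half_width


@dataclass(frozen=True)
class PoincarePoint:
    """One HR-difference pair; ``beat_index`` is the central beat of the triple."""

    x: float
    y: float
    beat_index: int = 0

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


def poincare_points(hr: ArrayLike) -> list[PoincarePoint]:
    """Build one point per interior HR value: point k has
    ``y = hr[k+1] - hr[k]`` and ``x = hr[k+2] - hr[k+1]``.
    """
    hr = np.asarray(hr, dtype=float)
    if hr.size < 3:
        raise InsufficientBeatsError(
            f"need at least 3 HR values for a Poincaré point, got {hr.size}"
        )
    d = np.diff(hr)
    return [
        PoincarePoint(x=float(d[k + 1]), y=float(d[k]), beat_index=k + 1)
        for k in range(hr.size - 2)
    ]


def _classify_xy(x: NDArray, y: NDArray, geom: QuadrantGeometry) -> NDArray[np.int64]:
    """Vectorized partition of (x, y) arrays into quadrant indices 0..8."""
    z = geom.zero_half_width
    sx = np.where(x > z, 1, np.where(x < -z, -1, 0))
    sy = np.where(y > z, 1, np.where(y < -z, -1, 0))
    # (sx, sy) sign pair -> quadrant index
    lookup = np.array(
        [
            [8, 6, 2],  # sx = -1 : sy = -1, 0, +1
            [3, 0, 5],  # sx =  0
            [4, 1, 7],  # sx = +1
        ],
        dtype=np.int64,
    )
    return lookup[sx + 1, sy + 1]


def classify_quadrant(
    point: PoincarePoint | tuple[float, float], geom: QuadrantGeometry | None = None
) -> int:
    """Assign a single difference point to its quadrant (total function)."""
    geom = geom or QuadrantGeometry()
    x, y = (point.x, point.y) if isinstance(point, PoincarePoint) else point
    return int(_classify_xy(np.asarray([x]), np.asarray([y]), geom)[0])


def trajectory_of(hr: ArrayLike, geom: QuadrantGeometry | None = None) -> NDArray[np.int64]:
    """Quadrant index per Poincaré point, in temporal order."""
    geom = geom or QuadrantGeometry()
    pts = poincare_points(hr)
    x = np.array([p.x for p in pts])
    y = np.array([p.y for p in pts])
    return _classify_xy(x, y, geom)


def zero_quadrant_ratio(traj: ArrayLike) -> float:
    """Fraction of trajectory points sitting in the central zero quadrant."""
    traj = np.asarray(traj)
    if traj.size == 0:
        raise ValueError("zero_quadrant_ratio is undefined for an empty trajectory")
    return float(np.count_nonzero(traj == 0) / traj.size)


def count_outside_cross(traj: ArrayLike) -> int:
    """Number of points in the corner quadrants {2, 4, 7, 8}."""
    traj = np.asarray(traj)
    if traj.size == 0:
        return 0
    return int(np.isin(traj, list(OUTSIDE_CROSS)).sum())


def export_trajectory_csv(
    points: Sequence[PoincarePoint], traj: ArrayLike, path: str | Path
) -> None:
    """Write ``beat_index,x,y,quadrant`` rows for plotting/debugging."""
    traj = np.asarray(traj)
    if len(points) != traj.size:
        raise ValueError("points and trajectory must be aligned")
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["beat_index", "x", "y", "quadrant"])
        for p, q in zip(points, traj):
            writer.writerow([p.beat_index, f"{p.x:.6f}", f"{p.y:.6f}", int(q)])


def plot_trajectory(
    points: Sequence[PoincarePoint],
    path: str | Path,
    geom: QuadrantGeometry | None = None,
) -> None:
    """Scatter the trajectory with the nine-quadrant grid (needs matplotlib)."""
    geom = geom or QuadrantGeometry()
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("plotting requires the optional 'matplotlib' package") from exc

    z, r = geom.zero_half_width, geom.half_range
    fig, ax = plt.subplots(figsize=(5, 5))
    xs = [p.x for p in points]
    ys = [p.y for p in points]
    ax.plot(xs, ys, "o-", ms=4, lw=0.8, alpha=0.7)
    for v in (-z, z):
        ax.axvline(v, color="gray", lw=0.8)
        ax.axhline(v, color="gray", lw=0.8)
    ax.set_xlim(-r, r)
    ax.set_ylim(-r, r)
    ax.set_xlabel("ΔHR current→next (BPM)")
    ax.set_ylabel("ΔHR previous→current (BPM)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
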