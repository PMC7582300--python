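"""Confusion matrices, per-class metrics and threshold sweeps.

UNDETERMINED predictions are excluded from the confusion matrix and reported
separately as coverage.  Metrics with a zero denominator are NaN, never
silently 0; rounding to two decimals (half-up, matching printed tables)
happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classifier import RhythmLabel, WindowDecision, _alg1, _alg2
from .patterns import ClassifierConfig, WindowFeatures, extract_features
from .poincare import QuadrantGeometry
from .synthetic import LabelledWindow

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "confusion",
    "metrics",
    "round2",
    "coverage",
    "evaluate_cohort",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    """Sensitivity/specificity/PPV/NPV/accuracy as percentages (NaN if undefined)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float

    def rounded(self) -> dict[str, float]:
        """Two-decimal half-up presentation values (NaN preserved)."""
        return {f.name: round2(getattr(self, f.name)) for f in fields(self)}


def round2(x: float) -> float:
    """Round half-up to two decimals, as the printed tables do."""
    if math.isnan(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _as_value(label: object) -> str:
    return label.value if isinstance(label, RhythmLabel) else str(label)


def confusion(
    decisions: Sequence[object],
    truth: Sequence[object],
    classes: Optional[Sequence[object]] = None,
) -> dict[str, ConfusionCounts]:
    """One-vs-rest confusion counts per class.

    Pairs whose prediction is UNDETERMINED are excluded (see :func:`coverage`).
    """
    if len(decisions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(decisions)} predictions vs {len(truth)} truths"
        )
    pred = [_as_value(p) for p in decisions]
    true = [_as_value(t) for t in truth]
    pairs = [
        (p, t) for p, t in zip(pred, true) if p != RhythmLabel.UNDETERMINED.value
    ]
    if classes is None:
        class_names = sorted({t for _, t in pairs} | {p for p, _ in pairs})
    else:
        class_names = [_as_value(c) for c in classes]
    out: dict[str, ConfusionCounts] = {}
    for c in class_names:
        tp = sum(1 for p, t in pairs if p == c and t == c)
        tn = sum(1 for p, t in pairs if p != c and t != c)
        fp = sum(1 for p, t in pairs if p == c and t != c)
        fn = sum(1 for p, t in pairs if p != c and t == c)
        out[c] = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return out


def coverage(decisions: Sequence[object]) -> float:
    """Fraction of windows with a determined label."""
    if not decisions:
        return math.nan
    determined = sum(
        1 for d in decisions if _as_value(d) != RhythmLabel.UNDETERMINED.value
    )
    return determined / len(decisions)


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den else math.nan


def metrics(c: ConfusionCounts) -> ClassMetrics:
    """Standard one-vs-rest metrics, ×100, full precision."""
    return ClassMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        accuracy=_ratio(c.tp + c.tn, c.total),
    )


def _decision_label(d: object) -> object:
    return d.label if isinstance(d, WindowDecision) else d


def evaluate_cohort(
    cohort: Sequence[LabelledWindow],
    geom: QuadrantGeometry | None = None,
    cfg: ClassifierConfig | None = None,
    prior_from_truth: bool = True,
) -> tuple[dict[str, ConfusionCounts], list[WindowDecision]]:
    """Classify a labelled synthetic cohort and tabulate the confusion.

    ``prior_from_truth`` routes each window with a perfect upstream AF
    detector (prior_af = truth == AF); otherwise the irregularity stub is
    used.
    """
    from .classifier import classify_window

    geom = geom or QuadrantGeometry()
    cfg = cfg or ClassifierConfig()
    decisions = []
    for w in cohort:
        prior = (w.truth is RhythmLabel.AF) if prior_from_truth else None
        decisions.append(
            classify_window(w.beats.hr, prior, geom=geom, cfg=cfg, window_id=w.window_id)
        )
    truths = [w.truth for w in cohort]
    labels = [d.label for d in decisions]
    classes = [RhythmLabel.NSR, RhythmLabel.AF, RhythmLabel.PACPVC]
    return confusion(labels, truths, classes=classes), decisions


def threshold_sweep(
    cohort: Sequence[LabelledWindow],
    cfg_grid: Mapping[str, Sequence[float]],
    geom: QuadrantGeometry | None = None,
    base_cfg: ClassifierConfig | None = None,
    prior_from_truth: bool = True,
) -> pd.DataFrame:
    """Per-class accuracy across one-at-a-time threshold variations.

    ``cfg_grid`` maps ClassifierConfig field names to value lists; each value
    replaces only that field on ``base_cfg``.  Features are extracted once per
    window, then every grid point re-runs only the decision logic.  Returns a
    tidy frame with columns ``threshold_name, value, class, accuracy``.
    """
    if not cfg_grid or all(len(v) == 0 for v in cfg_grid.values()):
        raise ValueError("cfg_grid must contain at least one grid point")
    geom = geom or QuadrantGeometry()
    base_cfg = base_cfg or ClassifierConfig()
    valid = {f.name for f in fields(ClassifierConfig)}
    unknown = set(cfg_grid) - valid
    if unknown:
        raise ValueError(f"unknown threshold names: {sorted(unknown)}")

    prepared: list[tuple[Optional[WindowFeatures], bool, RhythmLabel]] = []
    for w in cohort:
        hr = w.beats.hr
        feats = (
            extract_features(hr, geom) if hr.size + 1 >= base_cfg.min_beats else None
        )
        prior = (w.truth is RhythmLabel.AF) if prior_from_truth else None
        if prior is None and feats is not None:
            prior = feats.rzero < base_cfg.rzero_nsr
        prepared.append((feats, bool(prior), w.truth))

    classes = [RhythmLabel.NSR, RhythmLabel.AF, RhythmLabel.PACPVC]
    rows = []
    for name, values in cfg_grid.items():
        for value in values:
            cfg = replace(base_cfg, **{name: value})
            labels = [
                RhythmLabel.UNDETERMINED
                if feats is None
                else (_alg1 if prior else _alg2)(feats, cfg)[0]
                for feats, prior, _ in prepared
            ]
            table = confusion(labels, [t for *_, t in prepared], classes=classes)
            for cls in classes:
                rows.append(
                    {
                        "threshold_name": name,
                        "value": value,
                        "class": cls.value,
                        "accuracy": metrics(table[cls.value]).accuracy,
                    }
                )
    return pd.DataFrame(rows, columns=["threshold_name", "value", "class", "accuracy"])
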