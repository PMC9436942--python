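"""Isotonic probability calibration and two-stage decision-threshold tuning.

Calibration fits a monotone nondecreasing step function (pool-adjacent-
violators / isotonic regression) mapping raw classifier scores to
probabilities on the validation split; it is then applied to both
validation scores (for threshold tuning) and test scores.

Threshold tuning is two-stage, keyed to the minority class: over a
candidate grid (every unique calibrated score, plus 0 and 1), first take
the three thresholds with the highest minority-class F1 (F1_C1), then
among those pick the one with the highest balanced accuracy. All ties
resolve toward the *lower* threshold, which favors minority-class
recall. The prediction rule is "C1 iff score >= threshold". F1 is taken
as 0 where its denominator vanishes.

A single whole-population threshold is the default; per-subgroup tuning
exists for the whole-group-vs-subgroup comparison and flags small
validation subgroups, where a subgroup-tuned threshold tends to overfit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "Calibrator",
    "ThresholdChoice",
    "CalibrationError",
    "fit_isotonic",
    "tune_threshold",
    "tune_threshold_subgroup",
]

SMALL_SUBGROUP = 30  # below this many masked rows, flag the tuned threshold


class CalibrationError(ValueError):
    pass


@dataclass
class Calibrator:
    """Fitted nondecreasing step map from raw score to probability.

    Out-of-domain scores clamp to the boundary fitted values. Serializes
    to a JSON list of (breakpoint, fitted value) pairs.
    """

    x_breaks: np.ndarray
    y_values: np.ndarray

    def __post_init__(self):
        self.x_breaks = np.asarray(self.x_breaks, dtype=float)
        self.y_values = np.asarray(self.y_values, dtype=float)
        if np.any(np.diff(self.y_values) < -1e-12):
            raise CalibrationError("calibrator must be monotone nondecreasing")

    def __call__(self, scores) -> np.ndarray:
        s = np.clip(np.asarray(scores, dtype=float), self.x_breaks[0], self.x_breaks[-1])
        return np.interp(s, self.x_breaks, self.y_values)

    def to_json(self) -> str:
        return json.dumps(
            [[float(x), float(y)] for x, y in zip(self.x_breaks, self.y_values)]
        )

    @classmethod
    def from_json(cls, text: str) -> "Calibrator":
        pairs = json.loads(text)
        xs, ys = zip(*pairs)
        return cls(np.asarray(xs), np.asarray(ys))


def fit_isotonic(scores, labels) -> Calibrator:
    """Pool-adjacent-violators fit of labels on scores (squared error)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise CalibrationError("calibration requires both classes in labels")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, labels)
    return Calibrator(x_breaks=iso.X_thresholds_, y_values=iso.y_thresholds_)


@dataclass
class ThresholdChoice:
    """Result of two-stage threshold tuning.

    ``candidate_thresholds`` are the top-3 by F1_C1, sorted by descending
    F1_C1; ``threshold`` is the member with the best balanced accuracy.
    """

    threshold: float
    candidate_thresholds: list[float]
    f1_c1: list[float]
    balanced_accuracy: list[float]
    small_sample: bool = False
    n_tuning_rows: int = 0


def _f1_balacc_at(scores: np.ndarray, labels: np.ndarray, grid: np.ndarray):
    """Vectorized F1_C1 and balanced accuracy at every grid threshold."""
    pred = scores[None, :] >= grid[:, None]  # (T, n)
    pos = labels == 1
    tp = (pred & pos[None, :]).sum(axis=1).astype(float)
    fp = (pred & ~pos[None, :]).sum(axis=1).astype(float)
    fn = ((~pred) & pos[None, :]).sum(axis=1).astype(float)
    tn = ((~pred) & ~pos[None, :]).sum(axis=1).astype(float)
    denom = 2 * tp + fp + fn
    f1 = np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    rec1 = np.divide(tp, tp + fn, out=np.zeros_like(tp), where=(tp + fn) > 0)
    rec0 = np.divide(tn, tn + fp, out=np.zeros_like(tn), where=(tn + fp) > 0)
    return f1, (rec0 + rec1) / 2.0


def tune_threshold(calibrated_scores, labels) -> ThresholdChoice:
    """Two-stage tuning on the full candidate grid.

    Grid = sorted unique calibrated scores plus {0, 1}. Stage 1: top-3
    thresholds by F1_C1 (ties to the lower threshold). Stage 2: among
    them, the one maximizing balanced accuracy (ties to the lower
    threshold).
    """
    scores = np.asarray(calibrated_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise CalibrationError("threshold tuning requires both classes in labels")
    grid = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    f1, balacc = _f1_balacc_at(scores, labels, grid)
    # stage 1: sort by (-f1, threshold); grid is ascending so stable sort on
    # -f1 already breaks ties toward the lower threshold
    top3 = np.argsort(-f1, kind="stable")[:3]
    # stage 2: among top3, max balanced accuracy, ties toward lower threshold
    cand_sorted = top3  # already ordered by descending f1 then ascending thr
    best = min(
        cand_sorted, key=lambda i: (-balacc[i], grid[i])
    )
    return ThresholdChoice(
        threshold=float(grid[best]),
        candidate_thresholds=[float(grid[i]) for i in top3],
        f1_c1=[float(f1[i]) for i in top3],
        balanced_accuracy=[float(balacc[i]) for i in top3],
        n_tuning_rows=len(scores),
    )


def tune_threshold_subgroup(calibrated_scores, labels, mask) -> ThresholdChoice:
    """Threshold tuning restricted to masked rows.

    Used by the whole-group-vs-subgroup threshold comparison. Raises if
    the masked rows are single-class; flags (does not reject) small
    subgroups, where tuning overfits the validation set.
    """
    mask = np.asarray(mask, dtype=bool)
    scores = np.asarray(calibrated_scores, dtype=float)[mask]
    labels = np.asarray(labels, dtype=int)[mask]
    if len(np.unique(labels)) < 2:
        raise CalibrationError(
            "subgroup threshold tuning requires both classes among masked rows"
        )
    choice = tune_threshold(scores, labels)
    choice.small_sample = int(mask.sum()) < SMALL_SUBGROUP
    return choice
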