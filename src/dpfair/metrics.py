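"""Per-class metrics, subgroup panels, relative disparity, cross-group matrices.

The evaluation panel is the 12-metric set used throughout the package:
recall / precision / AUC-PR / F1 for each class (C1 = minority positive,
C0 = majority), overall accuracy, balanced accuracy (mean of the two
class recalls), AUC-ROC, and the Matthews correlation coefficient (MCC,
range [-1, 1], 0 for a random classifier). Accuracy and AUC-ROC are
dominated by the majority class on imbalanced data, which is why the
panel leads with class-conditional metrics.

Fairness is summarized by *relative disparity*: for one metric measured
across demographic subgroups, the ratio R1/R2 of the highest to the
lowest subgroup value. A ratio under 1.25 is considered fair, by the
four-fifths (80%) rule for disparate impact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import ClinicalDataset, SubgroupKey

__all__ = [
    "ConfusionCounts",
    "SubgroupMetricsReport",
    "DisparityReport",
    "FAIR_DISPARITY_CUTOFF",
    "METRIC_COLUMNS",
    "compute_metrics",
    "subgroup_heatmap",
    "relative_disparity",
    "cross_group_matrix",
    "aggregate_importance",
]

#: Disparity below this ratio is considered fair (four-fifths rule: 1/0.8).
FAIR_DISPARITY_CUTOFF = 1.25

METRIC_COLUMNS = [
    "rec_c1",
    "prec_c1",
    "pr_c1",
    "f1_c1",
    "rec_c0",
    "prec_c0",
    "pr_c0",
    "f1_c0",
    "acc",
    "bal_acc",
    "roc",
    "mcc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with C1 as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, labels, predictions) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=int)
        p = np.asarray(predictions, dtype=int)
        if len(y) != len(p):
            raise ValueError("labels and predictions must align")
        return cls(
            tp=int(((y == 1) & (p == 1)).sum()),
            fp=int(((y == 0) & (p == 1)).sum()),
            fn=int(((y == 1) & (p == 0)).sum()),
            tn=int(((y == 0) & (p == 0)).sum()),
        )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def _mcc(c: ConfusionCounts) -> float:
    num = c.tp * c.tn - c.fp * c.fn
    den = math.sqrt(
        float(c.tp + c.fp)
        * float(c.tp + c.fn)
        * float(c.tn + c.fp)
        * float(c.tn + c.fn)
    )
    return num / den if den > 0 else 0.0


@dataclass
class SubgroupMetricsReport:
    """The 12-metric panel for one subgroup (or the whole population).

    Threshold-free metrics (AUC-PR, AUC-ROC) are ``None`` — "undefined",
    distinct from 0 — when probabilities were not supplied or the rows
    are single-class.
    """

    subgroup: SubgroupKey | None  # None = whole population
    counts: ConfusionCounts
    rec_c1: float
    prec_c1: float
    pr_c1: float | None
    f1_c1: float
    rec_c0: float
    prec_c0: float
    pr_c0: float | None
    f1_c0: float
    acc: float
    bal_acc: float
    roc: float | None
    mcc: float
    n_rows: int = 0
    n_c1: int = 0
    small_sample: bool = False

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_COLUMNS}
        d["n_rows"] = self.n_rows
        d["n_c1"] = self.n_c1
        d["subgroup"] = "all" if self.subgroup is None else str(self.subgroup)
        return d


def compute_metrics(
    labels,
    predictions,
    probabilities=None,
    subgroup: SubgroupKey | None = None,
) -> SubgroupMetricsReport:
    """Full 12-metric panel from hard predictions (+ optional probabilities).

    Precision and F1 are 0 when their denominators are 0. AUC-PR for a
    class uses average precision with that class as positive; AUC-ROC and
    the AUC-PRs are undefined (``None``) on single-class rows.
    """
    y = np.asarray(labels, dtype=int)
    c = ConfusionCounts.from_predictions(y, predictions)

    rec_c1 = _safe_div(c.tp, c.tp + c.fn)
    prec_c1 = _safe_div(c.tp, c.tp + c.fp)
    f1_c1 = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    rec_c0 = _safe_div(c.tn, c.tn + c.fp)
    prec_c0 = _safe_div(c.tn, c.tn + c.fn)
    f1_c0 = _safe_div(2 * c.tn, 2 * c.tn + c.fn + c.fp)

    pr_c1 = pr_c0 = roc = None
    if probabilities is not None and len(np.unique(y)) == 2:
        prob = np.asarray(probabilities, dtype=float)
        pr_c1 = float(average_precision_score(y, prob))
        pr_c0 = float(average_precision_score(1 - y, 1 - prob))
        roc = float(roc_auc_score(y, prob))

    return SubgroupMetricsReport(
        subgroup=subgroup,
        counts=c,
        rec_c1=rec_c1,
        prec_c1=prec_c1,
        pr_c1=pr_c1,
        f1_c1=f1_c1,
        rec_c0=rec_c0,
        prec_c0=prec_c0,
        pr_c0=pr_c0,
        f1_c0=f1_c0,
        acc=_safe_div(c.tp + c.tn, c.n),
        bal_acc=(rec_c0 + rec_c1) / 2.0,
        roc=roc,
        mcc=_mcc(c),
        n_rows=c.n,
        n_c1=int((y == 1).sum()),
    )


def subgroup_heatmap(
    model,
    test: ClinicalDataset,
    attributes: list[str],
) -> pd.DataFrame:
    """Metric panel per (attribute, value) subgroup plus the whole population.

    ``model`` is anything with ``predict(dataset) -> (labels, probabilities)``
    (a fitted candidate model). Empty subgroups yield a flagged row with
    metrics absent. The frame serializes to the 12-column panel layout.
    """
    pred, prob = model.predict(test)
    rows = []
    rep = compute_metrics(test.labels, pred, prob)
    rows.append(rep.as_dict())
    for attr in attributes:
        for value in test.subgroup_values(attr):
            key = SubgroupKey(attr, value)
            m = test.group_mask(key)
            if not m.any():
                rows.append({"subgroup": str(key), "n_rows": 0, "n_c1": 0})
                continue
            rep = compute_metrics(
                test.labels[m], pred[m], prob[m], subgroup=key
            )
            rows.append(rep.as_dict())
    frame = pd.DataFrame(rows)
    return frame[["subgroup", "n_rows", "n_c1"] + METRIC_COLUMNS]


@dataclass
class DisparityReport:
    """Max/min subgroup values of one metric and their ratio R1/R2."""

    metric: str
    values: dict
    r1: float
    r2: float
    disparity: float
    fair: bool
    excluded: dict = field(default_factory=dict)
    note: str | None = None


def relative_disparity(values: dict, metric: str = "") -> DisparityReport:
    """R1/R2 across subgroups; < 1.25 is fair by the 80% rule.

    ``values`` maps subgroup name -> metric value; entries that are None
    or NaN are excluded with a reason. A non-positive minimum (possible
    for MCC) makes the ratio infinite, with an explanatory note, rather
    than fabricating a finite disparity.
    """
    excluded = {
        k: "undefined metric"
        for k, v in values.items()
        if v is None or (isinstance(v, float) and math.isnan(v))
    }
    kept = {k: float(v) for k, v in values.items() if k not in excluded}
    if len(kept) < 2:
        raise ValueError("relative disparity needs at least two finite values")
    r1 = max(kept.values())
    r2 = min(kept.values())
    if r2 <= 0:
        return DisparityReport(
            metric=metric,
            values=kept,
            r1=r1,
            r2=r2,
            disparity=float("inf"),
            fair=False,
            excluded=excluded,
            note=f"minimum value {r2} is non-positive; ratio undefined/infinite",
        )
    return DisparityReport(
        metric=metric,
        values=kept,
        r1=r1,
        r2=r2,
        disparity=r1 / r2,
        fair=(r1 / r2) < FAIR_DISPARITY_CUTOFF,
        excluded=excluded,
    )


def cross_group_matrix(
    models: dict,
    original,
    test: ClinicalDataset,
    metric: str = "rec_c1",
) -> pd.DataFrame:
    """Cross-group transfer matrix.

    Rows: one per subgroup-targeted model (keyed by its enrichment group
    g) plus a final ``original`` row; columns: test subgroups g'. Cell
    (g, g') is the metric of model g evaluated on the test rows of g'.
    The diagonal is the matched case g = g'.
    """
    if metric not in {"rec_c1", "bal_acc"}:
        raise ValueError("metric must be 'rec_c1' or 'bal_acc'")
    groups = list(models.keys())
    mat = {}
    for name, model in list(models.items()) + [("original", original)]:
        pred, prob = model.predict(test)
        row = {}
        for g in groups:
            m = test.group_mask(g)
            if not m.any() or len(np.unique(test.labels[m])) < 2:
                row[str(g)] = float("nan")
                continue
            rep = compute_metrics(test.labels[m], pred[m], prob[m])
            row[str(g)] = getattr(rep, metric)
        mat[str(name)] = row
    return pd.DataFrame(mat).T[[str(g) for g in groups]]


def aggregate_importance(
    column_importances: dict, column_map: dict
) -> tuple[dict, dict]:
    """Aggregate per-encoded-column importances back to source features.

    Returns ``(avg, total)``: per source feature, the mean and the sum of
    its encoded columns' importances. Continuous (identity-mapped)
    features pass through unchanged in both variants. This is how
    per-column attribution values (e.g. SHAP) of one-hot encoded
    categoricals are reported at the feature level.
    """
    missing = set(column_map) - set(column_importances)
    if missing:
        raise ValueError(f"importances missing for columns: {sorted(missing)}")
    per_feature: dict[str, list[float]] = {}
    for col, feat in column_map.items():
        per_feature.setdefault(feat, []).append(float(column_importances[col]))
    avg = {f: float(np.mean(v)) for f, v in per_feature.items()}
    total = {f: float(np.sum(v)) for f, v in per_feature.items()}
    return avg, total
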