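"""Double-prioritized (DP) bias correction: candidate training and model selection.

DP targets one demographic group g whose minority-class (C1) cases the
original model serves poorly. The workflow:

1. *Sample enrichment* — build n+1 training sets, the u-th containing u
   extra copies of every C1 row of g (u = 0..n; u = 0 is the original).
2. *Candidate training* — train one classifier per training set. Model
   architecture and hyperparameters are identical across candidates, so
   candidates differ only through their data.
3. *Model selection* — for each candidate, calibrate its validation
   scores (isotonic regression) and tune a whole-population decision
   threshold; rank candidates by whole-population balanced accuracy,
   keep the top three, and among them select the one with the highest
   minority-class precision-recall AUC on validation rows of g. That
   candidate is M*.
4. *Prediction* — apply M* (with its calibrator and threshold) to new
   patients of the matching group g' = g.

Validation and test data are never enriched.

The same selection loop drives prioritized reweighting: candidates come
from integer subgroup weights 1..n instead of duplication.

The module exposes both a functional surface (``train_candidates``,
``select_model``, ``run_dp``) and a model-object surface
(:class:`DoublePrioritizedModel` / :class:`DPResults`) for interactive
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .calibration import Calibrator, ThresholdChoice, fit_isotonic, tune_threshold
from .data import ClinicalDataset, SplitBundle, SubgroupKey
from .metrics import compute_metrics
from .reweighting import prioritized_reweight
from .samplers import DEFAULT_MAX_UNITS, dp_enrich

__all__ = [
    "CandidateModel",
    "DPResult",
    "SelectionError",
    "train_candidates",
    "select_model",
    "run_dp",
    "run_prioritized_reweighting",
    "DoublePrioritizedModel",
    "DPResults",
]


class SelectionError(RuntimeError):
    pass


def _unit_seed(seed: int, unit: int) -> int:
    """Independent per-candidate stream; kept below 2**31 for library limits."""
    return int(np.random.SeedSequence([int(seed), int(unit)]).generate_state(1)[0] % (2**31))


@dataclass
class CandidateModel:
    """One trained candidate: classifier + calibrator + tuned threshold."""

    unit: int
    learner: object
    calibrator: Calibrator
    threshold_choice: ThresholdChoice
    val_balanced_accuracy: float
    val_pr_c1_group: float
    train_size: int = 0

    @property
    def threshold(self) -> float:
        return self.threshold_choice.threshold

    def score(self, data: ClinicalDataset) -> np.ndarray:
        """Calibrated C1 probabilities."""
        return self.calibrator(self.learner.predict_proba1(data.feature_matrix()))

    def predict(self, data: ClinicalDataset):
        """Hard labels (C1 iff score >= threshold) plus calibrated probabilities."""
        if data.n_rows == 0:
            return np.empty(0, dtype=int), np.empty(0)
        prob = self.score(data)
        return (prob >= self.threshold).astype(int), prob


@dataclass
class DPResult:
    """Outcome of the DP loop: the selected candidate and the audit trail."""

    selected: CandidateModel
    candidates: list[CandidateModel]
    group: SubgroupKey
    trace: dict = field(default_factory=dict)

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "unit": c.unit,
                "train_size": c.train_size,
                "threshold": c.threshold,
                "val_bal_acc": c.val_balanced_accuracy,
                "val_pr_c1_group": c.val_pr_c1_group,
                "selected": c.unit == self.selected.unit,
            }
            for c in self.candidates
        ]
        return pd.DataFrame(rows)


def _fit_one_candidate(
    unit: int,
    train_data: ClinicalDataset,
    validation: ClinicalDataset,
    learner_proto,
    group: SubgroupKey,
    seed: int,
    sample_weight=None,
) -> CandidateModel:
    learner = learner_proto.clone()
    learner.fit(
        train_data.feature_matrix(),
        train_data.labels,
        sample_weight=sample_weight,
        seed=_unit_seed(seed, unit),
    )
    raw_val = learner.predict_proba1(validation.feature_matrix())
    calibrator = fit_isotonic(raw_val, validation.labels)
    cal_val = calibrator(raw_val)
    choice = tune_threshold(cal_val, validation.labels)
    pred_val = (cal_val >= choice.threshold).astype(int)
    rep = compute_metrics(validation.labels, pred_val, cal_val)

    gmask = validation.group_mask(group)
    if gmask.any() and len(np.unique(validation.labels[gmask])) == 2:
        pr_g = float(
            average_precision_score(validation.labels[gmask], cal_val[gmask])
        )
    else:
        pr_g = float("nan")

    return CandidateModel(
        unit=unit,
        learner=learner,
        calibrator=calibrator,
        threshold_choice=choice,
        val_balanced_accuracy=rep.bal_acc,
        val_pr_c1_group=pr_g,
        train_size=train_data.n_rows,
    )


def train_candidates(
    splits: SplitBundle,
    group: SubgroupKey,
    learner,
    max_units: int = DEFAULT_MAX_UNITS,
    seed: int = 0,
) -> list[CandidateModel]:
    """Train the n+1 DP candidates for units 0..max_units.

    Each candidate trains on the u-unit enriched training set, then is
    calibrated and threshold-tuned on the untouched validation split.
    """
    if len(np.unique(splits.validation.labels)) < 2:
        raise SelectionError("validation split must contain both classes")
    out = []
    for u in range(max_units + 1):
        try:
            enriched = dp_enrich(splits.train, group, u)
            out.append(
                _fit_one_candidate(
                    u, enriched.data, splits.validation, learner, group, seed
                )
            )
        except Exception as exc:
            raise SelectionError(f"candidate unit {u} failed: {exc}") from exc
    return out


def select_model(candidates: list[CandidateModel], group: SubgroupKey) -> DPResult:
    """Two-stage selection: top-3 balanced accuracy, then max group PR-AUC.

    Ties resolve toward the smaller unit at both stages. Candidates with
    undefined group PR-AUC lose stage 2 to any candidate with a finite
    value.
    """
    finite = [c for c in candidates if np.isfinite(c.val_balanced_accuracy)]
    if not finite:
        raise SelectionError("no candidate produced finite validation metrics")
    top3 = sorted(finite, key=lambda c: (-c.val_balanced_accuracy, c.unit))[:3]

    def stage2_key(c: CandidateModel):
        pr = c.val_pr_c1_group
        return (-(pr if np.isfinite(pr) else -np.inf), c.unit)

    selected = min(top3, key=stage2_key)
    trace = {
        "top3_units": [c.unit for c in top3],
        "top3_bal_acc": [c.val_balanced_accuracy for c in top3],
        "top3_pr_c1_group": [c.val_pr_c1_group for c in top3],
        "selected_unit": selected.unit,
    }
    return DPResult(selected=selected, candidates=candidates, group=group, trace=trace)


def run_dp(
    splits: SplitBundle,
    group: SubgroupKey,
    learner,
    max_units: int = DEFAULT_MAX_UNITS,
    seed: int = 0,
) -> DPResult:
    """Full DP loop: enrichment sweep, candidate training, model selection."""
    return select_model(train_candidates(splits, group, learner, max_units, seed), group)


def run_prioritized_reweighting(
    splits: SplitBundle,
    group: SubgroupKey,
    learner,
    max_unit: int = 20,
    seed: int = 0,
) -> DPResult:
    """Prioritized-reweighting twin of :func:`run_dp`.

    Candidates use integer weights 1..max_unit on C1 rows of the target
    group (unit 1 = uniform weights, the original model) and go through
    the same calibration, threshold tuning and two-stage selection.
    """
    candidates = []
    for u in range(1, max_unit + 1):
        w = prioritized_reweight(splits.train, group, u)
        candidates.append(
            _fit_one_candidate(
                u, splits.train, splits.validation, learner, group, seed,
                sample_weight=w.weights,
            )
        )
    return select_model(candidates, group)


# ---------------------------------------------------------------------------
# Model-object surface
# ---------------------------------------------------------------------------

class DoublePrioritizedModel:
    """DP bias correction as a fittable model object.

    Parameters
    ----------
    splits : SplitBundle
        Train/validation/test splits. Only the training split is ever
        enriched.
    group : SubgroupKey
        The demographic group g whose C1 cases are prioritized.
    learner : object, optional
        Classifier prototype (default: deterministic logistic learner).
    max_units : int
        Maximum number of enrichment units n; n+1 candidates are trained.

    Examples
    --------
    >>> model = DoublePrioritizedModel(splits, SubgroupKey("race", "Asian"))
    >>> res = model.fit(seed=1)
    >>> res.selected_unit
    7
    >>> labels, probs = res.predict(splits.test)
    """

    def __init__(
        self,
        splits: SplitBundle,
        group: SubgroupKey,
        learner=None,
        max_units: int = DEFAULT_MAX_UNITS,
    ):
        if learner is None:
            from .classifiers import LogisticLearner

            learner = LogisticLearner()
        self.splits = splits
        self.group = group
        self.learner = learner
        self.max_units = max_units

    def fit(self, seed: int = 0) -> "DPResults":
        result = run_dp(
            self.splits, self.group, self.learner, self.max_units, seed
        )
        return DPResults(self, result)


class DPResults:
    """Fitted DP results: selected model, candidate table, audit trace."""

    def __init__(self, model: DoublePrioritizedModel, result: DPResult):
        self.model = model
        self._result = result

    @property
    def selected(self) -> CandidateModel:
        return self._result.selected

    @property
    def selected_unit(self) -> int:
        return self._result.selected.unit

    @property
    def candidate_table(self) -> pd.DataFrame:
        return self._result.table

    @property
    def trace(self) -> dict:
        return self._result.trace

    def predict(self, data: ClinicalDataset):
        return self.selected.predict(data)

    def test_report(self, subgroup: SubgroupKey | None = None):
        """Metric panel of the selected model on the (untouched) test split.

        Restricted to ``subgroup`` rows when given; by convention the
        deployment group g' should match the enrichment group g.
        """
        test = self.model.splits.test
        pred, prob = self.predict(test)
        if subgroup is None:
            return compute_metrics(test.labels, pred, prob)
        m = test.group_mask(subgroup)
        return compute_metrics(
            test.labels[m], pred[m], prob[m], subgroup=subgroup
        )

    def summary(self) -> str:
        t = self._result.trace
        lines = [
            "Double-prioritized bias correction",
            "==================================",
            f"Target group g:        {self.model.group}",
            f"Candidates trained:    {len(self._result.candidates)} "
            f"(units 0..{self.model.max_units})",
            f"Top-3 by balanced acc: units {t['top3_units']}",
            f"  balanced accuracy:   {[round(v, 4) for v in t['top3_bal_acc']]}",
            f"  group AUC-PR (C1):   {[round(v, 4) for v in t['top3_pr_c1_group']]}",
            f"Selected unit (M*):    {t['selected_unit']}",
            f"Decision threshold:    {self.selected.threshold:.4f}",
            "",
            self.candidate_table.to_string(index=False),
        ]
        return "\n".join(lines)
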