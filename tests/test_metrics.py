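"""Metric panel, relative disparity, cross-group matrix, importance aggregation.

The 12-metric panel is validated against independent brute-force
formulas on randomized confusion matrices, and the rank-based AUC
identity (Mann-Whitney) on random score vectors.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpfair import (
    FAIR_DISPARITY_CUTOFF,
    SubgroupKey,
    aggregate_importance,
    compute_metrics,
    relative_disparity,
    subgroup_heatmap,
)
from dpfair.metrics import ConfusionCounts, METRIC_COLUMNS


def predictions_from_counts(tp, fp, fn, tn):
    labels = np.array([1] * tp + [0] * fp + [1] * fn + [0] * tn)
    preds = np.array([1] * tp + [1] * fp + [0] * fn + [0] * tn)
    return labels, preds


class TestPanelAgainstBruteForce:
    def test_known_mcc_value(self):
        labels, preds = predictions_from_counts(tp=2, fp=1, fn=1, tn=6)
        rep = compute_metrics(labels, preds)
        assert math.isclose(rep.mcc, 11 / 21, rel_tol=1e-12)

    def test_perfect_predictions(self):
        labels, preds = predictions_from_counts(tp=5, fp=0, fn=0, tn=15)
        rep = compute_metrics(labels, preds)
        assert rep.acc == rep.bal_acc == rep.f1_c1 == rep.mcc == 1.0

    def test_balanced_accuracy_is_mean_of_printed_recalls(self):
        # recalls 0.88 and 0.61 average to 0.745
        assert (0.88 + 0.61) / 2 == 0.745
        labels, preds = predictions_from_counts(tp=61, fp=12, fn=39, tn=88)
        rep = compute_metrics(labels, preds)
        assert math.isclose(rep.rec_c1, 0.61)
        assert math.isclose(rep.rec_c0, 0.88)
        assert math.isclose(rep.bal_acc, 0.745)

    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    @settings(deadline=None, max_examples=500, derandomize=True)
    def test_panel_matches_formulas_on_random_confusions(self, tp, fp, fn, tn):
        if tp + fn == 0 or fp + tn == 0:
            return  # need both classes present
        labels, preds = predictions_from_counts(tp, fp, fn, tn)
        rep = compute_metrics(labels, preds)
        n = tp + fp + fn + tn
        assert math.isclose(rep.acc, (tp + tn) / n)
        rec1 = tp / (tp + fn)
        rec0 = tn / (tn + fp)
        assert math.isclose(rep.rec_c1, rec1) and math.isclose(rep.rec_c0, rec0)
        assert math.isclose(rep.bal_acc, (rec0 + rec1) / 2)
        assert rep.prec_c1 == (tp / (tp + fp) if tp + fp else 0.0)
        assert rep.f1_c1 == (2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert math.isclose(rep.mcc, ((tp * tn - fp * fn) / den) if den else 0.0,
                            abs_tol=1e-12)
        assert -1.0 <= rep.mcc <= 1.0
        for m in ("rec_c1", "prec_c1", "f1_c1", "rec_c0", "prec_c0", "f1_c0",
                  "acc", "bal_acc"):
            assert 0.0 <= getattr(rep, m) <= 1.0

    def test_vector_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])

    def test_single_class_rows_have_undefined_aucs(self):
        rep = compute_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])
        assert rep.roc is None and rep.pr_c1 is None and rep.pr_c0 is None


class TestRankBasedAUC:
    @pytest.mark.parametrize("seed", range(10))
    def test_roc_auc_equals_mann_whitney_statistic(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        prob = rng.random(50)
        rep = compute_metrics(labels, (prob > 0.5).astype(int), prob)
        pos = prob[labels == 1]
        neg = prob[labels == 0]
        wins = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert math.isclose(rep.roc, wins / (len(pos) * len(neg)), rel_tol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_pr_auc_equals_step_integral(self, seed):
        rng = np.random.default_rng(seed + 100)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        prob = rng.random(40)
        rep = compute_metrics(labels, (prob > 0.5).astype(int), prob)
        # brute-force average precision: sum over recall steps
        order = np.argsort(-prob, kind="stable")
        y = labels[order]
        tp = np.cumsum(y)
        precision = tp / np.arange(1, len(y) + 1)
        recall = tp / y.sum()
        ap = 0.0
        prev_r = 0.0
        for p, r, yi in zip(precision, recall, y):
            if yi:
                ap += p * (r - prev_r)
                prev_r = r
        assert math.isclose(rep.pr_c1, ap, rel_tol=1e-9)

    def test_random_classifier_mcc_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            labels = rng.integers(0, 2, size=100)
            preds = rng.integers(0, 2, size=100)
            vals.append(compute_metrics(labels, preds).mcc)
        assert abs(np.mean(vals)) < 0.02


class TestRelativeDisparity:
    def test_direct_ratio(self):
        rep = relative_disparity({"a": 0.5, "b": 0.61, "c": 0.83})
        assert round(rep.disparity, 2) == 1.66
        assert not rep.fair

    def test_equal_values_ratio_one(self):
        rep = relative_disparity({"a": 0.4, "b": 0.4, "c": 0.4})
        assert rep.disparity == 1.0
        assert rep.fair

    def test_printed_pathological_ratio(self):
        # an extremely low minimum (0.001) blows the ratio up to 316.3
        rep = relative_disparity({"hi": 0.3163, "lo": 0.001})
        assert round(rep.disparity, 1) == 316.3

    def test_fair_cutoff_is_four_fifths_rule(self):
        assert FAIR_DISPARITY_CUTOFF == 1.25
        assert math.isclose(FAIR_DISPARITY_CUTOFF, 1 / 0.8)

    def test_nonpositive_minimum_reported_infinite(self):
        rep = relative_disparity({"a": 0.5, "b": -0.1})
        assert math.isinf(rep.disparity)
        assert rep.note and not rep.fair

    def test_undefined_values_excluded_with_reason(self):
        rep = relative_disparity({"a": 0.5, "b": None, "c": 0.25})
        assert rep.excluded == {"b": "undefined metric"}
        assert rep.disparity == 2.0

    @given(
        st.dictionaries(
            st.text(min_size=1, max_size=4),
            st.floats(0.01, 1.0, allow_nan=False),
            min_size=2,
            max_size=8,
        ),
        st.floats(0.1, 10.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_at_least_one_and_scale_invariant(self, values, scale):
        rep = relative_disparity(values)
        assert rep.disparity >= 1.0
        scaled = relative_disparity({k: v * scale for k, v in values.items()})
        assert math.isclose(rep.disparity, scaled.disparity, rel_tol=1e-9)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            relative_disparity({"a": 0.5})


class TestAggregateImportance:
    def test_one_hot_feature_avg_and_sum(self):
        cmap = {"f_a": "f", "f_b": "f", "f_c": "f", "x": "x"}
        imp = {"f_a": 0.3, "f_b": 0.6, "f_c": 0.3, "x": 0.2}
        avg, total = aggregate_importance(imp, cmap)
        assert math.isclose(avg["f"], 0.4)
        assert math.isclose(total["f"], 1.2)
        assert avg["x"] == total["x"] == 0.2

    def test_identity_map_passthrough(self):
        cmap = {"a": "a", "b": "b"}
        imp = {"a": 0.1, "b": 0.9}
        avg, total = aggregate_importance(imp, cmap)
        assert avg == total == {"a": 0.1, "b": 0.9}

    def test_sum_variant_conserves_total(self):
        rng = np.random.default_rng(1)
        cmap = {f"c{i}": f"f{i % 3}" for i in range(9)}
        imp = {c: float(rng.random()) for c in cmap}
        _, total = aggregate_importance(imp, cmap)
        assert math.isclose(sum(total.values()), sum(imp.values()))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            aggregate_importance({"a": 0.1}, {"a": "a", "b": "b"})


class _ConstantModel:
    """Predicts C1 with probability equal to the row's first feature."""

    def predict(self, data):
        prob = np.clip(data.feature_matrix()[:, 0], 0, 1)
        return (prob >= 0.5).astype(int), prob


class TestSubgroupHeatmap:
    def test_partition_and_whole_population_row(self, toy_dataset):
        frame = subgroup_heatmap(_ConstantModel(), toy_dataset, ["race"])
        whole = frame[frame.subgroup == "all"].iloc[0]
        race_rows = frame[frame.subgroup.str.startswith("race=")]
        assert whole["n_rows"] == toy_dataset.n_rows
        assert race_rows["n_rows"].sum() == toy_dataset.n_rows
        assert set(METRIC_COLUMNS) <= set(frame.columns)
        # confusion counts partition: subgroup recalls weighted by C1 counts
        # reconstruct whole-group TP
        tps = (race_rows["rec_c1"] * race_rows["n_c1"]).sum()
        assert math.isclose(tps, whole["rec_c1"] * whole["n_c1"], abs_tol=1e-9)
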