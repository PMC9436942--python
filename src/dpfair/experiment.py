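"""End-to-end experiment runner: methods x groups x replicate seeds.

Ties the generator/loader, samplers, reweighters, DP loop and metric
suite together into reproducible comparison experiments: per-subgroup
metric panels, relative-disparity comparisons across correction methods,
and cross-group transfer matrices. Replicate seeds yield mean +/- sd
summaries (sample sd, n-1). The test split is hashed before and after
every run; a changed hash is a hard error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import make_learner
from .data import ClinicalDataset, SplitBundle, SubgroupKey, stratified_split
from .dp import (
    CandidateModel,
    _fit_one_candidate,
    run_dp,
    run_prioritized_reweighting,
)
from .metrics import compute_metrics, cross_group_matrix, relative_disparity
from .reweighting import standard_reweight
from .samplers import SAMPLERS
from .simulate import generate, preset

__all__ = ["ExperimentConfig", "run_experiment", "compare_samplers", "fit_original"]

ALL_METHODS = ["original", "dp", "standard_reweight", "prioritized_reweight"] + list(
    SAMPLERS
)


@dataclass
class ExperimentConfig:
    """Declarative description of one comparison experiment."""

    preset: str = "bcs_like"
    n_rows: int = 6000
    split_fractions: tuple = (0.70, 0.15, 0.15)
    groups: list = field(default_factory=list)  # list[SubgroupKey]
    methods: list = field(default_factory=lambda: ["original", "dp"])
    learner: str = "logistic"
    max_units: int = 19
    replicate_seeds: list = field(default_factory=lambda: [0])
    disparity_attributes: list = field(default_factory=lambda: ["race", "age_group"])
    output_dir: str | None = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["split_fractions"] = list(self.split_fractions)
        d["groups"] = [str(g) for g in self.groups]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        d["split_fractions"] = tuple(d.get("split_fractions", (0.70, 0.15, 0.15)))
        d["groups"] = [SubgroupKey.parse(g) for g in d.get("groups", [])]
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        bad = [m for m in d.get("methods", []) if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; known: {ALL_METHODS}")
        return cls(**d)


def fit_original(splits: SplitBundle, learner, group: SubgroupKey, seed: int = 0):
    """The no-bias-correction baseline pipeline (train, calibrate, tune)."""
    return _fit_one_candidate(0, splits.train, splits.validation, learner, group, seed)


def _fit_method(
    method: str,
    splits: SplitBundle,
    group: SubgroupKey,
    learner,
    max_units: int,
    seed: int,
) -> CandidateModel:
    """Train + calibrate + tune one correction method; returns the final model."""
    if method == "original":
        return fit_original(splits, learner, group, seed)
    if method == "dp":
        return run_dp(splits, group, learner, max_units, seed).selected
    if method == "prioritized_reweight":
        return run_prioritized_reweighting(
            splits, group, learner, max_units + 1, seed
        ).selected
    if method == "standard_reweight":
        w = standard_reweight(splits.train)
        return _fit_one_candidate(
            0, splits.train, splits.validation, learner, group, seed,
            sample_weight=w.weights,
        )
    if method in SAMPLERS:
        sampler = SAMPLERS[method]
        try:
            sampled = sampler(splits.train, seed=seed)  # type: ignore[call-arg]
        except TypeError:  # distance-based samplers are deterministic
            sampled = sampler(splits.train)
        return _fit_one_candidate(
            0, sampled.data, splits.validation, learner, group, seed
        )
    raise ValueError(f"unknown method {method!r}")


def _make_splits(config: ExperimentConfig, seed: int) -> SplitBundle:
    spec = preset(config.preset, n_rows=config.n_rows, seed=seed)
    data = generate(spec)
    return stratified_split(data, config.split_fractions, seed=seed)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run methods x groups x replicate seeds; return the report bundle.

    The bundle holds a long-format metric table (one row per method,
    group, seed with the target group's test panel), a mean +/- sd
    summary across seeds, and per-cell failures (recorded, not fatal).
    """
    records, failures = [], []
    for seed in config.replicate_seeds:
        splits = _make_splits(config, seed)
        test_hash = splits.test.content_hash()
        for group in config.groups:
            for method in config.methods:
                try:
                    model = _fit_method(
                        method, splits, group, make_learner(config.learner),
                        config.max_units, seed,
                    )
                    pred, prob = model.predict(splits.test)
                    m = splits.test.group_mask(group)
                    if not m.any():
                        raise ValueError(f"no test rows in group {group}")
                    rep = compute_metrics(
                        splits.test.labels[m], pred[m], prob[m], subgroup=group
                    )
                    rec = rep.as_dict()
                    rec.update(
                        method=method, group=str(group), seed=seed,
                        selected_unit=getattr(model, "unit", 0),
                    )
                    records.append(rec)
                except Exception as exc:  # record and continue
                    failures.append(
                        {"method": method, "group": str(group), "seed": seed,
                         "error": str(exc)}
                    )
        if splits.test.content_hash() != test_hash:
            raise RuntimeError("test split was modified during the run")

    table = pd.DataFrame(records)
    summary = None
    if len(table):
        metric_cols = [c for c in table.columns if table[c].dtype.kind == "f"]
        summary = (
            table.groupby(["method", "group"])[metric_cols]
            .agg(["mean", lambda s: s.std(ddof=1)])
        )
        summary.columns = [
            f"{m}_{'sd' if callable(a) or a != 'mean' else 'mean'}"
            for m, a in summary.columns
        ]
        summary = summary.reset_index()

    bundle = {"table": table, "summary": summary, "failures": failures,
              "config": config}
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "metrics.csv", index=False)
        if summary is not None:
            summary.to_csv(out / "summary.csv", index=False)
        (out / "config.json").write_text(config.to_json())
        if failures:
            (out / "failures.json").write_text(json.dumps(failures, indent=2))
    return bundle


def compare_samplers(
    config: ExperimentConfig,
    metrics: tuple = ("rec_c1", "bal_acc", "mcc"),
) -> pd.DataFrame:
    """Relative disparity per correction method, per metric, per attribute.

    For each method, fits one final model per target group (DP-style
    methods target their own group; whole-population methods are fitted
    once), evaluates the test panel of every subgroup of each disparity
    attribute, and reports R1/R2 ratios. Rows: methods (always including
    ``original``); columns: (attribute, metric) disparity values.
    """
    seed = config.replicate_seeds[0]
    splits = _make_splits(config, seed)
    methods = list(config.methods)
    if "original" not in methods:
        methods = ["original"] + methods

    rows = []
    for method in methods:
        # For subgroup-targeted methods the deployed model depends on the
        # patient's group (g' = g); whole-population methods use one model.
        per_group_models: dict[str, CandidateModel] = {}
        if method in ("dp", "prioritized_reweight"):
            for group in config.groups:
                per_group_models[str(group)] = _fit_method(
                    method, splits, group, make_learner(config.learner),
                    config.max_units, seed,
                )
        else:
            anchor = config.groups[0] if config.groups else SubgroupKey("race", "white")
            shared = _fit_method(
                method, splits, anchor, make_learner(config.learner),
                config.max_units, seed,
            )

        row = {"method": method}
        for attr in config.disparity_attributes:
            values: dict[str, dict] = {}
            for value in splits.test.subgroup_values(attr):
                key = SubgroupKey(attr, value)
                model = per_group_models.get(str(key), None)
                if model is None and per_group_models:
                    continue  # targeted method: only configured groups compared
                mdl = model if model is not None else shared
                m = splits.test.group_mask(key)
                if not m.any() or len(np.unique(splits.test.labels[m])) < 2:
                    continue
                pred, prob = mdl.predict(splits.test)
                rep = compute_metrics(splits.test.labels[m], pred[m], prob[m])
                values[value] = rep
            for metric in metrics:
                vals = {k: getattr(r, metric) for k, r in values.items()}
                if len([v for v in vals.values() if v is not None]) >= 2:
                    row[f"{attr}:{metric}"] = relative_disparity(
                        vals, metric
                    ).disparity
                else:
                    row[f"{attr}:{metric}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def cross_group_experiment(
    config: ExperimentConfig, metric: str = "rec_c1"
) -> pd.DataFrame:
    """DP cross-group transfer matrix on the configured preset.

    One DP model per configured group (rows) evaluated on every
    configured group's test rows (columns), plus the original-model row.
    A diagonal that dominates its column indicates a matched DP model
    beats both mismatched DP models and the original model on its own
    group.
    """
    seed = config.replicate_seeds[0]
    splits = _make_splits(config, seed)
    models = {
        g: run_dp(
            splits, g, make_learner(config.learner), config.max_units, seed
        ).selected
        for g in config.groups
    }
    original = fit_original(
        splits, make_learner(config.learner), config.groups[0], seed
    )
    return cross_group_matrix(models, original, splits.test, metric)
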