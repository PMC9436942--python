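"""Tabular clinical datasets with demographic attributes.

The central container is :class:`ClinicalDataset`: an encoded numeric
feature matrix, a binary outcome (the minority prediction class is called
C1, e.g. in-hospital death; the majority class is C0), per-row demographic
attributes (race, age group, sex, ...), and a ``column_map`` recording
which encoded columns came from which source feature (identity for
continuous features, many-to-one for one-hot categoricals).

C1 is declared by the caller, never inferred from frequency: within a
subgroup the designated minority class may well be the local majority
(e.g. death among 90+ breast-cancer patients), and the dataset-level
designation must not flip under subsetting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalDataset",
    "SubgroupKey",
    "SplitBundle",
    "DatasetSchema",
    "SchemaError",
    "LabelError",
    "RowParseError",
    "SplitError",
    "load_dataset",
    "write_dataset",
    "stratified_split",
    "subset",
    "bin_age",
    "DEFAULT_AGE_BINS",
]


class SchemaError(ValueError):
    """A declared column is missing or the schema is inconsistent."""


class LabelError(ValueError):
    """The label column does not hold exactly two distinct values."""


class RowParseError(ValueError):
    """Feature values could not be parsed as numbers; carries offending ids."""

    def __init__(self, message: str, bad_ids: Sequence):
        super().__init__(message)
        self.bad_ids = list(bad_ids)


class SplitError(ValueError):
    """A train/validation/test split would leave a split without C1 cases."""


class KeyError_(KeyError):
    """Unknown demographic attribute."""


#: Default age-group bin edges, half-open [X, Y); below the first edge is
#: "<30" and at or above the last is "90+".
DEFAULT_AGE_BINS = (30, 40, 50, 60, 70, 80, 90)


def bin_age(ages, edges: Sequence[float] = DEFAULT_AGE_BINS) -> np.ndarray:
    """Map numeric ages to categorical age-group labels.

    Bins are half-open ``[X, Y)``: the lower edge is included, the upper
    excluded. Ages below the first edge map to ``"<E0"`` and ages at or
    above the last edge map to ``"E_last+"``.
    """
    edges = sorted(edges)
    labels = [f"<{edges[0]}"]
    labels += [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f"{edges[-1]}+")
    idx = np.searchsorted(edges, np.asarray(ages, dtype=float), side="right")
    return np.asarray(labels, dtype=object)[idx]


def age_bin_labels(edges: Sequence[float] = DEFAULT_AGE_BINS) -> list[str]:
    """All labels produced by :func:`bin_age`, in ascending age order."""
    edges = sorted(edges)
    return (
        [f"<{edges[0]}"]
        + [f"[{a},{b})" for a, b in zip(edges[:-1], edges[1:])]
        + [f"{edges[-1]}+"]
    )


@dataclass(frozen=True)
class SubgroupKey:
    """A demographic attribute/value pair identifying a target group.

    Examples: ``SubgroupKey("race", "Black")``,
    ``SubgroupKey("age_group", "[40,50)")``.
    """

    attribute: str
    value: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.attribute}={self.value}"

    @classmethod
    def parse(cls, text: str) -> "SubgroupKey":
        """Parse ``"attribute=value"`` (the CLI form)."""
        if "=" not in text:
            raise ValueError(f"expected 'attribute=value', got {text!r}")
        attr, _, val = text.partition("=")
        return cls(attr.strip(), val.strip())


@dataclass
class DatasetSchema:
    """Column-role declaration for loading a delimited-text dataset."""

    label_column: str
    positive_label: str
    demographic_columns: list[str]
    feature_columns: list[str] | None = None
    categorical_features: list[str] = field(default_factory=list)
    age_column: str | None = None
    age_bins: Sequence[float] = DEFAULT_AGE_BINS

    def to_json(self) -> str:
        d = {
            "label_column": self.label_column,
            "positive_label": self.positive_label,
            "demographic_columns": list(self.demographic_columns),
            "feature_columns": self.feature_columns,
            "categorical_features": list(self.categorical_features),
            "age_column": self.age_column,
            "age_bins": list(self.age_bins),
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DatasetSchema":
        d = json.loads(text)
        return cls(
            label_column=d["label_column"],
            positive_label=str(d["positive_label"]),
            demographic_columns=list(d["demographic_columns"]),
            feature_columns=d.get("feature_columns"),
            categorical_features=list(d.get("categorical_features", [])),
            age_column=d.get("age_column"),
            age_bins=tuple(d.get("age_bins", DEFAULT_AGE_BINS)),
        )


@dataclass
class ClinicalDataset:
    """Encoded features + binary labels + demographics + column bookkeeping.

    Parameters
    ----------
    features : pandas.DataFrame
        Numeric matrix, rows = patients, columns = encoded features.
    labels : numpy.ndarray
        0/1 vector; 1 is the minority prediction class C1.
    demographics : pandas.DataFrame
        One column per declared demographic attribute, aligned with rows.
    column_map : dict
        Encoded feature column -> source feature name. Identity for
        continuous features; several one-hot columns share a source name.
    ids : numpy.ndarray
        Stable per-row identifiers (surrogates when the input had none).
    """

    features: pd.DataFrame
    labels: np.ndarray
    demographics: pd.DataFrame
    column_map: dict[str, str]
    ids: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.ids = np.asarray(self.ids)
        n = len(self.features)
        if not (len(self.labels) == len(self.demographics) == len(self.ids) == n):
            raise ValueError("features, labels, demographics and ids must align")
        uniq = set(np.unique(self.labels))
        if not uniq <= {0, 1}:
            raise LabelError(f"labels must be 0/1, found {sorted(uniq)}")
        missing = set(self.features.columns) - set(self.column_map)
        extra = set(self.column_map) - set(self.features.columns)
        if missing or extra:
            raise SchemaError(
                f"column_map must cover every feature column exactly once "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def attributes(self) -> list[str]:
        return list(self.demographics.columns)

    @property
    def c1_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def c1_fraction(self) -> float:
        return float(self.labels.mean()) if self.n_rows else float("nan")

    def feature_matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def group_mask(self, key: SubgroupKey) -> np.ndarray:
        if key.attribute not in self.demographics.columns:
            raise KeyError_(
                f"unknown demographic attribute {key.attribute!r}; "
                f"declared: {self.attributes}"
            )
        return (
            self.demographics[key.attribute].astype(str).to_numpy() == str(key.value)
        )

    def subgroup_values(self, attribute: str) -> list[str]:
        if attribute not in self.demographics.columns:
            raise KeyError_(f"unknown demographic attribute {attribute!r}")
        vals = self.demographics[attribute].astype(str).unique().tolist()
        return sorted(vals)

    # -- derived datasets ------------------------------------------------
    def take(self, indices) -> "ClinicalDataset":
        """Row-subset view by positional indices (copying; views stay safe)."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        else:
            indices = indices.astype(int)
        return ClinicalDataset(
            features=self.features.iloc[indices].reset_index(drop=True),
            labels=self.labels[indices],
            demographics=self.demographics.iloc[indices].reset_index(drop=True),
            column_map=dict(self.column_map),
            ids=self.ids[indices],
        )

    def content_hash(self) -> str:
        """Hash of row contents; used to verify the test split is untouched."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.feature_matrix()).tobytes())
        h.update(self.labels.tobytes())
        h.update(self.demographics.astype(str).to_csv(index=False).encode())
        h.update(np.asarray(self.ids, dtype="U32").tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        """Single flat DataFrame (id, demographics, features, label)."""
        out = pd.DataFrame({"id": self.ids})
        for c in self.demographics.columns:
            out[c] = self.demographics[c].to_numpy()
        for c in self.features.columns:
            out[c] = self.features[c].to_numpy()
        out["label"] = self.labels
        return out


def subset(data: ClinicalDataset, key: SubgroupKey) -> ClinicalDataset:
    """Rows whose demographic value matches ``key``; empty result allowed."""
    return data.take(np.flatnonzero(data.group_mask(key)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(path, schema: DatasetSchema) -> ClinicalDataset:
    """Load a CSV into a :class:`ClinicalDataset`.

    Categorical feature columns are one-hot encoded (full dummy coding —
    no reference level is dropped, so per-column importances can later be
    summed or averaged back to the source feature). Row order is
    preserved; ids default to 0-based insertion order.
    """
    df = pd.read_csv(path)
    declared = [schema.label_column] + list(schema.demographic_columns)
    if schema.feature_columns is not None:
        declared += list(schema.feature_columns)
    if schema.age_column is not None:
        declared.append(schema.age_column)
    missing = [c for c in declared if c not in df.columns]
    if missing:
        raise SchemaError(f"missing declared columns: {missing}")

    lab = df[schema.label_column].astype(str)
    values = sorted(lab.unique())
    if len(values) != 2:
        raise LabelError(
            f"label column {schema.label_column!r} must hold exactly 2 "
            f"distinct values, found {values}"
        )
    if schema.positive_label not in values:
        raise LabelError(
            f"positive (C1) label {schema.positive_label!r} not among {values}"
        )
    labels = (lab == schema.positive_label).astype(int).to_numpy()

    demo = df[list(schema.demographic_columns)].astype(str).copy()
    if schema.age_column is not None:
        ages = pd.to_numeric(df[schema.age_column], errors="coerce")
        if ages.isna().any():
            bad = df.index[ages.isna()].tolist()
            raise RowParseError(f"unparseable ages in rows {bad}", bad)
        demo["age_group"] = bin_age(ages.to_numpy(), schema.age_bins)

    if schema.feature_columns is None:
        reserved = set(declared) | {"id"}
        feat_cols = [c for c in df.columns if c not in reserved]
    else:
        feat_cols = list(schema.feature_columns)

    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))

    blocks: list[pd.DataFrame] = []
    column_map: dict[str, str] = {}
    for c in feat_cols:
        if c in schema.categorical_features:
            onehot = pd.get_dummies(df[c].astype(str), prefix=c, dtype=float)
            blocks.append(onehot)
            for enc in onehot.columns:
                column_map[enc] = c
        else:
            num = pd.to_numeric(df[c], errors="coerce")
            if num.isna().any() and not df[c].isna().any():
                bad = ids[num.isna().to_numpy()].tolist()
                raise RowParseError(
                    f"unparseable numeric values in column {c!r}, rows {bad}",
                    bad,
                )
            if num.isna().any():
                bad = ids[num.isna().to_numpy()].tolist()
                raise RowParseError(f"missing values in column {c!r}, rows {bad}", bad)
            blocks.append(num.to_frame(name=c).astype(float))
            column_map[c] = c
    features = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)

    return ClinicalDataset(
        features=features.reset_index(drop=True),
        labels=labels,
        demographics=demo.reset_index(drop=True),
        column_map=column_map,
        ids=ids,
    )


def write_dataset(
    data: ClinicalDataset,
    path,
    label_names: tuple[str, str] = ("0", "1"),
) -> None:
    """Write a dataset to CSV (id, demographics, encoded features, label)."""
    out = data.to_frame()
    out["label"] = np.asarray(label_names, dtype=object)[data.labels]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitBundle:
    """Disjoint train/validation/test views of one source dataset.

    The test split is sacrosanct: no sampler or reweighter ever touches
    it, because at deployment the outcome of a new patient is unknown.
    """

    train: ClinicalDataset
    validation: ClinicalDataset
    test: ClinicalDataset
    split_fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self):
        ids = [set(s.ids.tolist()) for s in (self.train, self.validation, self.test)]
        if ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2]:
            raise SplitError("splits must be pairwise disjoint by id")


def stratified_split(
    data: ClinicalDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitBundle:
    """Deterministic stratified train/validation/test split.

    Stratifies jointly on label x every demographic attribute wherever the
    joint cell holds at least 3 rows; rows in smaller cells fall back to
    label-only strata. Within each stratum rows are shuffled with ``seed``
    and allocated to the three splits by largest-remainder rounding.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    joint = data.demographics.astype(str).agg("|".join, axis=1).to_numpy()
    strata = np.char.add(
        data.labels.astype(str), np.char.add("|", joint.astype(str))
    )
    # collapse joint cells with < 3 rows into label-only strata
    vals, counts = np.unique(strata, return_counts=True)
    small = {v for v, c in zip(vals, counts) if c < 3}
    strata = np.where(
        np.isin(strata, list(small)), data.labels.astype(str), strata
    )

    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    carry = np.zeros(3)  # fractional remainders carried across strata so the
    # global split sizes stay within +-1 of n * fractions
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        raw = np.array(fractions) * n + carry
        base = np.maximum(np.floor(raw), 0).astype(int)
        rem = n - base.sum()
        order = np.argsort(-(raw - base), kind="stable")
        for j in order[:rem]:
            base[j] += 1
        carry = raw - base
        cuts = np.cumsum(base)[:-1]
        for part, chunk in zip(parts, np.split(idx, cuts)):
            part.extend(chunk.tolist())

    splits = [data.take(sorted(p)) for p in parts]
    for name, s in zip(("train", "validation", "test"), splits):
        if s.n_rows and (s.labels == 1).sum() == 0:
            raise SplitError(
                f"{name} split received zero C1 rows; threshold tuning and "
                "evaluation require C1 cases in every split"
            )
    return SplitBundle(*splits, split_fractions=fractions, seed=seed)
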