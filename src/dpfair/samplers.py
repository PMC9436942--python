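"""Training-set samplers: DP subgroup enrichment and whole-population rebalancers.

``dp_enrich`` is the sample-enrichment step of double-prioritized (DP)
bias correction: it duplicates the minority-class (C1) training rows of
one demographic group a whole number of times ("units"), leaving every
other row alone. Sweeping the unit count 0..n yields the n+1 candidate
training sets the DP workflow trains on.

The remaining samplers are the standard whole-population comparisons:
random undersampling (RUS), NearMiss-1/NearMiss-3/Distant distance-based
undersampling, replicated oversampling (ROS), and interpolation-based
oversampling (SMOTE, ADASYN, and a gamma-interpolation variant). All of
them balance the two prediction classes; none of them distinguish
demographic subgroups — which is exactly the deficiency DP targets.

Samplers act on the training split only. Validation and test data are
never resampled: at deployment the outcome of a new patient is unknown.

Distances are Euclidean on the encoded feature matrix after per-column
standardization fitted on the input training data. Distance ties break
by ascending row position for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data import ClinicalDataset, SubgroupKey

__all__ = [
    "SampledDataset",
    "EnrichmentError",
    "dp_enrich",
    "random_undersample",
    "replicated_oversample",
    "nearmiss1",
    "nearmiss3",
    "distant",
    "smote",
    "adasyn",
    "gamma_oversample",
    "SAMPLERS",
]

DEFAULT_MAX_UNITS = 19


class EnrichmentError(ValueError):
    """The target subgroup has no minority-class rows to enrich."""


@dataclass
class SampledDataset:
    """A resampled training set plus per-row provenance.

    ``origin`` holds, for each output row, either ``"original"``, the id
    of the original row it duplicates (``"dup:<id>"``) or ``"synthetic"``.
    """

    data: ClinicalDataset
    method: str
    params: dict = field(default_factory=dict)
    origin: np.ndarray | None = None

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.data.ids, "origin": self.origin, "method": self.method}
        )


def _as_original(data: ClinicalDataset, method: str, params: dict) -> SampledDataset:
    return SampledDataset(
        data=data,
        method=method,
        params=params,
        origin=np.asarray(["original"] * data.n_rows, dtype=object),
    )


def _concat(
    train: ClinicalDataset,
    extra_features: np.ndarray,
    extra_demo: pd.DataFrame,
    extra_ids: np.ndarray,
    extra_label: int = 1,
) -> ClinicalDataset:
    feat = pd.DataFrame(extra_features, columns=train.features.columns)
    return ClinicalDataset(
        features=pd.concat([train.features, feat], ignore_index=True),
        labels=np.concatenate(
            [train.labels, np.full(len(feat), extra_label, dtype=int)]
        ),
        demographics=pd.concat(
            [train.demographics, extra_demo], ignore_index=True
        ),
        column_map=dict(train.column_map),
        ids=np.concatenate([np.asarray(train.ids), extra_ids]),
    )


def _fresh_ids(train: ClinicalDataset, count: int, tag: str) -> np.ndarray:
    return np.asarray([f"{tag}{i}" for i in range(count)], dtype=object)


# ---------------------------------------------------------------------------
# DP sample enrichment
# ---------------------------------------------------------------------------

def dp_enrich(
    train: ClinicalDataset, group: SubgroupKey, units: int
) -> SampledDataset:
    """Append ``units`` exact copies of every C1 row of ``group``.

    ``units = 0`` returns the training set unchanged. Rows outside
    C1 ∩ group are never duplicated. Raises :class:`EnrichmentError`
    when the group has no C1 rows.
    """
    if units < 0:
        raise ValueError("units must be >= 0")
    target = np.flatnonzero(train.c1_mask & train.group_mask(group))
    if target.size == 0:
        raise EnrichmentError(f"no C1 rows in group {group}")
    params = {"group": str(group), "units": int(units)}
    if units == 0:
        return _as_original(train, "dp", params)

    rep = np.tile(target, units)
    X = train.feature_matrix()
    out = _concat(
        train,
        X[rep],
        train.demographics.iloc[rep].reset_index(drop=True),
        np.asarray([f"dup:{train.ids[i]}:{k}" for k, i in enumerate(rep)], dtype=object),
    )
    origin = np.concatenate(
        [
            np.asarray(["original"] * train.n_rows, dtype=object),
            np.asarray([f"dup:{train.ids[i]}" for i in rep], dtype=object),
        ]
    )
    return SampledDataset(data=out, method="dp", params=params, origin=origin)


def enrichment_sweep(
    train: ClinicalDataset, group: SubgroupKey, max_units: int = DEFAULT_MAX_UNITS
) -> list[SampledDataset]:
    """The n+1 training sets for units 0..max_units, original included."""
    return [dp_enrich(train, group, u) for u in range(max_units + 1)]


# ---------------------------------------------------------------------------
# Whole-population undersamplers
# ---------------------------------------------------------------------------

def random_undersample(train: ClinicalDataset, seed: int = 0) -> SampledDataset:
    """Uniformly drop majority (C0) rows until the classes balance."""
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    if len(c0) <= len(c1):
        return _as_original(train, "rus", {"seed": seed})
    rng = np.random.default_rng(seed)
    keep_c0 = np.sort(rng.choice(c0, size=len(c1), replace=False))
    keep = np.sort(np.concatenate([keep_c0, c1]))
    return _as_original(train.take(keep), "rus", {"seed": seed})


def _standardized(train: ClinicalDataset) -> np.ndarray:
    X = train.feature_matrix()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _mean_knn_distance(
    majority: np.ndarray, minority: np.ndarray, k: int
) -> np.ndarray:
    """Mean distance of each majority point to its k nearest minority points."""
    k = min(k, len(minority))
    d = cdist(majority, minority)
    d.sort(axis=1)
    return d[:, :k].mean(axis=1)


def nearmiss1(train: ClinicalDataset, k: int = 3) -> SampledDataset:
    """Keep the |C1| majority rows closest (mean k-NN distance) to the minority."""
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    if len(c0) <= len(c1):
        return _as_original(train, "nearmiss1", {"k": k})
    Z = _standardized(train)
    score = _mean_knn_distance(Z[c0], Z[c1], k)
    # stable argsort: ties break by ascending row position
    keep_c0 = c0[np.argsort(score, kind="stable")[: len(c1)]]
    keep = np.sort(np.concatenate([keep_c0, c1]))
    return _as_original(train.take(keep), "nearmiss1", {"k": k})


def nearmiss3(train: ClinicalDataset, k: int = 3, m: int = 3) -> SampledDataset:
    """Two-stage undersampling around the class border.

    Stage 1 keeps, for every minority row, its ``m`` nearest majority rows
    as candidates. Stage 2 keeps the |C1| candidates with the *largest*
    mean distance to their ``k`` nearest minority rows. If the candidate
    pool is smaller than |C1| all candidates are kept with a warning.
    """
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    if len(c0) <= len(c1):
        return _as_original(train, "nearmiss3", {"k": k, "m": m})
    Z = _standardized(train)
    d = cdist(Z[c1], Z[c0])
    m_eff = min(m, len(c0))
    cand_pos = np.unique(np.argsort(d, axis=1, kind="stable")[:, :m_eff])
    cand = c0[cand_pos]
    if len(cand) < len(c1):
        warnings.warn(
            f"nearmiss3 candidate pool ({len(cand)}) smaller than |C1| "
            f"({len(c1)}); keeping all candidates",
            stacklevel=2,
        )
        keep_c0 = cand
    else:
        score = _mean_knn_distance(Z[cand], Z[c1], k)
        keep_c0 = cand[np.argsort(-score, kind="stable")[: len(c1)]]
    keep = np.sort(np.concatenate([keep_c0, c1]))
    return _as_original(train.take(keep), "nearmiss3", {"k": k, "m": m})


def distant(train: ClinicalDataset, k: int = 3) -> SampledDataset:
    """Keep the |C1| majority rows farthest from the minority (mirror of NearMiss-1)."""
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    if len(c0) <= len(c1):
        return _as_original(train, "distant", {"k": k})
    Z = _standardized(train)
    score = _mean_knn_distance(Z[c0], Z[c1], k)
    keep_c0 = c0[np.argsort(-score, kind="stable")[: len(c1)]]
    keep = np.sort(np.concatenate([keep_c0, c1]))
    return _as_original(train.take(keep), "distant", {"k": k})


# ---------------------------------------------------------------------------
# Whole-population oversamplers
# ---------------------------------------------------------------------------

def replicated_oversample(train: ClinicalDataset, seed: int = 0) -> SampledDataset:
    """Duplicate uniformly chosen minority rows (with replacement) to balance."""
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    deficit = len(c0) - len(c1)
    if deficit <= 0:
        return _as_original(train, "ros", {"seed": seed})
    rng = np.random.default_rng(seed)
    picks = c1[rng.integers(0, len(c1), size=deficit)]
    X = train.feature_matrix()
    out = _concat(
        train,
        X[picks],
        train.demographics.iloc[picks].reset_index(drop=True),
        np.asarray(
            [f"dup:{train.ids[i]}:{j}" for j, i in enumerate(picks)], dtype=object
        ),
    )
    origin = np.concatenate(
        [
            np.asarray(["original"] * train.n_rows, dtype=object),
            np.asarray([f"dup:{train.ids[i]}" for i in picks], dtype=object),
        ]
    )
    return SampledDataset(data=out, method="ros", params={"seed": seed}, origin=origin)


def _interpolated_oversample(
    train: ClinicalDataset,
    seed_rows: np.ndarray,
    k: int,
    lam_draw,
    method: str,
    params: dict,
) -> SampledDataset:
    """Shared SMOTE-style machinery: emit x + lam*(x' - x) per seed row.

    ``seed_rows`` lists the minority row index to interpolate from, one
    entry per synthetic point. Neighbors are the k nearest *minority*
    rows in standardized feature space; interpolation happens in the raw
    (unstandardized) encoded feature space. Demographics are inherited
    from the seed row. With a single minority row, falls back to
    replication with a warning.
    """
    c1 = np.flatnonzero(train.c1_mask)
    X = train.feature_matrix()
    rng_lam = lam_draw
    n_new = len(seed_rows)
    if n_new == 0:
        return _as_original(train, method, params)
    if len(c1) == 1:
        warnings.warn(
            f"{method}: single minority row; falling back to replication",
            stacklevel=3,
        )
        new_pts = np.tile(X[c1[0]], (n_new, 1))
        partners = np.full(n_new, c1[0])
    else:
        Z = _standardized(train)
        d = cdist(Z[c1], Z[c1])
        np.fill_diagonal(d, np.inf)
        k_eff = min(k, len(c1) - 1)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k_eff]  # minority-local
        pos_of = {row: i for i, row in enumerate(c1)}
        seed_pos = np.asarray([pos_of[r] for r in seed_rows])
        pick = rng_lam.integers(0, k_eff, size=n_new)
        partners = c1[nn[seed_pos, pick]]
        lam = params["_lam_fn"](rng_lam, n_new)
        new_pts = X[seed_rows] + lam[:, None] * (X[partners] - X[seed_rows])
    params = {kk: v for kk, v in params.items() if not kk.startswith("_")}
    out = _concat(
        train,
        new_pts,
        train.demographics.iloc[seed_rows].reset_index(drop=True),
        np.asarray([f"syn:{method}:{j}" for j in range(n_new)], dtype=object),
    )
    origin = np.concatenate(
        [
            np.asarray(["original"] * train.n_rows, dtype=object),
            np.asarray(["synthetic"] * n_new, dtype=object),
        ]
    )
    return SampledDataset(data=out, method=method, params=params, origin=origin)


def smote(train: ClinicalDataset, k: int = 5, seed: int = 0) -> SampledDataset:
    """Balance by interpolating between minority neighbors, lam ~ U[0,1]."""
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    deficit = len(c0) - len(c1)
    if deficit <= 0:
        return _as_original(train, "smote", {"k": k, "seed": seed})
    rng = np.random.default_rng(seed)
    seed_rows = c1[rng.integers(0, len(c1), size=deficit)]
    return _interpolated_oversample(
        train,
        seed_rows,
        k,
        rng,
        "smote",
        {"k": k, "seed": seed, "_lam_fn": lambda r, n: r.random(n)},
    )


def adasyn(train: ClinicalDataset, k: int = 5, seed: int = 0) -> SampledDataset:
    """Density-adaptive interpolation: harder minority rows get more synthetics.

    Each minority row i receives a share of the synthetic budget
    proportional to r_i = (majority rows among its k nearest neighbors
    overall) / k, rounded by largest remainder so the shares sum exactly
    to |C0| - |C1|. With all r_i = 0 (no borderline rows) the budget is
    allocated uniformly.
    """
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    deficit = len(c0) - len(c1)
    if deficit <= 0:
        return _as_original(train, "adasyn", {"k": k, "seed": seed})
    Z = _standardized(train)
    d = cdist(Z[c1], Z)
    d[np.arange(len(c1)), c1] = np.inf  # a row is not its own neighbor
    k_eff = min(k, train.n_rows - 1)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    is_majority = ~train.c1_mask
    r = is_majority[nn].sum(axis=1) / k_eff
    if r.sum() == 0:
        r = np.ones(len(c1))
    share = r / r.sum() * deficit
    counts = np.floor(share).astype(int)
    rem = deficit - counts.sum()
    order = np.argsort(-(share - counts), kind="stable")
    counts[order[:rem]] += 1
    seed_rows = np.repeat(c1, counts)
    rng = np.random.default_rng(seed)
    return _interpolated_oversample(
        train,
        seed_rows,
        k,
        rng,
        "adasyn",
        {"k": k, "seed": seed, "_lam_fn": lambda r_, n: r_.random(n)},
    )


def _gamma_lam(shape: float, scale: float):
    def draw(rng, n):
        lam = rng.gamma(shape, scale, size=n)
        bad = lam > 1.0
        while bad.any():  # resample out-of-range draws into [0,1]
            lam[bad] = rng.gamma(shape, scale, size=int(bad.sum()))
            bad = lam > 1.0
        return lam

    return draw


def gamma_oversample(
    train: ClinicalDataset,
    k: int = 5,
    shape: float = 4.0,
    scale: float = 0.125,
    seed: int = 0,
) -> SampledDataset:
    """SMOTE-style interpolation with gamma-distributed lam, resampled to [0,1].

    Defaults give E[lam] = shape*scale = 0.5 before truncation, i.e.
    synthetic points concentrated between neighbor pairs rather than
    uniformly spread.
    """
    c0 = np.flatnonzero(~train.c1_mask)
    c1 = np.flatnonzero(train.c1_mask)
    deficit = len(c0) - len(c1)
    if deficit <= 0:
        return _as_original(
            train, "gamma", {"k": k, "shape": shape, "scale": scale, "seed": seed}
        )
    rng = np.random.default_rng(seed)
    seed_rows = c1[rng.integers(0, len(c1), size=deficit)]
    return _interpolated_oversample(
        train,
        seed_rows,
        k,
        rng,
        "gamma",
        {
            "k": k,
            "shape": shape,
            "scale": scale,
            "seed": seed,
            "_lam_fn": _gamma_lam(shape, scale),
        },
    )


#: Whole-population samplers by CLI name (DP is separate: it needs a group).
SAMPLERS = {
    "rus": random_undersample,
    "ros": replicated_oversample,
    "nearmiss1": nearmiss1,
    "nearmiss3": nearmiss3,
    "distant": distant,
    "smote": smote,
    "adasyn": adasyn,
    "gamma": gamma_oversample,
}
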