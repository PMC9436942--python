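"""Synthetic imbalanced clinical-style tabular data.

The generator emulates the marginal structure of real hospital-mortality
and cancer-survivability cohorts without containing any patient data:
a skewed race/age/sex composition, a rare positive outcome (C1), and a
feature-outcome signal that may differ by demographic subgroup — the
premise that makes subgroup-targeted bias correction worthwhile.

Outcomes follow a logistic model: for a row with encoded features ``x``
in signal group ``s``,

    P(C1) = sigmoid(intercept_s + coef_s . x + eps),   eps ~ N(0, noise_sd)

where ``coef_s`` is a shared base coefficient vector plus an optional
subgroup-specific deviation, and ``intercept_s`` is solved numerically so
the realized expected prevalence of each signal group matches its target.
Label noise is identical across subgroups: representational imbalance is
the only bias present by construction.

Two presets mirror printed cohort compositions: ``ihm_like``
(in-hospital-mortality-like: 13.5% C1, 70.6% white, 9.6% Black, 76% of
ages in [50,90)) and ``bcs_like`` (breast-cancer-survivability-like:
12.7% C1, 81% white, 0.6% male, 70% of ages in [40,70)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data import ClinicalDataset, SubgroupKey, age_bin_labels

__all__ = ["PopulationSpec", "SpecError", "generate", "preset"]


class SpecError(ValueError):
    """Invalid population specification."""


def _check_mix(name: str, mix: Mapping[str, float]) -> None:
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise SpecError(f"{name} proportions must sum to 1, got {sum(mix.values())}")
    if any(p < 0 for p in mix.values()):
        raise SpecError(f"{name} proportions must be non-negative")


@dataclass
class PopulationSpec:
    """Everything needed to draw one synthetic cohort.

    ``c1_prevalence`` maps subgroup patterns (``SubgroupKey``) to target
    C1 probabilities, with ``"default"`` as the global fallback; a row is
    assigned to the first pattern it matches, in insertion order.
    ``signal_deviations`` adds a subgroup-specific coefficient deviation
    on top of ``base_coefficients`` for rows matching each pattern.
    """

    n_rows: int
    race_mix: dict[str, float]
    age_mix: dict[str, float]
    sex_mix: dict[str, float]
    c1_prevalence: dict = field(default_factory=dict)  # SubgroupKey -> p, + "default"
    n_continuous: int = 8
    n_categorical: int = 2
    categorical_levels: int = 3
    base_coefficients: np.ndarray | None = None
    signal_deviations: dict = field(default_factory=dict)  # SubgroupKey -> vector
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1:
            raise SpecError("n_rows must be >= 1")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be positive")
        _check_mix("race_mix", self.race_mix)
        _check_mix("age_mix", self.age_mix)
        _check_mix("sex_mix", self.sex_mix)
        for key, p in self.c1_prevalence.items():
            if not (0.0 < float(p) < 1.0):
                raise SpecError(f"prevalence for {key} must lie in (0,1), got {p}")

    @property
    def default_prevalence(self) -> float:
        return float(self.c1_prevalence.get("default", 0.5))

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        def enc_key(k):
            return "default" if k == "default" else f"{k.attribute}={k.value}"

        d = {
            "n_rows": self.n_rows,
            "race_mix": self.race_mix,
            "age_mix": self.age_mix,
            "sex_mix": self.sex_mix,
            "c1_prevalence": {enc_key(k): v for k, v in self.c1_prevalence.items()},
            "n_continuous": self.n_continuous,
            "n_categorical": self.n_categorical,
            "categorical_levels": self.categorical_levels,
            "base_coefficients": (
                None
                if self.base_coefficients is None
                else np.asarray(self.base_coefficients).tolist()
            ),
            "signal_deviations": {
                enc_key(k): np.asarray(v).tolist()
                for k, v in self.signal_deviations.items()
            },
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PopulationSpec":
        d = json.loads(text)

        def dec_key(k):
            return "default" if k == "default" else SubgroupKey.parse(k)

        return cls(
            n_rows=d["n_rows"],
            race_mix=d["race_mix"],
            age_mix=d["age_mix"],
            sex_mix=d["sex_mix"],
            c1_prevalence={dec_key(k): v for k, v in d["c1_prevalence"].items()},
            n_continuous=d["n_continuous"],
            n_categorical=d["n_categorical"],
            categorical_levels=d.get("categorical_levels", 3),
            base_coefficients=(
                None
                if d.get("base_coefficients") is None
                else np.asarray(d["base_coefficients"], dtype=float)
            ),
            signal_deviations={
                dec_key(k): np.asarray(v, dtype=float)
                for k, v in d["signal_deviations"].items()
            },
            noise_sd=d["noise_sd"],
            seed=d["seed"],
        )


def _sample_categorical(rng, mix: Mapping[str, float], n: int) -> np.ndarray:
    cats = list(mix.keys())
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    return np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n, p=probs)]


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept b with mean(sigmoid(b + eta)) = target, by bisection."""

    def gap(b):
        return float(expit(b + eta).mean() - target)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:  # pragma: no cover - requires extreme coefs
        raise SpecError(
            f"target prevalence {target} unattainable given the signal"
        )
    return brentq(gap, lo, hi, xtol=1e-10)


def generate(spec: PopulationSpec) -> ClinicalDataset:
    """Draw one synthetic cohort; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows

    demo = pd.DataFrame(
        {
            "race": _sample_categorical(rng, spec.race_mix, n),
            "age_group": _sample_categorical(rng, spec.age_mix, n),
            "sex": _sample_categorical(rng, spec.sex_mix, n),
        }
    )

    blocks: list[pd.DataFrame] = []
    column_map: dict[str, str] = {}
    cont = rng.standard_normal((n, spec.n_continuous))
    for j in range(spec.n_continuous):
        name = f"x{j}"
        blocks.append(pd.DataFrame({name: cont[:, j]}))
        column_map[name] = name
    for j in range(spec.n_categorical):
        name = f"c{j}"
        levels = [f"L{m}" for m in range(spec.categorical_levels)]
        draw = np.asarray(levels, dtype=object)[
            rng.integers(0, spec.categorical_levels, size=n)
        ]
        onehot = pd.get_dummies(pd.Series(draw), prefix=name, dtype=float)
        onehot = onehot.reindex(
            columns=[f"{name}_{lv}" for lv in levels], fill_value=0.0
        )
        blocks.append(onehot.reset_index(drop=True))
        for enc in onehot.columns:
            column_map[enc] = name
    features = pd.concat(blocks, axis=1)
    X = features.to_numpy(dtype=float)
    p = X.shape[1]

    base = (
        np.zeros(p)
        if spec.base_coefficients is None
        else np.asarray(spec.base_coefficients, dtype=float)
    )
    if base.shape != (p,):
        raise SpecError(
            f"base_coefficients must have length {p} (encoded), got {base.shape}"
        )

    def mask_of(key: SubgroupKey) -> np.ndarray:
        if key.attribute not in demo.columns:
            raise SpecError(f"pattern attribute {key.attribute!r} not generated")
        return demo[key.attribute].to_numpy() == key.value

    # assign each row to its first matching prevalence pattern
    patterns = [k for k in spec.c1_prevalence if k != "default"]
    assign = np.full(n, -1, dtype=int)
    for i, key in enumerate(patterns):
        m = mask_of(key) & (assign == -1)
        assign[m] = i

    coef = np.tile(base, (n, 1))
    for key, dev in spec.signal_deviations.items():
        dev = np.asarray(dev, dtype=float)
        if dev.shape != (p,):
            raise SpecError(
                f"deviation for {key} must have length {p}, got {dev.shape}"
            )
        coef[mask_of(key)] += dev

    eta = (coef * X).sum(axis=1) + rng.normal(0.0, spec.noise_sd, size=n)

    prob = np.empty(n)
    for i in range(-1, len(patterns)):
        m = assign == i
        if not m.any():
            continue
        target = (
            spec.default_prevalence
            if i == -1
            else float(spec.c1_prevalence[patterns[i]])
        )
        b = _solve_intercept(eta[m], target)
        prob[m] = expit(b + eta[m])

    labels = (rng.random(n) < prob).astype(int)
    return ClinicalDataset(
        features=features,
        labels=labels,
        demographics=demo,
        column_map=column_map,
        ids=np.arange(n),
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Shared base signal: moderate effects on the first four continuous
# features and a mild effect on the first categorical feature's levels.
# Continuous features x4..x7 carry no population-level signal.
_BASE = np.array(
    [1.0, -0.8, 0.6, -0.5, 0.0, 0.0, 0.0, 0.0]  # x0..x7
    + [0.3, -0.3, 0.0]  # c0 one-hot
    + [0.0, 0.2, -0.2]  # c1 one-hot
)

# Subgroup deviations activate markers (x4..x7) that are uninformative in
# the rest of the population: a model fitted to the pooled data dilutes
# their coefficients by the group's small share, so it systematically
# under-uses the group's own predictive signal — the situation
# subgroup-targeted enrichment is designed to repair.
_DEV_STRONG = np.array(
    [0.0, 0.0, 0.0, 0.0, 2.2, -1.8, 0.0, 0.0] + [0.0] * 6
)
_DEV_MODERATE = np.array(
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.6, -1.2] + [0.0] * 6
)


def preset(name: str, n_rows: int = 20_000, seed: int = 0) -> PopulationSpec:
    """Named cohort specifications.

    ``ihm_like``
        Hospital-mortality-like: C1 prevalence 0.135; races 70.6% white,
        9.6% Black; 76% of age mass in [50,90); subgroup-specific signal
        for Black and 90+ patients.
    ``bcs_like``
        Breast-cancer-survivability-like: C1 prevalence 0.127; 81% white;
        0.6% male; 70% of age mass in [40,70); subgroup-specific signal
        for Hispanic, Asian and [40,50) patients.

    All mixes and deviation vectors are ordinary spec fields and can be
    overridden after construction.
    """
    bins = age_bin_labels()
    if name == "ihm_like":
        age_mix = dict(
            zip(bins, [0.05, 0.06, 0.09, 0.19, 0.19, 0.19, 0.19, 0.04])
        )
        return PopulationSpec(
            n_rows=n_rows,
            race_mix={
                "white": 0.706,
                "Black": 0.096,
                "Hispanic": 0.04,
                "Asian": 0.03,
                "other": 0.128,
            },
            age_mix=age_mix,
            sex_mix={"female": 0.451, "male": 0.549},
            c1_prevalence={"default": 0.135},
            base_coefficients=_BASE.copy(),
            signal_deviations={
                SubgroupKey("race", "Black"): _DEV_STRONG.copy(),
                SubgroupKey("age_group", "90+"): _DEV_MODERATE.copy(),
            },
            noise_sd=0.5,
            seed=seed,
        )
    if name == "bcs_like":
        age_mix = dict(
            zip(bins, [0.02, 0.10, 0.23, 0.24, 0.23, 0.10, 0.06, 0.02])
        )
        return PopulationSpec(
            n_rows=n_rows,
            race_mix={
                "white": 0.81,
                "Black": 0.09,
                "Hispanic": 0.06,
                "Asian": 0.04,
            },
            age_mix=age_mix,
            sex_mix={"female": 0.994, "male": 0.006},
            c1_prevalence={"default": 0.127},
            base_coefficients=_BASE.copy(),
            signal_deviations={
                SubgroupKey("race", "Hispanic"): _DEV_STRONG.copy(),
                SubgroupKey("race", "Asian"): _DEV_MODERATE.copy(),
                SubgroupKey("age_group", "[40,50)"): _DEV_MODERATE.copy(),
            },
            noise_sd=0.5,
            seed=seed,
        )
    raise SpecError(f"unknown preset {name!r} (expected 'ihm_like' or 'bcs_like')")
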