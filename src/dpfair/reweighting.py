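"""Per-row training weights: standard class balancing and prioritized subgroup weights.

Standard reweighting equalizes the total weight of the two prediction
classes: class c gets per-sample weight N / (2 N_c), so each class
contributes total weight N/2 and the overall total stays N. With a rare
minority class this puts each minority sample above 1 and each majority
sample below 1 (e.g. a 12.7% minority yields weights 3.94 / 0.57).

Prioritized reweighting is the weighting twin of DP sample enrichment:
only the minority-class (C1) rows of one demographic subgroup have their
default weight of 1 multiplied by an integer unit n; everything else
stays at 1. For an exactly optimized convex weighted learner, weight n
is equivalent to training with n copies of those rows, i.e. to
``dp_enrich`` with n-1 extra units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ClinicalDataset, SubgroupKey

__all__ = [
    "WeightAssignment",
    "ReweightError",
    "standard_reweight",
    "prioritized_reweight",
    "sweep_prioritized",
]

DEFAULT_MAX_UNIT = 20


class ReweightError(ValueError):
    pass


@dataclass
class WeightAssignment:
    """Positive per-row weights aligned with a training dataset."""

    weights: np.ndarray
    method: str  # "standard" | "prioritized"
    group: SubgroupKey | None = None
    unit: int | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ReweightError("all weights must be positive")

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def standard_reweight(train: ClinicalDataset) -> WeightAssignment:
    """Class-balanced weights w_c = N / (2 N_c).

    Total weight per class is N/2; the overall total is preserved at N.
    Whenever C1 is the rarer class, its weight exceeds 1 and the majority
    weight is below 1.
    """
    n = train.n_rows
    n1 = int(train.c1_mask.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ReweightError("standard reweighting requires both classes present")
    w = np.where(train.c1_mask, n / (2.0 * n1), n / (2.0 * n0))
    return WeightAssignment(weights=w, method="standard")


def prioritized_reweight(
    train: ClinicalDataset, group: SubgroupKey, unit: int
) -> WeightAssignment:
    """Weight = ``unit`` on C1 rows of ``group``; 1 elsewhere."""
    if unit < 1:
        raise ReweightError("unit must be >= 1")
    target = train.c1_mask & train.group_mask(group)
    if not target.any():
        raise ReweightError(f"no C1 rows in group {group}")
    w = np.where(target, float(unit), 1.0)
    return WeightAssignment(weights=w, method="prioritized", group=group, unit=unit)


def sweep_prioritized(
    train: ClinicalDataset,
    group: SubgroupKey,
    max_unit: int = DEFAULT_MAX_UNIT,
) -> list[WeightAssignment]:
    """Assignments for unit = 1..max_unit, feeding DP-style model selection."""
    return [prioritized_reweight(train, group, u) for u in range(1, max_unit + 1)]
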