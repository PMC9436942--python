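import numpy as np
import pandas as pd
import pytest

from dpfair import ClinicalDataset, SubgroupKey


def make_dataset(
    n: int = 100,
    c1_fraction: float = 0.1,
    n_features: int = 4,
    races=("white", "Black", "Hispanic"),
    race_probs=(0.7, 0.2, 0.1),
    seed: int = 0,
) -> ClinicalDataset:
    """Small random dataset with controllable class and race composition."""
    rng = np.random.default_rng(seed)
    n1 = max(1, int(round(n * c1_fraction)))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n1, replace=False)] = 1
    feats = pd.DataFrame(
        rng.standard_normal((n, n_features)),
        columns=[f"x{i}" for i in range(n_features)],
    )
    demo = pd.DataFrame(
        {
            "race": rng.choice(races, size=n, p=race_probs),
            "sex": rng.choice(["female", "male"], size=n),
        }
    )
    return ClinicalDataset(
        features=feats,
        labels=labels,
        demographics=demo,
        column_map={c: c for c in feats.columns},
        ids=np.arange(n),
    )


def dataset_from_points(minority, majority, race_minority="g", race_majority="g"):
    """Dataset from explicit coordinates: minority rows first, then majority."""
    pts = np.asarray(list(minority) + list(majority), dtype=float)
    labels = np.array([1] * len(minority) + [0] * len(majority))
    feats = pd.DataFrame(pts, columns=[f"x{i}" for i in range(pts.shape[1])])
    demo = pd.DataFrame(
        {"race": [race_minority] * len(minority) + [race_majority] * len(majority)}
    )
    return ClinicalDataset(
        features=feats,
        labels=labels,
        demographics=demo,
        column_map={c: c for c in feats.columns},
        ids=np.arange(len(pts)),
    )


@pytest.fixture
def toy_dataset():
    return make_dataset(n=120, c1_fraction=0.25, seed=42)


@pytest.fixture
def black_group():
    return SubgroupKey("race", "Black")
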