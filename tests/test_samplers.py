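"""Sampler contracts: DP enrichment plus the eight whole-population rebalancers.

Distance-based samplers are checked against exhaustive brute-force
distance computations on explicit coordinates.
"""

import numpy as np
import pytest

from dpfair import (
    SubgroupKey,
    adasyn,
    distant,
    dp_enrich,
    gamma_oversample,
    nearmiss1,
    nearmiss3,
    random_undersample,
    replicated_oversample,
    smote,
)
from dpfair.samplers import EnrichmentError, enrichment_sweep

from conftest import dataset_from_points, make_dataset


def counts(data):
    return int((data.labels == 0).sum()), int((data.labels == 1).sum())


class TestDPEnrich:
    def test_adds_exactly_units_times_group_c1(self, toy_dataset, black_group):
        base = toy_dataset
        k = int((base.c1_mask & base.group_mask(black_group)).sum())
        assert k > 0
        out = dp_enrich(base, black_group, 3)
        assert out.data.n_rows == base.n_rows + 3 * k
        # every added row is a bit-identical copy of a Black C1 original
        added = out.data.take(range(base.n_rows, out.data.n_rows))
        assert (added.labels == 1).all()
        assert (added.demographics["race"] == "Black").all()
        originals = {
            tuple(row)
            for row in base.feature_matrix()[
                base.c1_mask & base.group_mask(black_group)
            ]
        }
        for row in added.feature_matrix():
            assert tuple(row) in originals

    def test_zero_units_is_identity(self, toy_dataset, black_group):
        out = dp_enrich(toy_dataset, black_group, 0)
        assert out.data.n_rows == toy_dataset.n_rows
        assert np.array_equal(out.data.labels, toy_dataset.labels)

    def test_sweep_yields_n_plus_one_datasets(self, toy_dataset, black_group):
        sweep = enrichment_sweep(toy_dataset, black_group, max_units=19)
        assert len(sweep) == 20
        k = int(
            (toy_dataset.c1_mask & toy_dataset.group_mask(black_group)).sum()
        )
        sizes = [s.data.n_rows for s in sweep]
        assert sizes == [toy_dataset.n_rows + u * k for u in range(20)]

    def test_provenance_references_existing_originals(self, toy_dataset, black_group):
        out = dp_enrich(toy_dataset, black_group, 2)
        dup_refs = [
            o.split(":", 1)[1] for o in out.origin if o.startswith("dup:")
        ]
        valid = {str(i) for i in toy_dataset.ids}
        assert dup_refs and all(r in valid for r in dup_refs)

    def test_empty_target_group_raises(self, toy_dataset):
        with pytest.raises(EnrichmentError):
            dp_enrich(toy_dataset, SubgroupKey("race", "Martian"), 1)


class TestRandomUndersample:
    def test_balances_counts(self):
        data = make_dataset(n=100, c1_fraction=0.1, seed=1)
        out = random_undersample(data, seed=0)
        assert counts(out.data) == (10, 10)
        assert out.data.n_rows == 20

    def test_already_balanced_unchanged(self):
        data = make_dataset(n=40, c1_fraction=0.5, seed=2)
        out = random_undersample(data, seed=0)
        assert out.data.n_rows == data.n_rows

    def test_seeds_vary_subset_not_counts(self):
        data = make_dataset(n=100, c1_fraction=0.1, seed=1)
        kept = set()
        for seed in range(10):
            out = random_undersample(data, seed=seed)
            assert counts(out.data) == (10, 10)
            kept.add(tuple(sorted(out.data.ids.tolist())))
        assert len(kept) > 1  # different seeds pick different C0 subsets


LINE = dict(minority=[(0.0, 0.0)], majority=[(1.0, 0.0), (2.0, 0.0), (5.0, 0.0)])


class TestDistanceBasedUndersamplers:
    def test_nearmiss1_keeps_closest(self):
        data = dataset_from_points(**LINE)
        out = nearmiss1(data, k=1)
        # brute force: distances 1, 2, 5 -> keep (1, 0)
        kept_majority = out.data.feature_matrix()[out.data.labels == 0]
        assert kept_majority.tolist() == [[1.0, 0.0]]

    def test_distant_keeps_farthest(self):
        data = dataset_from_points(**LINE)
        out = distant(data, k=1)
        kept_majority = out.data.feature_matrix()[out.data.labels == 0]
        assert kept_majority.tolist() == [[5.0, 0.0]]

    def test_nearmiss3_two_stage_on_line(self):
        # stage 1 candidates: all 3 majority rows (m=3); stage 2 keeps the
        # farthest one -> (5, 0)
        data = dataset_from_points(**LINE)
        out = nearmiss3(data, k=1, m=3)
        kept_majority = out.data.feature_matrix()[out.data.labels == 0]
        assert kept_majority.tolist() == [[5.0, 0.0]]

    def test_nearmiss1_tie_breaks_by_row_order(self):
        data = dataset_from_points(
            minority=[(0.0, 0.0)],
            majority=[(1.0, 0.0), (-1.0, 0.0), (0.0, 1.0)],  # all equidistant
        )
        out = nearmiss1(data, k=1)
        kept = out.data.ids[out.data.labels == 0]
        assert kept.tolist() == [1]  # the first majority row (lowest id)

    @pytest.mark.parametrize("sampler", [nearmiss1, nearmiss3, distant])
    def test_output_balanced(self, sampler):
        data = make_dataset(n=200, c1_fraction=0.15, seed=4)
        out = sampler(data)
        n0, n1 = counts(out.data)
        assert n0 == n1

    @pytest.mark.parametrize("seed", range(5))
    def test_nearmiss1_distant_disjoint_on_random_sets(self, seed):
        """With |C0| >= 2|C1| and distinct distances the nearest-kept and
        farthest-kept majority sets cannot overlap (brute-force property)."""
        rng = np.random.default_rng(seed)
        data = dataset_from_points(
            minority=rng.normal(size=(5, 2)).tolist(),
            majority=rng.normal(size=(14, 2)).tolist(),
        )
        near = set(nearmiss1(data, k=3).data.ids[nearmiss1(data, k=3).data.labels == 0])
        far = set(distant(data, k=3).data.ids[distant(data, k=3).data.labels == 0])
        assert not (near & far)

    def test_nearmiss3_candidate_shortfall_warns(self):
        data = dataset_from_points(
            minority=[(0.0, 0.0)] * 4,
            majority=[(1.0, 0.0)] * 6,
        )
        with pytest.warns(UserWarning, match="candidate pool"):
            out = nearmiss3(data, k=1, m=1)
        n0, _ = counts(out.data)
        assert n0 == 1  # the single candidate survives


class TestReplicatedOversample:
    def test_balances_and_duplicates_originals(self):
        data = make_dataset(n=100, c1_fraction=0.1, seed=1)
        out = replicated_oversample(data, seed=0)
        assert out.data.n_rows == 180
        assert counts(out.data) == (90, 90)
        originals = {tuple(r) for r in data.feature_matrix()[data.c1_mask]}
        added = out.data.feature_matrix()[100:]
        assert all(tuple(r) in originals for r in added)

    def test_balanced_input_unchanged(self):
        data = make_dataset(n=40, c1_fraction=0.5, seed=2)
        assert replicated_oversample(data, seed=0).data.n_rows == 40


class TestSMOTE:
    def test_synthetic_points_on_minority_segments(self):
        data = make_dataset(n=80, c1_fraction=0.2, seed=6)
        out = smote(data, k=3, seed=1)
        n0, n1 = counts(out.data)
        assert n0 == n1
        minority = data.feature_matrix()[data.c1_mask]
        for pt in out.data.feature_matrix()[data.n_rows:]:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = (d * d).sum()
                    if denom == 0:
                        continue
                    lam = ((pt - minority[i]) @ d) / denom
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                        minority[i] + lam * d, pt, atol=1e-9
                    ):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_demographics_inherited_from_seed_row(self):
        data = make_dataset(n=80, c1_fraction=0.2, seed=6)
        out = smote(data, k=3, seed=1)
        added = out.data.demographics.iloc[data.n_rows:]
        assert set(added["race"]) <= set(data.demographics["race"])

    def test_single_minority_row_falls_back_to_replication(self):
        data = dataset_from_points(
            minority=[(1.0, 2.0)], majority=[(0.0, 0.0)] * 5
        )
        with pytest.warns(UserWarning, match="single minority"):
            out = smote(data, k=3, seed=0)
        added = out.data.feature_matrix()[data.n_rows:]
        assert np.allclose(added, [1.0, 2.0])


class TestADASYN:
    def test_total_generated_exactly_fills_deficit(self):
        data = make_dataset(n=150, c1_fraction=0.2, seed=8)
        out = adasyn(data, k=5, seed=0)
        n0, n1 = counts(out.data)
        assert n0 == n1
        assert out.data.n_rows == data.n_rows + (n0 - int(data.c1_mask.sum()))

    def test_hard_rows_receive_the_budget(self):
        # one minority point surrounded by majority (r=1), the rest in a
        # tight remote cluster (r=0): the entire budget goes to the hard row
        far = [(10.0 + 0.01 * i, 10.0) for i in range(5)]
        data = dataset_from_points(
            minority=[(0.0, 0.0)] + far,
            majority=[(0.1, 0.0), (-0.1, 0.0), (0.0, 0.1), (0.0, -0.1),
                      (0.1, 0.1), (-0.1, -0.1), (0.2, 0.0), (-0.2, 0.0)],
        )
        out = adasyn(data, k=4, seed=0)
        added = out.data.feature_matrix()[data.n_rows:]
        # synthetic points interpolate from (0,0) toward its minority
        # neighbors; none originate in the remote cluster interior alone
        assert len(added) == 8 - 6
        assert (np.linalg.norm(added, axis=1) < np.linalg.norm([10, 10])).all()


class TestGammaOversample:
    def test_balances_and_lambda_in_unit_interval(self):
        data = make_dataset(n=120, c1_fraction=0.25, seed=9)
        out = gamma_oversample(data, seed=3)
        n0, n1 = counts(out.data)
        assert n0 == n1

    def test_small_scale_concentrates_near_seed_points(self):
        data = make_dataset(n=60, c1_fraction=0.3, seed=10)
        out = gamma_oversample(data, shape=4.0, scale=1e-6, seed=0)
        added = out.data.feature_matrix()[data.n_rows:]
        originals = data.feature_matrix()[data.c1_mask]
        for pt in added:
            assert np.min(np.linalg.norm(originals - pt, axis=1)) < 1e-3

    def test_mean_lambda_matches_gamma_moments(self):
        rng = np.random.default_rng(0)
        draws = rng.gamma(4.0, 0.125, size=100_000)
        assert abs(draws.mean() - 0.5) < 0.01  # shape * scale


@pytest.mark.parametrize(
    "sampler",
    [random_undersample, replicated_oversample, smote, adasyn, gamma_oversample],
)
def test_seeded_samplers_are_deterministic(sampler):
    data = make_dataset(n=100, c1_fraction=0.15, seed=11)
    a = sampler(data, seed=5)
    b = sampler(data, seed=5)
    assert np.array_equal(a.data.feature_matrix(), b.data.feature_matrix())
    assert np.array_equal(a.data.labels, b.data.labels)
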