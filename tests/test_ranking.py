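import numpy as np
import pytest

from deepida.datasets import (MultiViewDataset, NetworkSpec, TrainConfig,
                              validate_dataset)
from deepida.ranking import (aggregate_rank, make_pairs, permutation_scores,
                             rank_features, run_ensemble, select_and_retrain)


def blobs_dataset(rng, n_per_class=30, p=(12, 8), shift=4.0, n_signal=2):
    """Two well-separated Gaussian classes; signal in the first columns."""
    n = 2 * n_per_class
    labels = np.repeat([1, 2], n_per_class)
    views = []
    for pd in p:
        X = rng.standard_normal((n, pd))
        X[labels == 2, :n_signal] += shift
        views.append(X)
    return validate_dataset(MultiViewDataset(views=views, labels=labels))


@pytest.fixture
def tiny_spec():
    return NetworkSpec.uniform(2, hidden=(8,), output=3)


@pytest.fixture
def tiny_cfg():
    # separation-weighted: tiny samples make the association term easy to
    # satisfy spuriously
    return TrainConfig(epochs=15, lr=1e-2, seed=0, rho=0.8)


class TestMakePairs:
    def test_full_feature_fraction(self, small_dataset):
        pairs = make_pairs(small_dataset, M=3, feature_frac=1.0, seed=0)
        for pair in pairs:
            for d, p in enumerate(small_dataset.n_features):
                np.testing.assert_array_equal(pair.features[d], np.arange(p))

    def test_stratified_class_counts(self, rng):
        labels = np.repeat([1, 2], [8, 4])
        views = [rng.standard_normal((12, 5)), rng.standard_normal((12, 5))]
        ds = validate_dataset(MultiViewDataset(views=views, labels=labels))
        for pair in make_pairs(ds, M=10, seed=1):
            counts = np.bincount(ds.labels[pair.in_bag], minlength=3)[1:]
            assert list(counts) == [8, 4]

    def test_out_of_bag_disjoint_from_draws(self, small_dataset):
        for pair in make_pairs(small_dataset, M=5, seed=2):
            assert np.intersect1d(pair.in_bag, pair.out_of_bag).size == 0
            assert np.unique(ds_labels := small_dataset.labels[pair.out_of_bag]).size \
                == small_dataset.n_classes

    def test_feature_subset_sizes(self, small_dataset):
        pairs = make_pairs(small_dataset, M=4, feature_frac=0.8, seed=3)
        for pair in pairs:
            for d, p in enumerate(small_dataset.n_features):
                assert pair.features[d].size == int(np.floor(0.8 * p))
                assert np.unique(pair.features[d]).size == pair.features[d].size

    def test_oob_fraction_near_bootstrap_identity(self, rng):
        labels = np.repeat([1, 2], 150)
        views = [rng.standard_normal((300, 3)), rng.standard_normal((300, 3))]
        ds = validate_dataset(MultiViewDataset(views=views, labels=labels))
        fracs = [p.out_of_bag.size / 300 for p in make_pairs(ds, M=30, seed=4)]
        # E[OOB fraction] = (1 - 1/n)^n ~ exp(-1) = 0.368
        assert np.mean(fracs) == pytest.approx(np.exp(-1), abs=0.02)

    def test_bad_fraction_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            make_pairs(small_dataset, M=2, feature_frac=0.0, seed=0)


class TestEnsembleAndPermutation:
    def test_separable_baseline_near_one(self, rng, tiny_spec, tiny_cfg):
        ds = blobs_dataset(rng)
        pairs = make_pairs(ds, M=2, seed=5)
        models, baselines = run_ensemble(ds, pairs, tiny_spec, tiny_cfg)
        assert baselines.min() > 0.9
        for model, pair in zip(models, pairs):
            assert model.nets[0].sizes[0] == pair.features[0].size

    def test_permuting_constant_column_changes_nothing(self, rng, tiny_spec, tiny_cfg):
        ds = blobs_dataset(rng)
        ds.views[0][:, 5] = 2.5            # constant column
        ds = validate_dataset(ds)
        pairs = make_pairs(ds, M=1, feature_frac=1.0, seed=6)
        models, baselines = run_ensemble(ds, pairs, tiny_spec, tiny_cfg)
        oob = ds.subset_features(pairs[0].features).subset_samples(pairs[0].out_of_bag)
        ind = permutation_scores(models[0], pairs[0], oob, baselines[0], seed=1)
        assert not ind[0][5]

    def test_signal_feature_hit_rate_dominates(self, rng, tiny_spec, tiny_cfg):
        ds = blobs_dataset(rng, shift=3.0, n_signal=1)
        result = rank_features(ds, tiny_spec, tiny_cfg, M=8, seed=7)
        for d in range(2):
            noise = np.delete(result.proportions[d], 0)
            assert result.proportions[d][0] > noise.mean()

    def test_deterministic_under_seed(self, rng, tiny_spec, tiny_cfg):
        ds = blobs_dataset(rng, n_per_class=20)
        r1 = rank_features(ds, tiny_spec, tiny_cfg, M=3, seed=11)
        r2 = rank_features(ds, tiny_spec, tiny_cfg, M=3, seed=11)
        np.testing.assert_array_equal(r1.baselines, r2.baselines)
        for d in range(2):
            np.testing.assert_array_equal(r1.order[d], r2.order[d])
            np.testing.assert_array_equal(r1.hits[d], r2.hits[d])


class TestAggregateRank:
    def test_perfect_feature_ranks_first(self):
        ind = [[np.array([True, False, False]), np.array([False])]] * 4
        feats = [[np.array([0, 1, 2]), np.array([0])]] * 4
        res = aggregate_rank(ind, feats, [3, 1])
        assert res.order[0][0] == 0
        assert res.proportions[0][0] == 1.0
        np.testing.assert_array_equal(res.hits[0], [4, 0, 0])
        np.testing.assert_array_equal(res.exposures[0], [4, 4, 4])

    def test_never_exposed_feature_warns_and_zero(self, caplog):
        import logging
        ind = [[np.array([True]), np.array([False])]]
        feats = [[np.array([0]), np.array([0])]]
        with caplog.at_level(logging.WARNING, logger="deepida.ranking"):
            res = aggregate_rank(ind, feats, [2, 1])
        assert res.proportions[0][1] == 0.0
        assert any("never sampled" in r.message for r in caplog.records)

    def test_order_invariant_to_pair_shuffling(self, rng):
        M, p = 6, 5
        ind, feats = [], []
        for m in range(M):
            f = np.sort(rng.choice(p, 4, replace=False))
            ind.append([rng.random(4) < 0.5, np.array([False])])
            feats.append([f, np.array([0])])
        res1 = aggregate_rank(ind, feats, [p, 1])
        perm = rng.permutation(M)
        res2 = aggregate_rank([ind[i] for i in perm], [feats[i] for i in perm],
                              [p, 1])
        np.testing.assert_array_equal(res1.order[0], res2.order[0])

    def test_proportions_are_exact_integer_ratios(self):
        ind = [[np.array([True, True]), np.array([False])],
               [np.array([True, False]), np.array([True])]]
        feats = [[np.array([0, 1]), np.array([0])],
                 [np.array([0, 1]), np.array([0])]]
        res = aggregate_rank(ind, feats, [2, 1])
        assert res.proportions[0][0] == 1.0
        assert res.proportions[0][1] == 0.5
        assert res.proportions[1][0] == 0.5

    def test_tie_break_by_feature_index(self):
        ind = [[np.array([False, True, True]), np.array([False])]]
        feats = [[np.array([0, 1, 2]), np.array([0])]]
        res = aggregate_rank(ind, feats, [3, 1])
        np.testing.assert_array_equal(res.order[0], [1, 2, 0])


class TestSelectAndRetrain:
    def test_all_features_equals_plain_training(self, rng, tiny_spec, tiny_cfg):
        tr = blobs_dataset(rng, p=(10, 10))
        te = blobs_dataset(np.random.default_rng(99), p=(10, 10))
        ranking = rank_features(tr, tiny_spec, tiny_cfg, M=2, seed=8)
        selected, model, acc = select_and_retrain(
            tr, te, ranking, tiny_spec, tiny_cfg, top=10)
        assert selected[0].size == 10
        assert acc > 0.7
        assert model.accuracy(te.subset_features(selected),
                              representation="scores") > 0.8

    def test_selected_lists_sorted_unique(self, rng, tiny_spec, tiny_cfg):
        tr = blobs_dataset(rng)
        te = blobs_dataset(np.random.default_rng(98))
        ranking = rank_features(tr, tiny_spec, tiny_cfg, M=2, seed=9)
        selected, _, _ = select_and_retrain(tr, te, ranking, tiny_spec,
                                            tiny_cfg, top=4)
        for sel in selected:
            assert sel.size == 4
            assert np.all(np.diff(sel) > 0)

    def test_percent_selection_size(self, rng, tiny_spec, tiny_cfg):
        tr = blobs_dataset(rng)
        ranking = rank_features(tr, tiny_spec, tiny_cfg, M=2, seed=10)
        sel = ranking.top(0, percent=25)
        assert sel.size == int(np.ceil(0.25 * tr.n_features[0]))

    def test_too_many_requested_rejected(self, rng, tiny_spec, tiny_cfg):
        tr = blobs_dataset(rng)
        ranking = rank_features(tr, tiny_spec, tiny_cfg, M=2, seed=12)
        with pytest.raises(ValueError, match="top"):
            ranking.top(0, r=tr.n_features[0] + 1)
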