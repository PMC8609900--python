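"""Homogeneous-ensemble feature ranking by bootstrap and permutation.

M pairs of (stratified bootstrap sample set, random feature subset) are
drawn; a model is trained on each pair; its out-of-bag (OOB) accuracy is
the pair's baseline.  Permuting one feature column of the OOB data at a
time, a feature scores a hit whenever the permuted accuracy falls strictly
below the baseline.  The importance of feature k is its occurrence
proportion n_k / N_k: hits over exposures (pairs whose feature subset
contained k).  Top-ranked features are then used to retrain a fresh model
on the original data.

Permutation scoring only reshuffles rows within one column, so the first
affine layer is updated by a rank-one correction and all permuted variants
of a view are pushed through the remaining layers in one stacked pass;
this keeps the p_d x M permutation sweep affordable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import (MultiViewDataset, NetworkSpec, TrainConfig,
                       stratified_split, validate_dataset)
from .model import DeepIDAModel, train
from .network import leaky_relu

__all__ = [
    "BootstrapPair",
    "RankingResult",
    "make_pairs",
    "run_ensemble",
    "permutation_scores",
    "aggregate_rank",
    "select_and_retrain",
    "rank_features",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapPair:
    """One bootstrap draw: in-bag multiset, out-of-bag set, feature subsets."""

    in_bag: np.ndarray            # length-n index multiset (with replacement)
    out_of_bag: np.ndarray        # indices never drawn
    features: list                # per view, sorted unique feature indices


@dataclass
class RankingResult:
    """Occurrence proportions and orderings, one entry per view."""

    hits: list                    # per view, length-p_d integer n_k
    exposures: list               # per view, length-p_d integer N_k
    proportions: list             # per view, n_k / N_k (0 where N_k = 0)
    order: list                   # per view, feature indices sorted by descending proportion
    baselines: np.ndarray = field(default_factory=lambda: np.empty(0))

    def top(self, view: int, r: int | None = None, percent: float | None = None):
        """Sorted indices of the top-r (or top percent%) features of a view."""
        p = len(self.proportions[view])
        if percent is not None:
            r = int(np.ceil(percent / 100.0 * p))
        if r is None:
            raise ValueError("give either a count r or a percent")
        if r > p:
            raise ValueError(f"requested top {r} of {p} features")
        return np.sort(self.order[view][:r])


def _stratified_bootstrap(labels: np.ndarray, rng) -> tuple:
    """Per-class resample with replacement of the original class sizes."""
    in_bag = []
    for k in range(1, int(labels.max()) + 1):
        idx = np.where(labels == k)[0]
        in_bag.append(rng.choice(idx, size=idx.size, replace=True))
    in_bag = np.concatenate(in_bag)
    oob = np.setdiff1d(np.arange(labels.size), in_bag)
    return in_bag, oob


def make_pairs(ds: MultiViewDataset, M: int, feature_frac: float = 0.8,
               seed: int = 0, redraw_budget: int = 10) -> list:
    """Draw M (sample, feature) bootstrap pairs.

    Sample sets are stratified bootstraps (class proportions preserved
    exactly); feature subsets hold ``floor(feature_frac * p_d)`` distinct
    indices per view, drawn uniformly; sample and feature sets are paired
    by a seeded random matching.  Pairs whose out-of-bag set misses a
    class are redrawn (at most ``redraw_budget`` attempts).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not 0.0 < feature_frac <= 1.0:
        raise ValueError("feature_frac must lie in (0, 1]")
    ds = ds if ds._validated else validate_dataset(ds)
    sizes = [int(np.floor(feature_frac * p)) for p in ds.n_features]
    if any(s < 1 for s in sizes):
        raise ValueError("feature_frac leaves a view with no features")
    rng = np.random.default_rng(seed)
    K = ds.n_classes

    samples = []
    for _ in range(M):
        for attempt in range(redraw_budget):
            in_bag, oob = _stratified_bootstrap(ds.labels, rng)
            if np.unique(ds.labels[oob]).size == K:
                break
        else:
            raise RuntimeError("out-of-bag set missing a class after redraw budget")
        samples.append((in_bag, oob))
    feature_sets = [
        [np.sort(rng.choice(p, size=s, replace=False)) for p, s in zip(ds.n_features, sizes)]
        for _ in range(M)
    ]
    matching = rng.permutation(M)
    return [
        BootstrapPair(in_bag=samples[m][0], out_of_bag=samples[m][1],
                      features=feature_sets[matching[m]])
        for m in range(M)
    ]


def run_ensemble(ds: MultiViewDataset, pairs, spec: NetworkSpec, cfg: TrainConfig,
                 representation: str = "scores", pair_valid_frac: float = 0.3):
    """Train one model per pair; baseline = pooled OOB nearest-centroid accuracy.

    Classification defaults to the discriminant scores H^d A_d: the raw
    representations carry an arbitrary per-view scale (the whitened
    objective is invariant to it), which would let one view dominate the
    pooled distances; the scores are variance-normalized per component.

    Each pair's model holds out ``pair_valid_frac`` (default 0.3) of its
    in-bag data (stratified) to select the best epoch: unregularized pair models
    overfit their bootstrap sample and their permutation indicators lose
    the signal/noise separation the ranking depends on.  Set 0 to train
    on the full in-bag data.
    """
    ds = ds if ds._validated else validate_dataset(ds)
    models, baselines = [], []
    for m, pair in enumerate(pairs):
        sub = ds.subset_features(pair.features)
        boot = sub.subset_samples(pair.in_bag)
        pair_cfg = TrainConfig(**{**vars(cfg), "seed": cfg.seed + 1000 * (m + 1)})
        if pair_valid_frac > 0:
            btr, bva = stratified_split(
                boot, (1 - pair_valid_frac, pair_valid_frac), seed=pair_cfg.seed)
            model = train(btr, bva, spec, pair_cfg)
        else:
            model = train(boot, None, spec, pair_cfg)
        oob = sub.subset_samples(pair.out_of_bag)
        acc = model.accuracy(oob, representation=representation)
        models.append(model)
        baselines.append(acc)
        logger.debug("pair %d: baseline OOB accuracy %.3f", m, acc)
    return models, np.asarray(baselines)


def _permuted_oob_accuracy(model: DeepIDAModel, oob_views, oob_labels,
                           view: int, rng, representation: str = "scores") -> np.ndarray:
    """OOB accuracy after permuting each column of one view in turn.

    Exploits the feed-forward structure: a single-column permutation
    perturbs the first-layer pre-activations by a rank-one term, so all
    columns of the view are evaluated in blocked stacked passes through
    the deeper layers, and the pooled nearest-centroid distances of the
    untouched views are precomputed once.
    """
    D = len(oob_views)
    X = [np.asarray(v, dtype=float) for v in oob_views]
    if model.standardizer is not None:
        X = model.standardizer.transform(X)
    H_fixed = [model.nets[d].forward(X[d]) for d in range(D)]
    if representation == "scores":
        loadings = model.projections.loadings
        cen_model = model.score_centroids
        H_fixed = [h @ A for h, A in zip(H_fixed, loadings)]
    else:
        loadings = None
        cen_model = model.centroids

    # squared pooled distances contributed by the views left intact
    cen = cen_model.per_view
    n = X[view].shape[0]
    K = cen_model.n_classes
    dist_fixed = np.zeros((n, K))
    for j in range(D):
        if j == view:
            continue
        H = H_fixed[j]
        dist_fixed += ((H * H).sum(1)[:, None] - 2.0 * H @ cen[j].T
                       + (cen[j] * cen[j]).sum(1))

    net = model.nets[view]
    Xv = X[view]
    p = Xv.shape[1]
    Z1 = Xv @ net.W[0].T + net.b[0]
    cv = cen[view]
    labels = np.asarray(oob_labels)

    accs = np.empty(p)
    width = max(W.shape[0] for W in net.W)
    block = int(np.clip(4_000_000 // max(1, n * width), 1, p))
    for start in range(0, p, block):
        cols = np.arange(start, min(start + block, p))
        permuted = Xv[:, cols].T.copy()                       # b x n
        for i in range(cols.size):
            permuted[i] = permuted[i][rng.permutation(n)]
        diff = permuted - Xv[:, cols].T                       # b x n
        Z = Z1[None, :, :] + diff[:, :, None] * net.W[0][:, cols].T[:, None, :]
        A = leaky_relu(Z, net.slope)
        for m in range(1, net.n_layers):
            A = leaky_relu(A @ net.W[m].T + net.b[m], net.slope)
        if loadings is not None:
            A = A @ loadings[view]
        d2 = ((A * A).sum(-1)[:, :, None] - 2.0 * A @ cv.T
              + (cv * cv).sum(1)[None, None, :]) + dist_fixed[None, :, :]
        pred = np.argmin(d2, axis=2) + 1                      # b x n
        accs[cols] = (pred == labels).mean(axis=1)
    return accs


def permutation_scores(model: DeepIDAModel, pair: BootstrapPair,
                       oob_ds: MultiViewDataset, baseline: float, seed: int = 0,
                       representation: str = "scores"):
    """Indicator of accuracy decrease for every (view, feature) of one pair.

    ``oob_ds`` must already be restricted to the pair's feature subsets.
    Returns one boolean array per view, aligned with ``pair.features``.
    The decrease is strict: a permutation that leaves the out-of-bag
    accuracy unchanged does not count against the feature.
    """
    rng = np.random.default_rng(seed)
    out = []
    for d in range(oob_ds.n_views):
        accs = _permuted_oob_accuracy(model, oob_ds.views, oob_ds.labels, d, rng,
                                      representation)
        out.append(accs < baseline - 1e-12)
    return out


def aggregate_rank(indicator_records, feature_records, p_per_view) -> RankingResult:
    """Tally hits and exposures into occurrence proportions per view.

    ``indicator_records[m][d]`` are the per-pair decrease indicators and
    ``feature_records[m][d]`` the matching feature indices.  Features
    never exposed get proportion 0 with a logged warning.  Ordering is by
    descending proportion with ties broken by feature index.
    """
    D = len(p_per_view)
    hits = [np.zeros(p, dtype=int) for p in p_per_view]
    expo = [np.zeros(p, dtype=int) for p in p_per_view]
    for ind, feats in zip(indicator_records, feature_records):
        for d in range(D):
            expo[d][feats[d]] += 1
            hits[d][feats[d]] += ind[d].astype(int)
    props, order = [], []
    for d in range(D):
        never = expo[d] == 0
        if never.any():
            logger.warning("view %d: %d feature(s) never sampled; proportion set to 0",
                           d, int(never.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.where(never, 0.0, hits[d] / np.maximum(expo[d], 1))
        props.append(pr)
        order.append(np.lexsort((np.arange(pr.size), -pr)))
    return RankingResult(hits=hits, exposures=expo, proportions=props, order=order)


def rank_features(ds: MultiViewDataset, spec: NetworkSpec, cfg: TrainConfig,
                  M: int = 30, feature_frac: float = 0.8, seed: int = 0,
                  representation: str = "scores",
                  pair_valid_frac: float = 0.3) -> RankingResult:
    """End-to-end ranking: pairs -> ensemble -> permutation -> aggregation."""
    ds = ds if ds._validated else validate_dataset(ds)
    pairs = make_pairs(ds, M, feature_frac, seed)
    models, baselines = run_ensemble(ds, pairs, spec, cfg, representation,
                                     pair_valid_frac)
    indicators, feats = [], []
    for m, (model, pair) in enumerate(zip(models, pairs)):
        oob = ds.subset_features(pair.features).subset_samples(pair.out_of_bag)
        indicators.append(permutation_scores(model, pair, oob, baselines[m],
                                             seed=seed + 7919 * (m + 1),
                                             representation=representation))
        feats.append(pair.features)
    result = aggregate_rank(indicators, feats, ds.n_features)
    result.baselines = baselines
    return result


def select_and_retrain(train_ds: MultiViewDataset, test_ds: MultiViewDataset,
                       ranking: RankingResult, spec: NetworkSpec, cfg: TrainConfig,
                       top: int | None = None, percent: float | None = None,
                       valid_ds: MultiViewDataset | None = None):
    """Retrain on the top-ranked features and evaluate on the test data.

    Returns ``(selected, model, pooled_accuracy)`` where ``selected`` is
    one sorted index array per view.
    """
    train_ds = train_ds if train_ds._validated else validate_dataset(train_ds)
    selected = [ranking.top(d, r=top, percent=percent) for d in range(train_ds.n_views)]
    sub_train = train_ds.subset_features(selected)
    sub_valid = valid_ds.subset_features(selected) if valid_ds is not None else None
    model = train(sub_train, sub_valid, spec, cfg)
    sub_test = test_ds.subset_features(selected)
    sub_test = sub_test if sub_test._validated else validate_dataset(sub_test)
    acc = model.accuracy(sub_test)
    return selected, model, acc
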