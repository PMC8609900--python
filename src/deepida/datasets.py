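"""Core data containers for multi-view discriminant analysis.

A *view* is one data modality (e.g. a proteomics matrix) measured on a
common set of samples.  All views share the sample axis; every sample
carries a class label.  The containers here validate that structure once,
recode labels to contiguous integers ``1..K``, and provide stratified
splitting and per-view standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiViewDataset",
    "NetworkSpec",
    "TrainConfig",
    "validate_dataset",
    "stratified_split",
    "Standardizer",
]


@dataclass
class MultiViewDataset:
    """D aligned view matrices plus class labels.

    Parameters
    ----------
    views
        List of ``n x p_d`` real-valued arrays, one per view, with rows in
        a shared sample order.
    labels
        Length-``n`` vector of class identifiers.  Internally recoded to
        ``1..K`` in first-appearance order; the original labels are kept in
        ``original_labels``.
    feature_names
        Per-view lists of ``p_d`` feature names (generated if omitted).
    sample_ids
        Length-``n`` sample identifiers (generated if omitted).
    """

    views: list
    labels: np.ndarray
    feature_names: list | None = None
    sample_ids: list | None = None
    original_labels: np.ndarray | None = None
    _validated: bool = field(default=False, repr=False)

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_samples(self) -> int:
        return self.views[0].shape[0]

    @property
    def n_features(self) -> list:
        return [v.shape[1] for v in self.views]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def subset_samples(self, idx) -> "MultiViewDataset":
        """Row subset (or bootstrap multiset) by positional indices."""
        idx = np.asarray(idx)
        return MultiViewDataset(
            views=[v[idx] for v in self.views],
            labels=self.labels[idx],
            feature_names=self.feature_names,
            sample_ids=[self.sample_ids[i] for i in idx] if self.sample_ids else None,
            original_labels=(
                self.original_labels[idx] if self.original_labels is not None else None
            ),
            _validated=self._validated,
        )

    def subset_features(self, feature_idx: list) -> "MultiViewDataset":
        """Column subset per view; ``feature_idx`` is one index array per view."""
        return MultiViewDataset(
            views=[v[:, np.asarray(ix)] for v, ix in zip(self.views, feature_idx)],
            labels=self.labels,
            feature_names=(
                [[names[i] for i in ix] for names, ix in zip(self.feature_names, feature_idx)]
                if self.feature_names
                else None
            ),
            sample_ids=self.sample_ids,
            original_labels=self.original_labels,
            _validated=self._validated,
        )


def validate_dataset(ds: MultiViewDataset) -> MultiViewDataset:
    """Check invariants and return a canonicalized dataset.

    Ensures: D >= 2 views with identical row counts, finite entries, every
    class with at least two samples.  Labels are recoded to ``1..K`` in
    first-appearance order.  Idempotent.
    """
    if ds.n_views < 2:
        raise ValueError(f"need at least 2 views, got {ds.n_views}")
    views = [np.asarray(v, dtype=float) for v in ds.views]
    n = views[0].shape[0]
    for d, v in enumerate(views):
        if v.ndim != 2:
            raise ValueError(f"view {d} is not a matrix")
        if v.shape[0] != n:
            raise ValueError(
                f"row mismatch: view {d} has {v.shape[0]} rows, view 0 has {n}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite entries in view {d}")

    raw = np.asarray(ds.original_labels if ds.original_labels is not None else ds.labels)
    if raw.shape[0] != n:
        raise ValueError(f"row mismatch: {raw.shape[0]} labels for {n} samples")
    # contiguous recode in first-appearance order
    _, first_pos, inverse = np.unique(raw, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_pos))
    labels = order[inverse] + 1
    counts = np.bincount(labels)[1:]
    small = np.where(counts < 2)[0]
    if small.size:
        raise ValueError(f"class too small: class {small[0] + 1} has {counts[small[0]]} sample(s)")

    feature_names = ds.feature_names or [
        [f"v{d + 1}_f{j + 1}" for j in range(v.shape[1])] for d, v in enumerate(views)
    ]
    sample_ids = ds.sample_ids or [f"s{i + 1}" for i in range(n)]
    return MultiViewDataset(
        views=views,
        labels=labels.astype(np.int64),
        feature_names=feature_names,
        sample_ids=list(sample_ids),
        original_labels=raw,
        _validated=True,
    )


def stratified_split(ds: MultiViewDataset, fractions, seed: int):
    """Split samples into parts with per-class proportions preserved.

    Each class's samples are shuffled (seeded) and dealt to the parts; part
    sizes per class are ``floor(f * n_k)`` with leftover samples assigned to
    the parts with the largest fractional remainders.  Returns a tuple of
    :class:`MultiViewDataset`, one per fraction.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.min() <= 0:
        raise ValueError("fractions must be positive")
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1")
    ds = ds if ds._validated else validate_dataset(ds)
    rng = np.random.default_rng(seed)
    parts = [[] for _ in fractions]
    for k in range(1, ds.n_classes + 1):
        idx = np.where(ds.labels == k)[0]
        rng.shuffle(idx)
        target = fractions * idx.size
        sizes = np.floor(target).astype(int)
        rem = target - sizes
        # leftover samples go to the largest remainders, ties broken by seed
        order = np.lexsort((rng.random(fractions.size), -rem))
        for j in order[: idx.size - sizes.sum()]:
            sizes[j] += 1
        if np.any(sizes == 0):
            raise ValueError(f"class {k} too small for requested split")
        stops = np.cumsum(sizes)
        for j, (a, b) in enumerate(zip(np.r_[0, stops[:-1]], stops)):
            parts[j].append(idx[a:b])
    return tuple(ds.subset_samples(np.sort(np.concatenate(p))) for p in parts)


@dataclass
class NetworkSpec:
    """Per-view feed-forward architecture.

    ``hidden`` holds one list of hidden-layer widths per view; ``output``
    the final-layer width o_d per view.  The activation is a leaky
    rectifier applied after every affine map, the output layer included.
    """

    hidden: list
    output: list
    negative_slope: float = 0.01

    def __post_init__(self):
        if len(self.hidden) != len(self.output):
            raise ValueError("hidden and output must list one entry per view")
        for o in self.output:
            if o < 1:
                raise ValueError("output width must be >= 1")
        for widths in self.hidden:
            if any(int(w) <= 0 for w in widths):
                raise ValueError("hidden widths must be positive")

    @classmethod
    def uniform(cls, n_views: int, hidden=(256, 64), output: int = 10,
                negative_slope: float = 0.01) -> "NetworkSpec":
        return cls(
            hidden=[list(hidden) for _ in range(n_views)],
            output=[output] * n_views,
            negative_slope=negative_slope,
        )

    def max_l(self, n_classes: int) -> int:
        return min([n_classes - 1] + list(self.output))


@dataclass
class TrainConfig:
    """Training hyperparameters.

    rho in [0, 1] weighs class separation (rho -> 1) against cross-view
    association (rho -> 0); ``l`` is the projection dimension, at most
    ``min(K - 1, min_d o_d)``; ``ridge`` regularizes the total scatter
    before whitening (scaled by its mean diagonal).
    """

    rho: float = 0.5
    l: int | None = None
    ridge: float = 1e-3
    lr: float = 1e-3
    weight_decay: float = 0.0
    init_scale: float = 1.0
    epochs: int = 50
    batch_size: int | None = None  # None => full batch
    seed: int = 0
    solver_tol: float = 1e-6
    solver_max_iter: int = 100
    standardize: bool = True

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


class Standardizer:
    """Per-view z-scoring with training-set statistics.

    Means/sds are estimated on the training part only and re-applied to any
    later data; constant features get sd 1 so they pass through centered.
    """

    def __init__(self):
        self.means_ = None
        self.sds_ = None

    def fit(self, views) -> "Standardizer":
        self.means_ = [v.mean(axis=0) for v in views]
        self.sds_ = []
        for v in views:
            sd = v.std(axis=0, ddof=1)
            sd[sd < 1e-12] = 1.0
            self.sds_.append(sd)
        return self

    def transform(self, views):
        return [(v - m) / s for v, m, s in zip(views, self.means_, self.sds_)]

    def fit_transform(self, views):
        return self.fit(views).transform(views)
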