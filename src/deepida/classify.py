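"""Nearest-centroid classification and discriminant-score summaries.

Classification operates on the top-level representations H^d: class
centroids are means of the (optionally pooled across views) representation
rows, and a sample is assigned to the class with the closest centroid in
Euclidean distance, ties going to the smaller class index.  Projected
variants (on the discriminant scores H^d Gamma_d) are exposed as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CentroidModel",
    "fit_centroids",
    "predict_centroids",
    "discriminant_scores",
    "score_correlations",
]


@dataclass
class CentroidModel:
    """Class centroids, pooled across views and per view."""

    pooled: np.ndarray           # K x sum_d o_d
    per_view: list               # per view, K x o_d
    classes: np.ndarray          # class ids 1..K

    @property
    def n_classes(self) -> int:
        return self.classes.size


def fit_centroids(H_list, labels) -> CentroidModel:
    """Class means of the representations, per view and concatenated."""
    labels = np.asarray(labels)
    K = int(labels.max())
    per_view = []
    for H in H_list:
        H = np.asarray(H, dtype=float)
        cen = np.empty((K, H.shape[1]))
        for k in range(1, K + 1):
            mask = labels == k
            if not mask.any():
                raise ValueError(f"empty class {k}")
            cen[k - 1] = H[mask].mean(axis=0)
        per_view.append(cen)
    return CentroidModel(
        pooled=np.hstack(per_view), per_view=per_view,
        classes=np.arange(1, K + 1),
    )


def _nearest(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    # argmin takes the first (smallest class index) on ties
    return np.argmin(d2, axis=1) + 1


def predict_centroids(H_list, model: CentroidModel, mode: str = "pooled",
                      view: int | None = None) -> np.ndarray:
    """Assign each sample to the class with the nearest centroid.

    ``mode='pooled'`` concatenates all views; ``mode='per-view'`` uses the
    single view indexed by ``view`` (0-based).
    """
    if mode == "pooled":
        X = np.hstack([np.asarray(H, dtype=float) for H in H_list])
        cen = model.pooled
    elif mode == "per-view":
        if view is None:
            raise ValueError("per-view prediction needs a view index")
        X = np.asarray(H_list[view], dtype=float)
        cen = model.per_view[view]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if X.shape[1] != cen.shape[1]:
        raise ValueError(
            f"width mismatch: data {X.shape[1]} vs centroids {cen.shape[1]}"
        )
    return _nearest(X, cen)


def discriminant_scores(H: np.ndarray, Gamma: np.ndarray) -> np.ndarray:
    """Project a view's representation onto its learned loadings: H Gamma."""
    H = np.asarray(H, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    if H.shape[1] != Gamma.shape[0]:
        raise ValueError(
            f"dimension mismatch: H has {H.shape[1]} columns, Gamma {Gamma.shape[0]} rows"
        )
    return H @ Gamma


def score_correlations(scores_d: np.ndarray, scores_j: np.ndarray):
    """Component-wise Pearson correlations of matched discriminant scores.

    Returns ``(per_component, mean)``; a zero-variance component yields
    NaN for that entry and is excluded from the mean.
    """
    A = np.atleast_2d(np.asarray(scores_d, dtype=float))
    B = np.atleast_2d(np.asarray(scores_j, dtype=float))
    if A.shape != B.shape:
        raise ValueError("score matrices must have identical shape")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac * Ac).sum(axis=0))
    sb = np.sqrt((Bc * Bc).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Ac * Bc).sum(axis=0) / (sa * sb)
    r = np.where((sa < 1e-14) | (sb < 1e-14), np.nan, r)
    mean = float(np.nanmean(r)) if np.any(np.isfinite(r)) else float("nan")
    return r, mean
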