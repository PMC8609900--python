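"""Scatter (covariance) matrices for joint association and separation.

For a representation matrix ``H`` (n x o) with class labels, the central
mean is the *unweighted* mean of the class means,

    mu = (1/K) sum_k mu_k,

and all scatters are taken around it with divisor n - 1:

    S_b = (1/(n-1)) sum_k n_k (mu_k - mu)(mu_k - mu)^T
    S_t = (1/(n-1)) (H - 1 mu^T)^T (H - 1 mu^T)
    S_dj = (1/(n-1)) (H_d - 1 mu_d^T)^T (H_j - 1 mu_j^T)

For unbalanced classes mu differs from the grand sample mean, and S_t is
deliberately *not* the usual sample covariance.  The within-class scatter
S_w centers each sample at its own class mean; for balanced classes
S_t = S_b + S_w exactly.

Whitened forms drive the eigensystem: M = S_t^{-1/2} S_b S_t^{-1/2}
(discriminability; eigenvalues in [0, 1] for balanced classes) and
N_dj = S_t^{d,-1/2} S_dj S_t^{j,-1/2} (canonical-correlation-like
association between views d and j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "class_means",
    "between_scatter",
    "total_scatter",
    "within_scatter",
    "cross_scatter",
    "inv_sqrt_psd",
    "whiten_and_build",
    "ScatterSet",
]

EIG_FLOOR = 1e-10


def class_means(H: np.ndarray, labels: np.ndarray):
    """Per-class column means and their unweighted average.

    Returns ``(mu_k, mu)`` where ``mu_k`` is a K x o array of class means
    and ``mu = mu_k.mean(axis=0)``, the central mean used by every scatter.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    labels = np.asarray(labels)
    K = int(labels.max())
    mu_k = np.empty((K, H.shape[1]))
    for k in range(1, K + 1):
        mask = labels == k
        if not mask.any():
            raise ValueError(f"empty class {k}")
        mu_k[k - 1] = H[mask].mean(axis=0)
    return mu_k, mu_k.mean(axis=0)


def between_scatter(H: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Between-class scatter: n_k-weighted outer products of mu_k - mu, over n - 1."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    n = H.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    mu_k, mu = class_means(H, labels)
    counts = np.bincount(np.asarray(labels))[1:].astype(float)
    dev = mu_k - mu
    return (dev.T * counts) @ dev / (n - 1)


def total_scatter(H: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Total scatter around the unweighted mean of class means, divisor n - 1."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    n = H.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    _, mu = class_means(H, labels)
    Hc = H - mu
    return Hc.T @ Hc / (n - 1)


def within_scatter(H: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Within-class scatter: deviations from each sample's own class mean."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    n = H.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    labels = np.asarray(labels)
    mu_k, _ = class_means(H, labels)
    Hc = H - mu_k[labels - 1]
    return Hc.T @ Hc / (n - 1)


def cross_scatter(H_d: np.ndarray, H_j: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Cross-view scatter between two centered representations."""
    H_d = np.atleast_2d(np.asarray(H_d, dtype=float))
    H_j = np.atleast_2d(np.asarray(H_j, dtype=float))
    if H_d.shape[0] != H_j.shape[0]:
        raise ValueError("row mismatch between views")
    n = H_d.shape[0]
    _, mu_d = class_means(H_d, labels)
    _, mu_j = class_means(H_j, labels)
    return (H_d - mu_d).T @ (H_j - mu_j) / (n - 1)


def inv_sqrt_psd(S: np.ndarray, ridge: float = 0.0):
    """Symmetric inverse square root of a PSD matrix with ridge regularization.

    The ridge is scaled by the mean diagonal of ``S`` so it is invariant to
    the overall scale of the data.  Eigenvalues are floored at
    ``EIG_FLOOR`` before the -1/2 power.  Returns ``(R, lam, U)`` with
    ``R = U diag(lam_reg^{-1/2}) U^T`` where ``lam`` are the regularized
    eigenvalues and ``U`` the eigenvectors (needed for differentiation).
    """
    S = np.asarray(S, dtype=float)
    o = S.shape[0]
    cbar = float(np.trace(S)) / o
    A = S + (ridge * cbar) * np.eye(o)
    lam, U = np.linalg.eigh((A + A.T) / 2)
    if lam[-1] <= 0:
        raise np.linalg.LinAlgError("total scatter not positive definite after ridge")
    lam_f = np.maximum(lam, EIG_FLOOR)
    R = (U * lam_f ** -0.5) @ U.T
    return R, lam, U


@dataclass
class ScatterSet:
    """All scatter statistics of a set of top-level representations."""

    mu_k: list          # per view, K x o_d class means
    mu: list            # per view, central mean (mean of class means)
    S_b: list
    S_t: list
    S_w: list
    S_cross: dict       # (d, j) -> S_dj for all ordered pairs d != j
    R: list             # per view, (S_t + ridge)^(-1/2)
    M: list             # per view, R S_b R
    N: dict             # (d, j) -> R_d S_dj R_j for all ordered pairs
    ridge: float

    @property
    def n_views(self) -> int:
        return len(self.S_b)


def whiten_and_build(H_list, labels, ridge: float = 1e-3) -> ScatterSet:
    """Build every scatter matrix and the whitened forms M_d and N_dj.

    ``H_list`` holds one n x o_d representation per view.  ``S_cross`` and
    ``N`` are stored for every ordered pair; ``S_jd = S_dj^T`` holds by
    construction.
    """
    labels = np.asarray(labels)
    D = len(H_list)
    mu_k_l, mu_l, Sb_l, St_l, Sw_l, R_l, M_l = [], [], [], [], [], [], []
    for H in H_list:
        mu_k, mu = class_means(H, labels)
        mu_k_l.append(mu_k)
        mu_l.append(mu)
        Sb = between_scatter(H, labels)
        St = total_scatter(H, labels)
        Sb_l.append(Sb)
        St_l.append(St)
        Sw_l.append(within_scatter(H, labels))
        R, _, _ = inv_sqrt_psd(St, ridge)
        R_l.append(R)
        M = R @ Sb @ R
        M_l.append((M + M.T) / 2)
    S_cross, N = {}, {}
    for d in range(D):
        for j in range(D):
            if d == j:
                continue
            if (j, d) in S_cross:
                S_cross[(d, j)] = S_cross[(j, d)].T
            else:
                S_cross[(d, j)] = cross_scatter(H_list[d], H_list[j], labels)
            N[(d, j)] = R_l[d] @ S_cross[(d, j)] @ R_l[j]
    return ScatterSet(
        mu_k=mu_k_l, mu=mu_l, S_b=Sb_l, S_t=St_l, S_w=Sw_l,
        S_cross=S_cross, R=R_l, M=M_l, N=N, ridge=ridge,
    )
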