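"""Alternating eigensystem solver for the joint association/separation objective.

The objective over orthonormal projections Gamma_d (o_d x l) is

    J = c1 sum_d tr(Gamma_d^T M_d Gamma_d)
      + c2 sum_d sum_{j != d} tr(Gamma_d^T N_dj Gamma_j Gamma_j^T N_dj^T Gamma_d)

with c1 = rho/D and c2 = 2(1-rho)/(D(D-1)).  Holding every other view
fixed, the optimal Gamma_d consists of the top-l eigenvectors of

    C_d = c1 M_d + c2 sum_{j != d} N_dj Gamma_j Gamma_j^T N_dj^T,

so a block-coordinate sweep over d = 1..D is a monotone ascent on J; each
sweep's objective is the sum over views of the top-l eigenvalue sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["mixing_constants", "solve_ida", "objective_eq4", "ProjectionSet"]


def mixing_constants(rho: float, D: int):
    """Weights of the separation (c1) and association (c2) terms."""
    if D < 2:
        raise ValueError("need at least two views")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    return rho / D, 2.0 * (1.0 - rho) / (D * (D - 1))


@dataclass
class ProjectionSet:
    """Solution of the alternating eigensystem.

    ``objective`` is the eigen-sum sum_d sum_r eta_{d,r} (it equals the
    ordered-pair objective of :func:`objective_eq4` at a fixed point).
    ``trace`` records, after each sweep, the ascent functional F — the
    separation terms plus the once-counted pairwise association — which
    each block update exactly maximizes and which is therefore
    non-decreasing; the eigen-sum itself (2F minus the separation total)
    need not be monotone mid-run.
    """

    Gammas: list                       # per view, o_d x l orthonormal
    eigenvalues: list                  # per view, descending length-l
    objective: float
    trace: list = field(default_factory=list)   # ascent objective per sweep
    converged: bool = False
    n_sweeps: int = 0
    loadings: list | None = None       # A_d = S_t^{-1/2} Gamma_d, when scatters known

    @property
    def l(self) -> int:
        return self.Gammas[0].shape[1]


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _top_l_eig(C: np.ndarray, l: int):
    lam, V = np.linalg.eigh((C + C.T) / 2)
    lam, V = lam[::-1][:l], V[:, ::-1][:, :l]
    return lam, _fix_signs(V)


def objective_eq4(Gammas, Ms, Ns, rho: float) -> float:
    """Evaluate the joint objective at given orthonormal projections.

    ``Ns`` maps ordered pairs ``(d, j)`` to N_dj; missing pairs fall back
    on ``N_jd^T``.
    """
    D = len(Gammas)
    c1, c2 = mixing_constants(rho, D)
    total = 0.0
    for d in range(D):
        total += c1 * float(np.trace(Gammas[d].T @ Ms[d] @ Gammas[d]))
        for j in range(D):
            if j == d:
                continue
            N = Ns[(d, j)] if (d, j) in Ns else Ns[(j, d)].T
            B = Gammas[d].T @ N @ Gammas[j]
            total += c2 * float(np.sum(B * B))
    return total


def solve_ida(Ms, Ns, rho: float, l: int, tol: float = 1e-6,
              max_iter: int = 100, init_seed: int | None = None) -> ProjectionSet:
    """Block-coordinate solve for the projections Gamma_1..Gamma_D.

    Parameters
    ----------
    Ms
        Per-view whitened separation matrices (symmetric PSD, o_d x o_d).
    Ns
        Dict of whitened cross matrices for ordered pairs ``(d, j)``.
    rho
        Separation/association weight in [0, 1].
    l
        Projection dimension, at most ``min(K - 1, min_d o_d)``.
    tol, max_iter
        Stop when the objective improves by less than ``tol`` over a full
        sweep, or after ``max_iter`` sweeps.
    init_seed
        ``None`` initializes each Gamma_d to the first l columns of the
        identity; an integer draws a random orthonormal start.
    """
    D = len(Ms)
    if D < 2:
        raise ValueError("need at least two views")
    for d, M in enumerate(Ms):
        if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
            raise ValueError(f"M[{d}] must be symmetric")
        if l > M.shape[0]:
            raise ValueError(f"l={l} exceeds output width {M.shape[0]} of view {d}")
    c1, c2 = mixing_constants(rho, D)

    if init_seed is None:
        Gammas = [np.eye(M.shape[0])[:, :l].copy() for M in Ms]
    else:
        rng = np.random.default_rng(init_seed)
        Gammas = []
        for M in Ms:
            Q, _ = np.linalg.qr(rng.standard_normal((M.shape[0], l)))
            Gammas.append(_fix_signs(Q))

    def getN(d, j):
        return Ns[(d, j)] if (d, j) in Ns else Ns[(j, d)].T

    def ascent_objective():
        total = 0.0
        for d in range(D):
            total += c1 * float(np.trace(Gammas[d].T @ Ms[d] @ Gammas[d]))
            for j in range(d + 1, D):
                B = Gammas[d].T @ getN(d, j) @ Gammas[j]
                total += c2 * float(np.sum(B * B))
        return total

    eigvals = [np.zeros(l) for _ in range(D)]
    trace, prev, converged, sweep = [], -np.inf, False, 0
    for sweep in range(1, max_iter + 1):
        for d in range(D):
            C = c1 * Ms[d]
            for j in range(D):
                if j == d:
                    continue
                NG = getN(d, j) @ Gammas[j]
                C = C + c2 * (NG @ NG.T)
            eigvals[d], Gammas[d] = _top_l_eig(C, l)
        obj = ascent_objective()
        trace.append(obj)
        if obj - prev < tol:
            converged = True
            break
        prev = obj
    return ProjectionSet(
        Gammas=Gammas,
        eigenvalues=[ev.copy() for ev in eigvals],
        objective=float(sum(ev.sum() for ev in eigvals)),
        trace=trace,
        converged=converged,
        n_sweeps=sweep,
    )
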