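"""Training loss and its analytic gradient.

The variational objective maximized over orthonormal projections is

    F(H) = max_Gamma  c1 sum_d tr(Gamma_d^T M_d Gamma_d)
                    + c2 sum_{d<j} || Gamma_d^T N_dj Gamma_j ||_F^2

with c1 = rho/D and c2 = 2(1-rho)/(D(D-1)): the class-separation terms of
the D views plus the (1-rho)-weighted average of the D(D-1)/2 pairwise
squared-association measures.  The block update of each Gamma_d to the
top-l eigenvectors of C_d = c1 M_d + c2 sum_{j != d} N_dj P_j N_dj^T is
exact coordinate ascent on F, so the solver's fixed points are stationary
points of F.  The training loss is L = -F.

The per-view eigenvalue sums relate to F at a fixed point by
sum_d sum_r eta_{d,r} = 2 F - c1 sum_d tr(Gamma_d^T M_d Gamma_d): the
eigen-sum counts every pairwise association twice (once from each view's
eigensystem).  The eigen-sum is reported as a monitoring quantity;
differentiating F rather than the eigen-sum is what makes the envelope
gradient below exact.

Because the converged Gamma maximize F, the gradient of F with respect to
the representations H^d is taken with the projections held fixed (the
envelope, or Danskin, treatment): the Gamma-sensitivity vanishes to first
order.  What remains is deterministic matrix calculus:

* F is linear in M_d and quadratic in N_dj, giving dF/dM_d = c1 P_d and
  dF/dN_dj = c2 P_d N_dj P_j per ordered pair, with P = Gamma Gamma^T;
* M and N are congruences by R_d = (S_t^d + ridge c I)^{-1/2}; the adjoint
  of the matrix inverse square root uses the Daleckii-Krein formula on the
  eigendecomposition of the ridged total scatter;
* the scatters are quadratic in the centered representations, with the
  centering mean the unweighted mean of class means.

Every step is exercised against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .scatter import EIG_FLOOR, class_means
from .solver import mixing_constants, solve_ida

__all__ = ["deepida_loss", "loss_and_grad", "objective_f"]


def _forward_scatters(H_list, labels, ridge):
    """Scatters plus the eigendecompositions needed for the backward pass."""
    labels = np.asarray(labels)
    n = H_list[0].shape[0]
    D = len(H_list)
    data = {"n": n, "D": D, "labels": labels}
    data["counts"] = np.bincount(labels)[1:].astype(float)
    data["mu_k"], data["mu"], data["Hc"] = [], [], []
    data["S_b"], data["S_t"], data["lam"], data["U"], data["R"], data["M"] = (
        [], [], [], [], [], [])
    for H in H_list:
        mu_k, mu = class_means(H, labels)
        Hc = H - mu
        S_b_dev = mu_k - mu
        S_b = (S_b_dev.T * data["counts"]) @ S_b_dev / (n - 1)
        S_t = Hc.T @ Hc / (n - 1)
        o = S_t.shape[0]
        cbar = float(np.trace(S_t)) / o
        A = S_t + (ridge * cbar) * np.eye(o)
        lam, U = np.linalg.eigh((A + A.T) / 2)
        lam_f = np.maximum(lam, EIG_FLOOR)
        R = (U * lam_f ** -0.5) @ U.T
        M = R @ S_b @ R
        for key, val in (("mu_k", mu_k), ("mu", mu), ("Hc", Hc), ("S_b", S_b),
                         ("S_t", S_t), ("lam", lam), ("U", U), ("R", R),
                         ("M", (M + M.T) / 2)):
            data[key].append(val)
    data["S_cross"], data["N"] = {}, {}
    for d in range(D):
        for j in range(D):
            if d == j:
                continue
            if (j, d) in data["S_cross"]:
                S_dj = data["S_cross"][(j, d)].T
            else:
                S_dj = data["Hc"][d].T @ data["Hc"][j] / (n - 1)
            data["S_cross"][(d, j)] = S_dj
            data["N"][(d, j)] = data["R"][d] @ S_dj @ data["R"][j]
    return data


def _invsqrt_adjoint(G_R, lam, U):
    """Adjoint of A -> A^{-1/2} at eigendecomposition (lam, U) of A.

    Uses the Daleckii-Krein divided-difference kernel; floored eigenvalues
    contribute zero sensitivity.
    """
    f = np.maximum(lam, EIG_FLOOR) ** -0.5
    fprime = np.where(lam > EIG_FLOOR, -0.5 * np.maximum(lam, EIG_FLOOR) ** -1.5, 0.0)
    dl = lam[:, None] - lam[None, :]
    df = f[:, None] - f[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        Kmat = np.where(np.abs(dl) > 1e-12 * (1 + np.abs(lam).max()), df / dl, 0.0)
    np.fill_diagonal(Kmat, fprime)
    # off-diagonal near-degenerate pairs: fall back on the derivative limit
    close = (np.abs(dl) <= 1e-12 * (1 + np.abs(lam).max()))
    np.fill_diagonal(close, False)
    if close.any():
        avg = 0.5 * (fprime[:, None] + fprime[None, :])
        Kmat = np.where(close, avg, Kmat)
    G_sym = (G_R + G_R.T) / 2
    return U @ (Kmat * (U.T @ G_sym @ U)) @ U.T


def _scatter_to_H_grads(data, G_St, G_Sb, G_Scross):
    """Backpropagate scatter adjoints to the representations H^d."""
    n, D = data["n"], data["D"]
    labels, counts = data["labels"], data["counts"]
    G_Hc = [np.zeros_like(Hc) for Hc in data["Hc"]]
    for d in range(D):
        Gt = (G_St[d] + G_St[d].T) / 2
        G_Hc[d] += 2.0 * data["Hc"][d] @ Gt / (n - 1)
    for (d, j), G in G_Scross.items():
        G_Hc[d] += data["Hc"][j] @ G.T / (n - 1)
        G_Hc[j] += data["Hc"][d] @ G / (n - 1)
    grads = []
    K = counts.size
    for d in range(D):
        Gb = (G_Sb[d] + G_Sb[d].T) / 2
        dev = data["mu_k"][d] - data["mu"][d]          # K x o
        G_mu_k = 2.0 * (counts[:, None] * dev) @ Gb / (n - 1)
        G_mu = -G_mu_k.sum(axis=0) - G_Hc[d].sum(axis=0)
        G_mu_k = G_mu_k + G_mu / K
        G_H = G_Hc[d].copy()
        G_H += G_mu_k[labels - 1] / counts[labels - 1][:, None]
        grads.append(G_H)
    return grads


def objective_f(Gammas, Ms, Ns, rho: float) -> float:
    """The variational objective F: separation plus once-counted association."""
    D = len(Gammas)
    c1, c2 = mixing_constants(rho, D)
    total = 0.0
    for d in range(D):
        total += c1 * float(np.trace(Gammas[d].T @ Ms[d] @ Gammas[d]))
        for j in range(d + 1, D):
            N = Ns[(d, j)] if (d, j) in Ns else Ns[(j, d)].T
            B = Gammas[d].T @ N @ Gammas[j]
            total += c2 * float(np.sum(B * B))
    return total


def loss_and_grad(H_list, labels, rho: float, l: int, ridge: float = 1e-3,
                  solver_tol: float = 1e-13, solver_max_iter: int = 1000):
    """Loss -F, per-view gradients dL/dH^d, and the converged projections.

    The projections are solved to tight tolerance so that the envelope
    gradient (projections detached) coincides with the total derivative.
    """
    H_list = [np.asarray(H, dtype=float) for H in H_list]
    labels = np.asarray(labels)
    D = len(H_list)
    c1, c2 = mixing_constants(rho, D)
    data = _forward_scatters(H_list, labels, ridge)
    proj = solve_ida(data["M"], data["N"], rho, l,
                     tol=solver_tol, max_iter=solver_max_iter)
    proj.loadings = [data["R"][d] @ proj.Gammas[d] for d in range(D)]
    loss = -objective_f(proj.Gammas, data["M"], data["N"], rho)

    P = [G @ G.T for G in proj.Gammas]
    # adjoints of the whitened forms (gradient of F; negate at the end);
    # each unordered pair split evenly over its two ordered entries
    G_M = [c1 * P[d] for d in range(D)]
    G_N = {(d, j): c2 * P[d] @ N @ P[j] for (d, j), N in data["N"].items()}

    G_Sb = [data["R"][d] @ G_M[d] @ data["R"][d] for d in range(D)]
    G_R = [G_M[d] @ data["R"][d] @ data["S_b"][d]
           + data["S_b"][d] @ data["R"][d] @ G_M[d] for d in range(D)]
    G_Scross = {}
    for (d, j), G in G_N.items():
        S_dj = data["S_cross"][(d, j)]
        G_Scross[(d, j)] = data["R"][d] @ G @ data["R"][j]
        G_R[d] += G @ data["R"][j] @ S_dj.T
        G_R[j] += S_dj.T @ data["R"][d] @ G
    G_St = []
    for d in range(D):
        G_A = _invsqrt_adjoint(G_R[d], data["lam"][d], data["U"][d])
        o = G_A.shape[0]
        G_S = G_A + (ridge / o) * np.trace(G_A) * np.eye(o)
        G_St.append(G_S)

    grads = _scatter_to_H_grads(data, G_St, G_Sb, G_Scross)
    return loss, [-g for g in grads], proj


def deepida_loss(H_list, labels, rho: float, l: int, ridge: float = 1e-3) -> float:
    """Scalar training loss -F at the converged projections."""
    loss, _, _ = loss_and_grad(H_list, labels, rho, l, ridge)
    return loss
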