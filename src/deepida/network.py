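"""Per-view feed-forward networks and the Adam optimizer, in plain numpy.

Each view owns an independent multilayer perceptron.  Every layer — the
output layer included — applies an affine map followed by a leaky
rectifier, so the top-level representation is H = s(W_M h_{M-1} + b_M).
Gradients are computed by standard reverse-mode accumulation given the
upstream gradient dL/dH supplied by the scatter/eigenvalue loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "leaky_relu"]


def leaky_relu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z >= 0, z, slope * z)


class MLP:
    """Fully connected network with leaky-rectifier activations throughout.

    Parameters are He-initialized from a seeded generator.  ``forward``
    caches pre-activations; ``backward`` consumes dL/dH and returns
    per-parameter gradients (and does not modify the parameters).
    """

    def __init__(self, sizes, negative_slope: float = 0.01, rng=None):
        # sizes: [p_in, hidden..., o_out]
        if len(sizes) < 2:
            raise ValueError("need at least input and output widths")
        rng = rng or np.random.default_rng(0)
        self.sizes = list(int(s) for s in sizes)
        self.slope = float(negative_slope)
        self.W = [
            rng.standard_normal((m, n)) * np.sqrt(2.0 / n)
            for n, m in zip(self.sizes[:-1], self.sizes[1:])
        ]
        self.b = [np.zeros(m) for m in self.sizes[1:]]
        self._cache = None

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, X: np.ndarray, cache: bool = False) -> np.ndarray:
        A = np.asarray(X, dtype=float)
        if A.shape[1] != self.sizes[0]:
            raise ValueError(
                f"input width {A.shape[1]} does not match network width {self.sizes[0]}"
            )
        acts, pre = [A], []
        for W, b in zip(self.W, self.b):
            Z = A @ W.T + b
            A = leaky_relu(Z, self.slope)
            pre.append(Z)
            acts.append(A)
        if cache:
            self._cache = (acts, pre)
        return A

    def backward(self, G_out: np.ndarray):
        """Gradients (dW list, db list) given dL/dH from a cached forward."""
        if self._cache is None:
            raise RuntimeError("forward(..., cache=True) must precede backward")
        acts, pre = self._cache
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        G = np.asarray(G_out, dtype=float)
        for m in range(self.n_layers - 1, -1, -1):
            GZ = G * np.where(pre[m] >= 0, 1.0, self.slope)
            gW[m] = GZ.T @ acts[m]
            gb[m] = GZ.sum(axis=0)
            if m > 0:
                G = GZ @ self.W[m]
        return gW, gb

    def get_params(self):
        return [W.copy() for W in self.W], [b.copy() for b in self.b]

    def set_params(self, params):
        W, b = params
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


class Adam:
    """Adam over a flat list of parameter arrays (updated in place).

    ``weight_decay`` is decoupled (applied directly to the parameters, not
    through the moment estimates); ``decay_mask`` can exempt entries such
    as biases.
    """

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_mask=None):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.decay_mask = decay_mask if decay_mask is not None else [True] * len(params)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v, dk in zip(self.params, grads, self.m, self.v, self.decay_mask):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.wd and dk:
                p -= self.lr * self.wd * p
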