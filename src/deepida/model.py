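"""The fitted multi-view model and its training loop.

One epoch is: forward every view's network on the (full, by default)
batch, evaluate the eigenvalue-based loss and its analytic gradient with
respect to the top-level representations, backpropagate through each
sub-network independently, and take an Adam step.  When a validation set
is supplied, the returned parameters are those of the epoch with the
lowest validation loss; the projections and class centroids are refit on
the full training data at those parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import CentroidModel, fit_centroids, predict_centroids
from .datasets import MultiViewDataset, NetworkSpec, Standardizer, TrainConfig
from .gradients import loss_and_grad
from .network import MLP, Adam
from .solver import ProjectionSet

__all__ = ["DeepIDAModel", "train"]

_ARCHIVE_VERSION = 1


@dataclass
class DeepIDAModel:
    """Trained per-view networks with projections and centroids."""

    nets: list
    spec: NetworkSpec
    cfg: TrainConfig
    standardizer: Standardizer | None = None
    projections: ProjectionSet | None = None
    centroids: CentroidModel | None = None
    score_centroids: CentroidModel | None = None
    train_loss: list = field(default_factory=list)
    valid_loss: list = field(default_factory=list)
    best_epoch: int | None = None

    def transform(self, views, representation: str = "H") -> list:
        """Top-level representations H^d (or discriminant scores H^d A_d).

        ``representation='scores'`` projects each view onto its loadings
        A_d = S_t^{-1/2} Gamma_d; the scores have unit total variance per
        component, so pooled distances weight the views comparably.
        """
        views = [np.asarray(v, dtype=float) for v in views]
        if self.standardizer is not None:
            views = self.standardizer.transform(views)
        H = [net.forward(v) for net, v in zip(self.nets, views)]
        if representation == "H":
            return H
        if representation == "scores":
            if self.projections is None or self.projections.loadings is None:
                raise RuntimeError("model has no fitted loadings; train first")
            return [h @ A for h, A in zip(H, self.projections.loadings)]
        raise ValueError(f"unknown representation {representation!r}")

    def predict(self, views, mode: str = "pooled", view: int | None = None,
                representation: str = "H") -> np.ndarray:
        cen = self.centroids if representation == "H" else self.score_centroids
        if cen is None:
            raise RuntimeError("model has no fitted centroids; train first")
        return predict_centroids(self.transform(views, representation), cen, mode, view)

    def accuracy(self, ds: MultiViewDataset, mode: str = "pooled",
                 view: int | None = None, representation: str = "H") -> float:
        pred = self.predict(ds.views, mode=mode, view=view,
                            representation=representation)
        return float(np.mean(pred == ds.labels))

    def save(self, path: str) -> None:
        """Single-archive serialization (npz with a JSON metadata entry)."""
        arrays, meta = {}, {
            "version": _ARCHIVE_VERSION,
            "spec": {
                "hidden": self.spec.hidden,
                "output": self.spec.output,
                "negative_slope": self.spec.negative_slope,
            },
            "cfg": {k: v for k, v in vars(self.cfg).items()},
            "best_epoch": self.best_epoch,
            "train_loss": list(map(float, self.train_loss)),
            "valid_loss": list(map(float, self.valid_loss)),
            "n_views": len(self.nets),
            "n_layers": [net.n_layers for net in self.nets],
        }
        for d, net in enumerate(self.nets):
            for m, (W, b) in enumerate(zip(net.W, net.b)):
                arrays[f"W_{d}_{m}"] = W
                arrays[f"b_{d}_{m}"] = b
        if self.standardizer is not None:
            for d, (mu, sd) in enumerate(zip(self.standardizer.means_, self.standardizer.sds_)):
                arrays[f"std_mean_{d}"] = mu
                arrays[f"std_sd_{d}"] = sd
            meta["standardized"] = True
        else:
            meta["standardized"] = False
        if self.projections is not None:
            for d, (G, ev) in enumerate(zip(self.projections.Gammas, self.projections.eigenvalues)):
                arrays[f"Gamma_{d}"] = G
                arrays[f"eig_{d}"] = ev
                if self.projections.loadings is not None:
                    arrays[f"loading_{d}"] = self.projections.loadings[d]
            meta["objective"] = float(self.projections.objective)
        if self.centroids is not None:
            for d, cen in enumerate(self.centroids.per_view):
                arrays[f"centroid_{d}"] = cen
        if self.score_centroids is not None:
            for d, cen in enumerate(self.score_centroids.per_view):
                arrays[f"score_centroid_{d}"] = cen
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "DeepIDAModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"].tobytes()).decode())
            if meta["version"] != _ARCHIVE_VERSION:
                raise ValueError(f"unsupported archive version {meta['version']}")
            spec = NetworkSpec(**meta["spec"])
            cfg = TrainConfig(**meta["cfg"])
            nets = []
            for d in range(meta["n_views"]):
                W = [z[f"W_{d}_{m}"] for m in range(meta["n_layers"][d])]
                b = [z[f"b_{d}_{m}"] for m in range(meta["n_layers"][d])]
                sizes = [W[0].shape[1]] + [w.shape[0] for w in W]
                net = MLP(sizes, spec.negative_slope)
                net.set_params((W, b))
                nets.append(net)
            model = cls(nets=nets, spec=spec, cfg=cfg,
                        best_epoch=meta["best_epoch"],
                        train_loss=meta["train_loss"], valid_loss=meta["valid_loss"])
            if meta["standardized"]:
                st = Standardizer()
                st.means_ = [z[f"std_mean_{d}"] for d in range(meta["n_views"])]
                st.sds_ = [z[f"std_sd_{d}"] for d in range(meta["n_views"])]
                model.standardizer = st
            if "Gamma_0" in z:
                Gammas = [z[f"Gamma_{d}"] for d in range(meta["n_views"])]
                eigs = [z[f"eig_{d}"] for d in range(meta["n_views"])]
                model.projections = ProjectionSet(
                    Gammas=Gammas, eigenvalues=eigs,
                    objective=meta.get("objective", float("nan")), converged=True)
                if "loading_0" in z:
                    model.projections.loadings = [
                        z[f"loading_{d}"] for d in range(meta["n_views"])]
            for attr, key in (("centroids", "centroid"),
                              ("score_centroids", "score_centroid")):
                if f"{key}_0" in z:
                    per_view = [z[f"{key}_{d}"] for d in range(meta["n_views"])]
                    setattr(model, attr, CentroidModel(
                        pooled=np.hstack(per_view), per_view=per_view,
                        classes=np.arange(1, per_view[0].shape[0] + 1)))
        return model


def _stratified_batches(labels: np.ndarray, batch_size: int, rng) -> list:
    """Class-stratified minibatches, each containing every class."""
    n = labels.size
    n_batches = max(1, int(np.ceil(n / batch_size)))
    buckets = [[] for _ in range(n_batches)]
    for k in range(1, int(labels.max()) + 1):
        idx = np.where(labels == k)[0]
        if idx.size < n_batches:
            raise ValueError(
                f"class {k} has {idx.size} samples, fewer than {n_batches} batches"
            )
        rng.shuffle(idx)
        for b, chunk in enumerate(np.array_split(idx, n_batches)):
            buckets[b].extend(chunk.tolist())
    return [np.sort(np.asarray(b)) for b in buckets]


def train(train_ds: MultiViewDataset, valid_ds: MultiViewDataset | None,
          spec: NetworkSpec, cfg: TrainConfig) -> DeepIDAModel:
    """Fit the multi-view model; see the module docstring for the loop."""
    from .datasets import validate_dataset

    train_ds = train_ds if train_ds._validated else validate_dataset(train_ds)
    if valid_ds is not None and not valid_ds._validated:
        valid_ds = validate_dataset(valid_ds)
    K = train_ds.n_classes
    l = cfg.l if cfg.l is not None else spec.max_l(K)
    if l > spec.max_l(K):
        raise ValueError(f"l={l} exceeds min(K-1, output widths)={spec.max_l(K)}")

    rng = np.random.default_rng(cfg.seed)
    std = None
    Xtr = train_ds.views
    if cfg.standardize:
        std = Standardizer()
        Xtr = std.fit_transform(Xtr)
    Xva = None
    if valid_ds is not None:
        Xva = std.transform(valid_ds.views) if std else valid_ds.views

    nets = [
        MLP([p] + list(h) + [o], spec.negative_slope, rng)
        for p, h, o in zip(train_ds.n_features, spec.hidden, spec.output)
    ]
    if cfg.init_scale != 1.0:
        # damped first-layer start: feature weights grow only where the
        # loss gradient asks for them, reducing dependence on noise inputs
        for net in nets:
            net.W[0] *= cfg.init_scale
    params = [p for net in nets for p in (*net.W, *net.b)]
    mask = [m for net in nets for m in ([True] * len(net.W) + [False] * len(net.b))]
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay, decay_mask=mask)

    model = DeepIDAModel(nets=nets, spec=spec, cfg=cfg, standardizer=std)
    if cfg.epochs == 0:
        warnings.warn("0 epochs requested: returning the initialized model")

    best = (np.inf, None, None)  # (valid loss, epoch, params snapshot)
    for epoch in range(cfg.epochs):
        if cfg.batch_size is None:
            batches = [np.arange(train_ds.n_samples)]
        else:
            batches = _stratified_batches(train_ds.labels, cfg.batch_size, rng)
        losses = []
        for idx in batches:
            H = [net.forward(X[idx], cache=True) for net, X in zip(nets, Xtr)]
            loss, gH, _ = loss_and_grad(H, train_ds.labels[idx], cfg.rho, l, cfg.ridge)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "check input scaling or reduce the learning rate"
                )
            grads = []
            for net, g in zip(nets, gH):
                gW, gb = net.backward(g)
                grads.extend([*gW, *gb])
            opt.step(grads)
            losses.append(loss)
        model.train_loss.append(float(np.mean(losses)))
        if valid_ds is not None:
            Hv = [net.forward(X) for net, X in zip(nets, Xva)]
            vloss, _, _ = loss_and_grad(Hv, valid_ds.labels, cfg.rho, l, cfg.ridge,
                                        solver_tol=1e-8, solver_max_iter=200)
            model.valid_loss.append(float(vloss))
            if vloss < best[0]:
                best = (vloss, epoch, [net.get_params() for net in nets])

    if valid_ds is not None and best[1] is not None:
        for net, p in zip(nets, best[2]):
            net.set_params(p)
        model.best_epoch = best[1] + 1
    elif cfg.epochs > 0:
        model.best_epoch = cfg.epochs

    # refit projections and centroids on the full training data
    H = [net.forward(X) for net, X in zip(nets, Xtr)]
    _, _, proj = loss_and_grad(H, train_ds.labels, cfg.rho, l, cfg.ridge,
                               solver_tol=1e-10, solver_max_iter=500)
    model.projections = proj
    model.centroids = fit_centroids(H, train_ds.labels)
    model.score_centroids = fit_centroids(
        [h @ A for h, A in zip(H, proj.loadings)], train_ds.labels)
    return model
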