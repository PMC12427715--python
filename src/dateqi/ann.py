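"""Feed-forward neural regression of the quality index from spectra.

A small fully-connected network (default: one hidden layer of 32 tanh
units) maps preprocessed second-derivative spectra to the dimensionless
Qi in [0, 1].  Training minimizes mean squared error with Adam
(momentum-style adaptive gradient stepping), mini-batches shuffled from
a seeded generator, early stopping on a replicate-disjoint validation
split, and restoration of the best-validation weights.  Everything is
deterministic under the configured seed.

Inputs are standardized per wavelength using training statistics only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPConfig", "MLPModel", "mlp_fit", "mlp_predict", "compare_models"]


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MLPConfig:
    hidden_layer_sizes: tuple[int, ...] = (32,)
    activation: str = "tanh"  # or "rectifier"
    max_epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 64
    early_stopping_patience: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_layer_sizes or any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden_layer_sizes must be positive integers")
        if self.activation not in ("tanh", "rectifier"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else np.maximum(z, 0.0)


def _act_grad(a: np.ndarray, z: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - a * a if kind == "tanh" else (z > 0).astype(z.dtype)


@dataclass
class MLPModel:
    config: MLPConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_std: np.ndarray
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_inputs(self) -> int:
        return self.x_mean.size

    def to_json(self, path=None) -> str:
        payload = {
            "config": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in self.config.__dict__.items()
                }
            },
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MLPModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        cfg = dict(payload["config"])
        cfg["hidden_layer_sizes"] = tuple(cfg["hidden_layer_sizes"])
        return cls(
            config=MLPConfig(**cfg),
            weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
            biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            x_std=np.asarray(payload["x_std"], dtype=float),
            history=payload["history"],
            best_epoch=payload["best_epoch"],
        )


def _forward(model_w, model_b, X, kind):
    a = X
    pre, post = [], []
    for i, (W, b) in enumerate(zip(model_w, model_b)):
        z = a @ W + b
        pre.append(z)
        a = z if i == len(model_w) - 1 else _act(z, kind)
        post.append(a)
    return pre, post


def mlp_fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: MLPConfig | None = None,
) -> MLPModel:
    """Train by mini-batch Adam on MSE with early stopping.

    ``(X_val, y_val)`` must be replicate-disjoint from the training rows;
    the served weights are those of the best validation epoch.
    """
    cfg = cfg or MLPConfig()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    n, p = X_train.shape

    x_mean = X_train.mean(axis=0)
    x_std = X_train.std(axis=0)
    x_std = np.where(x_std < 1e-12, 1.0, x_std)
    Xt = (X_train - x_mean) / x_std
    Xv = (X_val - x_mean) / x_std

    rng = np.random.default_rng(cfg.seed)
    sizes = (p, *cfg.hidden_layer_sizes, 1)
    Ws = [
        rng.normal(0.0, 1.0 / np.sqrt(sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    bs = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    mW = [np.zeros_like(W) for W in Ws]
    vW = [np.zeros_like(W) for W in Ws]
    mb = [np.zeros_like(b) for b in bs]
    vb = [np.zeros_like(b) for b in bs]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def _loss(Xm, ym):
        _, post = _forward(Ws, bs, Xm, cfg.activation)
        return float(np.mean((post[-1].ravel() - ym) ** 2))

    best_val = np.inf
    best_epoch = -1
    best = None
    history: list[dict] = []
    patience_left = cfg.early_stopping_patience

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xb, yb = Xt[idx], y_train[idx]
            pre, post = _forward(Ws, bs, Xb, cfg.activation)
            m = Xb.shape[0]
            delta = 2.0 * (post[-1].ravel() - yb)[:, None] / m
            grads_W, grads_b = [None] * len(Ws), [None] * len(Ws)
            for layer in range(len(Ws) - 1, -1, -1):
                a_prev = Xb if layer == 0 else post[layer - 1]
                grads_W[layer] = a_prev.T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ Ws[layer].T) * _act_grad(
                        post[layer - 1], pre[layer - 1], cfg.activation
                    )
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for layer in range(len(Ws)):
                for g, mom, vel, param in (
                    (grads_W[layer], mW, vW, Ws),
                    (grads_b[layer], mb, vb, bs),
                ):
                    mom[layer] = beta1 * mom[layer] + (1 - beta1) * g
                    vel[layer] = beta2 * vel[layer] + (1 - beta2) * g * g
                    param[layer] = param[layer] - cfg.learning_rate * (
                        mom[layer] / corr1
                    ) / (np.sqrt(vel[layer] / corr2) + eps)
                mW[layer], vW[layer], mb[layer], vb[layer] = (
                    mW[layer],
                    vW[layer],
                    mb[layer],
                    vb[layer],
                )
        train_loss = _loss(Xt, y_train)
        val_loss = _loss(Xv, y_val)
        if not (np.isfinite(train_loss) and np.isfinite(val_loss)):
            raise DivergenceError(
                "non-finite loss during training; try a smaller learning rate"
            )
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best = ([W.copy() for W in Ws], [b.copy() for b in bs])
            patience_left = cfg.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    assert best is not None
    return MLPModel(
        config=cfg,
        weights=best[0],
        biases=best[1],
        x_mean=x_mean,
        x_std=x_std,
        history=history,
        best_epoch=best_epoch,
    )


def mlp_predict(model: MLPModel, X: np.ndarray, clip: bool = True) -> np.ndarray:
    """Deterministic forward pass; Qi predictions clipped to [0, 1] by
    default (the index is defined on that range)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_inputs:
        raise ValueError(f"X must have {model.n_inputs} columns")
    Xs = (X - model.x_mean) / model.x_std
    _, post = _forward(model.weights, model.biases, Xs, model.config.activation)
    out = post[-1].ravel()
    return np.clip(out, 0.0, 1.0) if clip else out


def compare_models(plsr_report, ann_report) -> dict:
    """Side-by-side PLSR vs ANN metrics with a per-metric winner flag.

    Both reports must come from identical splits (checked via the
    independent-set mean and range, which are model-independent).
    """

    def _get(rep, key):
        return rep[key] if isinstance(rep, dict) else getattr(rep, key)

    for key in ("y_mean", "y_range"):
        if abs(_get(plsr_report, key) - _get(ann_report, key)) > 1e-9:
            raise ValueError(
                "reports were not computed on identical evaluation splits"
            )
    higher_better = {"r_squared", "r_squared_cv", "r_squared_pred", "rer"}
    out = {}
    for key in (
        "r_squared",
        "rmsec",
        "rmsecv",
        "r_squared_cv",
        "rmsep",
        "r_squared_pred",
        "rep_percent",
        "rer",
    ):
        a, b = _get(plsr_report, key), _get(ann_report, key)
        if a == b:
            winner = "tie"
        elif (b > a) == (key in higher_better):
            winner = "ann"
        else:
            winner = "plsr"
        out[key] = {"plsr": a, "ann": b, "winner": winner}
    return out
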