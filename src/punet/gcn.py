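"""Frozen-feature graph-convolutional node scorer (NumPy implementation).

Three graph-convolution layers, each followed by batch normalization, ReLU
and dropout, then a fully connected layer producing one sigmoid score per
node. Message passing uses the symmetric-normalized adjacency with self
loops, Â = D̃^{-1/2} (A + I) D̃^{-1/2}. Node features are frozen inputs;
the learnable parameters are the three conv layers, the batch-norm affine
parameters and the final linear layer.

Forward and backward passes are written out explicitly over NumPy/SciPy
arrays (full-batch, CPU); gradients are exercised against finite differences
in the test suite. Training uses standard Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import PPINetwork

__all__ = [
    "ModelConfig",
    "ModelParams",
    "normalized_adjacency",
    "init_params",
    "forward",
    "backward",
    "Adam",
    "save_params",
    "load_params",
]

# Running-statistics momentum 0.3: batch statistics move quickly during the
# first training epochs, and inference-mode spy evaluation (which drives
# early stopping) must track them within the patience window.
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.3


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dims`` tapers toward the scalar output; ``dropout_p`` is the
    drop probability applied after each hidden layer during training.
    """

    hidden_dims: tuple[int, int, int] = (256, 64, 16)
    dropout_p: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden widths must be >= 1")


@dataclass
class _Layer:
    W: np.ndarray
    b: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    run_mean: np.ndarray
    run_var: np.ndarray


@dataclass
class ModelParams:
    """Learnable parameters plus batch-norm running statistics."""

    layers: list[_Layer]
    w_out: np.ndarray
    b_out: float

    def copy(self) -> "ModelParams":
        return ModelParams(
            [_Layer(*(a.copy() for a in (l.W, l.b, l.gamma, l.beta, l.run_mean, l.run_var)))
             for l in self.layers],
            self.w_out.copy(),
            float(self.b_out),
        )

    def trainable(self) -> list[np.ndarray]:
        """Flat list of trainable arrays (running stats excluded), in a fixed order."""
        out: list[np.ndarray] = []
        for l in self.layers:
            out += [l.W, l.b, l.gamma, l.beta]
        out += [self.w_out]
        return out


def normalized_adjacency(net: PPINetwork) -> sp.csr_matrix:
    """Symmetric-normalized adjacency with self loops.

    Â = D̃^{-1/2} (A + I) D̃^{-1/2} with A the unweighted adjacency and D̃
    the degree matrix of A + I. Rows follow the canonical node order.
    """
    a = net.adjacency().astype(float)
    a = a + sp.identity(net.n_nodes, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    d = sp.diags(d_inv_sqrt)
    return (d @ a @ d).tocsr()


def init_params(cfg: ModelConfig, n_features: int) -> ModelParams:
    """Deterministic uniform fan-in initialization (U(-1/sqrt(fan_in), +))."""
    rng = np.random.default_rng(cfg.seed)
    dims = [n_features, *cfg.hidden_dims]
    layers = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = 1.0 / np.sqrt(d_in)
        layers.append(_Layer(
            W=rng.uniform(-bound, bound, size=(d_in, d_out)),
            b=rng.uniform(-bound, bound, size=d_out),
            gamma=np.ones(d_out),
            beta=np.zeros(d_out),
            run_mean=np.zeros(d_out),
            run_var=np.ones(d_out),
        ))
    bound = 1.0 / np.sqrt(dims[-1])
    w_out = rng.uniform(-bound, bound, size=dims[-1])
    b_out = float(rng.uniform(-bound, bound))
    return ModelParams(layers, w_out, b_out)


@dataclass
class _Cache:
    """Intermediates kept by the training-mode forward pass for backprop."""

    x: np.ndarray
    a_hat: sp.csr_matrix | None
    per_layer: list[dict] = field(default_factory=list)
    h_final: np.ndarray | None = None
    scores: np.ndarray | None = None


def forward(
    params: ModelParams,
    a_hat: sp.csr_matrix | None,
    x: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
    dropout_p: float = 0.5,
    update_running_stats: bool = True,
) -> tuple[np.ndarray, _Cache]:
    """Full-batch forward pass; returns (scores, cache).

    ``a_hat=None`` substitutes the identity for the aggregation operator,
    degenerating the network to a pure feature model (used by the
    feature-only baseline and for mixup virtual nodes). In training mode
    batch norm uses batch statistics (and updates running stats in place
    unless disabled) and dropout is active; at inference both are frozen.
    """
    if training and dropout_p > 0 and rng is None:
        raise ValueError("training-mode forward with dropout needs an rng")
    cache = _Cache(x=x, a_hat=a_hat)
    h = x
    for layer in params.layers:
        m = a_hat @ h if a_hat is not None else h
        z = m @ layer.W + layer.b
        if training:
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            if update_running_stats:
                layer.run_mean += _BN_MOMENTUM * (mu - layer.run_mean)
                layer.run_var += _BN_MOMENTUM * (var - layer.run_var)
        else:
            mu, var = layer.run_mean, layer.run_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        z_hat = (z - mu) * inv_std
        y = layer.gamma * z_hat + layer.beta
        r = np.maximum(y, 0.0)
        if training and dropout_p > 0:
            mask = (rng.random(r.shape) >= dropout_p) / (1.0 - dropout_p)
            h_next = r * mask
        else:
            mask = None
            h_next = r
        cache.per_layer.append({
            "m": m, "z_hat": z_hat, "inv_std": inv_std,
            "relu_mask": (y > 0), "dropout_mask": mask,
            "batch_stats": training,
        })
        h = h_next
    logits = h @ params.w_out + params.b_out
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("numerical blow-up in forward pass")
    scores = 1.0 / (1.0 + np.exp(-logits))
    cache.h_final = h
    cache.scores = scores
    return scores, cache


@dataclass
class Gradients:
    layers: list[dict]
    w_out: np.ndarray
    b_out: float

    def trainable(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for g in self.layers:
            out += [g["W"], g["b"], g["gamma"], g["beta"]]
        out += [self.w_out]
        return out


def backward(params: ModelParams, cache: _Cache, d_scores: np.ndarray) -> Gradients:
    """Backpropagate d(loss)/d(scores) through the cached forward pass."""
    s = cache.scores
    d_logits = d_scores * s * (1.0 - s)
    d_w_out = cache.h_final.T @ d_logits
    d_b_out = float(d_logits.sum())
    d_h = np.outer(d_logits, params.w_out)

    layer_grads: list[dict] = [None] * len(params.layers)  # type: ignore[list-item]
    for li in range(len(params.layers) - 1, -1, -1):
        layer = params.layers[li]
        c = cache.per_layer[li]
        if c["dropout_mask"] is not None:
            d_h = d_h * c["dropout_mask"]
        d_y = d_h * c["relu_mask"]
        d_gamma = (d_y * c["z_hat"]).sum(axis=0)
        d_beta = d_y.sum(axis=0)
        d_z_hat = d_y * layer.gamma
        if c["batch_stats"]:
            n = d_z_hat.shape[0]
            d_z = c["inv_std"] * (
                d_z_hat
                - d_z_hat.mean(axis=0)
                - c["z_hat"] * (d_z_hat * c["z_hat"]).mean(axis=0)
            )
        else:
            d_z = d_z_hat * c["inv_std"]
        d_w = c["m"].T @ d_z
        d_b = d_z.sum(axis=0)
        d_m = d_z @ layer.W.T
        d_h = cache.a_hat.T @ d_m if cache.a_hat is not None else d_m
        layer_grads[li] = {"W": d_w, "b": d_b, "gamma": d_gamma, "beta": d_beta}
    return Gradients(layer_grads, d_w_out, d_b_out)


class Adam:
    """Standard Adam over a ModelParams instance (lr 0.001 by default)."""

    def __init__(self, params: ModelParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        arrays = params.trainable()
        self.m = [np.zeros_like(a) for a in arrays] + [0.0]
        self.v = [np.zeros_like(a) for a in arrays] + [0.0]

    def step(self, grads: Gradients) -> None:
        self.t += 1
        arrays = self.params.trainable() + [None]
        garrays = grads.trainable() + [grads.b_out]
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (a, g) in enumerate(zip(arrays, garrays)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * (np.asarray(g) ** 2)
            update = self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if a is None:
                self.params.b_out -= float(update)
            else:
                a -= update


def save_params(params: ModelParams, path) -> None:
    """Serialize parameters as a flat .npz (portable, text-free manifest in keys)."""
    arrays = {}
    for i, l in enumerate(params.layers):
        for name in ("W", "b", "gamma", "beta", "run_mean", "run_var"):
            arrays[f"layer{i}_{name}"] = getattr(l, name)
    arrays["w_out"] = params.w_out
    arrays["b_out"] = np.array(params.b_out)
    np.savez(path, **arrays)


def load_params(path) -> ModelParams:
    data = np.load(path)
    layers = []
    i = 0
    while f"layer{i}_W" in data:
        layers.append(_Layer(*(data[f"layer{i}_{n}"]
                               for n in ("W", "b", "gamma", "beta", "run_mean", "run_var"))))
        i += 1
    return ModelParams(layers, data["w_out"], float(data["b_out"]))
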