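"""Graph-convolutional classifier and feedforward baseline.

Both models are small enough that plain numpy with hand-written backprop is
the right tool.  The GCN consumes the 13-node upper-body skeleton with
3 coordinates per node; each graph convolution propagates features over the
symmetric renormalized adjacency with self-loops,

    H' = act( D^(-1/2) (A + I) D^(-1/2) · H · W + b ),

the standard first-order spectral rule, which is numerically stable on small
graphs.  Two convolutions (16 then 32 channels), each followed by dropout
during training, are flattened (13 × 32 = 416) into a 64-unit dense layer
whose activations form the latent feature space, then a linear softmax head.

The FFNN baseline takes the flattened 39-vector through two dense hidden
layers (128, 64) with dropout, matching the GCN's capacity scale and the
64-unit penultimate contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ContractError, ShapeError, ValidationError

PENULTIMATE_DIM = 64


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def relu(x):
    return np.maximum(x, 0.0)


def softmax(z):
    """Row-wise softmax, numerically stabilized."""
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def normalize_adjacency(A) -> np.ndarray:
    """Symmetric renormalization with self-loops: D^(-1/2)(A+I)D^(-1/2)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def graph_conv_layer(H, W, A_hat, activation=relu) -> np.ndarray:
    """One graph convolution on a single graph: ``activation(A_hat @ H @ W)``."""
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if H.shape[-1] != W.shape[0]:
        raise ShapeError(
            f"feature dim {H.shape[-1]} does not match weight rows {W.shape[0]}"
        )
    return activation(A_hat @ H @ W)


def _init_weight(rng, fan_in, shape):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _dropout_mask(rng, shape, rate):
    # Inverted dropout: activations are rescaled at train time so inference
    # needs no correction.
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _check_finite(X):
    if not np.all(np.isfinite(X)):
        raise ValidationError("input contains non-finite values")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GCNConfig:
    conv_channels: tuple[int, int] = (16, 32)
    dense_units: int = PENULTIMATE_DIM
    n_classes: int = 2
    dropout_rate: float = 0.2
    activation: str = "relu"

    def validate(self):
        if self.n_classes < 2:
            raise ValidationError("n_classes must be at least 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.activation != "relu":
            raise ValidationError("only the rectifier activation is supported")


@dataclass(frozen=True)
class FFNNConfig:
    hidden_units: tuple[int, ...] = (128, 64)
    dropout_rate: float = 0.2
    n_classes: int = 2
    input_dim: int = 39

    def validate(self):
        if self.n_classes < 2:
            raise ValidationError("n_classes must be at least 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if len(self.hidden_units) < 1:
            raise ValidationError("at least one hidden layer is required")


# ---------------------------------------------------------------------------
# GCN
# ---------------------------------------------------------------------------

class GCNClassifier:
    """Two graph convolutions + dense layer + softmax on a fixed skeleton."""

    kind = "gcn"

    def __init__(self, adjacency, config: GCNConfig | None = None, seed: int = 0):
        self.config = config or GCNConfig()
        self.config.validate()
        A = np.asarray(adjacency, dtype=float)
        self.adjacency = A
        self.a_hat = normalize_adjacency(A)
        self.n_nodes = A.shape[0]
        c1, c2 = self.config.conv_channels
        d, k = self.config.dense_units, self.config.n_classes
        rng = np.random.default_rng(seed)
        flat = self.n_nodes * c2
        self.params = {
            "W1": _init_weight(rng, 3, (3, c1)), "b1": np.zeros(c1),
            "W2": _init_weight(rng, c1, (c1, c2)), "b2": np.zeros(c2),
            "W3": _init_weight(rng, flat, (flat, d)), "b3": np.zeros(d),
            "W4": _init_weight(rng, d, (d, k)), "b4": np.zeros(k),
        }

    # -- forward ------------------------------------------------------------

    def _forward(self, X, training=False, rng=None):
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1:] != (self.n_nodes, 3):
            raise ShapeError(f"expected (batch, {self.n_nodes}, 3), got {X.shape}")
        _check_finite(X)
        p = self.params
        rate = self.config.dropout_rate
        drop = training and rate > 0.0
        if drop and rng is None:
            raise ValidationError("training-mode forward pass requires an rng for dropout")

        AX = np.einsum("ij,bjf->bif", self.a_hat, X)
        H1 = relu(AX @ p["W1"] + p["b1"])
        M1 = _dropout_mask(rng, H1.shape, rate) if drop else 1.0
        D1 = H1 * M1
        AD1 = np.einsum("ij,bjf->bif", self.a_hat, D1)
        H2 = relu(AD1 @ p["W2"] + p["b2"])
        M2 = _dropout_mask(rng, H2.shape, rate) if drop else 1.0
        D2 = H2 * M2
        F = D2.reshape(X.shape[0], -1)
        Z = relu(F @ p["W3"] + p["b3"])
        logits = Z @ p["W4"] + p["b4"]
        probs = softmax(logits)
        cache = dict(X=X, AX=AX, H1=H1, M1=M1, AD1=AD1, H2=H2, M2=M2,
                     F=F, Z=Z, probs=probs, single=single)
        return cache

    def forward(self, X, training=False, rng=None) -> np.ndarray:
        """Class probabilities; dropout is active only when ``training``."""
        cache = self._forward(X, training=training, rng=rng)
        probs = cache["probs"]
        return probs[0] if cache["single"] else probs

    def penultimate(self, X) -> np.ndarray:
        """64-unit dense-layer activations (inference mode)."""
        cache = self._forward(X, training=False)
        Z = cache["Z"]
        return Z[0] if cache["single"] else Z

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, X, Y_onehot, rng=None):
        """Mean cross-entropy loss and gradients for a minibatch."""
        cache = self._forward(X, training=True, rng=rng)
        p = self.params
        B = cache["X"].shape[0]
        probs, Z, F = cache["probs"], cache["Z"], cache["F"]
        Y = np.asarray(Y_onehot, dtype=float).reshape(B, -1)
        loss = float(-np.mean(np.sum(Y * np.log(np.clip(probs, 1e-12, None)), axis=1)))

        dlogits = (probs - Y) / B
        grads = {}
        grads["W4"] = Z.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        dZ = (dlogits @ p["W4"].T) * (Z > 0)
        grads["W3"] = F.T @ dZ
        grads["b3"] = dZ.sum(axis=0)
        dF = dZ @ p["W3"].T
        dD2 = dF.reshape(cache["H2"].shape)
        G2 = dD2 * cache["M2"] * (cache["H2"] > 0)
        grads["W2"] = np.einsum("bif,big->fg", cache["AD1"], G2)
        grads["b2"] = G2.sum(axis=(0, 1))
        dD1 = np.einsum("ij,bjg->big", self.a_hat, G2 @ p["W2"].T)
        G1 = dD1 * cache["M1"] * (cache["H1"] > 0)
        grads["W1"] = np.einsum("bif,big->fg", cache["AX"], G1)
        grads["b1"] = G1.sum(axis=(0, 1))
        return loss, grads

    # -- (de)serialization helpers -------------------------------------------

    def get_params(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params):
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=float).copy()

    def config_dict(self):
        return asdict(self.config)


# ---------------------------------------------------------------------------
# FFNN baseline
# ---------------------------------------------------------------------------

class FFNNClassifier:
    """Plain fully connected baseline on the flattened 39-feature vector."""

    kind = "ffnn"

    def __init__(self, config: FFNNConfig | None = None, seed: int = 0):
        self.config = config or FFNNConfig()
        self.config.validate()
        rng = np.random.default_rng(seed)
        dims = [self.config.input_dim, *self.config.hidden_units, self.config.n_classes]
        self.params = {}
        for layer, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:]), start=1):
            self.params[f"W{layer}"] = _init_weight(rng, fan_in, (fan_in, fan_out))
            self.params[f"b{layer}"] = np.zeros(fan_out)
        self.n_layers = len(dims) - 1

    def _forward(self, X, training=False, rng=None):
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None]
        if X.shape[1] != self.config.input_dim:
            raise ShapeError(
                f"expected input length {self.config.input_dim}, got {X.shape[1]}"
            )
        _check_finite(X)
        rate = self.config.dropout_rate
        drop = training and rate > 0.0
        if drop and rng is None:
            raise ValidationError("training-mode forward pass requires an rng for dropout")
        acts = [X]       # post-dropout activations feeding each layer
        hidden = []      # pre-dropout hidden activations
        masks = []
        H = X
        for layer in range(1, self.n_layers):
            H = relu(H @ self.params[f"W{layer}"] + self.params[f"b{layer}"])
            hidden.append(H)
            M = _dropout_mask(rng, H.shape, rate) if drop else 1.0
            masks.append(M)
            H = H * M
            acts.append(H)
        logits = H @ self.params[f"W{self.n_layers}"] + self.params[f"b{self.n_layers}"]
        probs = softmax(logits)
        return dict(acts=acts, hidden=hidden, masks=masks, probs=probs, single=single)

    def forward(self, X, training=False, rng=None) -> np.ndarray:
        cache = self._forward(X, training=training, rng=rng)
        probs = cache["probs"]
        return probs[0] if cache["single"] else probs

    def penultimate(self, X) -> np.ndarray:
        """Last hidden-layer activations (inference mode, no dropout)."""
        cache = self._forward(X, training=False)
        H = cache["hidden"][-1]
        return H[0] if cache["single"] else H

    def loss_and_grads(self, X, Y_onehot, rng=None):
        cache = self._forward(X, training=True, rng=rng)
        B = cache["acts"][0].shape[0]
        probs = cache["probs"]
        Y = np.asarray(Y_onehot, dtype=float).reshape(B, -1)
        loss = float(-np.mean(np.sum(Y * np.log(np.clip(probs, 1e-12, None)), axis=1)))

        grads = {}
        delta = (probs - Y) / B
        for layer in range(self.n_layers, 0, -1):
            A_in = cache["acts"][layer - 1]
            grads[f"W{layer}"] = A_in.T @ delta
            grads[f"b{layer}"] = delta.sum(axis=0)
            if layer > 1:
                dA = delta @ self.params[f"W{layer}"].T
                dH = dA * cache["masks"][layer - 2]
                delta = dH * (cache["hidden"][layer - 2] > 0)
        return loss, grads

    def get_params(self):
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params):
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=float).copy()

    def config_dict(self):
        return asdict(self.config)


def penultimate_features(model, X) -> np.ndarray:
    """Extract the 64-dimensional latent features from a model.

    Raises :class:`ContractError` if the model's penultimate layer does not
    have exactly 64 units.
    """
    feats = np.atleast_2d(model.penultimate(X))
    if feats.shape[-1] != PENULTIMATE_DIM:
        raise ContractError(
            f"penultimate layer has {feats.shape[-1]} units; "
            f"the latent-analysis contract requires {PENULTIMATE_DIM}"
        )
    single = np.asarray(X).ndim == (2 if getattr(model, "kind", "") == "gcn" else 1)
    return feats[0] if single else feats


def describe(model) -> str:
    return json.dumps({"kind": model.kind, "config": model.config_dict()}, indent=2)
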