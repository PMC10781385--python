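"""Gated recurrent unit (GRU) sequence classifier.

The cell follows the update/reset-gate formulation with the update gate z
weighting the candidate state:

    z = sigmoid(W' [h_prev; x] + b')
    r = sigmoid(W'' [h_prev; x] + b'')
    h = (1 - z) * h_prev + z * tanh(W [r * h_prev; x] + b)

so each hidden coordinate is a convex combination of the previous state and
a value in (-1, 1): z -> 1 leans entirely on the candidate, z -> 0 carries
the previous state through.  The classifier stacks k = 4 such layers of 125
hidden units and reads out the final hidden state of the top layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Linear, Module, Tensor, concat

__all__ = [
    "GRUConfig",
    "GRUCellParams",
    "gru_step",
    "build_gru",
    "GRUClassifier",
    "train_classifier",
]

train_classifier = nn.train_classifier


@dataclass(frozen=True)
class GRUConfig:
    """Architecture hyperparameters of the GRU classifier."""

    k_blocks: int = 4
    hidden: int = 125
    n_features: int = 54
    n_classes: int = 6

    def __post_init__(self):
        if self.k_blocks <= 0 or self.hidden <= 0:
            raise ValueError("k_blocks and hidden must be positive")


@dataclass
class GRUCellParams:
    """Weights over the concatenated [h_prev; x] vector.

    ``W``/``b`` drive the candidate state, ``W_z``/``b_z`` the update gate,
    ``W_r``/``b_r`` the reset gate.
    """

    W: np.ndarray
    W_z: np.ndarray
    W_r: np.ndarray
    b: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray

    def __post_init__(self):
        H = self.b.shape[-1]
        for name in ("W", "W_z", "W_r"):
            m = getattr(self, name)
            if m.ndim != 2 or m.shape[1] != H:
                raise ValueError(f"{name} must map [h; x] to {H} units")
        for name in ("b_z", "b_r"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must have shape ({H},)")


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


def gru_step(params: GRUCellParams, h_prev, x) -> np.ndarray:
    """One GRU state update (elementwise gate equations, numpy oracle)."""
    h_prev = np.asarray(h_prev, dtype=float)
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(h_prev)) and np.all(np.isfinite(x))):
        raise ValueError("inputs must be finite")
    hx = np.concatenate([h_prev, x], axis=-1)
    if hx.shape[-1] != params.W.shape[0]:
        raise ValueError(
            f"[h; x] has size {hx.shape[-1]}, weights expect "
            f"{params.W.shape[0]}"
        )
    z = _sigmoid(hx @ params.W_z + params.b_z)
    r = _sigmoid(hx @ params.W_r + params.b_r)
    rhx = np.concatenate([r * h_prev, x], axis=-1)
    cand = np.tanh(rhx @ params.W + params.b)
    return (1.0 - z) * h_prev + z * cand


class _GRULayer(Module):
    def __init__(self, n_in, hidden, rng):
        total = n_in + hidden
        self.Wz = nn._glorot(rng, total, hidden)
        self.Wr = nn._glorot(rng, total, hidden)
        self.Wc = nn._glorot(rng, total, hidden)
        self.bz = Tensor(np.zeros(hidden), requires_grad=True)
        self.br = Tensor(np.zeros(hidden), requires_grad=True)
        self.bc = Tensor(np.zeros(hidden), requires_grad=True)
        self.hidden = hidden

    def cell_params(self) -> GRUCellParams:
        return GRUCellParams(
            W=self.Wc.data, W_z=self.Wz.data, W_r=self.Wr.data,
            b=self.bc.data, b_z=self.bz.data, b_r=self.br.data,
        )

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.data.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            xt = x[:, t, :]
            hx = concat([h, xt], axis=1)
            z = (hx @ self.Wz + self.bz).sigmoid()
            r = (hx @ self.Wr + self.br).sigmoid()
            cand = (concat([r * h, xt], axis=1) @ self.Wc + self.bc).tanh()
            h = (1.0 - z) * h + z * cand
            outs.append(h.reshape(B, 1, H))
        return concat(outs, axis=1)


class GRUClassifier(Module):
    """Stacked GRU layers with a final-hidden-state classification head."""

    def __init__(self, cfg: GRUConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.layers = []
        n_in = cfg.n_features
        for _ in range(cfg.k_blocks):
            self.layers.append(_GRULayer(n_in, cfg.hidden, rng))
            n_in = cfg.hidden
        self.head = Linear(cfg.hidden, cfg.n_classes, rng)
        self.feature_dim = cfg.hidden
        self.trained = False
        self._drop_rng = np.random.default_rng(seed)

    def set_dropout_rng(self, rng):
        self._drop_rng = rng  # no inter-layer dropout by default

    def forward_features(self, x: Tensor, train: bool = False) -> Tensor:
        """Top-layer hidden states per timestep (B, T, hidden)."""
        h = self.normalize_input(x)
        for layer in self.layers:
            h = layer(h)
        return h

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        h = self.forward_features(x, train)
        return self.head(h[:, -1, :])


def build_gru(cfg: GRUConfig = GRUConfig(), seed: int = 0) -> GRUClassifier:
    """Instantiate an untrained GRU classifier from its configuration."""
    return GRUClassifier(cfg, seed=seed)
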