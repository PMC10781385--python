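"""Temporal Convolutional Network classifier.

Dilated causal convolutions (DCC) stacked in residual blocks: block k uses
dilation 2^(k-1), so with uniform kernel size S a K-level stack of single
DCCs sees D = (S - 1)(2^K - 1) + 1 past frames.  Each residual block holds
two weight-normalised DCC sublayers with the block's dilation, ReLU
activations and dropout, plus a residual connection (1x1 projection when the
channel count changes).  The classification head reads the last timestep
(causally consistent) or a temporal mean-pool, then a linear layer and
softmax over the six activity classes.

Default hyperparameters are the optimised architecture used throughout:
K = 4 blocks of 128 filters with kernel sizes (8, 5, 13, 8) and dropout
(0.5475, 0.1491, 0.005, 0.6214).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import DilatedCausalConv, Linear, Module, Tensor, dropout

__all__ = [
    "TCNConfig",
    "ReceptiveField",
    "dcc",
    "receptive_field",
    "build_tcn",
    "TCNClassifier",
    "train_classifier",
]

# re-exported shared supervised harness
train_classifier = nn.train_classifier

#: optimised per-block (filters N_k, kernel size S_k, dropout D_k)
DEFAULT_BLOCKS = (
    (128, 8, 0.5475),
    (128, 5, 0.1491),
    (128, 13, 0.005),
    (128, 8, 0.6214),
)


@dataclass(frozen=True)
class TCNConfig:
    """Architecture hyperparameters of the TCN classifier."""

    blocks: tuple = DEFAULT_BLOCKS  # per-block (N_k, S_k, D_k)
    n_frames: int = 30
    n_features: int = 54
    n_classes: int = 6
    readout: str = "last"  # "last" (causal) or "mean"

    def __post_init__(self):
        if not 3 <= len(self.blocks) <= 5:
            raise ValueError("number of residual blocks must be in [3, 5]")
        for n, s, p in self.blocks:
            if n <= 0 or s <= 0:
                raise ValueError("filters and kernel sizes must be positive")
            if not 0 <= p < 1:
                raise ValueError("dropout must be in [0, 1)")
        if self.readout not in ("last", "mean"):
            raise ValueError("readout must be 'last' or 'mean'")

    @property
    def K(self) -> int:
        return len(self.blocks)

    def dilation(self, k: int) -> int:
        """Dilation of block k (1-based): 2^(k-1)."""
        return 2 ** (k - 1)


@dataclass(frozen=True)
class ReceptiveField:
    """Number of past frames that can influence one output timestep."""

    D: int
    uniform_kernel: bool  # whether the closed form for uniform S applied


def dcc(x, g, d: int = 1) -> np.ndarray:
    """Dilated causal convolution of a 1-D sequence with kernel g.

    out[i] = sum_{j=0}^{S-1} g[j] * x[i - d*j], indices before the sequence
    start reading as zero.  For d = 1 this is the classical causal
    convolution.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g, dtype=float)
    if x.ndim != 1 or g.ndim != 1:
        raise ValueError("dcc operates on 1-D sequences")
    S = len(g)
    if S <= 0:
        raise ValueError("kernel size must be positive")
    if d <= 0:
        raise ValueError("dilation must be positive")
    T = len(x)
    out = np.zeros(T)
    P = (S - 1) * d
    xpad = np.concatenate([np.zeros(P), x])
    for j in range(S):
        lo = P - d * j
        out += g[j] * xpad[lo:lo + T]
    return out


def receptive_field(cfg: TCNConfig) -> ReceptiveField:
    """Receptive field of a K-level stack of one DCC per level.

    With a uniform kernel size S across levels this is the closed form
    (S - 1)(2^K - 1) + 1; with mixed kernel sizes the closed form does not
    apply and the telescoped per-level sum 1 + sum_k (S_k - 1) * 2^(k-1) is
    returned with ``uniform_kernel=False``.
    """
    sizes = [s for _, s, _ in cfg.blocks]
    K = cfg.K
    if len(set(sizes)) == 1:
        S = sizes[0]
        return ReceptiveField(D=(S - 1) * (2**K - 1) + 1, uniform_kernel=True)
    D = 1 + sum((s - 1) * 2**k for k, s in enumerate(sizes))
    return ReceptiveField(D=D, uniform_kernel=False)


class _ResidualBlock(Module):
    def __init__(self, c_in, n, s, p, dilation, rng):
        self.conv1 = DilatedCausalConv(s, c_in, n, dilation, rng)
        self.conv2 = DilatedCausalConv(s, n, n, dilation, rng)
        self.p = p
        self.proj = Linear(c_in, n, rng) if c_in != n else None

    def forward(self, x: Tensor, train: bool, rng) -> Tensor:
        h = dropout(self.conv1(x).relu(), self.p, rng, train)
        h = dropout(self.conv2(h).relu(), self.p, rng, train)
        res = self.proj(x) if self.proj is not None else x
        return (h + res).relu()


class TCNClassifier(Module):
    """Residual dilated-causal-convolution classifier over feature windows."""

    def __init__(self, cfg: TCNConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = cfg.n_features
        for k, (n, s, p) in enumerate(cfg.blocks, start=1):
            self.blocks.append(
                _ResidualBlock(c_in, n, s, p, cfg.dilation(k), rng)
            )
            c_in = n
        self.head = Linear(c_in, cfg.n_classes, rng)
        self.feature_dim = c_in
        self.trained = False
        self._drop_rng = np.random.default_rng(seed)

    def set_dropout_rng(self, rng):
        self._drop_rng = rng

    def forward_features(self, x: Tensor, train: bool = False) -> Tensor:
        """Per-timestep activations after the last residual block (B, T, C);
        the penultimate representation fed to the anomaly detector."""
        h = self.normalize_input(x)
        for blk in self.blocks:
            h = blk.forward(h, train, self._drop_rng)
        return h

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        h = self.forward_features(x, train)
        if self.cfg.readout == "last":
            pooled = h[:, -1, :]
        else:
            pooled = h.mean(axis=1)
        return self.head(pooled)


def build_tcn(cfg: TCNConfig = TCNConfig(), seed: int = 0) -> TCNClassifier:
    """Instantiate an untrained TCN classifier from its configuration."""
    return TCNClassifier(cfg, seed=seed)
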