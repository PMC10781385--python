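"""Minimal reverse-mode autodiff core and sequence-model layers.

Everything trainable in this package (temporal convolutional classifier, GRU
classifier, bidirectional LSTM autoencoder) runs on this engine: numpy
arrays wrapped in :class:`Tensor` nodes, a topologically sorted backward
pass, and an Adam optimizer.  The engine is deliberately small — only the
operations the models need — and fully deterministic: every stochastic
element (init, shuffling, dropout) draws from an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "Adam",
    "Linear",
    "DilatedCausalConv",
    "LSTMLayer",
    "BiLSTMLayer",
    "softmax_cross_entropy",
    "dropout",
    "stratified_split",
    "train_classifier",
    "predict_proba",
    "TrainResult",
]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_prev", "_bw", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._prev = ()
        self._bw = None
        self.requires_grad = requires_grad

    # -- graph construction helpers --------------------------------------
    @staticmethod
    def _node(data, prev, bw):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._bw = bw
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss")
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._node(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._node(-a.data, (a,),
                          lambda g: a._accum(-g) if a.requires_grad else None)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._node(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return self._node(a.data / b.data, (a, b), bw)

    def matmul(self, other):
        other = self._wrap(other)
        a, b = self, other
        if b.ndim != 2:
            raise ValueError("right operand of matmul must be 2-D")

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                if a.ndim == 2:
                    b._accum(a.data.T @ g)
                else:
                    axes = tuple(range(a.ndim - 1))
                    b._accum(np.tensordot(a.data, g, (axes, axes)))

        return self._node(a.data @ b.data, (a, b), bw)

    __matmul__ = matmul

    # -- reductions and shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.full_like(a.data, float(g)))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                gg = g
                if not keepdims:
                    for d in sorted(ax):
                        gg = np.expand_dims(gg, d)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[d] for d in
                     (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        old = a.shape
        return self._node(
            a.data.reshape(*shape), (a,),
            lambda g: a._accum(g.reshape(old)) if a.requires_grad else None,
        )

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return self._node(a.data[idx], (a,), bw)

    def flip_time(self):
        """Reverse axis 1 (the time axis of a (B, T, C) tensor)."""
        a = self
        return self._node(
            a.data[:, ::-1], (a,),
            lambda g: a._accum(g[:, ::-1]) if a.requires_grad else None,
        )

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        a = self
        mask = a.data > 0
        return self._node(
            a.data * mask, (a,),
            lambda g: a._accum(g * mask) if a.requires_grad else None,
        )

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return self._node(
            out, (a,),
            lambda g: a._accum(g * (1 - out**2)) if a.requires_grad else None,
        )

    def sigmoid(self):
        a = self
        out = np.empty_like(a.data)
        pos = a.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
        ez = np.exp(a.data[~pos])
        out[~pos] = ez / (1.0 + ez)
        return self._node(
            out, (a,),
            lambda g: a._accum(g * out * (1 - out))
            if a.requires_grad else None,
        )

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return self._node(
            out, (a,),
            lambda g: a._accum(g * 0.5 / out) if a.requires_grad else None,
        )


def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._node(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool):
    """Inverted dropout; identity when not training or p == 0."""
    if not train or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy over the batch, fused with softmax."""
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(np.maximum(probs[np.arange(n), labels], 1e-300)).mean()
    a = logits

    def bw(g):
        if a.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            a._accum(float(g) * grad / n)

    return Tensor._node(np.array(loss), (a,), bw)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def causal_conv1d(x: Tensor, W: Tensor, b: Tensor, d: int) -> Tensor:
    """Dilated causal convolution over (B, T, Cin) with kernel (S, Cin, Cout).

    output[:, i] = sum_j x[:, i - d*j] @ W[j], with indices before the start
    of the sequence reading as zero (left zero-padding); output[:, i] never
    depends on inputs after i.
    """
    if d <= 0:
        raise ValueError("dilation must be positive")
    S = W.shape[0]
    if S <= 0:
        raise ValueError("kernel size must be positive")
    B, T, Cin = x.data.shape
    P = (S - 1) * d
    xpad = np.concatenate(
        [np.zeros((B, P, Cin)), x.data], axis=1
    )
    out = np.zeros((B, T, W.shape[2]))
    for j in range(S):
        lo = P - d * j
        out += xpad[:, lo:lo + T, :] @ W.data[j]
    out += b.data

    def bw(g):
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))
        if W.requires_grad:
            gw = np.empty_like(W.data)
            for j in range(S):
                lo = P - d * j
                gw[j] = np.tensordot(
                    xpad[:, lo:lo + T, :], g, ((0, 1), (0, 1))
                )
            W._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(xpad)
            for j in range(S):
                lo = P - d * j
                gx[:, lo:lo + T, :] += g @ W.data[j].T
            x._accum(gx[:, P:, :])

    return Tensor._node(out, (x, W, b), bw)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Module:
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None

    def set_input_stats(self, mean, sd) -> None:
        """Per-feature input standardisation constants (fit on train data)."""
        self.input_mean = np.asarray(mean, dtype=np.float64)
        sd = np.asarray(sd, dtype=np.float64)
        self.input_sd = np.where(sd < 1e-8, 1.0, sd)

    def normalize_input(self, x: Tensor) -> Tensor:
        if self.input_mean is None:
            return x
        return (x - Tensor(self.input_mean)) * Tensor(1.0 / self.input_sd)

    def parameters(self) -> list:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


def _glorot(rng, *shape):
    fan_in, fan_out = shape[-2], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in, n_out, rng):
        self.W = _glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class DilatedCausalConv(Module):
    """Weight-normalised dilated causal convolution layer."""

    def __init__(self, S, c_in, c_out, dilation, rng):
        self.v = _glorot(rng, S, c_in, c_out)
        norm = np.sqrt((self.v.data**2).sum(axis=(0, 1)))
        self.g = Tensor(norm, requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.dilation = int(dilation)

    def weight(self) -> Tensor:
        norm = (self.v * self.v).sum(axis=(0, 1), keepdims=True).sqrt()
        return self.v * (self.g / norm)

    def __call__(self, x: Tensor) -> Tensor:
        return causal_conv1d(x, self.weight(), self.b, self.dilation)


class LSTMLayer(Module):
    """Single-direction LSTM over (B, T, C); returns all hidden states."""

    def __init__(self, n_in, hidden, rng):
        self.W = _glorot(rng, n_in + hidden, 4 * hidden)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.data.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        for t in range(T):
            xt = x[:, t, :]
            gates = concat([h, xt], axis=1) @ self.W + self.b
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(B, 1, H))
        return concat(outs, axis=1)


class BiLSTMLayer(Module):
    """Bidirectional LSTM: forward and time-reversed passes, concatenated."""

    def __init__(self, n_in, hidden, rng):
        self.fwd = LSTMLayer(n_in, hidden, rng)
        self.bwd = LSTMLayer(n_in, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        hf = self.fwd(x)
        hb = self.bwd(x.flip_time()).flip_time()
        return concat([hf, hb], axis=2)


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# shared supervised training harness (70/15/15 split, early stopping)
# ---------------------------------------------------------------------------


def stratified_split(strata, fractions=(0.70, 0.15, 0.15), seed=0):
    """Indices of train/val/test splits, stratified by the given keys."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    strata = np.asarray(strata)
    rng = np.random.default_rng(seed)
    splits = ([], [], [])
    for key in np.unique(strata):
        idx = np.flatnonzero(strata == key)
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        n_tr = min(n_tr, n)
        n_va = min(n_va, n - n_tr)
        splits[0].extend(idx[:n_tr])
        splits[1].extend(idx[n_tr:n_tr + n_va])
        splits[2].extend(idx[n_tr + n_va:])
    return tuple(np.sort(np.array(s, dtype=np.int64)) for s in splits)


@dataclass
class TrainResult:
    model: object
    metrics: dict
    history: list = field(default_factory=list)
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None


def predict_proba(model, X, batch_size=256) -> np.ndarray:
    probs = []
    with no_grad():
        for a in range(0, len(X), batch_size):
            logits = model.forward(Tensor(X[a:a + batch_size]), train=False)
            probs.append(softmax(logits.data))
    return np.concatenate(probs, axis=0)


def _accuracy(model, X, y) -> float:
    pred = predict_proba(model, X).argmax(axis=1)
    return float((pred == y).mean())


def train_classifier(
    model,
    windows: np.ndarray,
    labels: np.ndarray,
    split=(0.70, 0.15, 0.15),
    seed: int = 0,
    epochs: int = 60,
    batch_size: int = 64,
    lr: float = 1e-3,
    patience: int = 10,
    strata=None,
) -> TrainResult:
    """Train a windowed sequence classifier with early stopping.

    Deterministic given ``seed``: the split, shuffling and dropout all flow
    from it.  Raises if any class is absent from the training split.
    """
    X = np.asarray(windows, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if strata is None:
        strata = y
    tr, va, te = stratified_split(strata, split, seed=seed)
    classes = np.unique(y)
    missing = set(classes) - set(np.unique(y[tr]))
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from training split")
    rng = np.random.default_rng(seed + 1)
    model.set_dropout_rng(np.random.default_rng(seed + 2))
    model.set_input_stats(X[tr].mean(axis=(0, 1)), X[tr].std(axis=(0, 1)))
    opt = Adam(model.parameters(), lr=lr)
    best_val, best_state, bad_epochs = -1.0, model.state(), 0
    history = []
    for epoch in range(epochs):
        order = tr.copy()
        rng.shuffle(order)
        losses = []
        for a in range(0, len(order), batch_size):
            idx = order[a:a + batch_size]
            logits = model.forward(Tensor(X[idx]), train=True)
            loss = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = _accuracy(model, X[va], y[va]) if len(va) else 0.0
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "val_accuracy": val_acc}
        )
        if val_acc > best_val + 1e-12:
            best_val, best_state, bad_epochs = val_acc, model.state(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    model.load_state(best_state)
    model.trained = True
    y_pred = predict_proba(model, X[te]).argmax(axis=1) if len(te) else \
        np.array([], dtype=np.int64)
    test_acc = float((y_pred == y[te]).mean()) if len(te) else float("nan")
    metrics = {
        "val_accuracy": best_val,
        "test_accuracy": test_acc,
        "n_train": int(len(tr)),
        "n_val": int(len(va)),
        "n_test": int(len(te)),
        "epochs_run": len(history),
    }
    return TrainResult(
        model=model, metrics=metrics, history=history,
        y_true=y[te], y_pred=y_pred,
    )
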