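"""Semi-supervised abnormal-gait detection.

A bidirectional LSTM autoencoder (LSTMAE) is fitted to the per-timestep
activations that a pre-trained supervised classifier (TCN or GRU) produces
for *normal* walking windows.  At test time a window is scored by the
reconstruction error

    RE(z, z_hat) = 1/2 * sum_i (z_i - z_hat_i)^2

over the flattened (time-major) feature sequence; windows whose error
exceeds a threshold calibrated on held-out normal data are flagged abnormal.
No abnormal label is ever read during training — the training API rejects
abnormal-tagged windows outright.

Training modes: ``intra`` fits on the monitored subject's own normal
walking; ``inter`` on other subjects' normal walking only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    Adam,
    BiLSTMLayer,
    Linear,
    Module,
    Tensor,
    dropout,
    no_grad,
)
from .synthetic import WindowSet

__all__ = [
    "LSTMAEConfig",
    "TCN_FEATURE_CONFIG",
    "GRU_FEATURE_CONFIG",
    "AnomalyScore",
    "TrainingMode",
    "reconstruction_error",
    "extract_features",
    "LSTMAutoencoder",
    "GaitAnomalyDetector",
    "train_anomaly",
    "score",
    "score_windows",
    "load_pathological_gait_dataset",
]


@dataclass(frozen=True)
class LSTMAEConfig:
    """Three-layer bidirectional LSTM autoencoder hyperparameters.

    Each layer is (hidden units B_k per direction, output size F_k, dropout
    D_k); the middle layer is the bottleneck.  The two default sets are the
    optimised architectures for TCN-derived and GRU-derived features.
    """

    layers: tuple = (
        (256, 200, 0.0083),
        (128, 100, 0.2875),
        (256, 200, 0.0095),
    )
    feature_source: str = "tcn"

    def __post_init__(self):
        if len(self.layers) != 3:
            raise ValueError("the autoencoder has exactly three layers")
        for b, f, p in self.layers:
            if b <= 0 or f <= 0:
                raise ValueError("layer sizes must be positive")
            if not 0 <= p < 1:
                raise ValueError("dropout must be in [0, 1)")


TCN_FEATURE_CONFIG = LSTMAEConfig()
GRU_FEATURE_CONFIG = LSTMAEConfig(
    layers=((256, 200, 0.0106), (128, 100, 0.3127), (256, 200, 0.0112)),
    feature_source="gru",
)


@dataclass(frozen=True)
class TrainingMode:
    """Provenance constraint on the detector's training windows."""

    mode: str  # "intra" (monitored subject) or "inter" (other subjects)

    def __post_init__(self):
        if self.mode not in ("intra", "inter"):
            raise ValueError("mode must be 'intra' or 'inter'")


@dataclass
class AnomalyScore:
    """Reconstruction error of one window plus the threshold decision."""

    re: float
    threshold: float
    decision: str

    def __post_init__(self):
        if self.re < 0:
            raise ValueError("reconstruction error must be non-negative")
        want = "abnormal" if self.re > self.threshold else "normal"
        if self.decision != want:
            raise ValueError("decision inconsistent with re/threshold")


def reconstruction_error(z, z_hat) -> float:
    """Half the sum of squared differences between a feature sequence and
    its reconstruction (any common shape; flattened time-major)."""
    z = np.asarray(z, dtype=float).reshape(-1)
    z_hat = np.asarray(z_hat, dtype=float).reshape(-1)
    if z.shape != z_hat.shape:
        raise ValueError(
            f"length mismatch: {z.shape[0]} vs {z_hat.shape[0]}"
        )
    d = z - z_hat
    return float(0.5 * np.dot(d, d))


def extract_features(classifier, windows: np.ndarray) -> np.ndarray:
    """Per-timestep activations of the classifier's penultimate layer.

    ``windows`` is (N, T, M); the result is (N, T, F) with F the
    classifier's feature channel count.  The classifier must be trained and
    must not have seen the monitored subject (enforced by the calling
    protocol, not checkable from the weights).
    """
    if not getattr(classifier, "trained", False):
        raise ValueError("classifier must be trained before feature extraction")
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim == 2:
        windows = windows[None]
    feats = []
    with no_grad():
        for a in range(0, len(windows), 256):
            h = classifier.forward_features(
                Tensor(windows[a:a + 256]), train=False
            )
            feats.append(h.data)
    return np.concatenate(feats, axis=0)


class LSTMAutoencoder(Module):
    """Bidirectional LSTM encoder-decoder reconstructing feature sequences.

    The temporal axis is preserved end to end; the bottleneck is the second
    layer's output size.  A final linear map returns to the input feature
    dimension.
    """

    def __init__(self, cfg: LSTMAEConfig, n_features: int, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.layers = []
        self.projs = []
        n_in = n_features
        for b, f, _ in cfg.layers:
            self.layers.append(BiLSTMLayer(n_in, b, rng))
            self.projs.append(Linear(2 * b, f, rng))
            n_in = f
        self.out = Linear(n_in, n_features, rng)
        self.n_features = n_features
        self._drop_rng = np.random.default_rng(seed)

    def set_dropout_rng(self, rng):
        self._drop_rng = rng

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        h = x
        for (b, f, p), lstm, proj in zip(
            self.cfg.layers, self.layers, self.projs
        ):
            h = proj(lstm(h))
            h = dropout(h, p, self._drop_rng, train)
        return self.out(h)


@dataclass
class GaitAnomalyDetector:
    """Trained feature extractor + autoencoder + decision threshold."""

    classifier: object
    autoencoder: LSTMAutoencoder
    threshold: float
    mode: TrainingMode
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    monitored_subject: str | None = None

    def reconstruction_errors(self, windows: np.ndarray) -> np.ndarray:
        feats = extract_features(self.classifier, windows)
        z = (feats - self.feature_mean) / self.feature_sd
        with no_grad():
            out = []
            for a in range(0, len(z), 128):
                recon = self.autoencoder.forward(
                    Tensor(z[a:a + 128]), train=False
                )
                out.append(recon.data)
        recon = np.concatenate(out, axis=0)
        return 0.5 * ((z - recon) ** 2).sum(axis=(1, 2))


def _ae_loss(recon: Tensor, target: np.ndarray) -> Tensor:
    diff = recon - Tensor(target)
    return (diff * diff).sum() * (0.5 / len(target))


def train_anomaly(
    cfg: LSTMAEConfig,
    classifier,
    normal_windows: WindowSet,
    mode: TrainingMode | str = "intra",
    monitored_subject: str | None = None,
    seed: int = 0,
    epochs: int = 200,
    batch_size: int = 32,
    lr: float = 1e-3,
    patience: int = 20,
    val_frac: float = 0.15,
    threshold_quantile: float = 0.95,
) -> GaitAnomalyDetector:
    """Fit the semi-supervised detector on normal windows only.

    The windows' condition tags are checked: any abnormal-tagged window is a
    protocol violation and raises.  With ``mode='intra'`` every window must
    come from the monitored subject; with ``'inter'`` from other subjects
    only.  The decision threshold is the ``threshold_quantile`` of the
    held-out normal validation reconstruction errors.  Deterministic given
    ``seed``.
    """
    if isinstance(mode, str):
        mode = TrainingMode(mode)
    labels = normal_windows.labels
    if (labels["condition"] != "normal").any():
        bad = labels.loc[labels["condition"] != "normal", "seq_id"].iloc[0]
        raise ValueError(
            f"abnormal-labelled window in training input ({bad}); the "
            "detector is semi-supervised and trains on normal data only"
        )
    if monitored_subject is not None:
        subj = labels["subject_id"]
        if mode.mode == "intra" and (subj != monitored_subject).any():
            raise ValueError(
                "intra-class training requires windows from the monitored "
                "subject only"
            )
        if mode.mode == "inter" and (subj == monitored_subject).any():
            raise ValueError(
                "inter-class training must exclude the monitored subject"
            )

    feats = extract_features(classifier, normal_windows.windows)
    mean = feats.mean(axis=(0, 1), keepdims=True)
    sd = feats.std(axis=(0, 1), keepdims=True)
    sd = np.where(sd < 1e-8, 1.0, sd)
    z = (feats - mean) / sd

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(z))
    n_val = max(1, int(round(val_frac * len(z))))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        raise ValueError("not enough normal windows to train")

    ae = LSTMAutoencoder(cfg, n_features=z.shape[2], seed=seed)
    ae.set_dropout_rng(np.random.default_rng(seed + 1))
    opt = Adam(ae.parameters(), lr=lr)
    best_val, best_state, bad_epochs = np.inf, ae.state(), 0
    for epoch in range(epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        for a in range(0, len(order), batch_size):
            bidx = order[a:a + batch_size]
            recon = ae.forward(Tensor(z[bidx]), train=True)
            loss = _ae_loss(recon, z[bidx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        with no_grad():
            recon = ae.forward(Tensor(z[val_idx]), train=False)
        val_re = float(
            0.5 * ((z[val_idx] - recon.data) ** 2).sum(axis=(1, 2)).mean()
        )
        if val_re < best_val - 1e-12:
            best_val, best_state, bad_epochs = val_re, ae.state(), 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    ae.load_state(best_state)

    with no_grad():
        recon = ae.forward(Tensor(z[val_idx]), train=False)
    val_res = 0.5 * ((z[val_idx] - recon.data) ** 2).sum(axis=(1, 2))
    threshold = float(np.quantile(val_res, threshold_quantile))
    return GaitAnomalyDetector(
        classifier=classifier,
        autoencoder=ae,
        threshold=threshold,
        mode=mode,
        feature_mean=mean,
        feature_sd=sd,
        monitored_subject=monitored_subject,
    )


def score(detector: GaitAnomalyDetector, window: np.ndarray) -> AnomalyScore:
    """Score one feature window: extract, reconstruct, threshold."""
    window = np.asarray(window, dtype=np.float64)
    re = float(detector.reconstruction_errors(window[None])[0])
    return AnomalyScore(
        re=re,
        threshold=detector.threshold,
        decision="abnormal" if re > detector.threshold else "normal",
    )


def score_windows(
    detector: GaitAnomalyDetector, windows: np.ndarray
) -> list:
    res = detector.reconstruction_errors(np.asarray(windows, np.float64))
    return [
        AnomalyScore(
            re=float(r),
            threshold=detector.threshold,
            decision="abnormal" if r > detector.threshold else "normal",
        )
        for r in res
    ]


def load_pathological_gait_dataset(path):
    """Loader interface for the external multi-camera pathological-gait
    skeleton dataset (antalgic, stiff-legged, lurching, steppage,
    Trendelenburg and normal gaits from 25-joint depth-camera captures).

    The data are not bundled and the 25-joint topology differs from the
    27-joint model used here; this entry point only defines the interface
    and raises until a local copy and a joint mapping are supplied.
    """
    raise NotImplementedError(
        f"external dataset expected at {path!r}; provide a local copy and a "
        "25->27 joint mapping to use this loader"
    )
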