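"""Metrics, confusion matrices, and the camera-setup sweep harness.

ACC/SEN/SPE/PRE are computed from confusion-matrix counts; in the multiclass
case sensitivity, specificity and precision are computed one-vs-rest per
class and macro-averaged.  Ratios with zero denominators are reported as NaN
with an explicit flag, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_from_predictions",
    "compute_metrics",
    "sweep_setups",
    "split_frontal_lateral",
    "auroc",
]

auroc = roc_auc_score


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or \
                self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.labels:
            self.labels = tuple(range(self.counts.shape[0]))
        elif len(self.labels) != self.counts.shape[0]:
            raise ValueError("one label per class required")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_predictions(y_true, y_pred, labels=None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = tuple(np.unique(np.concatenate([y_true, y_pred])))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


@dataclass
class MetricsReport:
    """Per-class and macro ACC, SEN, SPE, PRE in [0, 1]; NaN where undefined."""

    per_class: pd.DataFrame
    macro: dict
    accuracy: float
    undefined: list = field(default_factory=list)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest metrics from a confusion matrix.

    For each class c: TP = counts[c, c], FN = rest of row c, FP = rest of
    column c, TN = everything else; SEN = TP/(TP+FN), SPE = TN/(TN+FP),
    PRE = TP/(TP+FP), ACC = (TP+TN)/total.  Macro values average over
    classes where the ratio is defined.
    """
    counts = cm.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp

    def ratio(num, den, name):
        out = np.full_like(num, np.nan, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for i in np.flatnonzero(~ok):
            undefined.append((str(cm.labels[i]), name))
        return out

    undefined: list = []
    sen = ratio(tp, tp + fn, "sen")
    spe = ratio(tn, tn + fp, "spe")
    pre = ratio(tp, tp + fp, "pre")
    acc = (tp + tn) / total
    per_class = pd.DataFrame(
        {"acc": acc, "sen": sen, "spe": spe, "pre": pre},
        index=list(cm.labels),
    )
    macro = {
        k: float(np.nanmean(per_class[k])) for k in ("acc", "sen", "spe", "pre")
    }
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        accuracy=float(tp.sum() / total),
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# experimental sweeps over camera setups
# ---------------------------------------------------------------------------


def _default_trainer(windows, labels, arch, seed):
    """Train the named architecture on a window set, return test accuracy."""
    from . import gru as gru_mod
    from . import tcn as tcn_mod
    from .nn import train_classifier

    classes = sorted(set(labels))
    y = np.array([classes.index(c) for c in labels])
    M = windows.shape[2]
    if arch == "tcn":
        model = tcn_mod.build_tcn(
            tcn_mod.TCNConfig(
                blocks=((32, 5, 0.1), (32, 5, 0.1), (32, 5, 0.1)),
                n_features=M, n_classes=len(classes),
            ),
            seed=seed,
        )
    elif arch == "gru":
        model = gru_mod.build_gru(
            gru_mod.GRUConfig(k_blocks=2, hidden=48, n_features=M,
                              n_classes=len(classes)),
            seed=seed,
        )
    else:
        raise ValueError(f"unknown architecture {arch!r}")
    result = train_classifier(
        model, windows, y, seed=seed, epochs=25, patience=6
    )
    return result.metrics["test_accuracy"]


def sweep_setups(
    window_set,
    archs=("tcn", "gru"),
    heights=(1.4, 1.6, 1.8, 2.0),
    directions=("NE", "N", "NW"),
    seed: int = 0,
    trainer=None,
) -> pd.DataFrame:
    """Per-cell train/test accuracy over the (arch, height, direction) grid.

    Every requested cell appears in the output; cells with no windows are
    flagged ``missing`` rather than silently skipped.  The argmax cell per
    architecture carries ``best=True``.
    """
    if trainer is None:
        trainer = _default_trainer
    labels = window_set.labels
    rows = []
    for arch in archs:
        for h in heights:
            for d in directions:
                mask = (
                    np.isclose(labels["camera_height"].to_numpy(), h)
                    & (labels["direction"] == d).to_numpy()
                )
                if not mask.any():
                    rows.append(
                        {"arch": arch, "height": h, "direction": d,
                         "accuracy": np.nan, "missing": True, "best": False}
                    )
                    continue
                sub = window_set.select(mask)
                acc = trainer(
                    sub.windows,
                    sub.labels["adl_label"].to_numpy(),
                    arch,
                    seed,
                )
                rows.append(
                    {"arch": arch, "height": h, "direction": d,
                     "accuracy": acc, "missing": False, "best": False}
                )
    table = pd.DataFrame(rows)
    for arch in archs:
        sub = table[(table["arch"] == arch) & ~table["missing"]]
        if len(sub):
            table.loc[sub["accuracy"].idxmax(), "best"] = True
    return table


def split_frontal_lateral(records, direction: str = "N"):
    """Partition a manifest's direction-``N`` records by camera.

    Returns (frontal, lateral) record lists tagged by view; every
    direction-matched record must carry a camera id.
    """
    matched = [r for r in records if r.get("direction") == direction]
    for r in matched:
        if r.get("camera_id") not in (1, 2):
            raise ValueError(
                f"record {r.get('seq_id', '?')} lacks a camera_id"
            )
    frontal = [r for r in matched if r["camera_id"] == 1]
    lateral = [r for r in matched if r["camera_id"] == 2]
    return frontal, lateral
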