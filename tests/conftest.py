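"""Shared fixtures: synthetic window sets and small trained models.

The heavier fixtures are session-scoped so the supervised classifiers are
trained once and reused by the learnability, feature-extraction and anomaly
suites.  Problem sizes are scaled-down study conditions (documented in the
package's methods note): ~700 windows for 6-class recognition, 3 subjects
with one camera cell for the anomaly protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitadl.gru import GRUConfig, build_gru
from gaitadl.nn import train_classifier
from gaitadl.synthetic import ProtocolConfig, window_dataset
from gaitadl.tcn import TCNConfig, build_tcn

SMALL_TCN_BLOCKS = ((32, 5, 0.1), (32, 5, 0.1), (32, 5, 0.1))
SMALL_GRU = dict(k_blocks=2, hidden=48)
SMALL_AE_LAYERS = ((16, 12, 0.0), (8, 6, 0.0), (16, 12, 0.0))


@pytest.fixture(scope="session")
def adl_window_set():
    """~720-window 6-class set from one subject, three directions."""
    cfg = ProtocolConfig(
        n_subjects=1,
        directions=("NE", "N", "NW"),
        heights=(1.6, 1.8),
        duration_s=25.0,
        fps=24.0,
        window=30,
        seed=5,
        include_abnormal=False,
    )
    return window_dataset(cfg)


@pytest.fixture(scope="session")
def adl_xy(adl_window_set):
    classes = sorted(adl_window_set.labels["adl_label"].unique())
    y = adl_window_set.labels["adl_label"].map(classes.index).to_numpy()
    return adl_window_set.windows, y, classes


@pytest.fixture(scope="session")
def trained_tcn(adl_xy):
    X, y, _ = adl_xy
    model = build_tcn(TCNConfig(blocks=SMALL_TCN_BLOCKS), seed=0)
    result = train_classifier(model, X, y, seed=0, epochs=40, patience=10)
    return result


@pytest.fixture(scope="session")
def trained_gru(adl_xy):
    X, y, _ = adl_xy
    model = build_gru(GRUConfig(**SMALL_GRU), seed=0)
    result = train_classifier(model, X, y, seed=0, epochs=40, patience=10)
    return result


@pytest.fixture(scope="session")
def anomaly_protocol():
    """Three-subject walking protocol with abnormal variants, one cell.

    Returns a dict with the window subsets the semi-supervised protocol
    needs: classifier pretraining windows (subjects other than S1), S1
    normal-walk train/test halves, size-matched other-subject normal walks,
    and S1 abnormal walks.
    """
    cfg = ProtocolConfig(
        n_subjects=3,
        directions=("N",),
        heights=(1.6, 1.8),
        duration_s=50.0,
        fps=24.0,
        window=30,
        seed=11,
        include_abnormal=True,
    )
    ws = window_dataset(cfg)
    lab = ws.labels
    normal = (lab["condition"] == "normal").to_numpy()
    s1 = (lab["subject_id"] == "S1").to_numpy()
    wlk = (lab["adl_label"] == "WLK").to_numpy()
    pretrain = ws.select(~s1 & normal)
    s1_norm = ws.select(wlk & s1 & normal)
    half = len(s1_norm) // 2
    s1_train = s1_norm.select(np.arange(len(s1_norm)) < half)
    s1_test = s1_norm.select(np.arange(len(s1_norm)) >= half)
    others_norm = ws.select(wlk & ~s1 & normal)
    pick = np.random.default_rng(7).choice(
        len(others_norm), size=len(s1_train), replace=False
    )
    others_matched = others_norm.select(
        np.isin(np.arange(len(others_norm)), pick)
    )
    s1_abn = ws.select(wlk & s1 & ~normal)
    return {
        "pretrain": pretrain,
        "s1_train": s1_train,
        "s1_test": s1_test,
        "others_matched": others_matched,
        "s1_abnormal": s1_abn,
        "window_set": ws,
    }


@pytest.fixture(scope="session")
def pretrained_tcn_for_anomaly(anomaly_protocol):
    """TCN trained on subjects S2/S3 only (monitored S1 excluded)."""
    pre = anomaly_protocol["pretrain"]
    classes = sorted(pre.labels["adl_label"].unique())
    y = pre.labels["adl_label"].map(classes.index).to_numpy()
    model = build_tcn(TCNConfig(blocks=SMALL_TCN_BLOCKS), seed=0)
    train_classifier(model, pre.windows, y, seed=0, epochs=30, patience=8)
    return model


@pytest.fixture(scope="session")
def pretrained_gru_for_anomaly(anomaly_protocol):
    pre = anomaly_protocol["pretrain"]
    classes = sorted(pre.labels["adl_label"].unique())
    y = pre.labels["adl_label"].map(classes.index).to_numpy()
    model = build_gru(GRUConfig(**SMALL_GRU), seed=0)
    train_classifier(model, pre.windows, y, seed=0, epochs=30, patience=8)
    return model
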