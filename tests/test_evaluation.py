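"""Metrics arithmetic, sweep harness, and frontal/lateral splitting."""

import numpy as np
import pytest

from gaitadl.evaluation import (
    ConfusionMatrix,
    compute_metrics,
    confusion_from_predictions,
    split_frontal_lateral,
    sweep_setups,
)
from gaitadl.synthetic import ProtocolConfig, window_dataset


class TestComputeMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionMatrix(np.diag([10, 10])))
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.macro.values())

    def test_hand_worked_binary_example(self):
        rep = compute_metrics(ConfusionMatrix(np.array([[9, 1], [2, 8]])))
        row = rep.per_class.loc[0]
        assert row["sen"] == pytest.approx(0.9)
        assert row["spe"] == pytest.approx(0.8)
        assert row["pre"] == pytest.approx(9 / 11)
        assert rep.accuracy == pytest.approx(0.85)

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(4, 4))
        rep = compute_metrics(ConfusionMatrix(counts))
        perm = rng.permutation(4)
        permuted = counts[np.ix_(perm, perm)]
        rep2 = compute_metrics(ConfusionMatrix(permuted))
        for key in ("acc", "sen", "spe", "pre"):
            assert rep.macro[key] == pytest.approx(rep2.macro[key])

    def test_zero_denominator_is_nan_with_flag(self):
        # class 1 never occurs and is never predicted -> SEN and PRE undefined
        rep = compute_metrics(ConfusionMatrix(np.array([[5, 0], [0, 0]])))
        assert np.isnan(rep.per_class.loc[1, "sen"])
        assert np.isnan(rep.per_class.loc[1, "pre"])
        assert ("1", "sen") in rep.undefined
        assert ("1", "pre") in rep.undefined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1], [0, 2]]))

    def test_against_independent_recomputation(self):
        """Definition-level loop recomputation on 1000 random matrices."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            C = int(rng.integers(2, 6))
            counts = rng.integers(0, 15, size=(C, C))
            if counts.sum() == 0:
                continue
            rep = compute_metrics(ConfusionMatrix(counts))
            total = counts.sum()
            for c in range(C):
                tp = counts[c, c]
                fn = counts[c].sum() - tp
                fp = counts[:, c].sum() - tp
                tn = total - tp - fn - fp
                row = rep.per_class.loc[c]
                if tp + fn:
                    assert row["sen"] == pytest.approx(tp / (tp + fn))
                if tn + fp:
                    assert row["spe"] == pytest.approx(tn / (tn + fp))
                if tp + fp:
                    assert row["pre"] == pytest.approx(tp / (tp + fp))
                assert row["acc"] == pytest.approx((tp + tn) / total)

    def test_row_sums_conserved(self):
        y_true = np.array([0, 0, 1, 2, 2, 2])
        y_pred = np.array([0, 1, 1, 2, 0, 2])
        cm = confusion_from_predictions(y_true, y_pred)
        np.testing.assert_array_equal(
            cm.counts.sum(axis=1), [2, 1, 3]
        )
        assert cm.total == 6


class TestSweep:
    def test_full_grid_enumeration(self, adl_window_set):
        table = sweep_setups(
            adl_window_set,
            archs=("tcn",),
            heights=(1.4, 1.6, 1.8, 2.0),
            directions=("NE", "N", "NW"),
            trainer=lambda w, y, a, s: 0.9,
        )
        assert len(table) == 12
        # the fixture only covers heights 1.6/1.8 -> 6 populated cells
        assert int((~table["missing"]).sum()) == 6
        assert int(table["missing"].sum()) == 6

    def test_restricted_manifest_flags_missing(self, adl_window_set):
        mask = np.isclose(
            adl_window_set.labels["camera_height"].to_numpy(), 1.6
        )
        sub = adl_window_set.select(mask)
        table = sweep_setups(
            sub, archs=("gru",),
            heights=(1.4, 1.6, 1.8, 2.0), directions=("NE", "N", "NW"),
            trainer=lambda w, y, a, s: 0.9,
        )
        assert int((~table["missing"]).sum()) == 3
        assert int(table["missing"].sum()) == 9

    def test_planted_optimum_recovered(self):
        """Noise in all but one cell: the argmax lands on the clean cell."""
        from gaitadl.nn import train_classifier
        from gaitadl.tcn import TCNConfig, build_tcn

        cfg = ProtocolConfig(
            n_subjects=1, adls=("WLK", "SLP", "EAT"),
            directions=("N",), heights=(1.6, 1.8),
            duration_s=12.5, fps=24.0, window=30, seed=21,
            include_abnormal=False,
        )
        ws = window_dataset(cfg)
        noisy = ws.windows.copy()
        rng = np.random.default_rng(0)
        spoil = ~np.isclose(ws.labels["camera_height"].to_numpy(), 1.6)
        noisy[spoil] += rng.normal(scale=3.0, size=noisy[spoil].shape)
        ws_noisy = type(ws)(windows=noisy, labels=ws.labels)

        def trainer(windows, labels, arch, seed):
            classes = sorted(set(labels))
            y = np.array([classes.index(c) for c in labels])
            model = build_tcn(
                TCNConfig(blocks=((12, 3, 0.0),) * 3,
                          n_classes=len(classes)),
                seed=seed,
            )
            res = train_classifier(model, windows, y, seed=seed, epochs=8,
                                   patience=8)
            return res.metrics["test_accuracy"]

        hits = 0
        for s in range(10):
            table = sweep_setups(
                ws_noisy, archs=("tcn",), heights=(1.6, 1.8),
                directions=("N",), seed=s, trainer=trainer,
            )
            best = table[table["best"]].iloc[0]
            hits += bool(np.isclose(best["height"], 1.6))
        assert hits >= 8

    def test_best_cell_marked(self, adl_window_set):
        table = sweep_setups(
            adl_window_set, archs=("tcn",), heights=(1.6, 1.8),
            directions=("NE", "N", "NW"),
            trainer=lambda w, y, a, s: float(w.mean()),
        )
        assert int(table["best"].sum()) == 1


def _records():
    recs = []
    for i in range(10):
        recs.append(
            {"seq_id": f"n{i}", "direction": "N", "camera_id": 1 + i % 2}
        )
    recs.append({"seq_id": "x", "direction": "NE", "camera_id": 1})
    return recs


class TestFrontalLateralSplit:
    def test_counts_conserved(self):
        frontal, lateral = split_frontal_lateral(_records())
        assert len(frontal) == 5 and len(lateral) == 5

    def test_non_matching_direction_excluded(self):
        frontal, lateral = split_frontal_lateral(_records())
        ids = {r["seq_id"] for r in frontal + lateral}
        assert "x" not in ids

    def test_union_equals_direction_subset(self):
        recs = _records()
        frontal, lateral = split_frontal_lateral(recs)
        union = {r["seq_id"] for r in frontal + lateral}
        expected = {r["seq_id"] for r in recs if r["direction"] == "N"}
        assert union == expected

    def test_missing_camera_id_rejected(self):
        recs = [{"seq_id": "a", "direction": "N"}]
        with pytest.raises(ValueError, match="camera_id"):
            split_frontal_lateral(recs)
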