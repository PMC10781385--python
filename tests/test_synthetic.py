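"""Synthetic protocol generator: kinematics, cameras, dataset arithmetic."""

import numpy as np
import pytest

from gaitadl.skeleton import REDUCED_GRAPH, read_sequence
from gaitadl.synthetic import (
    AbnormalityProfile,
    CameraSetup,
    NORMAL_PROFILE,
    ProtocolConfig,
    ankle_excursion_ratio,
    build_dataset,
    dataset_counts,
    generate_adl_sequence,
    project_to_camera,
    window_dataset,
)

G = REDUCED_GRAPH


class TestGenerator:
    def test_sixty_seconds_at_24fps_is_1440_frames(self):
        seq = generate_adl_sequence("WLK", duration_s=60, fps=24, seed=0)
        assert len(seq) == 1440

    def test_determinism(self):
        a = generate_adl_sequence("WLK", duration_s=5, seed=7)
        b = generate_adl_sequence("WLK", duration_s=5, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown ADL"):
            generate_adl_sequence("JOG", seed=0)

    def test_asymmetry_gain_sets_excursion_ratio(self):
        seq = generate_adl_sequence(
            "WLK",
            profile=AbnormalityProfile(asymmetry_gain=0.5),
            duration_s=60,
            seed=2,
        )
        assert ankle_excursion_ratio(seq) == pytest.approx(0.5, abs=0.05)

    def test_normal_profile_is_identity(self):
        assert not NORMAL_PROFILE.is_abnormal
        assert AbnormalityProfile(tremor_amp=0.01).is_abnormal

    def test_gait_cycle_periodicity(self):
        """Ankle height autocorrelation peaks at the configured cadence."""
        seq = generate_adl_sequence("WLK", duration_s=30, seed=3,
                                    noise_sd=0.0)
        hips = 0.5 * (
            seq.positions[:, G.index("left_hip"), 1]
            + seq.positions[:, G.index("right_hip"), 1]
        )
        sig = seq.positions[:, G.index("right_ankle"), 1] - hips
        sig = sig - sig.mean()
        ac = np.correlate(sig, sig, mode="full")[len(sig) - 1:]
        # default cadence 0.8 Hz at 24 fps -> period of 30 frames
        lag = 15 + int(np.argmax(ac[15:45]))
        assert abs(lag - 30) <= 1

    def test_abnormality_separability_auroc(self):
        """Per-window left-right excursion separates strong abnormality."""
        from sklearn.metrics import roc_auc_score

        profile = AbnormalityProfile(asymmetry_gain=0.5, tremor_amp=0.02)
        stats, labels = [], []
        for cond, prof in (("normal", NORMAL_PROFILE), ("abn", profile)):
            for s in range(4):
                seq = generate_adl_sequence(
                    "WLK", profile=prof, duration_s=31.25, seed=s
                )
                T = len(seq)
                for a in range(0, T - 30 + 1, 30):
                    sub = seq.positions[a:a + 30]
                    hips = 0.5 * (
                        sub[:, G.index("left_hip"), 1]
                        + sub[:, G.index("right_hip"), 1]
                    )
                    left = sub[:, G.index("left_ankle"), 1] - hips
                    right = sub[:, G.index("right_ankle"), 1] - hips
                    ratio = np.ptp(left) / np.ptp(right)
                    stats.append(abs(np.log(ratio)))
                    labels.append(cond == "abn")
        assert len(stats) == 200
        assert roc_auc_score(labels, stats) > 0.95

    def test_slowdown_stretches_period(self):
        slow = generate_adl_sequence(
            "WLK", profile=AbnormalityProfile(slowdown_factor=2.0),
            duration_s=30, seed=4, noise_sd=0.0,
        )
        hips = 0.5 * (
            slow.positions[:, G.index("left_hip"), 1]
            + slow.positions[:, G.index("right_hip"), 1]
        )
        sig = slow.positions[:, G.index("right_ankle"), 1] - hips
        sig = sig - sig.mean()
        ac = np.correlate(sig, sig, mode="full")[len(sig) - 1:]
        lag = 40 + int(np.argmax(ac[40:90]))
        assert abs(lag - 60) <= 2


class TestCameraProjection:
    def test_identity_setup_unchanged(self):
        seq = generate_adl_sequence("WLK", duration_s=2, seed=0)
        setup = CameraSetup(height_m=0.0, alpha_deg=0.0, baseline_m=0.0,
                            camera_id=1)
        out = project_to_camera(seq, setup, "N")
        np.testing.assert_allclose(out.positions, seq.positions, atol=1e-12)

    def test_height_shifts_vertical_coordinate_exactly(self):
        seq = generate_adl_sequence("WLK", duration_s=2, seed=0)
        lo = project_to_camera(seq, CameraSetup(height_m=1.4), "N")
        hi = project_to_camera(seq, CameraSetup(height_m=1.6), "N")
        np.testing.assert_allclose(
            hi.positions[..., 1] - lo.positions[..., 1], -0.2, atol=1e-12
        )
        np.testing.assert_allclose(
            hi.positions[..., [0, 2]], lo.positions[..., [0, 2]], atol=1e-12
        )

    def test_direction_n_views(self):
        seq = generate_adl_sequence("WLK", duration_s=2, seed=0)
        cam1 = project_to_camera(seq, CameraSetup(camera_id=1), "N")
        cam2 = project_to_camera(seq, CameraSetup(camera_id=2), "N")
        assert cam1.meta.view == "frontal"
        assert cam2.meta.view == "lateral"

    def test_oblique_direction_views(self):
        seq = generate_adl_sequence("WLK", duration_s=2, seed=0,
                                    direction="NE")
        assert project_to_camera(
            seq, CameraSetup(camera_id=1), "NE"
        ).meta.view == "frontal"
        assert project_to_camera(
            seq, CameraSetup(camera_id=2), "NE"
        ).meta.view == "lateral"


MICRO = ProtocolConfig(
    n_subjects=1,
    adls=("WLK", "SLP"),
    directions=("N",),
    heights=(1.6,),
    duration_s=10.0,
    fps=24.0,
    window=30,
    seed=9,
)


class TestDatasetBuilder:
    def test_micro_build_writes_and_reads_back(self, tmp_path):
        records = build_dataset(MICRO, tmp_path)
        # 2 normal + 1 abnormal variant (WLK only)
        assert len(records) == 3
        conditions = sorted(r["condition"] for r in records)
        assert conditions == ["abnormal", "normal", "normal"]
        assert (tmp_path / "manifest.jsonl").exists()
        seq = read_sequence(tmp_path / records[0]["path"])
        assert len(seq) == records[0]["n_frames"] == 240

    def test_counts_match_config_arithmetic(self, tmp_path):
        records = build_dataset(MICRO, tmp_path)
        counts = dataset_counts(records)
        assert counts["sequences_per_subject"]["S1"] == \
            MICRO.sequences_per_subject == 2
        assert counts["frames_per_subject"]["S1"] == \
            MICRO.frames_per_subject == 480
        assert counts["frames_total"] == 480

    def test_window_counts(self):
        ws = window_dataset(MICRO, window=30)
        # 3 sequences x 240 frames / 30 = 24 windows, labels carried over
        assert len(ws) == 24
        assert ws.windows.shape[1:] == (30, 54)
        assert set(ws.labels["adl_label"]) == {"WLK", "SLP"}
        per_seq = ws.labels.groupby("seq_id").size()
        assert (per_seq == 8).all()

    def test_one_1440_frame_sequence_gives_48_windows(self):
        seq = generate_adl_sequence("WLK", duration_s=60, seed=0)
        rec = {"seq_id": "x", **seq.meta.to_dict()}
        ws = window_dataset([(rec, seq)], window=30)
        assert len(ws) == 48

    def test_oversized_window_rejected(self):
        seq = generate_adl_sequence("WLK", duration_s=1.25, seed=0)
        rec = {"seq_id": "x", **seq.meta.to_dict()}
        with pytest.raises(ValueError, match="window"):
            window_dataset([(rec, seq)], window=31)

    def test_window_must_divide_sequence(self):
        with pytest.raises(ValueError, match="divide"):
            ProtocolConfig(duration_s=10.0, fps=24.0, window=7)
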