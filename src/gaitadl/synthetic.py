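"""Kinematic generator emulating the laboratory ADL protocol.

Produces 27-joint skeleton sequences for six activities of daily living
(EAT, DRN, DRS, HSK, SLP, WLK) performed in three directions (NE, N, NW)
under four camera heights, 60 s at 24 fps, captured by a two-camera rig with
5 m baseline and 45 degree orientation.  Walking-type activities run on a
phase-coupled sinusoidal gait oscillator (hips/knees/ankles with left-right
antiphase and arm counter-swing); abnormal gait is injected by modulating
that oscillator with left-right asymmetry, tremor, rigidity (reduced range
of motion), postural sway, slow-down, stop-and-go holds, and a limp phase
offset.

World frame: +y up, +z north, +x east, meters.  All randomness flows from a
single seeded generator per sequence, so sequences are reproducible
bit-for-bit from (parameters, seed).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .representations import euclidean_array, spherical_array
from .skeleton import (
    ADL_LABELS,
    DIRECTIONS,
    REDUCED_GRAPH,
    SequenceMeta,
    SkeletonSequence,
    write_manifest,
    write_sequence,
    read_sequence,
)

__all__ = [
    "AbnormalityProfile",
    "NORMAL_PROFILE",
    "DEFAULT_ABNORMAL_PROFILE",
    "CameraSetup",
    "ProtocolConfig",
    "SubjectStyle",
    "generate_adl_sequence",
    "project_to_camera",
    "build_dataset",
    "iter_protocol_sequences",
    "window_dataset",
    "WindowSet",
    "dataset_counts",
    "ankle_excursion_ratio",
    "child_seed",
]

_G = REDUCED_GRAPH
_J = {name: _G.index(name) for name in _G.joint_names}

#: azimuth of each walking direction, radians from +z (north) toward +x (east)
DIRECTION_AZIMUTH = {"N": 0.0, "NE": math.pi / 4, "NW": -math.pi / 4}

# Standing reference pose (subject facing +z), tuned to a ~1.7 m adult.
_TEMPLATE = {
    "left_hip": (0.12, 0.95, 0.00), "right_hip": (-0.12, 0.95, 0.00),
    "left_knee": (0.12, 0.52, 0.02), "right_knee": (-0.12, 0.52, 0.02),
    "left_ankle": (0.12, 0.09, 0.00), "right_ankle": (-0.12, 0.09, 0.00),
    "left_heel": (0.12, 0.03, -0.05), "right_heel": (-0.12, 0.03, -0.05),
    "left_foot_index": (0.12, 0.02, 0.12),
    "right_foot_index": (-0.12, 0.02, 0.12),
    "left_shoulder": (0.18, 1.45, 0.00), "right_shoulder": (-0.18, 1.45, 0.00),
    "left_elbow": (0.22, 1.17, 0.01), "right_elbow": (-0.22, 1.17, 0.01),
    "left_wrist": (0.24, 0.92, 0.02), "right_wrist": (-0.24, 0.92, 0.02),
    "left_pinky": (0.25, 0.84, 0.02), "right_pinky": (-0.25, 0.84, 0.02),
    "left_index": (0.24, 0.83, 0.05), "right_index": (-0.24, 0.83, 0.05),
    "left_thumb": (0.21, 0.85, 0.06), "right_thumb": (-0.21, 0.85, 0.06),
    "nose": (0.00, 1.62, 0.09),
    "left_eye": (0.03, 1.66, 0.07), "right_eye": (-0.03, 1.66, 0.07),
    "left_ear": (0.07, 1.64, 0.00), "right_ear": (-0.07, 1.64, 0.00),
}
_BASE = np.array([_TEMPLATE[n] for n in _G.joint_names])

_LEFT_LEG = [_J[n] for n in
             ("left_knee", "left_ankle", "left_heel", "left_foot_index")]
_RIGHT_LEG = [_J[n] for n in
              ("right_knee", "right_ankle", "right_heel", "right_foot_index")]
_LEFT_FOOT = [_J[n] for n in ("left_ankle", "left_heel", "left_foot_index")]
_RIGHT_FOOT = [_J[n] for n in ("right_ankle", "right_heel", "right_foot_index")]
_LEFT_ARM = [_J[n] for n in
             ("left_elbow", "left_wrist", "left_pinky", "left_index",
              "left_thumb")]
_RIGHT_ARM = [_J[n] for n in
              ("right_elbow", "right_wrist", "right_pinky", "right_index",
               "right_thumb")]
_LEFT_HAND = [_J[n] for n in ("left_wrist", "left_pinky", "left_index",
                              "left_thumb")]
_RIGHT_HAND = [_J[n] for n in ("right_wrist", "right_pinky", "right_index",
                               "right_thumb")]
_HEAD = [_J[n] for n in ("nose", "left_eye", "right_eye", "left_ear",
                         "right_ear")]
_TORSO = [_J[n] for n in ("left_hip", "right_hip", "left_shoulder",
                          "right_shoulder")]
_UPPER = sorted(set(_HEAD + _LEFT_ARM + _RIGHT_ARM
                    + [_J["left_shoulder"], _J["right_shoulder"]]))
_LEGS = sorted(set(_LEFT_LEG + _RIGHT_LEG))


@dataclass(frozen=True)
class AbnormalityProfile:
    """Gait-abnormality injection parameters.

    The normal profile is the identity: asymmetry 1, no tremor, full range of
    motion, no sway, unit speed, no holds, no limp.
    """

    asymmetry_gain: float = 1.0     # scales the left side's stride amplitude
    tremor_amp: float = 0.0         # meters, distal-joint jitter amplitude
    tremor_freq: float = 5.0        # Hz
    rigidity_rom_scale: float = 1.0  # (0, 1]; shrinks joint excursions
    sway_amp: float = 0.0           # meters, low-frequency torso oscillation
    slowdown_factor: float = 1.0    # >= 1; stretches the gait period
    stop_go_rate: float = 0.0       # zero-velocity holds per minute
    limp_phase_offset: float = 0.0  # radians added to the left leg's phase

    def __post_init__(self):
        if not 0 < self.rigidity_rom_scale <= 1:
            raise ValueError("rigidity_rom_scale must be in (0, 1]")
        if self.slowdown_factor < 1:
            raise ValueError("slowdown_factor must be >= 1")
        if self.tremor_amp < 0 or self.sway_amp < 0 or self.stop_go_rate < 0:
            raise ValueError("amplitudes and rates must be non-negative")

    @property
    def is_abnormal(self) -> bool:
        return not (
            self.asymmetry_gain == 1.0
            and self.tremor_amp == 0.0
            and self.rigidity_rom_scale == 1.0
            and self.sway_amp == 0.0
            and self.slowdown_factor == 1.0
            and self.stop_go_rate == 0.0
            and self.limp_phase_offset == 0.0
        )


NORMAL_PROFILE = AbnormalityProfile()

#: Default injected pathology: pronounced asymmetry, 2 cm 5 Hz tremor,
#: reduced range of motion, postural sway, slowed cadence with holds.
DEFAULT_ABNORMAL_PROFILE = AbnormalityProfile(
    asymmetry_gain=0.6,
    tremor_amp=0.02,
    tremor_freq=5.0,
    rigidity_rom_scale=0.7,
    sway_amp=0.04,
    slowdown_factor=1.3,
    stop_go_rate=4.0,
    limp_phase_offset=0.6,
)


@dataclass(frozen=True)
class SubjectStyle:
    """Per-subject anthropometric and gait-style variation.

    Styles differ not only in body scale (which the angle-based features
    largely normalise away) but in joint-angle space: stride amplitude,
    arm carriage and swing, habitual trunk pitch and cadence.
    """

    scale: float = 1.0        # global body scale
    cadence: float = 0.8      # stride cycles per second
    arm_swing: float = 1.0    # arm counter-swing amplitude factor
    bob: float = 1.0          # pelvis vertical bob factor
    stride: float = 1.0       # stride length / foot lift factor
    trunk_pitch: float = 0.0  # habitual forward lean, radians
    arm_carriage: float = 0.0  # lateral elbow/wrist offset, meters


def _default_style(subject_index: int) -> SubjectStyle:
    styles = (
        SubjectStyle(scale=0.93, cadence=0.68, arm_swing=0.50, bob=0.70,
                     stride=0.70, trunk_pitch=0.14, arm_carriage=0.06),
        SubjectStyle(),
        SubjectStyle(scale=1.08, cadence=0.95, arm_swing=1.60, bob=1.30,
                     stride=1.35, trunk_pitch=-0.10, arm_carriage=-0.05),
    )
    return styles[subject_index % 3]


@dataclass(frozen=True)
class CameraSetup:
    """One camera of the two-camera rig.

    Cameras sit ``baseline_m`` apart, each yawed ``alpha_deg`` toward the
    scene centre so their optical axes intersect at the origin.  Camera 1 is
    the west camera (yaw +alpha, pointing north-east), camera 2 the east one.
    """

    height_m: float = 1.6
    alpha_deg: float = 45.0
    baseline_m: float = 5.0
    camera_id: int = 1

    def __post_init__(self):
        if self.camera_id not in (1, 2):
            raise ValueError("camera_id must be 1 or 2")
        if self.height_m < 0 or self.baseline_m < 0:
            raise ValueError("height and baseline must be non-negative")

    @property
    def yaw_rad(self) -> float:
        sign = 1.0 if self.camera_id == 1 else -1.0
        return sign * math.radians(self.alpha_deg)

    @property
    def position(self) -> np.ndarray:
        sign = -1.0 if self.camera_id == 1 else 1.0
        half = self.baseline_m / 2.0
        alpha = math.radians(self.alpha_deg)
        standoff = half / math.tan(alpha) if alpha > 1e-9 and half > 0 else 0.0
        return np.array([sign * half, self.height_m, -standoff])

    def view_of(self, direction: str) -> str:
        """Frontal when the walking azimuth is within 45 deg of the optical
        axis; the exact 45 deg tie (direction N) resolves to camera 1
        frontal, camera 2 lateral."""
        az = DIRECTION_AZIMUTH[direction]
        rel = abs(az - self.yaw_rad)
        quarter = math.pi / 4
        if rel < quarter - 1e-9:
            return "frontal"
        if abs(rel - quarter) < 1e-9:
            return "frontal" if self.camera_id == 1 else "lateral"
        return "lateral"


def _rot_y(theta):
    c, s = np.cos(theta), np.sin(theta)
    zeros = np.zeros_like(c)
    ones = np.ones_like(c)
    return np.stack(
        [
            np.stack([c, zeros, s], axis=-1),
            np.stack([zeros, ones, zeros], axis=-1),
            np.stack([-s, zeros, c], axis=-1),
        ],
        axis=-2,
    )


def child_seed(seed: int, *keys) -> int:
    """Stable sub-seed derivation (< 2**31) from a parent seed and keys."""
    payload = repr((int(seed),) + tuple(keys)).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (
        2**31
    )


# ---------------------------------------------------------------------------
# motion models
# ---------------------------------------------------------------------------


def _stop_go_gate(T, fps, rate_per_min, duration_s, rng):
    gate = np.ones(T)
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    for _ in range(n_events):
        start = rng.uniform(0, duration_s)
        hold = rng.uniform(0.6, 1.2)
        a, b = int(start * fps), int(min((start + hold) * fps, T))
        gate[a:b] = 0.0
    return gate


def _gait(pos, t, fps, profile, style, rng, amp_factor=1.0,
          arm_swing_factor=1.0):
    """Phase-coupled sinusoidal gait oscillator; returns the gated time base
    so superposed movements (broom swing, translation) can pause with it."""
    T = len(t)
    gate = _stop_go_gate(T, fps, profile.stop_go_rate, t[-1] + 1.0 / fps, rng)
    freq = style.cadence / profile.slowdown_factor
    t_gated = np.cumsum(gate) / fps
    phase = 2 * np.pi * freq * t_gated + rng.uniform(0, 2 * np.pi)
    rom = profile.rigidity_rom_scale * amp_factor
    s = style.scale

    ph_r = phase
    ph_l = phase + np.pi + profile.limp_phase_offset
    lift = 0.065 * rom * s * style.stride
    stride = 0.22 * rom * s * style.stride
    for idxs, ph, gain in (
        (_RIGHT_FOOT, ph_r, 1.0),
        (_LEFT_FOOT, ph_l, profile.asymmetry_gain),
    ):
        dy = gain * lift * 0.5 * (1 - np.cos(ph))
        dz = gain * stride * np.sin(ph)
        pos[:, idxs, 1] += dy[:, None]
        pos[:, idxs, 2] += dz[:, None]
    pos[:, _J["right_knee"], 1] += 0.3 * lift * 0.5 * (1 - np.cos(ph_r + 0.5))
    pos[:, _J["left_knee"], 1] += (
        profile.asymmetry_gain * 0.3 * lift * 0.5 * (1 - np.cos(ph_l + 0.5))
    )
    pos[:, _J["right_knee"], 2] += 0.6 * stride * np.sin(ph_r)
    pos[:, _J["left_knee"], 2] += (
        profile.asymmetry_gain * 0.6 * stride * np.sin(ph_l)
    )

    # pelvis bob and lateral weight shift carried by the whole body
    bob = 0.018 * rom * style.bob * s * 0.5 * (1 - np.cos(2 * phase))
    shift = 0.02 * rom * s * np.sin(phase)
    pos[:, :, 1] += bob[:, None]
    pos[:, :, 0] += shift[:, None]

    # arm counter-swing: left arm in phase with the right leg
    swing = 0.14 * rom * style.arm_swing * s * arm_swing_factor
    pos[:, _LEFT_ARM, 2] += (swing * np.sin(ph_r))[:, None]
    pos[:, _RIGHT_ARM, 2] += (swing * np.sin(ph_l))[:, None]

    # back-and-forth progression within the capture volume
    travel = 1.1 * np.sin(2 * np.pi * t_gated / 20.0)
    pos[:, :, 2] += travel[:, None]
    return t_gated


def _seated(pos, bed_height=0.46):
    """Deform the standing template into a seated posture (legs forward)."""
    drop = _BASE[_J["left_hip"], 1] * (pos[0, _J["left_hip"], 1]
                                       / _BASE[_J["left_hip"], 1]) - bed_height
    upper = [j for j in range(_G.n_joints) if j not in _LEGS]
    pos[:, upper, 1] -= drop
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        knee, ankle = _J[f"{side}_knee"], _J[f"{side}_ankle"]
        heel, toe = _J[f"{side}_heel"], _J[f"{side}_foot_index"]
        pos[:, knee] = [sgn * 0.12, bed_height + 0.02, 0.40]
        pos[:, ankle] = [sgn * 0.12, 0.09, 0.44]
        pos[:, heel] = [sgn * 0.12, 0.03, 0.40]
        pos[:, toe] = [sgn * 0.12, 0.02, 0.55]


def _hand_arc(pos, t, freq, rng, hand, elbow, target_offset, shape="cos",
              amp=1.0):
    """Cyclic hand-to-target arc; elbow follows at half amplitude."""
    ph = 2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
    bump = 0.5 * (1 - np.cos(ph))
    if shape == "hold":
        bump = bump**2  # slower rise, longer dwell near the target
    rest = pos[0, hand[0]].copy()
    target = pos[0, _J["nose"]] + np.asarray(target_offset)
    delta = (target - rest) * amp
    pos[:, hand, :] += bump[:, None, None] * delta[None, None, :]
    pos[:, [elbow], :] += 0.5 * bump[:, None, None] * delta[None, None, :]
    return bump


def generate_adl_sequence(
    adl: str,
    profile: AbnormalityProfile = NORMAL_PROFILE,
    setup: CameraSetup | None = None,
    direction: str = "N",
    duration_s: float = 60.0,
    fps: float = 24.0,
    seed: int = 0,
    subject_id: str = "S1",
    style: SubjectStyle | None = None,
    noise_sd: float = 0.0015,
) -> SkeletonSequence:
    """Generate one labelled ADL sequence (world frame unless ``setup``).

    Deterministic given all arguments; a 60 s sequence at 24 fps has exactly
    1440 frames.
    """
    if adl not in ADL_LABELS:
        raise ValueError(f"unknown ADL label {adl!r}")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    style = style or SubjectStyle()
    rng = np.random.default_rng(seed)
    T = int(round(duration_s * fps))
    t = np.arange(T) / fps
    base = _BASE * style.scale
    # habitual subject posture: trunk lean and arm carriage show up in the
    # joint-angle feature space, unlike pure body scale
    if style.trunk_pitch != 0.0:
        hip_y = base[_J["left_hip"], 1]
        upper = _UPPER + [_J["left_hip"], _J["right_hip"]]
        dy = base[upper, 1] - hip_y
        base = base.copy()
        base[upper, 2] += np.sin(style.trunk_pitch) * dy
        base[upper, 1] = hip_y + np.cos(style.trunk_pitch) * dy
    if style.arm_carriage != 0.0:
        base = base.copy()
        base[_LEFT_ARM, 0] += style.arm_carriage
        base[_RIGHT_ARM, 0] -= style.arm_carriage
    pos = np.tile(base, (T, 1, 1))

    if adl == "WLK":
        _gait(pos, t, fps, profile, style, rng)
    elif adl == "HSK":
        # both hands grip the broom, so there is no walking arm counter-swing
        t_gated = _gait(pos, t, fps, profile, style, rng, amp_factor=0.8,
                        arm_swing_factor=0.0)
        # broom posture and swing: hands forward and low, sweeping together
        broom_ph = 2 * np.pi * 1.1 * t_gated + rng.uniform(0, 2 * np.pi)
        sweep = 0.22 * profile.rigidity_rom_scale * np.sin(broom_ph)
        hands = _LEFT_HAND + _RIGHT_HAND
        pos[:, hands, 2] += 0.25 + sweep[:, None]
        pos[:, hands, 1] -= 0.12  # lowered grip on the broom
        pos[:, [_J["left_elbow"], _J["right_elbow"]], 2] += (
            0.12 + 0.5 * sweep[:, None]
        )
        yaw = 0.22 * profile.rigidity_rom_scale * np.sin(broom_ph)
        centre = 0.5 * (
            pos[:, _J["left_hip"], :] + pos[:, _J["right_hip"], :]
        )
        rot = _rot_y(yaw)
        rel = pos[:, _UPPER, :] - centre[:, None, :]
        pos[:, _UPPER, :] = (
            np.einsum("tab,tjb->tja", rot, rel) + centre[:, None, :]
        )
    elif adl == "EAT":
        _seated(pos)
        # both forearms forward over the table, quick hand-to-mouth arcs
        for hand, elbow in ((_LEFT_HAND, _J["left_elbow"]),
                            (_RIGHT_HAND, _J["right_elbow"])):
            pos[:, hand, 2] += 0.30
            pos[:, hand, 1] += 0.12
            pos[:, [elbow], 2] += 0.14
        _hand_arc(pos, t, 0.45, rng, _RIGHT_HAND, _J["right_elbow"],
                  (-0.03, -0.08, 0.05), amp=0.85)
        _hand_arc(pos, t, 0.38, rng, _LEFT_HAND, _J["left_elbow"],
                  (0.03, -0.12, 0.05), amp=0.45)
    elif adl == "DRN":
        _seated(pos)
        # left hand raised holding the glass; slow raise-drink-lower cycle
        # with a dwell at the mouth, head tilting back at the apex
        pos[:, _LEFT_HAND, 1] += 0.30
        pos[:, _LEFT_HAND, 0] -= 0.06
        pos[:, [_J["left_elbow"]], 1] += 0.12
        bump = _hand_arc(pos, t, 0.12, rng, _RIGHT_HAND, _J["right_elbow"],
                         (-0.03, -0.05, 0.06), shape="hold", amp=1.0)
        pos[:, _HEAD, 1] += 0.03 * bump[:, None]
        pos[:, _HEAD, 2] -= 0.025 * bump[:, None]
    elif adl == "DRS":
        _seated(pos, bed_height=0.50)
        # trunk pitched forward over the clothing
        pos[:, _HEAD, 2] += 0.18
        pos[:, _HEAD, 1] -= 0.10
        pos[:, [_J["left_shoulder"], _J["right_shoulder"]], 2] += 0.10
        pos[:, [_J["left_shoulder"], _J["right_shoulder"]], 1] -= 0.05
        # broad bilateral dressing arcs around the torso
        ph = 2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi)
        for hand, elbow, off in (
            (_LEFT_HAND, _J["left_elbow"], 0.0),
            (_RIGHT_HAND, _J["right_elbow"], np.pi / 2),
        ):
            dx = 0.12 * np.cos(ph + off)
            dy = 0.20 * np.abs(np.sin(ph + off))
            dz = 0.10 * np.sin(ph + off)
            arc = np.stack([dx, dy, dz], axis=-1)
            pos[:, hand, :] += arc[:, None, :]
            pos[:, [elbow], :] += 0.5 * arc[:, None, :]
        pitch = 0.06 * np.sin(ph)
        pos[:, _UPPER, 2] += pitch[:, None]
    elif adl == "SLP":
        # lying supine on the bed, head toward -z, with breathing motion
        hips_y = pos[0, _J["left_hip"], 1]
        lying = pos.copy()
        lying[..., 1] = 0.55 + pos[..., 2]
        lying[..., 2] = -(pos[..., 1] - hips_y)
        pos = lying
        breathe = 0.008 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 6.28))
        chest = _TORSO + _HEAD
        pos[:, chest, 1] += breathe[:, None]

    # tremor: narrow-band jitter on distal upper-limb joints and the head
    if profile.tremor_amp > 0:
        joints = _LEFT_HAND + _RIGHT_HAND + [_J["left_elbow"],
                                             _J["right_elbow"]] + _HEAD
        env = 1.0 + 0.3 * np.sin(
            2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi)
        )
        for j in joints:
            direction_vec = rng.normal(size=3)
            direction_vec /= np.linalg.norm(direction_vec)
            amp = profile.tremor_amp * (1.0 if j not in _HEAD else 0.4)
            wave = amp * env * np.sin(
                2 * np.pi * profile.tremor_freq * t
                + rng.uniform(0, 2 * np.pi)
            )
            pos[:, j, :] += wave[:, None] * direction_vec[None, :]

    # postural instability: low-frequency lateral sway of torso and head
    if profile.sway_amp > 0:
        sway = profile.sway_amp * np.sin(
            2 * np.pi * 0.35 * t + rng.uniform(0, 2 * np.pi)
        )
        pos[:, _TORSO + _HEAD, 0] += sway[:, None]

    # orient the whole performance along the walking direction, with a small
    # random placement offset inside the capture volume
    az = DIRECTION_AZIMUTH[direction]
    rot = _rot_y(np.array(az))
    pos = pos @ rot.T
    pos[:, :, 0] += rng.uniform(-0.2, 0.2)
    pos[:, :, 2] += rng.uniform(-0.2, 0.2)

    if noise_sd > 0:
        pos = pos + rng.normal(scale=noise_sd, size=pos.shape)

    meta = SequenceMeta(
        subject_id=subject_id,
        adl_label=adl,
        condition="abnormal" if profile.is_abnormal else "normal",
        direction=direction,
        camera_height=setup.height_m if setup is not None else 1.6,
    )
    seq = SkeletonSequence(positions=pos, fps=fps, meta=meta)
    if setup is not None:
        seq = project_to_camera(seq, setup, direction)
    return seq


def project_to_camera(
    seq: SkeletonSequence, setup: CameraSetup, subject_azimuth: str
) -> SkeletonSequence:
    """Rigidly transform a world-frame sequence into the camera frame.

    The camera frame keeps +y up (so raising the camera by dh shifts all
    y coordinates by -dh) and +z along the optical axis into the scene.
    """
    c = setup.position
    rot = _rot_y(np.array(-setup.yaw_rad))
    cam_pos = (seq.positions - c[None, None, :]) @ rot.T
    meta = replace(
        seq.meta,
        camera_id=setup.camera_id,
        camera_height=setup.height_m if setup.height_m > 0 else
        seq.meta.camera_height,
        view=setup.view_of(subject_azimuth),
    )
    return SkeletonSequence(
        positions=cam_pos,
        fps=seq.fps,
        meta=meta,
        timestamps=seq.timestamps,
        visibility=seq.visibility,
        graph=seq.graph,
    )


# ---------------------------------------------------------------------------
# protocol builder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConfig:
    """The full laboratory protocol: subjects x ADLs x directions x heights."""

    n_subjects: int = 3
    adls: tuple = ADL_LABELS
    directions: tuple = DIRECTIONS
    heights: tuple = (1.4, 1.6, 1.8, 2.0)
    duration_s: float = 60.0
    fps: float = 24.0
    window: int = 30
    seed: int = 0
    cameras: tuple = (1,)
    include_abnormal: bool = True
    abnormal_adls: tuple = ("WLK", "HSK")
    abnormal_profile: AbnormalityProfile = DEFAULT_ABNORMAL_PROFILE
    noise_sd: float = 0.0015

    def __post_init__(self):
        if self.n_subjects <= 0 or not self.adls or not self.directions \
                or not self.heights:
            raise ValueError("all protocol counts must be positive")
        frames = self.duration_s * self.fps
        if abs(frames - round(frames)) > 1e-9 or \
                round(frames) % self.window != 0:
            raise ValueError(
                "window must divide evenly into duration_s * fps"
            )

    @property
    def frames_per_sequence(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def sequences_per_subject(self) -> int:
        """Normal-condition performances per subject (one per combination)."""
        return len(self.adls) * len(self.directions) * len(self.heights)

    @property
    def frames_per_subject(self) -> int:
        return self.sequences_per_subject * self.frames_per_sequence

    @property
    def windows_per_subject(self) -> int:
        return self.frames_per_subject // self.window


def iter_protocol_sequences(cfg: ProtocolConfig, include_abnormal=None):
    """Yield (record, SkeletonSequence) pairs for the whole protocol.

    Normal-condition sequences cover every (subject, adl, direction, height,
    camera) cell; abnormal variants of the gait-bearing ADLs are emitted as
    additional tagged sequences.
    """
    if include_abnormal is None:
        include_abnormal = cfg.include_abnormal
    conditions = [("normal", NORMAL_PROFILE)]
    if include_abnormal:
        conditions.append(("abnormal", cfg.abnormal_profile))
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1}"
        style = _default_style(s)
        for condition, profile in conditions:
            adls = cfg.adls if condition == "normal" else tuple(
                a for a in cfg.adls if a in cfg.abnormal_adls
            )
            for adl in adls:
                for direction in cfg.directions:
                    for height in cfg.heights:
                        seed = child_seed(
                            cfg.seed, subject_id, adl, direction, height,
                            condition,
                        )
                        world = generate_adl_sequence(
                            adl,
                            profile=profile,
                            direction=direction,
                            duration_s=cfg.duration_s,
                            fps=cfg.fps,
                            seed=seed,
                            subject_id=subject_id,
                            style=style,
                            noise_sd=cfg.noise_sd,
                        )
                        for cam in cfg.cameras:
                            setup = CameraSetup(
                                height_m=height, camera_id=cam
                            )
                            seq = project_to_camera(world, setup, direction)
                            rec = {
                                "seq_id": (
                                    f"{subject_id}_{adl}_{direction}_"
                                    f"h{height:g}_{condition}_cam{cam}"
                                ),
                                "n_frames": len(seq),
                                "fps": cfg.fps,
                                "seed": seed,
                                **seq.meta.to_dict(),
                            }
                            yield rec, seq


def build_dataset(cfg: ProtocolConfig, out_dir) -> list:
    """Generate the full protocol and write it (CSV + JSON + manifest).

    Returns the manifest records; partial-write failures raise after writing
    the manifest of the completed subset.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    try:
        for rec, seq in iter_protocol_sequences(cfg):
            rel = rec["seq_id"] + ".csv"
            write_sequence(seq, out_dir / rel)
            rec = dict(rec, path=rel)
            records.append(rec)
    finally:
        write_manifest(records, out_dir / "manifest.jsonl")
    return records


def dataset_counts(records) -> dict:
    """Closed-form-checkable arithmetic of a built dataset, computed from
    the actually generated sequences (camera-1, normal-condition core)."""
    core = [
        r for r in records
        if r["condition"] == "normal" and r.get("camera_id") in (1, None)
    ]
    subjects = sorted({r["subject_id"] for r in core})
    per_subject = {
        s: [r for r in core if r["subject_id"] == s] for s in subjects
    }
    frames_per_subject = {
        s: sum(r["n_frames"] for r in rs) for s, rs in per_subject.items()
    }
    adls = sorted({r["adl_label"] for r in core})
    frames_per_adl = {
        (s, a): sum(
            r["n_frames"] for r in per_subject[s] if r["adl_label"] == a
        )
        for s in subjects
        for a in adls
    }
    return {
        "subjects": subjects,
        "sequences_per_subject": {
            s: len(rs) for s, rs in per_subject.items()
        },
        "frames_per_subject": frames_per_subject,
        "frames_per_adl_per_subject": frames_per_adl,
        "frames_total": sum(frames_per_subject.values()),
    }


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

_REPRESENTATIONS = {
    "euclidean": lambda p: euclidean_array(p),
    "spherical": lambda p: spherical_array(p, fixed_rho=False),
    "spherical_fixed_rho": lambda p: spherical_array(p, fixed_rho=True),
}


@dataclass
class WindowSet:
    """Fixed-length feature windows plus per-window labels."""

    windows: np.ndarray  # (N, T, M) float32
    labels: pd.DataFrame

    def __len__(self):
        return len(self.windows)

    def select(self, mask) -> "WindowSet":
        mask = np.asarray(mask)
        return WindowSet(
            self.windows[mask], self.labels[mask].reset_index(drop=True)
        )


def window_dataset(
    source,
    window: int = 30,
    stride: int | None = None,
    representation: str = "spherical_fixed_rho",
    base_dir=None,
) -> WindowSet:
    """Cut sequences into non-overlapping feature windows with labels.

    ``source`` may be a :class:`ProtocolConfig` (sequences generated in
    memory), an iterable of (record, sequence) pairs, or manifest records
    with ``base_dir`` pointing at the stored CSVs.
    """
    if stride is None:
        stride = window
    if window <= 0 or stride <= 0:
        raise ValueError("window and stride must be positive")
    if representation not in _REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    feat = _REPRESENTATIONS[representation]

    if isinstance(source, ProtocolConfig):
        pairs = iter_protocol_sequences(source)
    elif source and isinstance(source[0] if isinstance(source, list) else
                               None, dict):
        if base_dir is None:
            raise ValueError("base_dir required for manifest records")
        pairs = (
            (r, read_sequence(Path(base_dir) / r["path"])) for r in source
        )
    else:
        pairs = source

    blocks, rows = [], []
    for rec, seq in pairs:
        T = len(seq)
        if window > T:
            raise ValueError(
                f"window {window} exceeds sequence length {T} "
                f"({rec.get('seq_id', '?')})"
            )
        n_win = (T - window) // stride + 1
        values = feat(seq.positions)
        for w in range(n_win):
            a = w * stride
            blocks.append(values[a:a + window])
            rows.append(
                {
                    "seq_id": rec.get("seq_id", ""),
                    "window_idx": w,
                    **{
                        k: rec[k]
                        for k in (
                            "subject_id", "adl_label", "condition",
                            "direction", "camera_height", "camera_id",
                            "view",
                        )
                        if k in rec
                    },
                }
            )
    if not blocks:
        raise ValueError("no windows produced")
    return WindowSet(
        windows=np.asarray(blocks, dtype=np.float32),
        labels=pd.DataFrame(rows),
    )


def ankle_excursion_ratio(seq: SkeletonSequence) -> float:
    """Left/right vertical ankle excursion ratio, pelvis-referenced and
    percentile-robust; ~1 for symmetric gait, ~gain under asymmetry."""
    hips = 0.5 * (
        seq.positions[:, _J["left_hip"], 1]
        + seq.positions[:, _J["right_hip"], 1]
    )
    left = seq.positions[:, _J["left_ankle"], 1] - hips
    right = seq.positions[:, _J["right_ankle"], 1] - hips

    def exc(v):
        return np.percentile(v, 97.5) - np.percentile(v, 2.5)

    return float(exc(left) / exc(right))
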