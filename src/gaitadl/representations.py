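"""Skeletal feature representations.

Three per-frame encodings of the 27-joint skeleton:

1. **Euclidean** — the raw 3D coordinates in traversal order, 81 values.
2. **Spherical adjacency** — each joint's offset from its graph parent in
   spherical coordinates (rho, phi, psi); 81 values, or 54 when the radial
   distances are held fixed (``fixed_rho``), since inter-joint distances are
   anatomically constant.
3. **Rotation adjacency** — for each joint, the minimal rotation (a unit
   quaternion) taking its parent's bone direction onto its own bone
   direction.

Spherical convention: rho is the radial distance, phi the polar inclination
from +z in [0, pi], psi the azimuth in the xy-plane from +x in (-pi, pi].
Offsets are measured in global axes by default; with ``local_frames=True``
they are expressed in a frame aligned with the parent's own bone, which makes
the features (except the first bones') invariant to rigid motions of the
whole body.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .skeleton import REDUCED_GRAPH, SkeletonFrame, SkeletonGraph

__all__ = [
    "EuclideanFeatures",
    "SphericalAdjacencyFeatures",
    "RotationAdjacencyFeatures",
    "to_euclidean",
    "to_spherical_adjacency",
    "from_spherical_adjacency",
    "to_rotation_adjacency",
    "euclidean_array",
    "spherical_array",
    "save_feature_windows",
    "load_feature_windows",
]

_EPS = 1e-12


@dataclass
class EuclideanFeatures:
    values: np.ndarray  # (81,)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if self.values.shape != (81,):
            raise ValueError("Euclidean features must have length 81")


@dataclass
class SphericalAdjacencyFeatures:
    values: np.ndarray  # (81,) or (54,) when fixed_rho
    fixed_rho: bool = False
    local_frames: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        want = 54 if self.fixed_rho else 81
        if self.values.shape != (want,):
            raise ValueError(
                f"spherical features must have length {want}, got "
                f"{self.values.shape[0]}"
            )

    @property
    def per_joint(self) -> np.ndarray:
        width = 2 if self.fixed_rho else 3
        return self.values.reshape(-1, width)


@dataclass
class RotationAdjacencyFeatures:
    quaternions: np.ndarray  # (27, 4), scalar-first (w, x, y, z)

    def __post_init__(self):
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.shape != (27, 4):
            raise ValueError("expected (27, 4) quaternion array")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must have unit norm within 1e-9")


# ---------------------------------------------------------------------------
# vectorised cores over (..., 27, 3) position arrays
# ---------------------------------------------------------------------------


def euclidean_array(positions: np.ndarray) -> np.ndarray:
    """Flatten (..., J, 3) positions to (..., 3J) in traversal order."""
    positions = np.asarray(positions, dtype=float)
    return positions.reshape(*positions.shape[:-2], -1)


def _cart_to_sph(offsets: np.ndarray) -> np.ndarray:
    """(..., 3) cartesian -> (..., 3) spherical (rho, phi, psi)."""
    rho = np.linalg.norm(offsets, axis=-1)
    safe = np.maximum(rho, _EPS)
    phi = np.arccos(np.clip(offsets[..., 2] / safe, -1.0, 1.0))
    psi = np.arctan2(offsets[..., 1], offsets[..., 0])
    # close the azimuth range to (-pi, pi]
    psi = np.where(psi <= -np.pi + _EPS, np.pi, psi)
    return np.stack([rho, phi, psi], axis=-1)


def _joint_local_axes(positions: np.ndarray, graph: SkeletonGraph, j: int):
    """Body-fixed orthonormal frame for expressing joint j's offset.

    z lies along the bone arriving at j's parent; the in-plane reference is
    the first body axis out of the root (the pelvis line, traversal slot 1),
    falling back to the second body axis (slot 2) and finally global x/y
    when near-parallel.  Built entirely from body geometry, the frame
    co-rotates with the skeleton, so the resulting angles are invariant
    under rigid motions.  Joints whose parent is the root use global axes.
    Returns rows (x, y, z) of shape (..., 3, 3).
    """
    par = graph.parent_index
    p = par[j]
    shape = positions.shape[:-2]
    eye = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    if p < 0 or par[p] < 0:
        return eye  # root or first bones: global axes
    bone = positions[..., p, :] - positions[..., par[p], :]
    z = bone / np.maximum(np.linalg.norm(bone, axis=-1, keepdims=True), _EPS)
    refs = []
    for t in (1, 2):
        if t < graph.n_joints and t != j:
            refs.append(positions[..., t, :] - positions[..., 0, :])
    refs.append(np.broadcast_to(np.array([1.0, 0.0, 0.0]), z.shape))
    refs.append(np.broadcast_to(np.array([0.0, 1.0, 0.0]), z.shape))
    x = np.zeros_like(z)
    done = np.zeros(shape + (1,), dtype=bool)
    for ref in refs:
        ref = ref / np.maximum(
            np.linalg.norm(ref, axis=-1, keepdims=True), _EPS
        )
        cand = ref - np.sum(ref * z, axis=-1, keepdims=True) * z
        norm = np.linalg.norm(cand, axis=-1, keepdims=True)
        ok = ~done & (norm > 1e-3)
        x = np.where(ok, cand / np.maximum(norm, _EPS), x)
        done = done | ok
    y = np.cross(z, x)
    axes = eye
    axes[..., 0, :] = x
    axes[..., 1, :] = y
    axes[..., 2, :] = z
    return axes


def spherical_array(
    positions: np.ndarray,
    fixed_rho: bool = False,
    local_frames: bool = False,
    graph: SkeletonGraph = REDUCED_GRAPH,
) -> np.ndarray:
    """Spherical adjacency features for (..., J, 3) positions.

    Returns (..., 3J) values, or (..., 2J) when ``fixed_rho``.  The root's
    slot is all zeros.
    """
    positions = np.asarray(positions, dtype=float)
    par = graph.parent_index
    offsets = np.zeros_like(positions)
    nz = par >= 0
    offsets[..., nz, :] = positions[..., nz, :] - positions[..., par[nz], :]
    lengths = np.linalg.norm(offsets[..., nz, :], axis=-1)
    if np.any(lengths <= _EPS):
        bad = np.argwhere(lengths <= _EPS)
        j = np.flatnonzero(nz)[bad[0, -1]]
        raise ValueError(
            "zero-length bone "
            f"{graph.joint_names[par[j]]}->{graph.joint_names[j]}"
        )
    if local_frames:
        local = np.empty_like(offsets)
        for j in range(graph.n_joints):
            axes = _joint_local_axes(positions, graph, j)
            local[..., j, :] = np.einsum(
                "...ab,...b->...a", axes, offsets[..., j, :]
            )
        offsets = local
    sph = _cart_to_sph(offsets)
    root = np.flatnonzero(par < 0)
    sph[..., root, :] = 0.0
    if fixed_rho:
        sph = sph[..., 1:]
    return sph.reshape(*positions.shape[:-2], -1)


def to_euclidean(frame: SkeletonFrame) -> EuclideanFeatures:
    """Concatenated (x, y, z) of all joints in traversal order (81 values)."""
    return EuclideanFeatures(euclidean_array(frame.positions))


def to_spherical_adjacency(
    frame: SkeletonFrame,
    fixed_rho: bool = False,
    local_frames: bool = False,
) -> SphericalAdjacencyFeatures:
    """Per-joint spherical offset from the graph parent.

    The root is encoded as zeros.  With ``fixed_rho`` the radial entries are
    dropped, giving the 54-dimensional variant used as the default model
    input.
    """
    values = spherical_array(
        frame.positions, fixed_rho=fixed_rho, local_frames=local_frames,
        graph=frame.graph,
    )
    return SphericalAdjacencyFeatures(
        values, fixed_rho=fixed_rho, local_frames=local_frames
    )


def from_spherical_adjacency(
    feat: SphericalAdjacencyFeatures,
    bone_lengths: np.ndarray | None = None,
    root_position=(0.0, 0.0, 0.0),
    graph: SkeletonGraph = REDUCED_GRAPH,
) -> SkeletonFrame:
    """Reconstruct joint positions from spherical adjacency features.

    ``bone_lengths`` (one positive value per non-root joint, traversal
    order) is required when ``fixed_rho`` dropped the radial distances.
    """
    per = feat.per_joint
    par = graph.parent_index
    J = graph.n_joints
    if feat.fixed_rho:
        if bone_lengths is None:
            raise ValueError("bone_lengths required when fixed_rho=True")
        bone_lengths = np.asarray(bone_lengths, dtype=float).reshape(-1)
        if bone_lengths.shape != (J - 1,):
            raise ValueError(f"expected {J - 1} bone lengths")
        if np.any(bone_lengths <= 0):
            raise ValueError("bone lengths must be positive")
        rho = np.zeros(J)
        rho[par >= 0] = bone_lengths
        ang = per
    else:
        rho = per[:, 0]
        if np.any(rho[par >= 0] <= 0):
            raise ValueError("bone lengths must be positive")
        ang = per[:, 1:]
    positions = np.zeros((J, 3))
    positions[0] = np.asarray(root_position, dtype=float)
    need_axes = feat.local_frames
    for j in range(1, J):
        phi, psi = ang[j]
        offset = rho[j] * np.array(
            [
                np.sin(phi) * np.cos(psi),
                np.sin(phi) * np.sin(psi),
                np.cos(phi),
            ]
        )
        if need_axes:
            axes = _joint_local_axes(positions, graph, j)
            offset = axes.T @ offset  # local -> global
        positions[j] = positions[par[j]] + offset
    return SkeletonFrame(positions=positions, graph=graph)


def _quat_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unit quaternion of the minimal rotation taking unit u onto unit v.

    Anti-parallel inputs use the documented tie-break: a half-turn about
    global +y.
    """
    d = float(np.dot(u, v))
    c = np.cross(u, v)
    if d < -1.0 + 1e-12 and np.linalg.norm(c) < 1e-9:
        return np.array([0.0, 0.0, 1.0, 0.0])  # pi about +y
    w = 1.0 + d
    q = np.array([w, c[0], c[1], c[2]])
    return q / np.linalg.norm(q)


def to_rotation_adjacency(frame: SkeletonFrame) -> RotationAdjacencyFeatures:
    """Minimal rotation from each parent bone direction onto the own bone.

    The root and the first bones (children of the root) carry the identity
    rotation.
    """
    graph = frame.graph
    par = graph.parent_index
    pos = frame.positions
    quats = np.zeros((graph.n_joints, 4))
    quats[:, 0] = 1.0
    for j in range(graph.n_joints):
        p = par[j]
        if p < 0 or par[p] < 0:
            continue
        u = pos[p] - pos[par[p]]
        v = pos[j] - pos[p]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu <= _EPS or nv <= _EPS:
            raise ValueError(
                "zero-length bone at joint " + graph.joint_names[j]
            )
        quats[j] = _quat_between(u / nu, v / nv)
    return RotationAdjacencyFeatures(quats)


# ---------------------------------------------------------------------------
# feature-window serialisation: dense float32 matrices in HDF5 with a JSON
# attribute block naming the representation
# ---------------------------------------------------------------------------


def save_feature_windows(
    path, windows: np.ndarray, representation: str, labels: dict | None = None
) -> Path:
    path = Path(path)
    windows = np.asarray(windows, dtype=np.float32)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("windows", data=windows)
        fh.attrs["attributes"] = json.dumps(
            {"representation": representation, "shape": list(windows.shape)}
        )
        if labels:
            grp = fh.create_group("labels")
            for key, arr in labels.items():
                arr = np.asarray(arr)
                if arr.dtype.kind in ("U", "O"):
                    arr = arr.astype("S")
                grp.create_dataset(key, data=arr)
    return path


def load_feature_windows(path):
    with h5py.File(Path(path), "r") as fh:
        windows = fh["windows"][...]
        attrs = json.loads(fh.attrs["attributes"])
        labels = {}
        if "labels" in fh:
            for key in fh["labels"]:
                arr = fh["labels"][key][...]
                if arr.dtype.kind == "S":
                    arr = arr.astype(str)
                labels[key] = arr
    return windows, attrs["representation"], labels
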