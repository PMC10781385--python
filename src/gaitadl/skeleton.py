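"""Canonical 27-joint skeleton data model, graph topology, and sequence I/O.

The skeleton is a tree with 27 vertices and 26 edges obtained by reducing the
33-landmark full-body pose model: the four inner/outer eye refinement
landmarks and the two mouth landmarks are dropped, keeping nose, eyes, ears
and every torso/limb/hand/foot landmark.  Joints are stored in a fixed
traversal order in which every joint's graph parent appears earlier in the
list, so adjacency-based feature representations can walk the list directly.

Coordinates are camera-frame (or world-frame before projection), right-handed,
in meters, with +y up.  Frame indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ADL_LABELS",
    "CONDITIONS",
    "DIRECTIONS",
    "VIEWS",
    "MEDIAPIPE_LANDMARKS",
    "DROPPED_LANDMARKS",
    "LANDMARK_TO_JOINT",
    "SkeletonGraph",
    "REDUCED_GRAPH",
    "SequenceMeta",
    "SkeletonFrame",
    "SkeletonSequence",
    "FormatError",
    "reduce_landmarks",
    "read_sequence",
    "write_sequence",
    "read_manifest",
    "write_manifest",
]

ADL_LABELS = ("EAT", "DRN", "DRS", "HSK", "SLP", "WLK")
CONDITIONS = ("normal", "abnormal")
DIRECTIONS = ("NE", "N", "NW")
VIEWS = ("frontal", "lateral")

# The 33 landmarks of the standard full-body pose model, in canonical order.
MEDIAPIPE_LANDMARKS = (
    "nose", "left_eye_inner", "left_eye", "left_eye_outer", "right_eye_inner",
    "right_eye", "right_eye_outer", "left_ear", "right_ear", "mouth_left",
    "mouth_right", "left_shoulder", "right_shoulder", "left_elbow",
    "right_elbow", "left_wrist", "right_wrist", "left_pinky", "right_pinky",
    "left_index", "right_index", "left_thumb", "right_thumb", "left_hip",
    "right_hip", "left_knee", "right_knee", "left_ankle", "right_ankle",
    "left_heel", "right_heel", "left_foot_index", "right_foot_index",
)

# Fine-detail landmarks removed when reducing 33 -> 27.
DROPPED_LANDMARKS = (
    "left_eye_inner", "left_eye_outer", "right_eye_inner", "right_eye_outer",
    "mouth_left", "mouth_right",
)


class FormatError(ValueError):
    """A sequence file or metadata sidecar violates the storage contract."""


@dataclass(frozen=True)
class SkeletonGraph:
    """Tree topology over named joints.

    ``joint_names`` doubles as the traversal order: the first entry is the
    root and every later joint's parent occurs earlier in the tuple.
    """

    joint_names: tuple
    edges: tuple  # (parent_name, child_name) pairs
    root: str

    def __post_init__(self):
        n = len(self.joint_names)
        if len(set(self.joint_names)) != n:
            raise ValueError("duplicate joint names")
        if len(self.edges) != n - 1:
            raise ValueError(
                f"a skeleton tree over {n} vertices needs {n - 1} edges, "
                f"got {len(self.edges)}"
            )
        if self.joint_names[0] != self.root:
            raise ValueError("traversal order must start at the root")
        index = {name: i for i, name in enumerate(self.joint_names)}
        # union-find cycle check: adding the N-1 edges must never close a loop
        uf = list(range(n))

        def find(a):
            while uf[a] != a:
                uf[a] = uf[uf[a]]
                a = uf[a]
            return a

        parent = np.full(n, -1, dtype=np.int64)
        for p, c in self.edges:
            if p not in index or c not in index:
                raise ValueError(f"edge ({p}, {c}) references unknown joint")
            ra, rb = find(index[p]), find(index[c])
            if ra == rb:
                raise ValueError(f"edge ({p}, {c}) creates a cycle")
            uf[ra] = rb
            if parent[index[c]] != -1:
                raise ValueError(f"joint {c} has two parents")
            parent[index[c]] = index[p]
        for i, name in enumerate(self.joint_names):
            if i == 0:
                continue
            if parent[i] < 0:
                raise ValueError(f"joint {name} is disconnected")
            if parent[i] >= i:
                raise ValueError(
                    f"parent of {name} must appear earlier in traversal order"
                )
        object.__setattr__(self, "_index", index)
        object.__setattr__(self, "_parent", parent)

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def parent_index(self) -> np.ndarray:
        """Per-joint parent position in traversal order; -1 for the root."""
        return self._parent

    @property
    def traversal_order(self) -> tuple:
        return self.joint_names

    def index(self, name: str) -> int:
        return self._index[name]

    def parent_of(self, name: str):
        p = self._parent[self._index[name]]
        return None if p < 0 else self.joint_names[p]


_EDGES = (
    ("left_hip", "right_hip"),
    ("left_hip", "left_shoulder"),
    ("left_shoulder", "left_elbow"),
    ("left_elbow", "left_wrist"),
    ("left_wrist", "left_pinky"),
    ("left_wrist", "left_index"),
    ("left_wrist", "left_thumb"),
    ("left_shoulder", "right_shoulder"),
    ("right_shoulder", "right_elbow"),
    ("right_elbow", "right_wrist"),
    ("right_wrist", "right_pinky"),
    ("right_wrist", "right_index"),
    ("right_wrist", "right_thumb"),
    ("left_shoulder", "nose"),
    ("nose", "left_eye"),
    ("left_eye", "left_ear"),
    ("nose", "right_eye"),
    ("right_eye", "right_ear"),
    ("right_hip", "right_knee"),
    ("right_knee", "right_ankle"),
    ("right_ankle", "right_heel"),
    ("right_heel", "right_foot_index"),
    ("left_hip", "left_knee"),
    ("left_knee", "left_ankle"),
    ("left_ankle", "left_heel"),
    ("left_heel", "left_foot_index"),
)

#: Traversal order: root and the two body axes (pelvis, torso) first so the
#: body-fixed reference frames of downstream features are always available,
#: then left arm, right arm, head chain, right leg, left leg.
_TRAVERSAL = (
    "left_hip", "right_hip", "left_shoulder",
    "left_elbow", "left_wrist", "left_pinky", "left_index", "left_thumb",
    "right_shoulder", "right_elbow", "right_wrist", "right_pinky",
    "right_index", "right_thumb",
    "nose", "left_eye", "left_ear", "right_eye", "right_ear",
    "right_knee", "right_ankle", "right_heel", "right_foot_index",
    "left_knee", "left_ankle", "left_heel", "left_foot_index",
)

#: The canonical reduced skeleton, rooted at the left hip.
REDUCED_GRAPH = SkeletonGraph(
    joint_names=_TRAVERSAL,
    edges=_EDGES,
    root="left_hip",
)

#: landmark name -> joint slot in REDUCED_GRAPH.joint_names (the documented
#: 33 -> 27 reduction mapping; alternatives are one edit away).
LANDMARK_TO_JOINT = {
    name: REDUCED_GRAPH.index(name)
    for name in MEDIAPIPE_LANDMARKS
    if name not in DROPPED_LANDMARKS
}


@dataclass
class SequenceMeta:
    """Acquisition metadata attached to a sequence."""

    subject_id: str = "S1"
    adl_label: str = "WLK"
    condition: str = "normal"
    direction: str = "N"
    camera_height: float = 1.6
    camera_id: int | None = None
    view: str | None = None

    def __post_init__(self):
        if self.adl_label not in ADL_LABELS:
            raise FormatError(f"unknown ADL label {self.adl_label!r}")
        if self.condition not in CONDITIONS:
            raise FormatError(f"unknown condition {self.condition!r}")
        if self.direction not in DIRECTIONS:
            raise FormatError(
                f"direction {self.direction!r} not in {DIRECTIONS}"
            )
        if not self.camera_height > 0:
            raise FormatError("camera_height must be positive")
        if self.camera_id is not None and self.camera_id not in (1, 2):
            raise FormatError("camera_id must be 1 or 2")
        if self.view is not None and self.view not in VIEWS:
            raise FormatError(f"view {self.view!r} not in {VIEWS}")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "adl_label": self.adl_label,
            "condition": self.condition,
            "direction": self.direction,
            "camera_height": self.camera_height,
            "camera_id": self.camera_id,
            "view": self.view,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceMeta":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown metadata keys {sorted(unknown)}")
        return cls(**d)


@dataclass
class SkeletonFrame:
    """27 named 3D joint positions (meters) at one time instant."""

    positions: np.ndarray  # (27, 3)
    timestamp: float = 0.0
    visibility: np.ndarray | None = None  # (27,) bool
    graph: SkeletonGraph = field(default=REDUCED_GRAPH, repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        n = self.graph.n_joints
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions must have shape ({n}, 3), got "
                f"{self.positions.shape}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.visibility is None:
            self.visibility = np.ones(n, dtype=bool)
        else:
            self.visibility = np.asarray(self.visibility, dtype=bool)
            if self.visibility.shape != (n,):
                raise ValueError(f"visibility must have shape ({n},)")

    def bone_lengths(self) -> np.ndarray:
        """Per-joint distance to the parent (nan at the root)."""
        par = self.graph.parent_index
        out = np.full(self.graph.n_joints, np.nan)
        nz = par >= 0
        out[nz] = np.linalg.norm(
            self.positions[nz] - self.positions[par[nz]], axis=1
        )
        return out

    def validate_bones(self) -> None:
        par = self.graph.parent_index
        for i in np.flatnonzero(par >= 0):
            if self.visibility[i] and self.visibility[par[i]]:
                if np.allclose(self.positions[i], self.positions[par[i]]):
                    raise ValueError(
                        "zero-length bone "
                        f"{self.graph.joint_names[par[i]]}->"
                        f"{self.graph.joint_names[i]}"
                    )


@dataclass
class SkeletonSequence:
    """Ordered skeleton frames with sampling rate, metadata and labels.

    Internally frame positions are a dense ``(T, 27, 3)`` array; frames are
    materialised lazily as :class:`SkeletonFrame` views.
    """

    positions: np.ndarray  # (T, 27, 3)
    fps: float
    meta: SequenceMeta
    timestamps: np.ndarray | None = None  # (T,), seconds
    visibility: np.ndarray | None = None  # (T, 27) bool
    graph: SkeletonGraph = field(default=REDUCED_GRAPH, repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (
            self.graph.n_joints,
            3,
        ):
            raise ValueError(
                f"positions must be (T, {self.graph.n_joints}, 3)"
            )
        if len(self.positions) == 0:
            raise FormatError("sequence has no frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.positions)) / self.fps
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (len(self.positions),):
                raise ValueError("one timestamp per frame required")
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        if self.visibility is None:
            self.visibility = np.ones(
                (len(self.positions), self.graph.n_joints), dtype=bool
            )
        else:
            self.visibility = np.asarray(self.visibility, dtype=bool)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            positions=self.positions[i],
            timestamp=float(self.timestamps[i]),
            visibility=self.visibility[i],
            graph=self.graph,
        )

    @property
    def frames(self) -> Iterator[SkeletonFrame]:
        return (self.frame(i) for i in range(len(self)))

    def with_meta(self, **kwargs) -> "SkeletonSequence":
        return SkeletonSequence(
            positions=self.positions,
            fps=self.fps,
            meta=replace(self.meta, **kwargs),
            timestamps=self.timestamps,
            visibility=self.visibility,
            graph=self.graph,
        )


def reduce_landmarks(
    full_pose, graph: SkeletonGraph = REDUCED_GRAPH
) -> SkeletonFrame:
    """Reduce a 33-landmark full-body pose to the canonical 27-joint frame.

    Retained joints keep their source landmark's coordinates exactly; the
    output joint order equals ``graph.joint_names``.
    """
    full_pose = np.asarray(full_pose, dtype=float)
    if full_pose.shape != (33, 3):
        raise ValueError(
            f"expected 33 landmarks of 3 coordinates, got {full_pose.shape}"
        )
    pos = np.empty((graph.n_joints, 3))
    for lm_idx, name in enumerate(MEDIAPIPE_LANDMARKS):
        if name in DROPPED_LANDMARKS:
            continue
        pos[graph.index(name)] = full_pose[lm_idx]
    return SkeletonFrame(positions=pos, graph=graph)


# ---------------------------------------------------------------------------
# Sequence I/O: long-format CSV (frame_idx, joint, x, y, z, visibility) plus a
# JSON sidecar holding fps and metadata.  Coordinates round-trip at 9
# significant digits.
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_sequence(seq: SkeletonSequence, path) -> Path:
    path = Path(path)
    n_j = seq.graph.n_joints
    T = len(seq)
    frame_idx = np.repeat(np.arange(T), n_j)
    joints = np.tile(np.array(seq.graph.joint_names), T)
    flat = seq.positions.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame_idx": frame_idx,
            "joint": joints,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
            "visibility": seq.visibility.reshape(-1).astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {"fps": seq.fps, "meta": seq.meta.to_dict()}
    uniform = np.allclose(
        seq.timestamps, np.arange(T) / seq.fps, atol=1e-12
    )
    if not uniform:
        sidecar["timestamps"] = [float(t) for t in seq.timestamps]
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=0))
    return path


def read_sequence(path, graph: SkeletonGraph = REDUCED_GRAPH) -> SkeletonSequence:
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing JSON sidecar {side}")
    sidecar = json.loads(side.read_text())
    meta = SequenceMeta.from_dict(sidecar["meta"])
    fps = float(sidecar["fps"])
    df = pd.read_csv(path)
    required = {"frame_idx", "joint", "x", "y", "z", "visibility"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"missing columns {sorted(required - set(df.columns))}"
        )
    if len(df) == 0:
        raise FormatError("sequence has no frames")
    n_j = graph.n_joints
    fidx = df["frame_idx"].to_numpy()
    drops = np.flatnonzero(np.diff(fidx) < 0)
    if len(drops):
        raise FormatError(f"non-monotone frame index at row {int(drops[0]) + 1}")
    uniq = np.unique(fidx)
    if not np.array_equal(uniq, np.arange(len(uniq))):
        raise FormatError("frame indices must be 0-based and gap-free")
    T = len(uniq)
    if len(df) != T * n_j:
        raise FormatError(
            f"expected {n_j} joints per frame; frame counts do not divide"
        )
    jindex = {name: i for i, name in enumerate(graph.joint_names)}
    positions = np.empty((T, n_j, 3))
    visibility = np.empty((T, n_j), dtype=bool)
    seen = np.zeros((T, n_j), dtype=bool)
    joints = df["joint"].to_numpy()
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    vis = df["visibility"].to_numpy().astype(bool)
    for row in range(len(df)):
        j = jindex.get(joints[row])
        if j is None:
            raise FormatError(f"row {row}: unknown joint {joints[row]!r}")
        f = int(fidx[row])
        if seen[f, j]:
            raise FormatError(f"row {row}: duplicate joint {joints[row]!r}")
        seen[f, j] = True
        positions[f, j] = xyz[row]
        visibility[f, j] = vis[row]
    missing = np.argwhere(~seen)
    if len(missing):
        f, j = missing[0]
        raise FormatError(
            f"frame {f} is missing joint {graph.joint_names[j]!r}"
        )
    ts = sidecar.get("timestamps")
    return SkeletonSequence(
        positions=positions,
        fps=fps,
        meta=meta,
        timestamps=None if ts is None else np.asarray(ts, dtype=float),
        visibility=visibility,
        graph=graph,
    )


def write_manifest(records: Sequence[dict], path) -> Path:
    """Write a dataset manifest as JSON-lines, one record per sequence."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return path


def read_manifest(path) -> list:
    path = Path(path)
    return [json.loads(line) for line in path.read_text().splitlines() if line]
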