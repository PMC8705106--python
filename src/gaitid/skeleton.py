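"""Skeleton keypoint types, OpenPose JSON parsing, and index-scheme conversion.

Two joint-numbering conventions are handled:

* **COCO18** — the 18 2D keypoints produced by OpenPose
  (0 nose, 1 neck, 2 R-shoulder, 3 R-elbow, 4 R-wrist, 5 L-shoulder,
  6 L-elbow, 7 L-wrist, 8 R-hip, 9 R-knee, 10 R-ankle, 11 L-hip,
  12 L-knee, 13 L-ankle, 14 R-eye, 15 L-eye, 16 R-ear, 17 L-ear).
* **H36M17** — the Human3.6M subset consumed by 2D-to-3D lifting networks
  (0 hip-center, 1 R-hip, 2 R-knee, 3 R-ankle, 6 L-hip, 7 L-knee,
  8 L-ankle, 12 spine, 13 thorax, 14 neck/nose, 15 head, 17 L-shoulder,
  18 L-elbow, 19 L-wrist, 25 R-shoulder, 26 R-elbow, 27 R-wrist).

3D sequences use the canonical right-handed z-up frame: the ground is the
x-y plane and z points up. Coordinates are unitless (pose-lifting networks
emit scale-free positions).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scheme",
    "Keypoints2DFrame",
    "JointSequence3D",
    "JointIndexMap",
    "COCO18_N_JOINTS",
    "H36M_JOINTS",
    "h36m_column",
    "parse_openpose_json",
    "coco_to_h36m",
    "normalize_sequence_3d",
    "load_sequence_csv",
    "save_sequence_csv",
]


class Scheme(enum.Enum):
    """Joint-indexing scheme of a 2D keypoint frame."""

    COCO18 = "coco18"
    H36M17 = "h36m17"


COCO18_N_JOINTS = 18

#: H3.6M joint ids used throughout the package, in canonical column order.
H36M_JOINTS: tuple[int, ...] = (0, 1, 2, 3, 6, 7, 8, 12, 13, 14, 15, 17, 18, 19, 25, 26, 27)

_H36M_COL = {j: c for c, j in enumerate(H36M_JOINTS)}

# Direct COCO -> H3.6M copies (source COCO index, target H3.6M id).
_DIRECT_PAIRS: tuple[tuple[int, int], ...] = (
    (8, 1),    # right hip
    (9, 2),    # right knee
    (10, 3),   # right ankle
    (11, 6),   # left hip
    (12, 7),   # left knee
    (13, 8),   # left ankle
    (1, 13),   # neck -> thorax
    (0, 14),   # nose -> neck/nose
    (5, 17),   # left shoulder
    (6, 18),   # left elbow
    (7, 19),   # left wrist
    (2, 25),   # right shoulder
    (3, 26),   # right elbow
    (4, 27),   # right wrist
)


def h36m_column(joint_id: int) -> int:
    """Column position of an H3.6M joint id in the canonical layout."""
    try:
        return _H36M_COL[joint_id]
    except KeyError:
        raise KeyError(f"H3.6M joint id {joint_id} is not in the supported subset") from None


class OpenPoseParseError(ValueError):
    """Raised when an OpenPose JSON document does not follow the expected layout."""


class ConversionError(ValueError):
    """Raised when a keypoint frame cannot be converted between schemes."""


@dataclass
class Keypoints2DFrame:
    """One frame of 2D joints with per-joint detection confidence.

    ``joints`` is an (n, 3) float array of (x, y, confidence) rows; a
    confidence of 0 marks an undetected joint whose x, y carry no meaning.
    Pixel coordinates are 0-based with the origin at the top-left corner
    (the OpenPose convention).
    """

    scheme: Scheme
    joints: np.ndarray
    frame_index: int = 0
    person_index: int = 0

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=float)
        expected = COCO18_N_JOINTS if self.scheme is Scheme.COCO18 else len(H36M_JOINTS)
        if self.joints.shape != (expected, 3):
            raise ValueError(
                f"{self.scheme.value} frame requires shape ({expected}, 3), "
                f"got {self.joints.shape}"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    def confidence(self, i: int) -> float:
        return float(self.joints[i, 2])


@dataclass
class JointSequence3D:
    """Time-ordered 3D positions of the H3.6M joint subset for one walking bout.

    ``positions`` has shape (T, 17, 3) with columns ordered as
    :data:`H36M_JOINTS`; z is the vertical (up) axis and the ground plane is
    x-y. Coordinates are unitless.
    """

    positions: np.ndarray
    fps: float
    subject_id: str | None = None
    bout_id: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(H36M_JOINTS), 3):
            raise ValueError(
                f"positions must have shape (T, {len(H36M_JOINTS)}, 3), "
                f"got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise ValueError("a sequence needs at least two frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if np.isnan(self.positions).any():
            raise ValueError("positions contain NaN; gap-fill before construction")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def joint(self, joint_id: int) -> np.ndarray:
        """(T, 3) track of one H3.6M joint."""
        return self.positions[:, h36m_column(joint_id), :]

    def with_positions(self, positions: np.ndarray, fps: float | None = None) -> "JointSequence3D":
        return JointSequence3D(
            positions=positions,
            fps=self.fps if fps is None else fps,
            subject_id=self.subject_id,
            bout_id=self.bout_id,
        )


@dataclass
class JointIndexMap:
    """Mapping from a source scheme to H3.6M target indices.

    ``pairs`` are direct (source index, target id) copies; ``synthesized``
    lists (target id, recipe) entries where the recipe names source joints
    and a combination rule. Every supported H3.6M id is produced exactly once.
    """

    pairs: tuple[tuple[int, int], ...] = _DIRECT_PAIRS
    synthesized: tuple[tuple[int, str], ...] = (
        (0, "midpoint of COCO 8 and COCO 11 (hip center)"),
        (12, "midpoint of H3.6M 0 and H3.6M 13 (spine)"),
        (15, "midpoint of COCO ears 16/17, eyes 14/15 fallback (head)"),
    )

    def validate(self) -> None:
        produced = sorted([t for _, t in self.pairs] + [t for t, _ in self.synthesized])
        if produced != sorted(H36M_JOINTS):
            raise ValueError("index map does not produce every H3.6M target exactly once")


def parse_openpose_json(text: str) -> list[Keypoints2DFrame]:
    """Parse an OpenPose JSON document into COCO18 keypoint frames.

    One frame is returned per detected person; ``person_index`` preserves the
    order within the ``people`` array. A document with zero people yields an
    empty list. Malformed documents raise :class:`OpenPoseParseError` naming
    the offending key.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise OpenPoseParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "people" not in doc:
        raise OpenPoseParseError("missing required key 'people'")
    people = doc["people"]
    if not isinstance(people, list):
        raise OpenPoseParseError("'people' must be a list")
    frame_index = int(doc.get("frame_index", 0))

    frames: list[Keypoints2DFrame] = []
    for pi, person in enumerate(people):
        if not isinstance(person, dict):
            raise OpenPoseParseError(f"people[{pi}] is not an object")
        kps = person.get("pose_keypoints_2d", person.get("pose_keypoints"))
        if kps is None:
            raise OpenPoseParseError(f"people[{pi}] missing 'pose_keypoints_2d'")
        arr = np.asarray(kps, dtype=float)
        if arr.ndim != 1 or arr.size != COCO18_N_JOINTS * 3:
            raise OpenPoseParseError(
                f"people[{pi}].pose_keypoints_2d has {arr.size} values; "
                f"expected {COCO18_N_JOINTS * 3} flat x,y,c triples"
            )
        frames.append(
            Keypoints2DFrame(
                scheme=Scheme.COCO18,
                joints=arr.reshape(COCO18_N_JOINTS, 3),
                frame_index=frame_index,
                person_index=pi,
            )
        )
    return frames


def _midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    xy = (a[:2] + b[:2]) / 2.0
    return np.array([xy[0], xy[1], min(a[2], b[2])])


def coco_to_h36m(frame: Keypoints2DFrame) -> Keypoints2DFrame:
    """Convert a COCO18 keypoint frame to the H3.6M subset layout.

    Directly-mapped joints are copied bit-exactly. Synthesized joints:
    hip center (0) = midpoint of the two hips; spine (12) = midpoint of hip
    center and thorax; thorax (13) = COCO neck; neck/nose (14) = COCO nose;
    head (15) = midpoint of the ears, falling back to the eyes if an ear is
    undetected. A synthesized joint's confidence is the minimum of its
    sources'. Re-converting an H36M17 frame raises rather than silently
    mapping again.
    """
    if frame.scheme is not Scheme.COCO18:
        raise ConversionError("frame is already in H3.6M indexing; refusing to re-convert")
    src = frame.joints
    out = np.zeros((len(H36M_JOINTS), 3))

    for s, t in _DIRECT_PAIRS:
        out[h36m_column(t)] = src[s]

    if src[8, 2] == 0 and src[11, 2] == 0:
        raise ConversionError("both hips undetected; hip center undefined")
    out[h36m_column(0)] = _midpoint(src[8], src[11])
    out[h36m_column(12)] = _midpoint(out[h36m_column(0)], out[h36m_column(13)])
    if src[16, 2] > 0 and src[17, 2] > 0:
        out[h36m_column(15)] = _midpoint(src[16], src[17])
    else:
        out[h36m_column(15)] = _midpoint(src[14], src[15])

    return Keypoints2DFrame(
        scheme=Scheme.H36M17,
        joints=out,
        frame_index=frame.frame_index,
        person_index=frame.person_index,
    )


_KNOWN_CONVENTIONS = ("canonical", "z-up-origin-at-root")


def normalize_sequence_3d(seq: JointSequence3D, source_convention: str = "z-up-origin-at-root") -> JointSequence3D:
    """Bring a 3D sequence into the canonical frame by a rigid transform.

    Both supported source conventions are z-up; normalization translates the
    whole bout so the root joint (H3.6M 0) of frame 0 sits at the origin.
    Rigid transform only: all inter-joint distances are preserved exactly.
    """
    if source_convention not in _KNOWN_CONVENTIONS:
        raise ValueError(
            f"unknown source convention {source_convention!r}; "
            f"expected one of {_KNOWN_CONVENTIONS}"
        )
    root0 = seq.positions[0, h36m_column(0), :]
    return seq.with_positions(seq.positions - root0[None, None, :])


def _gap_fill(frames: np.ndarray) -> np.ndarray:
    """Linear interpolation over time of NaN entries, per joint per axis.

    Leading/trailing gaps copy the nearest valid frame.
    """
    T = frames.shape[0]
    flat = frames.reshape(T, -1)
    df = pd.DataFrame(flat)
    df = df.interpolate(method="linear", axis=0, limit_direction="both")
    if df.isna().any().any():
        raise ValueError("a joint track is entirely missing; cannot gap-fill")
    return df.to_numpy().reshape(frames.shape)


def save_sequence_csv(seq: JointSequence3D, path) -> None:
    """Write a sequence as delimited text, one frame per row.

    Columns: ``frame`` then ``j<idx>_x, j<idx>_y, j<idx>_z`` per H3.6M id.
    """
    cols: dict[str, np.ndarray] = {"frame": np.arange(seq.n_frames)}
    for j in H36M_JOINTS:
        trk = seq.joint(j)
        cols[f"j{j}_x"] = trk[:, 0]
        cols[f"j{j}_y"] = trk[:, 1]
        cols[f"j{j}_z"] = trk[:, 2]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_sequence_csv(path, fps: float, subject_id: str | None = None, bout_id: str | None = None) -> JointSequence3D:
    """Read a 3D joint sequence from the delimited-text format.

    Unknown columns are ignored; missing samples (empty cells or NaN) are
    gap-filled by linear interpolation over time.
    """
    df = pd.read_csv(path)
    missing = [f"j{j}_{ax}" for j in H36M_JOINTS for ax in "xyz" if f"j{j}_{ax}" not in df.columns]
    if missing:
        raise ValueError(f"sequence file lacks columns: {missing[:6]}...")
    if "frame" in df.columns:
        df = df.sort_values("frame")
    T = len(df)
    pos = np.empty((T, len(H36M_JOINTS), 3))
    for c, j in enumerate(H36M_JOINTS):
        for a, ax in enumerate("xyz"):
            pos[:, c, a] = df[f"j{j}_{ax}"].to_numpy(dtype=float)
    if np.isnan(pos).any():
        pos = _gap_fill(pos)
    return JointSequence3D(positions=pos, fps=fps, subject_id=subject_id, bout_id=bout_id)
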