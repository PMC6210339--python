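"""Data model for body-pose recordings.

A pose is one time frame of nine body-segment orientations, each a unit
quaternion ``(w, x, y, z)``.  Recordings are stored as float arrays of shape
``(n_frames, 9, 4)`` after *canonicalization*: every quaternion is
renormalized to unit length and mapped onto the ``w >= 0`` hemisphere so that
``q`` and ``-q`` (the same rotation) become identical vectors and Euclidean
distances between poses are well defined.

On-disk format: one pose-CSV per recording (header
``frame,seg1_w,seg1_x,...,seg9_z``) plus a single ``manifest.json`` naming the
files, subjects, labels, frame rates and the segment label list.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from cav.errors import FormatError, InvalidPoseError

logger = logging.getLogger(__name__)

N_SEGMENTS = 9
QUAT_DIM = 4
POSE_DIM = N_SEGMENTS * QUAT_DIM

#: Default segment labels: one torso segment plus four left/right limb pairs.
DEFAULT_SEGMENTS: tuple[str, ...] = (
    "torso",
    "l_upper_arm",
    "r_upper_arm",
    "l_forearm",
    "r_forearm",
    "l_thigh",
    "r_thigh",
    "l_shank",
    "r_shank",
)

_UNIT_NORM_SKIP_TOL = 1e-12


def round_half_up(x: float) -> int:
    """Deterministic half-up rounding (``round()`` is banker's rounding)."""
    return int(math.floor(x + 0.5))


def canonicalize_quaternions(q: np.ndarray, *, context: str = "") -> np.ndarray:
    """Renormalize quaternions and resolve the sign ambiguity.

    Works on any ``(..., 4)`` array.  Each quaternion is scaled to unit norm
    (skipped when already unit within 1e-12, keeping canonical data bit-exact)
    and negated when ``w < 0``, or when ``w == 0`` and the first nonzero
    remaining component is negative.

    Raises
    ------
    InvalidPoseError
        If any quaternion has zero norm or non-finite components.  The message
        includes ``context`` plus the offending index.
    """
    arr = np.array(q, dtype=float, copy=True)
    if arr.shape[-1] != QUAT_DIM:
        raise InvalidPoseError(f"{context}: expected trailing dimension 4, got {arr.shape}")
    flat = arr.reshape(-1, QUAT_DIM)
    finite = np.isfinite(flat).all(axis=1)
    norms = np.where(finite, np.linalg.norm(np.where(finite[:, None], flat, 0.0), axis=1), 0.0)
    bad = ~finite | (norms <= 0)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        where = np.unravel_index(idx, arr.shape[:-1]) if arr.ndim > 1 else (idx,)
        raise InvalidPoseError(
            f"{context}: degenerate quaternion (zero norm or non-finite) at index {tuple(where)}"
        )
    scale = np.where(np.abs(norms - 1.0) > _UNIT_NORM_SKIP_TOL, norms, 1.0)
    flat /= scale[:, None]

    w = flat[:, 0]
    flip = w < 0.0
    undecided = w == 0.0
    for j in range(1, QUAT_DIM):
        nonzero = undecided & (flat[:, j] != 0.0)
        flip |= nonzero & (flat[:, j] < 0.0)
        undecided &= ~nonzero
    flat[flip] *= -1.0
    return flat.reshape(arr.shape)


@dataclasses.dataclass(frozen=True)
class Pose:
    """Nine unit quaternions, one per body segment, at one time frame."""

    quaternions: np.ndarray  # shape (9, 4)

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternions, dtype=float)
        if q.shape != (N_SEGMENTS, QUAT_DIM):
            raise InvalidPoseError(f"pose must have shape (9, 4), got {q.shape}")
        object.__setattr__(self, "quaternions", q)

    def flatten(self) -> np.ndarray:
        return self.quaternions.reshape(-1)

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, Pose):
            return NotImplemented
        return bool(np.array_equal(self.quaternions, other.quaternions))


def canonicalize_pose(pose: Pose, *, context: str = "pose") -> Pose:
    """Return the canonical representative of ``pose`` (idempotent)."""
    return Pose(canonicalize_quaternions(pose.quaternions, context=context))


def _as_frame_array(frames: "Sequence[Pose] | np.ndarray") -> np.ndarray:
    if isinstance(frames, np.ndarray):
        arr = np.asarray(frames, dtype=float)
        if arr.ndim != 3 or arr.shape[1:] != (N_SEGMENTS, QUAT_DIM):
            raise InvalidPoseError(f"frame array must have shape (L, 9, 4), got {arr.shape}")
        return arr
    return np.stack([p.quaternions for p in frames])


@dataclasses.dataclass
class ActivityRecording:
    """A labeled, subject-attributed pose sequence at a fixed frame rate."""

    frames: np.ndarray  # (n_frames, 9, 4), canonical
    frame_rate: float
    label: str
    subject_id: str
    recording_id: str

    def __post_init__(self) -> None:
        arr = _as_frame_array(self.frames)
        if arr.shape[0] == 0:
            raise InvalidPoseError(f"recording {self.recording_id!r}: no frames")
        if not self.frame_rate > 0:
            raise FormatError(f"recording {self.recording_id!r}: frame rate must be positive")
        self.frames = canonicalize_quaternions(arr, context=f"recording {self.recording_id!r}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.frame_rate

    def poses(self) -> Iterator[Pose]:
        for row in self.frames:
            yield Pose(row)


@dataclasses.dataclass
class LabeledDataset:
    """A set of recordings plus the ordered set of activity labels."""

    recordings: list[ActivityRecording]
    segments: tuple[str, ...] = DEFAULT_SEGMENTS

    def __post_init__(self) -> None:
        if len(self.segments) != N_SEGMENTS:
            raise FormatError(f"expected {N_SEGMENTS} segment labels, got {len(self.segments)}")
        ids = [r.recording_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate recording ids: {dup}")

    @property
    def activity_set(self) -> list[str]:
        return sorted({r.label for r in self.recordings})

    @property
    def subjects(self) -> list[str]:
        return sorted({r.subject_id for r in self.recordings})

    def by_label(self, label: str) -> list[ActivityRecording]:
        return [r for r in self.recordings if r.label == label]

    def subset(self, recordings: Iterable[ActivityRecording]) -> "LabeledDataset":
        return LabeledDataset(recordings=list(recordings), segments=self.segments)

    def __len__(self) -> int:
        return len(self.recordings)


def resample_indices(length: int, target_len: int) -> np.ndarray:
    """Nearest-index decimation map from ``length`` frames to ``target_len``."""
    if length < 1:
        raise ValueError("cannot resample an empty sequence")
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if target_len == 1:
        return np.array([0], dtype=int)
    pos = np.arange(target_len) * (length - 1) / (target_len - 1)
    return np.floor(pos + 0.5).astype(int)


def resample_frames(frames: np.ndarray, target_len: int) -> np.ndarray:
    """Resample a ``(L, 9, 4)`` frame array to exactly ``target_len`` frames."""
    arr = _as_frame_array(frames)
    return arr[resample_indices(arr.shape[0], target_len)]


def resample_sequence(frames: Sequence[Pose], target_len: int) -> list[Pose]:
    """Pose-level wrapper around :func:`resample_frames`."""
    if len(frames) == 0:
        raise ValueError("cannot resample an empty sequence")
    arr = np.stack([p.quaternions for p in frames])
    return [Pose(row) for row in resample_frames(arr, target_len)]


# ---------------------------------------------------------------------------
# pose-CSV + manifest I/O
# ---------------------------------------------------------------------------

def _csv_columns() -> list[str]:
    cols = ["frame"]
    for i in range(1, N_SEGMENTS + 1):
        cols.extend(f"seg{i}_{c}" for c in ("w", "x", "y", "z"))
    return cols


def write_dataset(dataset: LabeledDataset, path: "str | os.PathLike[str]") -> None:
    """Write one pose-CSV per recording plus ``manifest.json`` under ``path``."""
    root = os.fspath(path)
    os.makedirs(root, exist_ok=True)
    manifest: dict = {"segments": list(dataset.segments), "recordings": []}
    for rec in dataset.recordings:
        fname = f"{rec.recording_id}.csv"
        flat = rec.frames.reshape(rec.n_frames, POSE_DIM)
        # repr() gives the shortest string that round-trips each float exactly
        with open(os.path.join(root, fname), "w", encoding="utf-8", newline="\n") as fh:
            fh.write(",".join(_csv_columns()) + "\n")
            for i, row in enumerate(flat):
                fh.write(str(i) + "," + ",".join(repr(float(v)) for v in row) + "\n")
        manifest["recordings"].append(
            {
                "id": rec.recording_id,
                "file": fname,
                "subject": rec.subject_id,
                "label": rec.label,
                "frame_rate": rec.frame_rate,
            }
        )
    with open(os.path.join(root, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


def read_dataset(path: "str | os.PathLike[str]") -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`.

    ``path`` may point at the directory or at the manifest file itself.
    Round-trips bit-exactly with :func:`write_dataset` on canonical data.
    """
    p = os.fspath(path)
    manifest_path = p if p.endswith(".json") else os.path.join(p, "manifest.json")
    root = os.path.dirname(manifest_path)
    try:
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"{manifest_path}: manifest not found")
    except json.JSONDecodeError as exc:
        raise FormatError(f"{manifest_path}: invalid JSON ({exc})")

    segments = tuple(manifest.get("segments", DEFAULT_SEGMENTS))
    expected = _csv_columns()
    recordings = []
    for entry in manifest.get("recordings", []):
        for key in ("id", "file", "subject", "label", "frame_rate"):
            if key not in entry:
                raise FormatError(f"{manifest_path}: recording entry missing {key!r}: {entry}")
        csv_path = os.path.join(root, entry["file"])
        try:
            df = pd.read_csv(csv_path, float_precision="round_trip")
        except FileNotFoundError:
            raise FormatError(f"{csv_path}: file not found (listed in manifest)")
        if list(df.columns) != expected:
            raise FormatError(
                f"{csv_path}:1: bad header: expected {len(expected)} columns "
                f"{expected[:2]}...{expected[-1:]}, got {len(df.columns)}"
            )
        values = df[expected[1:]].to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise FormatError(f"{csv_path}:{row + 2}: non-finite value")
        frames = values.reshape(-1, N_SEGMENTS, QUAT_DIM)
        recordings.append(
            ActivityRecording(
                frames=frames,
                frame_rate=float(entry["frame_rate"]),
                label=str(entry["label"]),
                subject_id=str(entry["subject"]),
                recording_id=str(entry["id"]),
            )
        )
    return LabeledDataset(recordings=recordings, segments=segments)
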