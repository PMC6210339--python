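"""Deterministic synthetic pose-activity generator with planted primitives.

Activities are built from a pool of short motion primitives (0.5-2 s of
smooth single-axis oscillations per body segment, converted to unit
quaternions).  Each activity grammar lists an ordered sequence of primitive
steps with variation knobs — left/right mirroring, speed jitter, step
reordering, optional steps, idle insertions and quaternion-component noise —
all scaled by a single ``variation_level`` in [0, 1].  Some primitives are
shared across activities so that classes are confusable by construction.

All randomness flows through seeded generators; per-recording substreams are
derived from (seed, subject index, activity index), so datasets are
byte-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from cav.core import (
    DEFAULT_SEGMENTS,
    N_SEGMENTS,
    ActivityRecording,
    LabeledDataset,
    canonicalize_quaternions,
    resample_frames,
    round_half_up,
)
from cav.metrics import flatten

#: Left/right segment index pairs swapped by mirroring (torso is index 0).
MIRROR_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 6), (7, 8))


@dataclasses.dataclass(frozen=True)
class PrimitiveSpec:
    """Per-segment oscillation parameters defining one motion primitive."""

    primitive_id: int
    duration_s: float
    axes: np.ndarray  # (9, 3) unit rotation axis per segment
    amplitudes: np.ndarray  # (9,) radians
    frequencies: np.ndarray  # (9,) Hz
    phases: np.ndarray  # (9,) radians

    def __post_init__(self) -> None:
        if not 0.5 <= self.duration_s <= 2.0:
            raise ValueError("primitive duration must lie in [0.5, 2] s")


@dataclasses.dataclass(frozen=True)
class GrammarStep:
    primitive_id: int
    prob: float = 1.0  # inclusion probability (1.0 = mandatory)
    repeats: tuple[int, int] = (1, 1)  # inclusive range


@dataclasses.dataclass
class ActivityGrammar:
    label: str
    steps: list[GrammarStep]
    mirror_prob: float = 0.0
    speed_range: tuple[float, float] = (1.0, 1.0)
    reorder_prob: float = 0.0
    idle_rate: float = 0.0
    idle_dur_s: tuple[float, float] = (0.3, 0.6)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not any(s.prob >= 1.0 for s in self.steps):
            raise ValueError("grammar needs at least one mandatory step")
        if not 0 <= self.mirror_prob <= 1 or not 0 <= self.reorder_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.speed_range[0] <= 0 or self.speed_range[0] > self.speed_range[1]:
            raise ValueError("invalid speed range")
        if self.noise_sd < 0 or self.idle_rate < 0:
            raise ValueError("noise_sd and idle_rate must be >= 0")


@dataclasses.dataclass(frozen=True)
class PrimitiveInstance:
    primitive_id: int
    start_frame: int
    end_frame: int
    mirrored: bool
    speed: float


@dataclasses.dataclass
class RecordingTruth:
    recording_id: str
    label: str
    instances: list[PrimitiveInstance]


@dataclasses.dataclass
class GroundTruth:
    primitives: dict[int, PrimitiveSpec]
    grammars: dict[str, ActivityGrammar]
    recordings: dict[str, RecordingTruth]


def _axis_angle_to_quat(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """(9, 3) axes + (n, 9) angles -> (n, 9, 4) quaternions."""
    half = angles / 2.0
    w = np.cos(half)
    xyz = np.sin(half)[..., None] * axes[None, :, :]
    return np.concatenate([w[..., None], xyz], axis=-1)


def mirror_frames(frames: np.ndarray) -> np.ndarray:
    """Swap left/right segments and flip the rotation across the sagittal plane.

    Involutive: mirroring twice returns the original frames.
    """
    out = frames.copy()
    for a, b in MIRROR_PAIRS:
        out[:, [a, b]] = out[:, [b, a]]
    out[:, :, 2] *= -1.0
    out[:, :, 3] *= -1.0
    return out


def render_primitive(
    spec: PrimitiveSpec,
    frame_rate: float,
    speed: float = 1.0,
    mirrored: bool = False,
) -> np.ndarray:
    """Render a primitive to ``round(duration/speed * frame_rate)`` canonical frames.

    ``speed`` compresses or stretches the time axis; the trajectory shape is
    preserved (phase runs over the same normalized arc).
    """
    n = max(1, round_half_up(spec.duration_s / speed * frame_rate))
    u = np.arange(n) / n * spec.duration_s  # normalized trajectory time
    angles = spec.amplitudes[None, :] * np.sin(
        2.0 * np.pi * spec.frequencies[None, :] * u[:, None] + spec.phases[None, :]
    )
    frames = _axis_angle_to_quat(spec.axes, angles)
    if mirrored:
        frames = mirror_frames(frames)
    return canonicalize_quaternions(frames, context=f"primitive {spec.primitive_id}")


def _idle_frames(n: int) -> np.ndarray:
    frames = np.zeros((n, N_SEGMENTS, 4))
    frames[:, :, 0] = 1.0
    return frames


def generate_example(
    grammar: ActivityGrammar,
    primitives: dict[int, PrimitiveSpec],
    subject_id: str,
    recording_id: str,
    frame_rate: float,
    rng: np.random.Generator,
) -> tuple[ActivityRecording, RecordingTruth]:
    """Sample one recording from a grammar, recording ground-truth spans."""
    steps = list(grammar.steps)
    if len(steps) > 1 and rng.random() < grammar.reorder_prob:
        i = int(rng.integers(0, len(steps) - 1))
        steps[i], steps[i + 1] = steps[i + 1], steps[i]
    mirrored = bool(rng.random() < grammar.mirror_prob)

    chunks: list[np.ndarray] = []
    instances: list[PrimitiveInstance] = []
    cursor = 0
    for step in steps:
        if step.prob < 1.0 and rng.random() >= step.prob:
            continue
        lo, hi = step.repeats
        n_rep = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        for _ in range(n_rep):
            lo_s, hi_s = grammar.speed_range
            speed = float(rng.uniform(lo_s, hi_s)) if hi_s > lo_s else lo_s
            frames = render_primitive(primitives[step.primitive_id], frame_rate, speed, mirrored)
            chunks.append(frames)
            instances.append(
                PrimitiveInstance(
                    primitive_id=step.primitive_id,
                    start_frame=cursor,
                    end_frame=cursor + len(frames),
                    mirrored=mirrored,
                    speed=speed,
                )
            )
            cursor += len(frames)
        if grammar.idle_rate > 0 and rng.random() < grammar.idle_rate:
            lo_i, hi_i = grammar.idle_dur_s
            dur = float(rng.uniform(lo_i, hi_i))
            n_idle = max(1, round_half_up(dur * frame_rate))
            chunks.append(_idle_frames(n_idle))
            cursor += n_idle

    frames = np.concatenate(chunks, axis=0)
    if grammar.noise_sd > 0:
        frames = frames + rng.normal(0.0, grammar.noise_sd, size=frames.shape)
    recording = ActivityRecording(
        frames=frames,
        frame_rate=frame_rate,
        label=grammar.label,
        subject_id=subject_id,
        recording_id=recording_id,
    )
    return recording, RecordingTruth(recording_id=recording_id, label=grammar.label, instances=instances)


def _random_primitive(pid: int, rng: np.random.Generator) -> PrimitiveSpec:
    axes = rng.normal(size=(N_SEGMENTS, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    return PrimitiveSpec(
        primitive_id=pid,
        duration_s=float(rng.uniform(0.8, 1.6)),
        axes=axes,
        amplitudes=rng.uniform(0.3, 1.1, size=N_SEGMENTS),
        frequencies=rng.uniform(0.6, 1.8, size=N_SEGMENTS),
        phases=rng.uniform(0.0, 2.0 * np.pi, size=N_SEGMENTS),
    )


def build_grammars(
    n_activities: int,
    variation_level: float,
    seed: int,
    n_shared: int = 4,
) -> tuple[dict[int, PrimitiveSpec], dict[str, ActivityGrammar]]:
    """Primitive pool + grammars with knobs scaled by ``variation_level``.

    Each activity owns one unique primitive and borrows one shared primitive
    (shared primitives rotate across activities), so neighboring classes are
    confusable through their common vocabulary.
    """
    if not 0 <= variation_level <= 1:
        raise ValueError("variation_level must lie in [0, 1]")
    rng = np.random.default_rng([seed, 0xC0DE])
    primitives: dict[int, PrimitiveSpec] = {}
    for pid in range(n_activities + n_shared):
        primitives[pid] = _random_primitive(pid, rng)

    v = variation_level
    grammars: dict[str, ActivityGrammar] = {}
    for a in range(n_activities):
        label = f"activity{a:02d}"
        shared_id = n_activities + (a % n_shared) if n_shared > 0 else a
        extra_id = n_activities + ((a + 1) % n_shared) if n_shared > 0 else a
        steps = [
            GrammarStep(primitive_id=a, repeats=(2, 2 + (1 if v > 0 else 0))),
            GrammarStep(primitive_id=shared_id),
            GrammarStep(primitive_id=extra_id, prob=1.0 - 0.6 * v if v > 0 else 1.0),
            GrammarStep(primitive_id=a),
        ]
        grammars[label] = ActivityGrammar(
            label=label,
            steps=steps,
            mirror_prob=0.4 * v,
            speed_range=(1.0 - 0.3 * v, 1.0 + 0.3 * v),
            reorder_prob=0.3 * v,
            idle_rate=0.5 * v,
            noise_sd=0.02 * v,
        )
    return primitives, grammars


def generate_dataset(
    n_activities: int = 8,
    n_subjects: int = 15,
    variation_level: float = 0.5,
    seed: int = 0,
    frame_rate: float = 30.0,
    n_shared: int = 4,
    primitives: Optional[dict[int, PrimitiveSpec]] = None,
    grammars: Optional[dict[str, ActivityGrammar]] = None,
) -> tuple[LabeledDataset, GroundTruth]:
    """Multi-subject dataset: every subject performs every activity once.

    Custom ``primitives``/``grammars`` may replace the built-in pool, e.g. to
    plant disjoint or deliberately shared primitives.
    """
    if primitives is None or grammars is None:
        primitives, grammars = build_grammars(n_activities, variation_level, seed, n_shared)
    recordings = []
    truth = GroundTruth(primitives=primitives, grammars=grammars, recordings={})
    for a, label in enumerate(sorted(grammars)):
        for s in range(n_subjects):
            subject_id = f"subj{s + 1:02d}"
            recording_id = f"{label}_{subject_id}"
            rng = np.random.default_rng([seed, s, a])
            rec, rec_truth = generate_example(
                grammars[label], primitives, subject_id, recording_id, frame_rate, rng
            )
            recordings.append(rec)
            truth.recordings[recording_id] = rec_truth
    return LabeledDataset(recordings=recordings, segments=DEFAULT_SEGMENTS), truth


def planted_primitive_vectors(
    primitives: dict[int, PrimitiveSpec], frame_rate: float, base_len: int
) -> dict[int, np.ndarray]:
    """Base-length flattened vector of each primitive at speed 1, unmirrored."""
    out = {}
    for pid, spec in primitives.items():
        frames = render_primitive(spec, frame_rate)
        out[pid] = flatten(resample_frames(frames, base_len))
    return out
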