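"""Dataset-profiling metrics: per-activity Complexity and per-set Variation.

Complexity sums, over whole-second circular time-shifts, the Euclidean
distance between a recording and its shifted self; repetitive or constant
signals score low.  Variation is the mean pairwise Euclidean distance between
length-normalized examples of one activity and quantifies within-class
heterogeneity.  Both are also exposed divided by duration ("normalized by
activity length").
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from cav.core import ActivityRecording, LabeledDataset, resample_frames, round_half_up
from cav.errors import MetricError


def flatten(frames: np.ndarray) -> np.ndarray:
    """Flatten a ``(L, 9, 4)`` frame array to a frame-major ``36*L`` vector."""
    arr = np.asarray(frames, dtype=float)
    return arr.reshape(-1)


@dataclasses.dataclass(frozen=True)
class ComplexityResult:
    complexity: float
    normalized: float  # complexity / duration_seconds


@dataclasses.dataclass(frozen=True)
class VariationResult:
    variation: float
    normalized: float  # variation / mean duration_seconds of the set


def activity_complexity(recording: ActivityRecording) -> ComplexityResult:
    """Sum of distances between the recording and its s-second rotations.

    ``s`` runs over 1..floor(duration); each rotation shifts frames circularly
    by ``round(s * frame_rate)`` frames.  A shift equal to the full length is
    the identity and contributes zero.
    """
    duration = recording.duration_seconds
    if duration < 2.0:
        raise MetricError(
            f"recording {recording.recording_id!r} is {duration:.3f}s long; "
            "too short for the complexity metric (needs >= 2 s)"
        )
    base = flatten(recording.frames)
    n = recording.n_frames
    total = 0.0
    for s in range(1, int(math.floor(duration)) + 1):
        shift = round_half_up(s * recording.frame_rate) % n
        rotated = np.roll(recording.frames, -shift, axis=0)
        total += float(np.linalg.norm(base - flatten(rotated)))
    return ComplexityResult(complexity=total, normalized=total / duration)


def set_variation(
    recordings: Sequence[ActivityRecording], canonical_len: Optional[int] = None
) -> VariationResult:
    """Mean pairwise distance between length-normalized recordings.

    Each recording is resampled to ``canonical_len`` frames (default: the
    set's minimum length) and flattened; the metric averages the Euclidean
    distance over all unordered distinct pairs.
    """
    if len(recordings) < 2:
        raise MetricError("variation needs at least 2 recordings")
    if canonical_len is None:
        canonical_len = min(r.n_frames for r in recordings)
    vectors = np.stack([flatten(resample_frames(r.frames, canonical_len)) for r in recordings])
    variation = float(pdist(vectors).mean())
    mean_duration = float(np.mean([r.duration_seconds for r in recordings]))
    return VariationResult(variation=variation, normalized=variation / mean_duration)


def dataset_profile(dataset: LabeledDataset, canonical_len: Optional[int] = None) -> pd.DataFrame:
    """Per-activity metric table: mean Complexity and set Variation.

    Recordings shorter than 2 s are skipped for Complexity; labels with a
    single example get NaN Variation.
    """
    rows = []
    for label in dataset.activity_set:
        recs = dataset.by_label(label)
        comps = [activity_complexity(r) for r in recs if r.duration_seconds >= 2.0]
        if len(recs) >= 2:
            var = set_variation(recs, canonical_len)
            variation, variation_norm = var.variation, var.normalized
        else:
            variation = variation_norm = float("nan")
        rows.append(
            {
                "activity": label,
                "n_examples": len(recs),
                "complexity_mean": float(np.mean([c.complexity for c in comps])) if comps else float("nan"),
                "complexity_norm_mean": float(np.mean([c.normalized for c in comps])) if comps else float("nan"),
                "variation": variation,
                "variation_norm": variation_norm,
            }
        )
    return pd.DataFrame(rows)
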