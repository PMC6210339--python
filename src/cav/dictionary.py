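"""Training-phase motion extraction.

Each training recording is tiled with windows at four sizes (0.5, 1, 1.5 and
2 s) and three start offsets (0%, 25%, 50% of the window size); every window
is resampled to a common base length and flattened.  Windows are clustered
per activity with k-means (Euclidean distance), clusters with five or fewer
members are dropped, overlapping retained windows within each recording are
resolved largest-size-first, and a second k-means over all first-level
cluster centers builds the motion dictionary with full provenance from every
dictionary entry back to the clusters, and from every retained training
window to its motion ID.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Hashable, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from cav.config import RunConfig
from cav.core import ActivityRecording, LabeledDataset, resample_frames, round_half_up
from cav.errors import ModelError
from cav.metrics import flatten

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class Window:
    """One extracted window, resampled to the base length and flattened."""

    recording_id: str
    start_frame: int
    length_frames: int
    increment_fraction: float
    vector: np.ndarray  # length 36 * base_len

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.length_frames

    def overlaps(self, other: "Window") -> bool:
        return self.start_frame < other.end_frame and other.start_frame < self.end_frame


@dataclasses.dataclass
class MotionCluster:
    activity_label: str
    cluster_index: int
    windows: list[Window]
    centroid: np.ndarray
    radius: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.activity_label, self.cluster_index)

    @property
    def n_members(self) -> int:
        return len(self.windows)


@dataclasses.dataclass
class DictionaryEntry:
    motion_id: int
    centroid: np.ndarray
    radius: float
    provenance: list[tuple[str, int]]  # contributing (activity, cluster) keys


@dataclasses.dataclass
class MotionDictionary:
    """Motion vocabulary plus provenance.

    ``cluster_to_motion`` maps every contributing first-level cluster key to
    its motion ID; ``window_provenance`` maps a recording ID to its retained,
    overlap-resolved windows as ``(start_frame, length_frames, motion_id)``
    triples ordered by start.
    """

    entries: list[DictionaryEntry]
    base_len: int
    cluster_to_motion: dict[tuple[str, int], int]
    window_provenance: dict[str, list[tuple[int, int, int]]] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        ids = [e.motion_id for e in self.entries]
        if ids != list(range(len(ids))):
            raise ModelError("motion ids must be contiguous from 0")

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def centroid_matrix(self) -> np.ndarray:
        return np.stack([e.centroid for e in self.entries])

    @property
    def radii(self) -> np.ndarray:
        return np.array([e.radius for e in self.entries])


def window_count(n_frames: int, window_frames: int, offset: int) -> int:
    """Closed-form number of non-overlapping windows tiled from ``offset``."""
    if n_frames - offset < window_frames:
        return 0
    return (n_frames - offset) // window_frames


def segment_windows(
    recording: ActivityRecording,
    sizes_s: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    increments: Sequence[float] = (0.0, 0.25, 0.5),
    base_len: Optional[int] = None,
) -> list[Window]:
    """Tile a recording with multi-scale, multi-offset windows.

    For each size ``w`` (``round(w * frame_rate)`` frames) and increment
    fraction ``f``, non-overlapping windows start at
    ``round(f * frames) + k * frames`` while they fit.  Sizes that do not fit
    yield no windows.  Returns an empty list (with a warning) when even the
    smallest size does not fit.
    """
    if base_len is None:
        base_len = max(1, round_half_up(min(sizes_s) * recording.frame_rate))
    n = recording.n_frames
    out: list[Window] = []
    for size_s in sizes_s:
        frames_w = round_half_up(size_s * recording.frame_rate)
        if frames_w < 1 or frames_w > n:
            continue
        for frac in increments:
            offset = round_half_up(frac * frames_w)
            start = offset
            while start + frames_w <= n:
                vec = flatten(resample_frames(recording.frames[start : start + frames_w], base_len))
                out.append(
                    Window(
                        recording_id=recording.recording_id,
                        start_frame=start,
                        length_frames=frames_w,
                        increment_fraction=float(frac),
                        vector=vec,
                    )
                )
                start += frames_w
    if not out:
        logger.warning(
            "recording %r (%d frames) is shorter than the smallest window; no windows extracted",
            recording.recording_id,
            n,
        )
    return out


def cluster_activity_windows(
    windows: Sequence[Window],
    k: int,
    seed: int,
    activity_label: str = "",
    n_init: int = 10,
) -> list[MotionCluster]:
    """k-means over window vectors (Euclidean); centroids are member means."""
    if not windows:
        return []
    if k < 1:
        raise ModelError("k must be >= 1")
    if k > len(windows):
        logger.warning(
            "activity %r: k=%d > %d windows; reducing k", activity_label, k, len(windows)
        )
        k = len(windows)
    X = np.stack([w.vector for w in windows])
    if k == 1:
        labels = np.zeros(len(windows), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
    clusters = []
    for c in range(k):
        member_idx = np.flatnonzero(labels == c)
        if member_idx.size == 0:  # pragma: no cover - sklearn avoids empties
            continue
        members = [windows[i] for i in member_idx]
        centroid = X[member_idx].mean(axis=0)
        radius = float(np.linalg.norm(X[member_idx] - centroid, axis=1).max())
        clusters.append(
            MotionCluster(
                activity_label=activity_label,
                cluster_index=len(clusters),
                windows=members,
                centroid=centroid,
                radius=radius,
            )
        )
    return clusters


def prune_clusters(
    clusters: Sequence[MotionCluster], min_members: int = 6
) -> list[MotionCluster]:
    """Drop clusters with fewer than ``min_members`` windows (default: drop <= 5)."""
    kept = [c for c in clusters if c.n_members >= min_members]
    if clusters and not kept:
        logger.warning("all %d clusters dropped by pruning (min_members=%d)", len(clusters), min_members)
    return kept


def resolve_overlaps(
    tagged_windows: Sequence[tuple[Window, Hashable]],
) -> list[tuple[Window, Hashable]]:
    """Greedy overlap resolution for one recording's retained windows.

    Windows are processed in descending length (ties: earlier start, then
    lower increment fraction); a window is kept iff its frame interval shares
    no frame with an already-kept window.  Output is sorted by start frame.
    """
    rec_ids = {w.recording_id for w, _ in tagged_windows}
    if len(rec_ids) > 1:
        raise ModelError(f"overlap resolution expects one recording, got {sorted(rec_ids)}")
    order = sorted(
        tagged_windows,
        key=lambda t: (-t[0].length_frames, t[0].start_frame, t[0].increment_fraction),
    )
    kept: list[tuple[Window, Hashable]] = []
    for win, tag in order:
        if not any(win.overlaps(k) for k, _ in kept):
            kept.append((win, tag))
    kept.sort(key=lambda t: t[0].start_frame)
    return kept


def build_dictionary(
    clusters: Sequence[MotionCluster],
    k2: int,
    seed: int,
    base_len: int,
    n_init: int = 10,
) -> MotionDictionary:
    """Second-level k-means over first-level cluster centers.

    Similar motions from different activities merge into a single dictionary
    entry; ``cluster_to_motion`` records where each entry originated.  Entry
    radii cover all member clusters: ``max(center distance + member radius)``.
    """
    if not clusters:
        raise ModelError("cannot build a dictionary from zero clusters")
    centers = np.stack([c.centroid for c in clusters])
    if k2 > len(clusters):
        logger.warning("k2=%d > %d cluster centers; reducing", k2, len(clusters))
        k2 = len(clusters)
    if k2 == len(clusters):
        labels = np.arange(len(clusters))
    elif k2 == 1:
        labels = np.zeros(len(clusters), dtype=int)
    else:
        km = KMeans(n_clusters=k2, n_init=n_init, random_state=seed)
        labels = km.fit_predict(centers)

    # Re-index motion ids by order of first appearance for determinism.
    remap: dict[int, int] = {}
    for lab in labels:
        if int(lab) not in remap:
            remap[int(lab)] = len(remap)
    labels = np.array([remap[int(lab)] for lab in labels])

    entries: list[DictionaryEntry] = []
    cluster_to_motion: dict[tuple[str, int], int] = {}
    for motion_id in range(labels.max() + 1):
        member_idx = np.flatnonzero(labels == motion_id)
        members = [clusters[i] for i in member_idx]
        centroid = centers[member_idx].mean(axis=0)
        radius = max(
            float(np.linalg.norm(centroid - c.centroid)) + c.radius for c in members
        )
        entries.append(
            DictionaryEntry(
                motion_id=motion_id,
                centroid=centroid,
                radius=radius,
                provenance=[c.key for c in members],
            )
        )
        for c in members:
            cluster_to_motion[c.key] = motion_id
    return MotionDictionary(
        entries=entries, base_len=base_len, cluster_to_motion=cluster_to_motion
    )


def extract_dictionary(dataset: LabeledDataset, config: RunConfig) -> MotionDictionary:
    """Full training-phase extraction: windows -> clusters -> dictionary.

    Runs per-activity clustering and pruning, resolves window overlaps per
    recording, builds the second-level dictionary, and fills in window-level
    provenance so every training recording can be re-encoded as a motion-ID
    sequence.
    """
    if not dataset.recordings:
        raise ModelError("empty dataset")
    frame_rate = dataset.recordings[0].frame_rate
    base_len = config.resolve_base_len(frame_rate)

    surviving: list[MotionCluster] = []
    per_recording: dict[str, list[tuple[Window, tuple[str, int]]]] = {
        r.recording_id: [] for r in dataset.recordings
    }
    for label in dataset.activity_set:
        windows: list[Window] = []
        for rec in dataset.by_label(label):
            windows.extend(
                segment_windows(rec, config.sizes_s, config.increments, base_len)
            )
        if not windows:
            logger.warning("activity %r produced no windows", label)
            continue
        k = config.k_for_activity(len(windows))
        clusters = cluster_activity_windows(
            windows, k, seed=config.seed, activity_label=label, n_init=config.kmeans_n_init
        )
        kept = prune_clusters(clusters, config.prune_min_members)
        surviving.extend(kept)
        for cluster in kept:
            for win in cluster.windows:
                per_recording[win.recording_id].append((win, cluster.key))

    if not surviving:
        raise ModelError("no clusters survived pruning; dataset too small or threshold too high")

    k2 = config.k_for_dictionary(len(surviving))
    dictionary = build_dictionary(
        surviving, k2, seed=config.seed, base_len=base_len, n_init=config.kmeans_n_init
    )
    for rec_id, tagged in per_recording.items():
        resolved = resolve_overlaps(tagged) if tagged else []
        dictionary.window_provenance[rec_id] = [
            (w.start_frame, w.length_frames, dictionary.cluster_to_motion[key])
            for w, key in resolved
        ]
    return dictionary
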