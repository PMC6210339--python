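"""Motion-ID sequences and per-example features.

Training examples are re-encoded from the dictionary's window provenance;
observations are encoded by a greedy longest-window-first scan matched against
dictionary centroids within a radius threshold.  Each example is then
represented by a log-normalized tf-idf weighted motion histogram (with a stop
list covering the top 5% most frequent motions) and a Laplace-smoothed
first-order transition matrix plus initial-motion probabilities.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from typing import Optional, Sequence

import numpy as np

from cav.config import RunConfig
from cav.core import ActivityRecording, LabeledDataset, resample_frames, round_half_up
from cav.dictionary import MotionDictionary, extract_dictionary
from cav.errors import ModelError
from cav.metrics import flatten

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MotionSequence:
    recording_id: str
    ids: list[int]
    start_frames: list[int]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.start_frames):
            raise ModelError("ids and start_frames must be parallel")
        if any(b <= a for a, b in zip(self.start_frames, self.start_frames[1:])):
            raise ModelError("start_frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ids)


def encode_training_example(
    recording: ActivityRecording, dictionary: MotionDictionary
) -> MotionSequence:
    """Map a training recording's retained windows to motion IDs via provenance."""
    if recording.recording_id not in dictionary.window_provenance:
        raise ModelError(
            f"recording {recording.recording_id!r} was not part of dictionary training"
        )
    triples = sorted(dictionary.window_provenance[recording.recording_id])
    if not triples:
        logger.warning("recording %r has no retained windows", recording.recording_id)
    return MotionSequence(
        recording_id=recording.recording_id,
        ids=[m for _, _, m in triples],
        start_frames=[s for s, _, _ in triples],
    )


def encode_observation(
    recording: ActivityRecording,
    dictionary: MotionDictionary,
    tau: float = 1.0,
    step_fraction: float = 0.25,
    sizes_s: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
) -> MotionSequence:
    """Greedy left-to-right encoding of an unlabeled observation.

    At each cursor position window sizes are tried longest first; a window
    matches when its distance to the nearest centroid is within ``tau`` times
    that entry's radius.  On a match the cursor jumps to the window's end;
    otherwise it advances by ``round(step_fraction * smallest_window)``
    frames.  The scan stops once the smallest window no longer fits.
    """
    size_frames = sorted(
        {round_half_up(s * recording.frame_rate) for s in sizes_s}, reverse=True
    )
    size_frames = [f for f in size_frames if f >= 1]
    if not size_frames:
        raise ModelError("no usable window sizes")
    smallest = size_frames[-1]
    step = max(1, round_half_up(step_fraction * smallest))
    centroids = dictionary.centroid_matrix
    radii = dictionary.radii

    ids: list[int] = []
    starts: list[int] = []
    cursor = 0
    n = recording.n_frames
    while cursor + smallest <= n:
        matched = False
        for frames_w in size_frames:
            if cursor + frames_w > n:
                continue
            vec = flatten(
                resample_frames(recording.frames[cursor : cursor + frames_w], dictionary.base_len)
            )
            dists = np.linalg.norm(centroids - vec, axis=1)
            j = int(np.argmin(dists))
            if dists[j] <= tau * radii[j] + 1e-9:
                ids.append(j)
                starts.append(cursor)
                cursor += frames_w
                matched = True
                break
        if not matched:
            cursor += step
    return MotionSequence(recording_id=recording.recording_id, ids=ids, start_frames=starts)


def motion_histogram(ids: Sequence[int], vocabulary_size: int) -> np.ndarray:
    """Occurrence counts per motion ID; sums to ``len(ids)``."""
    return np.bincount(np.asarray(ids, dtype=int), minlength=vocabulary_size).astype(float)


@dataclasses.dataclass
class TfidfModel:
    """Corpus statistics for log-normalized tf-idf plus the stop list.

    ``stop_list`` holds the ``floor(stop_fraction * V)`` motions with the
    largest total corpus count (ties: lower ID first); ``active_ids`` are the
    remaining vocabulary coordinates, in increasing ID order.
    """

    doc_freq: np.ndarray
    n_docs: int
    idf: np.ndarray
    stop_list: tuple[int, ...]
    active_ids: np.ndarray

    @property
    def vocabulary_size(self) -> int:
        return int(self.doc_freq.shape[0])


def fit_tfidf(count_vectors: Sequence[np.ndarray], stop_fraction: float = 0.05) -> TfidfModel:
    """Fit document frequencies, idf weights and the stop list.

    ``idf(t) = ln(N / df(t))``; motions never seen (df = 0) get idf 0, as do
    motions present in every document.
    """
    if not count_vectors:
        raise ModelError("need at least one histogram")
    counts = np.stack(count_vectors)
    n_docs = counts.shape[0]
    vocab = counts.shape[1]
    doc_freq = (counts > 0).sum(axis=0)
    with np.errstate(divide="ignore"):
        idf = np.where(doc_freq > 0, np.log(n_docs / np.maximum(doc_freq, 1)), 0.0)
    totals = counts.sum(axis=0)
    n_stop = int(math.floor(stop_fraction * vocab))
    order = sorted(range(vocab), key=lambda t: (-totals[t], t))
    stop_list = tuple(sorted(order[:n_stop]))
    active = np.array([t for t in range(vocab) if t not in set(stop_list)], dtype=int)
    return TfidfModel(
        doc_freq=doc_freq.astype(float),
        n_docs=n_docs,
        idf=idf,
        stop_list=stop_list,
        active_ids=active,
    )


def apply_tfidf(counts: np.ndarray, model: TfidfModel) -> np.ndarray:
    """Weight a count vector: ``(1 + ln(count)) * idf`` and drop stop-list coords."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (model.vocabulary_size,):
        raise ModelError(
            f"count vector has shape {counts.shape}, expected ({model.vocabulary_size},)"
        )
    with np.errstate(divide="ignore"):
        tf = np.where(counts > 0, 1.0 + np.log(np.maximum(counts, 1e-300)), 0.0)
    weighted = tf * model.idf
    return weighted[model.active_ids]


def transition_matrix(
    ids: Sequence[int], vocabulary_size: int, alpha: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Laplace-smoothed first-order transition matrix and initial probabilities.

    ``trans[a, b] = (#(a->b) + alpha) / (#a_as_source + alpha * V)`` and
    ``init[a] = (count(a) + alpha) / (n + alpha * V)``; both strictly positive
    and normalized for any sequence, including the empty one (uniform rows).
    """
    if alpha <= 0:
        raise ModelError("alpha must be > 0")
    V = vocabulary_size
    seq = np.asarray(ids, dtype=int)
    pair_counts = np.zeros((V, V))
    if seq.size >= 2:
        np.add.at(pair_counts, (seq[:-1], seq[1:]), 1.0)
    source_counts = pair_counts.sum(axis=1)
    trans = (pair_counts + alpha) / (source_counts[:, None] + alpha * V)
    init = (motion_histogram(seq, V) + alpha) / (seq.size + alpha * V)
    return trans, init


@dataclasses.dataclass
class ActivityRepresentation:
    """Per-training-example features used at inference time."""

    recording_id: str
    label: str
    hist: np.ndarray  # tf-idf weighted, stop-list coordinates removed
    trans: np.ndarray  # (V, V) row-stochastic
    init: np.ndarray  # (V,) probability vector


@dataclasses.dataclass
class CavModel:
    """A trained classifier: dictionary + tf-idf model + example representations."""

    dictionary: MotionDictionary
    tfidf: TfidfModel
    representations: list[ActivityRepresentation]
    config: RunConfig
    frame_rate: float

    @property
    def labels(self) -> list[str]:
        return sorted({r.label for r in self.representations})

    def representations_for(self, label: str) -> list[ActivityRepresentation]:
        return [r for r in self.representations if r.label == label]


def train_model(dataset: LabeledDataset, config: Optional[RunConfig] = None) -> CavModel:
    """Run the full training phase on a labeled dataset."""
    config = config or RunConfig()
    dictionary = extract_dictionary(dataset, config)
    V = dictionary.size
    sequences = [encode_training_example(r, dictionary) for r in dataset.recordings]
    counts = [motion_histogram(s.ids, V) for s in sequences]
    tfidf = fit_tfidf(counts, config.stop_fraction)
    representations = []
    for rec, seq, cnt in zip(dataset.recordings, sequences, counts):
        trans, init = transition_matrix(seq.ids, V, config.alpha)
        representations.append(
            ActivityRepresentation(
                recording_id=rec.recording_id,
                label=rec.label,
                hist=apply_tfidf(cnt, tfidf),
                trans=trans,
                init=init,
            )
        )
    return CavModel(
        dictionary=dictionary,
        tfidf=tfidf,
        representations=representations,
        config=config,
        frame_rate=dataset.recordings[0].frame_rate,
    )


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: CavModel) -> dict:
    return {
        "config": model.config.to_dict(),
        "frame_rate": model.frame_rate,
        "dictionary": {
            "base_len": model.dictionary.base_len,
            "entries": [
                {
                    "motion_id": e.motion_id,
                    "centroid": e.centroid.tolist(),
                    "radius": e.radius,
                    "provenance": [list(p) for p in e.provenance],
                }
                for e in model.dictionary.entries
            ],
            "cluster_to_motion": [
                [label, idx, mid]
                for (label, idx), mid in sorted(model.dictionary.cluster_to_motion.items())
            ],
            "window_provenance": {
                rid: [list(t) for t in triples]
                for rid, triples in model.dictionary.window_provenance.items()
            },
        },
        "tfidf": {
            "doc_freq": model.tfidf.doc_freq.tolist(),
            "n_docs": model.tfidf.n_docs,
            "idf": model.tfidf.idf.tolist(),
            "stop_list": list(model.tfidf.stop_list),
            "active_ids": model.tfidf.active_ids.tolist(),
        },
        "representations": [
            {
                "recording_id": r.recording_id,
                "label": r.label,
                "hist": r.hist.tolist(),
                "trans": r.trans.tolist(),
                "init": r.init.tolist(),
            }
            for r in model.representations
        ],
    }


def model_from_dict(data: dict) -> CavModel:
    from cav.dictionary import DictionaryEntry

    d = data["dictionary"]
    dictionary = MotionDictionary(
        entries=[
            DictionaryEntry(
                motion_id=e["motion_id"],
                centroid=np.array(e["centroid"]),
                radius=e["radius"],
                provenance=[tuple(p) for p in e["provenance"]],
            )
            for e in d["entries"]
        ],
        base_len=d["base_len"],
        cluster_to_motion={(label, idx): mid for label, idx, mid in d["cluster_to_motion"]},
        window_provenance={
            rid: [tuple(t) for t in triples] for rid, triples in d["window_provenance"].items()
        },
    )
    t = data["tfidf"]
    tfidf = TfidfModel(
        doc_freq=np.array(t["doc_freq"]),
        n_docs=t["n_docs"],
        idf=np.array(t["idf"]),
        stop_list=tuple(t["stop_list"]),
        active_ids=np.array(t["active_ids"], dtype=int),
    )
    reps = [
        ActivityRepresentation(
            recording_id=r["recording_id"],
            label=r["label"],
            hist=np.array(r["hist"]),
            trans=np.array(r["trans"]),
            init=np.array(r["init"]),
        )
        for r in data["representations"]
    ]
    return CavModel(
        dictionary=dictionary,
        tfidf=tfidf,
        representations=reps,
        config=RunConfig.from_dict(data["config"]),
        frame_rate=data["frame_rate"],
    )


def save_model(model: CavModel, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path: str) -> CavModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
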