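"""Classification cost and the evaluation harness.

An observation is scored against every training representation with
``cost = histDiff / seqProb``: the Euclidean distance between tf-idf weighted
histograms divided by the probability of the observed motion sequence under
the representation's initial + transition model.  Costs are averaged per
activity (in the log domain, since seqProb underflows for long sequences) and
the activity with the lowest average cost wins.

Evaluation protocols: leave-one-out cross-validation with a full retrain per
fold, a narrowed-variation split (train on the least-varied two-thirds of
each activity), and repeated random subject holdout.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from cav.config import RunConfig
from cav.core import ActivityRecording, LabeledDataset
from cav.errors import ModelError
from cav.metrics import flatten, set_variation
from cav.representation import (
    ActivityRepresentation,
    CavModel,
    MotionSequence,
    apply_tfidf,
    encode_observation,
    motion_histogram,
    train_model,
)

logger = logging.getLogger(__name__)


def hist_diff(h1: np.ndarray, h2: np.ndarray) -> float:
    """Euclidean distance between two weighted histograms."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != h2.shape:
        raise ModelError(f"histogram shapes differ: {h1.shape} vs {h2.shape}")
    return float(np.linalg.norm(h1 - h2))


def seq_prob(ids: Sequence[int], rep: ActivityRepresentation) -> float:
    """Log probability of a motion-ID sequence under a representation.

    ``log Pr = log init[m1] + sum_i log trans[m_{i-1}, m_i]``; finite for any
    sequence because the representation is smoothed.
    """
    seq = np.asarray(ids, dtype=int)
    if seq.size == 0:
        raise ModelError("sequence probability of an empty sequence is undefined")
    logp = math.log(rep.init[seq[0]])
    if seq.size > 1:
        logp += float(np.sum(np.log(rep.trans[seq[:-1], seq[1:]])))
    return logp


@dataclasses.dataclass(frozen=True)
class CostBreakdown:
    hist_diff: float
    log_seq_prob: float
    cost: float  # hist_diff / exp(log_seq_prob), +inf on overflow, 0 iff hist_diff == 0

    @property
    def log_cost(self) -> float:
        if self.hist_diff == 0.0:
            return -math.inf
        return math.log(self.hist_diff) - self.log_seq_prob


def observation_cost(
    obs_hist: np.ndarray,
    obs_ids: Sequence[int],
    rep: ActivityRepresentation,
    empty_policy: str = "fallback",
) -> CostBreakdown:
    """Cost of one observation against one training representation.

    With an empty observation sequence the seqProb term is replaced by the
    smoothed floor ``1/V`` under the default ``fallback`` policy, or raises
    under ``strict``.
    """
    hd = hist_diff(obs_hist, rep.hist)
    if len(obs_ids) == 0:
        if empty_policy == "strict":
            raise ModelError("empty observation sequence (strict policy)")
        logger.warning("empty observation sequence; using smoothed seqProb floor")
        lsp = -math.log(rep.init.shape[0])
    else:
        lsp = seq_prob(obs_ids, rep)
    if hd == 0.0:
        return CostBreakdown(hist_diff=0.0, log_seq_prob=lsp, cost=0.0)
    log_cost = math.log(hd) - lsp
    cost = math.exp(log_cost) if log_cost < 709.0 else math.inf
    return CostBreakdown(hist_diff=hd, log_seq_prob=lsp, cost=cost)


@dataclasses.dataclass
class ClassificationResult:
    predicted_label: str
    activity_costs: dict[str, float]
    per_example_costs: dict[str, list[CostBreakdown]]
    sequence: MotionSequence


def classify(recording: ActivityRecording, model: CavModel) -> ClassificationResult:
    """Encode an observation and match it to the lowest-average-cost activity."""
    if not model.representations:
        raise ModelError("model has no training representations")
    cfg = model.config
    seq = encode_observation(
        recording,
        model.dictionary,
        tau=cfg.tau,
        step_fraction=cfg.step_fraction,
        sizes_s=cfg.sizes_s,
    )
    if len(seq) == 0 and cfg.empty_observation_policy == "fallback":
        logger.warning(
            "observation %r matched nothing at tau=%g; falling back to nearest-centroid",
            recording.recording_id,
            cfg.tau,
        )
        seq = encode_observation(
            recording,
            model.dictionary,
            tau=math.inf,
            step_fraction=cfg.step_fraction,
            sizes_s=cfg.sizes_s,
        )
    counts = motion_histogram(seq.ids, model.dictionary.size)
    obs_hist = apply_tfidf(counts, model.tfidf)

    activity_costs: dict[str, float] = {}
    activity_log_costs: dict[str, float] = {}
    per_example: dict[str, list[CostBreakdown]] = {}
    for label in model.labels:
        reps = model.representations_for(label)
        breakdowns = [
            observation_cost(obs_hist, seq.ids, r, cfg.empty_observation_policy) for r in reps
        ]
        per_example[label] = breakdowns
        log_costs = np.array([b.log_cost for b in breakdowns])
        # mean on the linear scale, accumulated in the log domain
        log_mean = float(logsumexp(log_costs)) - math.log(len(log_costs))
        activity_log_costs[label] = log_mean
        activity_costs[label] = math.exp(log_mean) if log_mean < 709.0 else math.inf
    predicted = min(model.labels, key=lambda lab: (activity_log_costs[lab], lab))
    return ClassificationResult(
        predicted_label=predicted,
        activity_costs=activity_costs,
        per_example_costs=per_example,
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionMatrix:
    labels: list[str]
    counts: np.ndarray  # (K, K) rows = truth, cols = prediction
    percentages: np.ndarray  # row-normalized to 100
    overall_accuracy: float  # percent

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[str, str]], labels: Optional[Sequence[str]] = None
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = sorted({t for t, _ in pairs} | {p for _, p in pairs})
        labels = list(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)))
        for truth, pred in pairs:
            counts[index[truth], index[pred]] += 1
        return cls.from_counts(labels, counts)

    @classmethod
    def from_counts(cls, labels: Sequence[str], counts: np.ndarray) -> "ConfusionMatrix":
        counts = np.asarray(counts, dtype=float)
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
        total = counts.sum()
        acc = 100.0 * float(np.trace(counts)) / total if total > 0 else float("nan")
        return cls(labels=list(labels), counts=counts, percentages=pct, overall_accuracy=acc)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "counts": self.counts.tolist(),
            "percentages": self.percentages.tolist(),
            "overall_accuracy": self.overall_accuracy,
            "chance_ratio": chance_ratio(self.overall_accuracy, len(self.labels)),
        }


def chance_ratio(accuracy_percent: float, n_classes: int) -> float:
    """How many times better than uniform chance an accuracy is."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return accuracy_percent / (100.0 / n_classes)


def printed_chance_ratio(accuracy_percent: float, n_classes: int, decimals: int = 2) -> float:
    """Chance ratio truncated (not rounded) to ``decimals`` places.

    Matches the convention of reported figures such as 93.33% -> 7.46x for
    8 classes (7.4664 truncates to 7.46).
    """
    scale = 10**decimals
    return math.floor(chance_ratio(accuracy_percent, n_classes) * scale) / scale


# ---------------------------------------------------------------------------
# evaluation protocols
# ---------------------------------------------------------------------------

def evaluate_loocv(dataset: LabeledDataset, config: Optional[RunConfig] = None) -> ConfusionMatrix:
    """Leave-one-out cross-validation with a full retrain per fold."""
    config = config or RunConfig()
    usable = []
    for label in dataset.activity_set:
        recs = dataset.by_label(label)
        if len(recs) < 2:
            logger.warning("label %r has a single example; excluded from LOOCV", label)
            continue
        usable.extend(recs)
    if not usable:
        raise ModelError("no label has >= 2 examples")
    eligible = dataset.subset(usable)
    pairs = []
    for held_out in eligible.recordings:
        train_set = eligible.subset(r for r in eligible.recordings if r.recording_id != held_out.recording_id)
        model = train_model(train_set, config)
        pairs.append((held_out.label, classify(held_out, model).predicted_label))
    return ConfusionMatrix.from_pairs(pairs, labels=eligible.activity_set)


def narrowed_variation_split(
    dataset: LabeledDataset,
    fraction: float = 2 / 3,
    canonical_len: Optional[int] = None,
    selector: Optional[Callable[[list[ActivityRecording]], list[ActivityRecording]]] = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Per activity, pick the ``fraction`` of examples with the narrowest variation.

    Default selector: greedily remove the example with the largest mean
    distance to the rest (on length-normalized flattened recordings) until the
    target size is reached — minimizing the retained subset's variation.
    A custom ``selector`` may replace this policy.
    """
    train: list[ActivityRecording] = []
    test: list[ActivityRecording] = []
    for label in dataset.activity_set:
        recs = dataset.by_label(label)
        target = max(1, int(round(fraction * len(recs))))
        if selector is not None:
            chosen = selector(recs)
        else:
            chosen = _narrowest_subset(recs, target, canonical_len)
        chosen_ids = {r.recording_id for r in chosen}
        train.extend(r for r in recs if r.recording_id in chosen_ids)
        test.extend(r for r in recs if r.recording_id not in chosen_ids)
    return dataset.subset(train), dataset.subset(test)


def _narrowest_subset(
    recs: list[ActivityRecording], target: int, canonical_len: Optional[int]
) -> list[ActivityRecording]:
    if len(recs) <= target:
        return list(recs)
    if canonical_len is None:
        canonical_len = min(r.n_frames for r in recs)
    from cav.core import resample_frames

    vectors = np.stack([flatten(resample_frames(r.frames, canonical_len)) for r in recs])
    dist = np.linalg.norm(vectors[:, None, :] - vectors[None, :, :], axis=2)
    alive = list(range(len(recs)))
    while len(alive) > target:
        sub = dist[np.ix_(alive, alive)]
        mean_dist = sub.sum(axis=1) / (len(alive) - 1)
        alive.pop(int(np.argmax(mean_dist)))
    return [recs[i] for i in alive]


def evaluate_split(
    train_set: LabeledDataset,
    test_set: LabeledDataset,
    config: Optional[RunConfig] = None,
) -> ConfusionMatrix:
    """Train once on ``train_set`` and classify every ``test_set`` recording."""
    config = config or RunConfig()
    model = train_model(train_set, config)
    pairs = [(r.label, classify(r, model).predicted_label) for r in test_set.recordings]
    return ConfusionMatrix.from_pairs(pairs, labels=train_set.activity_set)


def evaluate_narrowed_variation(
    dataset: LabeledDataset,
    config: Optional[RunConfig] = None,
    fraction: float = 2 / 3,
) -> ConfusionMatrix:
    """Train on the narrowest-variation subset, test on the held-out variations."""
    train_set, test_set = narrowed_variation_split(dataset, fraction)
    return evaluate_split(train_set, test_set, config)


def evaluate_subject_holdout(
    dataset: LabeledDataset,
    config: Optional[RunConfig] = None,
    train_fraction: float = 2 / 3,
    repeats: int = 20,
    seed: int = 0,
    subject_groups: Optional[dict[str, str]] = None,
) -> ConfusionMatrix:
    """Repeated random subject holdout, averaged cell-wise over repeats.

    When ``subject_groups`` maps subject IDs to strata (e.g. gender), the
    split keeps each stratum's proportions in the training set.
    """
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ModelError("subject holdout needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    labels = dataset.activity_set
    pct_sum = np.zeros((len(labels), len(labels)))
    counts_sum = np.zeros((len(labels), len(labels)))
    accs = []
    for _ in range(repeats):
        train_subjects = _sample_subjects(subjects, train_fraction, rng, subject_groups)
        train_set = dataset.subset(r for r in dataset.recordings if r.subject_id in train_subjects)
        test_set = dataset.subset(r for r in dataset.recordings if r.subject_id not in train_subjects)
        if not train_set.recordings or not test_set.recordings:
            raise ModelError("degenerate subject split; adjust train_fraction")
        cm = evaluate_split(train_set, test_set, config)
        pct_sum += cm.percentages
        counts_sum += cm.counts
        accs.append(cm.overall_accuracy)
    avg = ConfusionMatrix(
        labels=labels,
        counts=counts_sum,
        percentages=pct_sum / repeats,
        overall_accuracy=float(np.mean(accs)),
    )
    return avg


def _sample_subjects(
    subjects: list[str],
    train_fraction: float,
    rng: np.random.Generator,
    subject_groups: Optional[dict[str, str]],
) -> set[str]:
    if subject_groups is None:
        n_train = max(1, min(len(subjects) - 1, int(round(train_fraction * len(subjects)))))
        return set(rng.choice(subjects, size=n_train, replace=False).tolist())
    chosen: set[str] = set()
    for group in sorted({subject_groups.get(s, "") for s in subjects}):
        members = [s for s in subjects if subject_groups.get(s, "") == group]
        n_train = max(1, min(len(members) - 1, int(round(train_fraction * len(members))))) if len(members) > 1 else len(members)
        chosen |= set(rng.choice(members, size=n_train, replace=False).tolist())
    return chosen
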