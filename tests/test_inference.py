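import math

import numpy as np
import pytest

from cav.config import RunConfig
from cav.errors import ModelError
from cav.inference import (
    ClassificationResult,
    ConfusionMatrix,
    chance_ratio,
    classify,
    evaluate_loocv,
    evaluate_split,
    evaluate_subject_holdout,
    hist_diff,
    narrowed_variation_split,
    observation_cost,
    printed_chance_ratio,
    seq_prob,
)
from cav.representation import ActivityRepresentation, train_model
from cav.synthdata import generate_dataset
from conftest import make_dataset


def make_rep(init, trans, hist=None, label="a"):
    init = np.asarray(init, dtype=float)
    trans = np.asarray(trans, dtype=float)
    if hist is None:
        hist = np.zeros(2)
    return ActivityRepresentation(
        recording_id="train01", label=label, hist=np.asarray(hist, dtype=float), trans=trans, init=init
    )


class TestHistDiff:
    def test_identical_zero(self):
        h = np.array([1.0, 2.0, 3.0])
        assert hist_diff(h, h) == 0.0

    def test_three_four_five(self):
        assert hist_diff(np.array([3.0, 0.0]), np.array([0.0, 4.0])) == pytest.approx(5.0)

    def test_symmetry(self, rng):
        h1, h2 = rng.normal(size=8), rng.normal(size=8)
        assert hist_diff(h1, h2) == pytest.approx(hist_diff(h2, h1))

    def test_dimension_mismatch(self):
        with pytest.raises(ModelError):
            hist_diff(np.zeros(3), np.zeros(4))


class TestSeqProb:
    def test_single_motion_is_log_init(self):
        rep = make_rep([0.2, 0.8], [[0.5, 0.5], [0.5, 0.5]])
        assert seq_prob([0], rep) == pytest.approx(math.log(0.2))

    def test_hand_product(self):
        rep = make_rep([0.2, 0.8], [[0.5, 0.5], [0.5, 0.5]])
        assert seq_prob([0, 1], rep) == pytest.approx(math.log(0.1))

    def test_always_nonpositive(self, rng):
        from cav.representation import transition_matrix

        ids = rng.integers(0, 4, size=20).tolist()
        trans, init = transition_matrix(ids, 4, alpha=0.5)
        rep = make_rep(init, trans)
        assert seq_prob(ids, rep) <= 0.0

    def test_empty_sequence_rejected(self):
        rep = make_rep([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]])
        with pytest.raises(ModelError):
            seq_prob([], rep)


class TestObservationCost:
    def test_zero_hist_diff_zero_cost(self):
        rep = make_rep([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], hist=[1.0, 2.0])
        b = observation_cost(np.array([1.0, 2.0]), [0], rep)
        assert b.cost == 0.0
        assert b.log_cost == -math.inf

    def test_hand_division(self):
        # hist_diff 2 against seqProb 0.5 -> cost 4
        rep = make_rep([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], hist=[2.0, 0.0])
        b = observation_cost(np.array([0.0, 0.0]), [0], rep)
        assert b.hist_diff == pytest.approx(2.0)
        assert b.cost == pytest.approx(4.0)

    def test_monotone_in_seq_prob(self):
        rep_hi = make_rep([0.9, 0.1], [[0.5, 0.5], [0.5, 0.5]], hist=[2.0, 0.0])
        rep_lo = make_rep([0.1, 0.9], [[0.5, 0.5], [0.5, 0.5]], hist=[2.0, 0.0])
        obs = np.array([0.0, 0.0])
        assert observation_cost(obs, [0], rep_lo).cost > observation_cost(obs, [0], rep_hi).cost

    def test_overflow_guarded(self):
        rep = make_rep([1e-300, 1.0], [[1e-300, 1.0], [1e-300, 1.0]], hist=[2.0, 0.0])
        b = observation_cost(np.array([0.0, 0.0]), [0, 0, 0], rep)
        assert b.cost == math.inf

    def test_empty_sequence_policies(self):
        rep = make_rep([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], hist=[2.0, 0.0])
        b = observation_cost(np.array([0.0, 0.0]), [], rep, empty_policy="fallback")
        assert b.log_seq_prob == pytest.approx(-math.log(2))
        with pytest.raises(ModelError):
            observation_cost(np.array([0.0, 0.0]), [], rep, empty_policy="strict")


@pytest.fixture(scope="module")
def separable():
    ds, truth = generate_dataset(
        n_activities=3, n_subjects=5, variation_level=0.1, seed=21, frame_rate=15.0
    )
    model = train_model(ds, RunConfig(seed=21, kmeans_n_init=2))
    return ds, truth, model


class TestClassify:
    def test_training_example_self_consistency(self, separable):
        ds, _, model = separable
        rec = ds.recordings[0]
        result = classify(rec, model)
        assert isinstance(result, ClassificationResult)
        assert result.predicted_label == rec.label

    def test_costs_cover_all_labels(self, separable):
        ds, _, model = separable
        result = classify(ds.recordings[-1], model)
        assert set(result.activity_costs) == set(ds.activity_set)
        assert all(c >= 0 for c in result.activity_costs.values())

    def test_single_activity_model_always_wins(self):
        ds, _ = generate_dataset(n_activities=1, n_subjects=5, variation_level=0.2, seed=3, frame_rate=15.0)
        model = train_model(ds, RunConfig(seed=3, kmeans_n_init=2))
        for rec in ds.recordings[:3]:
            assert classify(rec, model).predicted_label == ds.activity_set[0]

    def test_fresh_examples_disjoint_vocabularies_all_correct(self):
        # two activities with no shared primitives: fresh draws classify perfectly
        ds, truth = generate_dataset(
            n_activities=2, n_subjects=5, variation_level=0.1, seed=21, frame_rate=15.0,
            n_shared=0,
        )
        model = train_model(ds, RunConfig(seed=21, kmeans_n_init=2))
        fresh, _ = generate_dataset(
            n_activities=2, n_subjects=3, variation_level=0.1, seed=99, frame_rate=15.0,
            primitives=truth.primitives, grammars=truth.grammars,
        )
        correct = sum(classify(r, model).predicted_label == r.label for r in fresh.recordings)
        assert correct == len(fresh)


class TestConfusionMatrix:
    def test_rows_sum_to_100(self):
        cm = ConfusionMatrix.from_pairs([("a", "a"), ("a", "b"), ("b", "b")])
        np.testing.assert_allclose(cm.percentages.sum(axis=1), [100.0, 100.0], atol=1e-6)

    def test_accuracy_trace(self):
        cm = ConfusionMatrix.from_pairs([("a", "a"), ("a", "b"), ("b", "b"), ("b", "b")])
        assert cm.overall_accuracy == pytest.approx(75.0)

    def test_chance_ratio(self):
        assert chance_ratio(50.0, 8) == pytest.approx(4.0)
        assert printed_chance_ratio(93.33, 8) == 7.46  # 7.4664 truncated
        assert printed_chance_ratio(60.0, 8) == 4.8


class TestEvaluation:
    def test_loocv_perfect_on_separable(self):
        ds, _ = generate_dataset(n_activities=2, n_subjects=3, variation_level=0.0, seed=5, frame_rate=15.0)
        cm = evaluate_loocv(ds, RunConfig(seed=5, kmeans_n_init=2))
        assert cm.overall_accuracy == pytest.approx(100.0)
        np.testing.assert_allclose(cm.percentages, 100.0 * np.eye(2), atol=1e-9)

    def test_loocv_excludes_singleton_labels(self, rng):
        ds, _ = generate_dataset(n_activities=2, n_subjects=3, variation_level=0.0, seed=5, frame_rate=15.0)
        lonely = generate_dataset(n_activities=1, n_subjects=1, variation_level=0.0, seed=77, frame_rate=15.0)[0]
        lone = lonely.recordings[0]
        lone.label = "lonely"
        lone.recording_id = "lonely_rec"
        merged = make_dataset(ds.recordings + [lone])
        cm = evaluate_loocv(merged, RunConfig(seed=5, kmeans_n_init=2))
        assert "lonely" not in cm.labels

    def test_holdout_deterministic_given_seed(self):
        ds, _ = generate_dataset(n_activities=2, n_subjects=4, variation_level=0.2, seed=6, frame_rate=15.0)
        cfg = RunConfig(seed=6, kmeans_n_init=2)
        cm1 = evaluate_subject_holdout(ds, cfg, repeats=1, seed=6)
        cm2 = evaluate_subject_holdout(ds, cfg, repeats=1, seed=6)
        np.testing.assert_array_equal(cm1.percentages, cm2.percentages)

    def test_holdout_average_of_identical_matrices(self):
        # variation 0: every repeat yields the same perfect matrix
        ds, _ = generate_dataset(n_activities=2, n_subjects=4, variation_level=0.0, seed=6, frame_rate=15.0)
        cfg = RunConfig(seed=6, kmeans_n_init=2)
        cm = evaluate_subject_holdout(ds, cfg, repeats=3, seed=6)
        np.testing.assert_allclose(cm.percentages, 100.0 * np.eye(2), atol=1e-9)

    def test_holdout_stratified_groups(self):
        ds, _ = generate_dataset(n_activities=2, n_subjects=6, variation_level=0.1, seed=6, frame_rate=15.0)
        groups = {s: ("f" if i % 2 else "m") for i, s in enumerate(ds.subjects)}
        cfg = RunConfig(seed=6, kmeans_n_init=2)
        cm = evaluate_subject_holdout(ds, cfg, repeats=1, seed=6, subject_groups=groups)
        assert 0.0 <= cm.overall_accuracy <= 100.0

    def test_narrowed_split_sizes(self):
        ds, _ = generate_dataset(n_activities=2, n_subjects=6, variation_level=0.5, seed=8, frame_rate=15.0)
        train, test = narrowed_variation_split(ds, fraction=2 / 3)
        for label in ds.activity_set:
            assert len(train.by_label(label)) == 4
            assert len(test.by_label(label)) == 2

    def test_narrowed_split_minimizes_variation(self):
        from cav.metrics import set_variation

        ds, _ = generate_dataset(n_activities=1, n_subjects=8, variation_level=0.8, seed=8, frame_rate=15.0)
        train, _ = narrowed_variation_split(ds, fraction=0.5)
        label = ds.activity_set[0]
        n = min(r.n_frames for r in ds.recordings)
        narrow = set_variation(train.by_label(label), canonical_len=n).variation
        full = set_variation(ds.by_label(label), canonical_len=n).variation
        assert narrow < full

    def test_relabeling_equivariance(self):
        ds, _ = generate_dataset(n_activities=2, n_subjects=3, variation_level=0.0, seed=12, frame_rate=15.0)
        cfg = RunConfig(seed=12, kmeans_n_init=2)
        model = train_model(ds, cfg)
        preds = [classify(r, model).predicted_label for r in ds.recordings]
        # permute labels and retrain: predictions must permute accordingly
        mapping = {"activity00": "zebra", "activity01": "ant"}
        for r in ds.recordings:
            r.label = mapping[r.label]
        model2 = train_model(make_dataset(ds.recordings), cfg)
        preds2 = [classify(r, model2).predicted_label for r in ds.recordings]
        assert preds2 == [mapping[p] for p in preds]
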