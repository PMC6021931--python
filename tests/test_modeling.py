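"""Splits, scaling, the Rprop perceptron, and double cross-validation."""

import numpy as np
import pandas as pd
import pytest

import chromclass as cc
from chromclass.modeling import (
    MLPConfig,
    averaged_confusion,
    ccr,
    confusion_counts,
    default_search_space,
    grouped_stratified_split,
    make_partition_plans,
    one_hot,
    run_cv,
    select_architecture,
    standardize,
    train_mlp,
)


def _manifest(class_sizes=(11, 27, 36, 27), reps=3):
    rows = []
    k = 0
    for cls, n in enumerate(class_sizes, start=1):
        for _ in range(n):
            k += 1
            for r in range(1, reps + 1):
                rows.append(
                    {"sample_id": f"S{k:03d}", "replicate_id": r, "class_label": cls}
                )
    return pd.DataFrame(rows)


class TestGroupedStratifiedSplit:
    def test_class_of_27_sends_19_oils_to_training(self):
        plan = grouped_stratified_split(_manifest(), rng=np.random.default_rng(0))
        class2 = [f"S{i:03d}" for i in range(12, 39)]  # the 27 oils of class 2
        n_train = sum(plan.assignment[s] == "train" for s in class2)
        assert n_train == 19

    def test_per_class_counts_follow_rounding_rule(self):
        plan = grouped_stratified_split(_manifest(), rng=np.random.default_rng(1))
        manifest = _manifest()
        oils = manifest.drop_duplicates("sample_id")
        expected = {1: (8, 1, 2), 2: (19, 3, 5), 3: (25, 4, 7), 4: (19, 3, 5)}
        for cls, grp in oils.groupby("class_label"):
            got = tuple(
                sum(plan.assignment[s] == sub for s in grp["sample_id"])
                for sub in ("train", "internal_validation", "external_validation")
            )
            assert got == expected[cls]

    def test_partition_is_disjoint_and_exhaustive(self):
        manifest = _manifest()
        plan = grouped_stratified_split(manifest, rng=np.random.default_rng(2))
        assert len(plan.assignment) == 101
        masks = [
            plan.row_mask(manifest, s)
            for s in ("train", "internal_validation", "external_validation")
        ]
        total = np.sum(masks, axis=0)
        assert (total == 1).all()

    def test_replicates_share_a_subset(self):
        manifest = _manifest()
        plan = grouped_stratified_split(manifest, rng=np.random.default_rng(3))
        subsets = manifest["sample_id"].map(plan.assignment)
        assert (manifest.assign(s=subsets).groupby("sample_id")["s"].nunique() == 1).all()

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            grouped_stratified_split(
                _manifest(class_sizes=(2, 5, 5, 5)), rng=np.random.default_rng(0)
            )

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            grouped_stratified_split(_manifest(), fractions=(0.5, 0.5, 0.5))


class TestStandardize:
    def test_training_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(4)
        X = rng.normal(3.0, 2.0, size=(60, 5))
        mask = np.zeros(60, bool)
        mask[:40] = True
        Xs, _ = standardize(X, mask)
        np.testing.assert_allclose(Xs[mask].mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(Xs[mask].std(axis=0), 1.0, atol=1e-8)

    def test_constant_column_becomes_zero_with_warning(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Xs, _ = standardize(X, np.ones(10, bool))
        assert (Xs[:, 0] == 0).all()

    def test_validation_rows_use_training_scaler(self):
        X = np.array([[1.0], [3.0], [5.0], [100.0]])
        mask = np.array([True, True, True, False])
        Xs, scaler = standardize(X, mask)
        # hand computation: train mean 3, sd sqrt(8/3)
        sd = np.sqrt(8.0 / 3.0)
        assert Xs[3, 0] == pytest.approx((100.0 - 3.0) / sd)


class TestScoring:
    @pytest.mark.parametrize(
        "pred,true,expected",
        [([1, 2, 3, 3], [1, 2, 3, 4], 0.75), ([1, 1], [1, 1], 1.0), ([1, 2], [2, 1], 0.0)],
    )
    def test_ccr(self, pred, true, expected):
        assert ccr(np.array(pred), np.array(true)) == pytest.approx(expected)

    def test_ccr_empty_rejected(self):
        with pytest.raises(ValueError):
            ccr(np.array([]), np.array([]))

    def test_one_hot_coding(self):
        Y = one_hot(np.array([1, 3, 4]), classes=np.array([1, 2, 3, 4]))
        np.testing.assert_array_equal(
            Y, [[1, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]]
        )

    def test_averaged_confusion_identity_for_perfect_models(self):
        m = np.diag([5.0, 3.0, 4.0, 2.0])
        out = averaged_confusion([m, m])
        np.testing.assert_allclose(out, np.eye(4) * 100.0)

    def test_averaged_confusion_rows_sum_to_100(self):
        rng = np.random.default_rng(6)
        mats = [rng.integers(0, 10, size=(4, 4)).astype(float) + 1 for _ in range(5)]
        out = averaged_confusion(mats)
        np.testing.assert_allclose(out.sum(axis=1), 100.0, atol=0.5)

    def test_identical_matrices_average_to_themselves(self):
        m = np.array([[8.0, 2, 0, 0], [1, 7, 2, 0], [0, 1, 9, 0], [0, 0, 3, 7]])
        expected = 100.0 * m / m.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(averaged_confusion([m] * 3), expected)


def _blobs(rng, n_per_class=30, spread=0.3):
    centers = np.array([[-3, -3], [-3, 3], [3, -3], [3, 3]], dtype=float)
    X, y = [], []
    for cls, c in enumerate(centers, start=1):
        X.append(c + rng.normal(0, spread, size=(n_per_class, 2)))
        y.append(np.full(n_per_class, cls))
    return np.vstack(X), np.concatenate(y)


class TestTrainMLP:
    @pytest.mark.parametrize("activation", ["tanh_sigmoid", "logistic_sigmoid"])
    def test_separable_blobs_reach_high_training_ccr(self, activation):
        rng = np.random.default_rng(7)
        X, y = _blobs(rng)
        cfg = MLPConfig(n_inputs=2, hidden_layers=(8,), hidden_activation=activation, seed=1)
        model = train_mlp(X, one_hot(y), cfg)
        assert ccr(model.predict(X), y) >= 0.99

    def test_seeded_training_is_deterministic(self):
        rng = np.random.default_rng(8)
        X, y = _blobs(rng)
        cfg = MLPConfig(n_inputs=2, hidden_layers=(4,), seed=3, max_epochs=50)
        m1 = train_mlp(X, one_hot(y), cfg)
        m2 = train_mlp(X, one_hot(y), cfg)
        for a, b in zip(m1.weights, m2.weights):
            assert np.array_equal(a, b)

    def test_input_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train_mlp(np.ones((8, 3)), one_hot(np.array([1, 2, 3, 4] * 2)),
                      MLPConfig(n_inputs=2))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=2, hidden_layers=(1, 2, 3))
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=2, hidden_activation="relu")
        with pytest.raises(ValueError):
            MLPConfig(n_inputs=2, algorithm="levenberg_marquardt")

    def test_weight_count(self):
        cfg = MLPConfig(n_inputs=22, hidden_layers=(4, 13))
        assert cfg.n_weights == 23 * 4 + 5 * 13 + 14 * 4


class TestRunCV:
    def test_shuffled_labels_score_near_class_prior(self, default_specs):
        X, manifest = cc.simulate_log_heights(
            default_specs, cc.StudyDesign(separability=0.0, seed=21)
        )
        res = run_cv(
            X, manifest, MLPConfig(n_inputs=22), n_partitions=25,
            rng=np.random.default_rng(1),
        )
        prior = 36 / 101
        assert abs(res.external_ccr.mean() - prior) <= 0.1

    def test_no_replicate_spans_subsets_in_any_partition(self):
        manifest = _manifest(class_sizes=(4, 5, 5, 4))
        plans = make_partition_plans(manifest, 50, np.random.default_rng(2))
        for plan in plans:
            subsets = manifest["sample_id"].map(plan.assignment)
            assert (
                manifest.assign(s=subsets).groupby("sample_id")["s"].nunique() == 1
            ).all()

    def test_confusion_rows_sum_to_100(self, default_specs):
        X, manifest = cc.simulate_log_heights(
            default_specs, cc.StudyDesign(class_sizes=(4, 6, 6, 4), seed=5)
        )
        res = run_cv(
            X, manifest, MLPConfig(n_inputs=22, max_epochs=100), n_partitions=8,
            rng=np.random.default_rng(3),
        )
        np.testing.assert_allclose(res.confusion_percent.sum(axis=1), 100.0, atol=0.5)


class TestSelectArchitecture:
    def test_single_candidate_space_returns_it(self, default_specs):
        X, manifest = cc.simulate_log_heights(
            default_specs, cc.StudyDesign(class_sizes=(4, 5, 5, 4), seed=6)
        )
        cand = MLPConfig(n_inputs=1, hidden_layers=(4,))
        winner, result = select_architecture(
            X, manifest, search_space=[cand], n_partitions=4,
            rng=np.random.default_rng(4),
        )
        assert winner.hidden_layers == (4,)
        assert len(result.external_ccr) == 4

    def test_parsimony_among_equal_scorers(self, default_specs):
        # strongly separable data: both candidates hit CCR 1.0 internally
        X, manifest = cc.simulate_log_heights(
            default_specs,
            cc.StudyDesign(class_sizes=(4, 5, 5, 4), separability=6.0, seed=7),
        )
        space = [
            MLPConfig(n_inputs=1, hidden_layers=(16, 16)),
            MLPConfig(n_inputs=1, hidden_layers=(4,)),
        ]
        winner, result = select_architecture(
            X, manifest, search_space=space, n_partitions=4,
            rng=np.random.default_rng(5),
        )
        scores = result.search_scores
        if scores["internal_ccr_mean"].nunique() == 1:
            assert winner.hidden_layers == (4,)
        assert (
            scores.loc[scores["hidden_layers"] == winner.hidden_layers,
                       "internal_ccr_mean"].iloc[0]
            >= scores["internal_ccr_mean"].max()
            - scores["internal_ccr_sd"].max()
        )

    def test_no_overfit_gap_on_strong_signal(self, default_specs):
        X, manifest = cc.simulate_log_heights(
            default_specs, cc.StudyDesign(separability=4.0, seed=8)
        )
        space = [MLPConfig(n_inputs=1, hidden_layers=(w,)) for w in (2, 4, 8)]
        _, result = select_architecture(
            X, manifest, search_space=space, n_partitions=10,
            rng=np.random.default_rng(6),
        )
        gap = abs(result.external_ccr.mean() - result.internal_ccr.mean())
        assert gap <= 0.05

    def test_empty_space_rejected(self, default_heights):
        X, manifest = default_heights
        with pytest.raises(ValueError):
            select_architecture(X, manifest, search_space=[])

    def test_default_search_space_covers_reference_architecture(self):
        space = default_search_space()
        assert any(
            c.hidden_layers == (4, 13) and c.hidden_activation == "tanh_sigmoid"
            for c in space
        )
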