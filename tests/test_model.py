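"""Dimensionality reduction, kNN scoring, metrics, training MCCV, tuning."""

import numpy as np
import pytest

from srmrad import (
    GeneratorConfig,
    ModelConfig,
    SplitSpec,
    default_grid,
    evaluate_metrics,
    fit_reduction,
    generate_cohort,
    knn_score,
    run_fs_mccv,
    run_training_mccv,
    select_signature,
    stratified_split,
    tune,
)
from srmrad.model import ModelError, train_round
from test_selection import brute_force_u


class TestModelConfig:
    @pytest.mark.parametrize("kwargs", [
        {"reduction": "svd"}, {"d": 4}, {"d": 1}, {"k": 4}, {"k": 1},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ModelError):
            ModelConfig(**{"reduction": "pca", "d": 2, "k": 7, **kwargs})

    def test_grid_is_odd_k_only(self):
        assert all(cfg.k % 2 == 1 for cfg in default_grid())


class TestReduction:
    def test_planar_data_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(40, 2))
        X = coords @ basis  # rank-2 data embedded in 10-D
        red = fit_reduction(X, ModelConfig("pca", 2, 7))
        T = red.transform(X)
        recon = T @ red.weights_ + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-10)

    def test_pca_variances_equal_covariance_eigenvalues(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 6)) @ np.diag([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        red = fit_reduction(X, ModelConfig("pca", 3, 7))
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        assert np.allclose(red.component_variance_, eigvals[:3], rtol=1e-10)

    def test_ica_is_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        S = np.column_stack([rng.laplace(size=200), rng.uniform(-1, 1, 200)])
        X = S @ rng.normal(size=(2, 5))
        a = fit_reduction(X, ModelConfig("ica", 2, 7), seed=9)
        b = fit_reduction(X, ModelConfig("ica", 2, 7), seed=9)
        assert np.array_equal(a.weights_, b.weights_)

    def test_sign_convention_largest_weight_positive(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 4))
        red = fit_reduction(X, ModelConfig("pca", 2, 7))
        for row in red.weights_:
            assert row[np.argmax(np.abs(row))] > 0

    def test_rank_deficient_d_rejected(self):
        X = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])  # rank 1
        with pytest.raises(ModelError, match="rank"):
            fit_reduction(X, ModelConfig("pca", 2, 7))


class TestKnn:
    def test_query_on_reference_point_k1(self):
        refs = np.array([[0.0, 0.0], [5.0, 5.0]])
        labels = np.array([0, 1])
        assert knn_score(refs, labels, [[5.0, 5.0]], k=1)[0] == 1.0
        assert knn_score(refs, labels, [[0.0, 0.0]], k=1)[0] == 0.0

    def test_equidistant_balanced_references_score_half(self):
        # four references on a circle around the query, two per class
        refs = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float)
        labels = np.array([1, 0, 1, 0])
        assert knn_score(refs, labels, [[0.0, 0.0]], k=4)[0] == 0.5

    def test_matches_brute_force_ranking(self):
        rng = np.random.default_rng(4)
        refs = rng.normal(size=(15, 3))
        labels = rng.integers(0, 2, 15)
        queries = rng.normal(size=(8, 3))
        got = knn_score(refs, labels, queries, k=5)
        for i, q in enumerate(queries):
            order = sorted(range(15), key=lambda j: (np.sum((q - refs[j]) ** 2), j))
            assert got[i] == pytest.approx(labels[order[:5]].mean())

    def test_distance_ties_broken_by_insertion_order(self):
        refs = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
        labels = np.array([1, 0, 0])
        # first two refs tie at distance 1; k=1 must pick the earlier one
        assert knn_score(refs, labels, [[0.0, 0.0]], k=1)[0] == 1.0

    def test_k_exceeding_references_rejected(self):
        with pytest.raises(ModelError):
            knn_score(np.zeros((3, 2)), np.zeros(3), [[0.0, 0.0]], k=5)


class TestMetrics:
    def test_perfect_separation(self):
        m = evaluate_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert all(m[k] == 1.0 for k in m)

    def test_anti_classifier_has_auc_zero(self):
        m = evaluate_metrics([0.1, 0.2, 0.9, 0.8], [1, 1, 0, 0])
        assert m["roc_auc"] == 0.0

    def test_auc_equals_normalized_u(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.random(8), 1)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        m = evaluate_metrics(scores, labels)
        u = brute_force_u(scores[labels == 1], scores[labels == 0])
        assert m["roc_auc"] == pytest.approx(u / (4 * 4))

    def test_ppv_prevalence_identity(self):
        rng = np.random.default_rng(6)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.6).astype(int)
        m = evaluate_metrics(scores, labels)
        pi = labels.mean()
        expected = (m["sensitivity"] * pi) / (
            m["sensitivity"] * pi + (1 - m["specificity"]) * (1 - pi)
        )
        assert m["ppv"] == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            evaluate_metrics([0.1, 0.9], [1, 1])


@pytest.fixture(scope="module")
def strong_setup():
    c = generate_cohort(GeneratorConfig(effect_size=2.0, seed=41))
    train, test = stratified_split(c, SplitSpec(0.2, True, 41))
    board = run_fs_mccv(train, 10, base_seed=410)
    return train, test, select_signature(board, 10)


class TestTrainingMccv:
    def test_deterministic_under_base_seed(self, strong_setup):
        train, test, sig = strong_setup
        a = run_training_mccv(train, sig, ModelConfig(), 5, 7, test)
        b = run_training_mccv(train, sig, ModelConfig(), 5, 7, test)
        assert np.allclose(a.test_rounds.to_numpy(), b.test_rounds.to_numpy())

    def test_single_round_sd_zero_and_flagged(self, strong_setup):
        train, test, sig = strong_setup
        perf = run_training_mccv(train, sig, ModelConfig(), 1, 3, test)
        assert perf.degenerate_sd
        assert (perf.summary()[("validation", "sd")] == 0.0).all()

    def test_validation_rows_never_in_reference_fit(self, strong_setup):
        """The 20% held-out rows of a round are disjoint from the rows the
        model was fitted on (no leakage into standardizer/reduction/kNN)."""
        train, _, sig = strong_setup
        model, held_out = train_round(train, sig, ModelConfig(), seed=99)
        work, held_again = stratified_split(
            train.select_features(sig), SplitSpec(0.2, True, 99)
        )
        assert held_out.patient_ids == held_again.patient_ids
        assert set(held_out.patient_ids).isdisjoint(work.patient_ids)
        # reference set = balanced version of the 80% side only
        assert len(model.reference_labels) == 2 * max(work.label_counts().values())

    def test_missing_signature_feature_rejected(self, strong_setup):
        train, test, _ = strong_setup
        with pytest.raises(ModelError):
            run_training_mccv(train, ["not_a_feature"], ModelConfig(), 2, 0, test)


class TestTune:
    def test_single_point_grid_returned(self, strong_setup):
        train, _, sig = strong_setup
        only = ModelConfig("pca", 3, 9)
        res = tune(train, sig, [only], rounds=3, base_seed=5)
        assert res.best == only and len(res.curve) == 1

    def test_curve_reproducible_and_covers_grid(self, strong_setup):
        train, _, sig = strong_setup
        grid = default_grid(("pca",), (2,), (3, 5, 7))
        a = tune(train, sig, grid, rounds=4, base_seed=6)
        b = tune(train, sig, grid, rounds=4, base_seed=6)
        assert a.curve.equals(b.curve)
        assert list(a.curve["k"]) == [3, 5, 7]
        assert a.best.d == 2  # d constraint honored by construction
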