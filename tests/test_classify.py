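import numpy as np
import pandas as pd
import pytest

from rehoseed.classify import (
    FisherLDA,
    PCSearchSpec,
    ValidationReport,
    choose_n_components,
    make_classifier,
    pca_fit_reduce,
    random_sampling_validate,
)
from rehoseed.errors import ParameterError
from rehoseed.features import FeatureMatrix
from rehoseed.groupstats import SubjectTable

from _oracles import explained_variance_eig, fisher_direction_grid


def _subject_table(n_per_group=20):
    rows = []
    for g, n in (("ADHD", n_per_group), ("control", n_per_group)):
        for i in range(n):
            rows.append(
                {"subject_id": f"{g}_{i}", "group": g, "sex": "F" if i % 3 == 0 else "M"}
            )
    return SubjectTable(pd.DataFrame(rows))


def _feature_matrix(values, table):
    cols = [("ReHo", "", v) for v in range(values.shape[1])]
    return FeatureMatrix(values=values, subject_ids=table.subject_ids, columns=cols)


class TestPCA:
    def test_planar_data_needs_two_components(self, rng):
        basis = rng.normal(size=(2, 10))
        coeff = rng.normal(size=(30, 2))
        X = coeff @ basis  # exactly rank 2
        pca, _ = pca_fit_reduce(X, 2)
        assert pca.explained_variance_ratio_.sum() == pytest.approx(1.0)

    def test_full_rank_reconstruction_is_exact(self, rng):
        X = rng.normal(size=(12, 6))
        pca, reduced = pca_fit_reduce(X, 6)
        back = reduced @ pca.components_ + pca.mean_
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_explained_variance_matches_eigendecomposition(self, rng):
        X = rng.normal(size=(20, 50))
        pca, _ = pca_fit_reduce(X, 19)
        np.testing.assert_allclose(
            pca.explained_variance_ratio_, explained_variance_eig(X)[:19], atol=1e-8
        )

    def test_test_rows_projected_with_training_mean(self, rng):
        X = rng.normal(size=(15, 8))
        T = rng.normal(size=(4, 8))
        pca, _, reduced_t = pca_fit_reduce(X, 3, T)
        np.testing.assert_allclose(reduced_t, (T - pca.mean_) @ pca.components_.T, atol=1e-10)

    def test_oversized_component_count_rejected(self, rng):
        with pytest.raises(ParameterError):
            pca_fit_reduce(rng.normal(size=(5, 3)), 5)


class TestChooseNComponents:
    def test_separable_along_single_dominant_component(self, rng):
        # one direction carries ~60% of variance and separates the classes
        y = np.repeat([0, 1], 20)
        pc1 = (y * 2.0 - 1.0) * 2.0 + rng.normal(scale=0.4, size=40)
        rest = rng.normal(scale=0.35, size=(40, 11))
        X = np.column_stack([pc1, rest])
        spec = PCSearchSpec()
        nc = choose_n_components(X, y, spec, "lda", seed=0)
        assert nc == 1

    def test_tie_breaks_to_smaller_count(self, rng):
        # both candidate counts classify perfectly -> smallest returned
        y = np.repeat([0, 1], 15)
        pc1 = (y * 2.0 - 1.0) * 5.0 + rng.normal(scale=0.1, size=30)
        X = np.column_stack([pc1, rng.normal(scale=1.0, size=(30, 6))])
        nc = choose_n_components(X, y, PCSearchSpec(), "lda", seed=1)
        cumvar = explained_variance_eig(X)
        first_in_window = int(np.argmax(np.cumsum(cumvar) >= 0.5)) + 1
        assert nc == first_in_window

    def test_permuted_labels_stay_in_range_near_chance(self, rng):
        X = rng.normal(size=(32, 20))
        y = rng.permutation(np.repeat([0, 1], 16))
        nc = choose_n_components(X, y, PCSearchSpec(), "lda", seed=2)
        cumvar = np.cumsum(explained_variance_eig(X)[:31])
        assert 1 <= nc <= 31
        assert 0.50 - 1e-9 <= cumvar[nc - 1] <= 0.90 + 1e-9


class TestFisherLDA:
    def test_separated_clouds_fit_perfectly(self, rng):
        X0 = rng.normal(size=(40, 3)) + np.array([5.0, 0.0, 0.0])
        X1 = rng.normal(size=(40, 3)) - np.array([5.0, 0.0, 0.0])
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 40)
        clf = FisherLDA().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_1d_decision_threshold_near_bayes_boundary(self, rng):
        # N(-3,1) vs N(+3,1): equal priors put the optimal boundary at 0
        x = np.concatenate([rng.normal(-3, 1, 200), rng.normal(3, 1, 200)])[:, None]
        y = np.repeat([0, 1], 200)
        clf = FisherLDA().fit(x, y)
        boundary = clf.threshold_ / clf.w_[0]
        assert abs(boundary) < 0.3

    def test_projection_direction_matches_grid_search(self, rng):
        # anisotropic two-class cloud in 2D; compare with brute-force angles
        cov = np.array([[2.0, 1.2], [1.2, 1.0]])
        L = np.linalg.cholesky(cov)
        X0 = rng.normal(size=(150, 2)) @ L.T
        X1 = rng.normal(size=(150, 2)) @ L.T + np.array([1.5, -0.5])
        X = np.vstack([X0, X1])
        y = np.repeat([0, 1], 150)
        clf = FisherLDA().fit(X, y)
        angle = np.arctan2(clf.w_[1], clf.w_[0]) % np.pi
        oracle = fisher_direction_grid(X, y) % np.pi
        diff = min(abs(angle - oracle), np.pi - abs(angle - oracle))
        assert np.degrees(diff) < 2.0

    def test_singular_scatter_regularized(self):
        # duplicated feature -> singular within-class scatter
        x = np.array([[0.0], [1.0], [4.0], [5.0]])
        X = np.hstack([x, x])
        y = np.array([0, 0, 1, 1])
        clf = FisherLDA().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_linear_svm_variant_available(self, rng):
        X = np.vstack([rng.normal(size=(20, 2)) + 4, rng.normal(size=(20, 2)) - 4])
        y = np.repeat([0, 1], 20)
        clf = make_classifier("linsvm").fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0


class TestValidationReport:
    def test_metric_definitions(self):
        m = ValidationReport.metrics(tp=15, tn=14, fp=5, fn=3)
        assert m["sensitivity"] == pytest.approx(15 / 18, abs=5e-4)
        assert m["specificity"] == pytest.approx(14 / 19, abs=5e-4)
        assert m["accuracy"] == pytest.approx(29 / 37, abs=5e-4)
        assert m["sensitivity"] == pytest.approx(0.833, abs=1e-3)
        assert m["specificity"] == pytest.approx(0.737, abs=1e-3)
        assert m["accuracy"] == pytest.approx(0.784, abs=1e-3)


class TestRandomSamplingValidate:
    def test_label_encoding_features_classify_perfectly(self):
        table = _subject_table(16)
        y = table.group_indicator()
        X = np.column_stack([y * 4.0 - 2.0, y * 2.0 - 1.0, np.zeros(len(y)) + 0.01])
        X = X + np.random.default_rng(0).normal(scale=0.01, size=X.shape)
        fm = _feature_matrix(X, table)
        rep = random_sampling_validate(fm, table, repeats=10, seed=3)
        assert rep.mean_accuracy == 1.0
        assert rep.mean_sensitivity == 1.0
        assert rep.mean_specificity == 1.0

    def test_noise_features_score_near_chance(self, rng):
        table = _subject_table(20)
        fm = _feature_matrix(rng.normal(size=(40, 30)), table)
        rep = random_sampling_validate(fm, table, repeats=10, seed=4)
        assert 0.35 <= rep.mean_accuracy <= 0.65

    def test_same_seed_reproduces_report_byte_for_byte(self, rng):
        table = _subject_table(12)
        fm = _feature_matrix(rng.normal(size=(24, 15)), table)
        r1 = random_sampling_validate(fm, table, repeats=5, seed=7)
        r2 = random_sampling_validate(fm, table, repeats=5, seed=7)
        assert r1.to_json().encode() == r2.to_json().encode()

    def test_different_seeds_differ(self, rng):
        table = _subject_table(12)
        fm = _feature_matrix(rng.normal(size=(24, 15)), table)
        r1 = random_sampling_validate(fm, table, repeats=5, seed=7)
        r2 = random_sampling_validate(fm, table, repeats=5, seed=8)
        assert r1.to_json() != r2.to_json()

    def test_confusion_counts_cover_test_set(self, rng):
        table = _subject_table(16)
        fm = _feature_matrix(rng.normal(size=(32, 10)), table)
        rep = random_sampling_validate(fm, table, repeats=4, seed=5)
        for r in rep.repeats:
            assert r["tp"] + r["tn"] + r["fp"] + r["fn"] == 8  # 25% of 32
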