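"""PLS-DA engine: NIPALS properties, VIP, Venetian blinds, CV honesty."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nmrfinger.plsda import (
    cross_validate_plsda,
    encode_labels,
    fit_pls,
    top_weighted_peaks,
    venetian_blinds_split,
    vip_scores,
)


def _separable(n0=10, n1=10, p=30, gap=6.0, seed=0, informative=(0,)):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n0 + n1, p))
    y = np.repeat([0, 1], [n0, n1])
    for j in informative:
        X[y == 1, j] += gap
    return X, y


class TestFitPls:
    def test_single_informative_column_gets_unit_weight(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        X = np.zeros((20, 5))
        X[:, 2] = 3.0 * y
        model = fit_pls(X, y, 1)
        w = np.abs(model.x_weights[:, 0])
        assert w[2] == pytest.approx(1.0, abs=1e-10)
        assert np.all(w[[0, 1, 3, 4]] < 1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_component_fit_equals_least_squares(self, seed):
        # normal-equations oracle: with all components, PLS spans the full
        # predictor space and reproduces the OLS fit
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = fit_pls(X, y, 3)
        Xc = np.column_stack([np.ones(10), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        np.testing.assert_allclose(model.predict(X), Xc @ beta, atol=1e-8)

    def test_scores_orthogonal_weights_unit_norm(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        model = fit_pls(X, y, 4)
        gram = model.scores.T @ model.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        np.testing.assert_allclose(
            np.linalg.norm(model.x_weights, axis=0), 1.0, atol=1e-10)
        assert np.all(model.explained_variance_fraction >= 0)
        assert np.all(model.explained_variance_fraction <= 1 + 1e-12)

    def test_matches_sklearn_pls(self, rng):
        # independent implementation cross-check
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        ours = fit_pls(X, y, 3).predict(X)
        ref = PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(8), 2)  # zero-variance response
        with pytest.raises(ValueError):
            fit_pls(X, rng.normal(size=8), 8)  # too many components


class TestVip:
    def test_mean_squared_vip_is_one(self, rng):
        for n, p, a in [(15, 6, 2), (30, 50, 3), (12, 4, 1)]:
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            v = vip_scores(fit_pls(X, y, a))
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-9)

    def test_informative_column_has_max_vip(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 8)) * 0.01
        X[:, 5] = y
        v = vip_scores(fit_pls(X, y, 2))
        assert np.argmax(v) == 5

    def test_duplicated_columns_equal_vip(self, rng):
        X = rng.normal(size=(20, 6))
        X[:, 3] = X[:, 1]
        y = rng.normal(size=20)
        v = vip_scores(fit_pls(X, y, 2))
        assert v[1] == pytest.approx(v[3], abs=1e-9)


class TestVenetianBlinds:
    def test_interleave_definition(self):
        np.testing.assert_array_equal(venetian_blinds_split(6, 3),
                                      [0, 1, 2, 0, 1, 2])

    def test_fold_sizes(self):
        sizes = np.bincount(venetian_blinds_split(7, 3))
        assert sorted(sizes.tolist()) == [2, 2, 3]

    def test_balance_exhaustive(self):
        for n in range(2, 31):
            for k in range(2, n + 1):
                sizes = np.bincount(venetian_blinds_split(n, k), minlength=k)
                assert sizes.max() - sizes.min() <= 1

    def test_block_size(self):
        np.testing.assert_array_equal(venetian_blinds_split(8, 2, block_size=2),
                                      [0, 0, 1, 1, 0, 0, 1, 1])

    def test_bad_k(self):
        with pytest.raises(ValueError):
            venetian_blinds_split(5, 6)


class TestCrossValidation:
    def test_separable_data_perfect(self):
        X, y = _separable()
        cv = cross_validate_plsda(X, y, k=5, positive_class=1)
        assert cv.sensitivity == 1.0 and cv.specificity == 1.0

    def test_confusion_counts_partition_samples(self):
        X, y = _separable(7, 9, gap=0.5, seed=4)
        cv = cross_validate_plsda(X, y, k=4)
        assert cv.n == 16

    def test_positive_class_orientation(self):
        X, y = _separable(6, 10)
        a = cross_validate_plsda(X, y, k=4, positive_class=0)
        b = cross_validate_plsda(X, y, k=4, positive_class=1)
        assert a.true_positive == b.true_negative
        assert a.positive_class == 0 and b.positive_class == 1

    def test_heldout_rows_do_not_influence_their_fold_model(self):
        # leakage probe: wildly rescaling one held-out sample must not move
        # predictions for other samples in the same fold (same training set)
        X, y = _separable(8, 8, seed=6)
        k = 4
        folds = venetian_blinds_split(len(y), k)
        i = int(np.flatnonzero(folds == 0)[0])
        j = int(np.flatnonzero(folds == 0)[1])
        Xp = X.copy()
        Xp[i] *= 1e9
        base = cross_validate_plsda(X, y, k=k)
        pert = cross_validate_plsda(Xp, y, k=k)
        assert pert.decision_values[j] == base.decision_values[j]

    def test_missing_class_in_training_fold(self):
        X = np.random.default_rng(0).normal(size=(4, 3))
        y = np.array([0, 1, 0, 1])  # fold 0 trains on samples 1, 3: one class
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate_plsda(X, y, k=2, n_components=1)

    def test_accuracy_monotone_in_effect_size(self):
        accs = []
        for gap in (0.0, 1.5, 6.0):
            vals = []
            for seed in range(10):
                X, y = _separable(10, 10, gap=gap, seed=seed,
                                  informative=(0, 1, 2))
                vals.append(cross_validate_plsda(X, y, k=5).accuracy)
            accs.append(np.mean(vals))
        assert accs[1] >= accs[0] - 0.1
        assert accs[2] >= accs[1] - 0.1


class TestTopPeaks:
    def test_informative_column_ranks_first(self):
        X, y = _separable(10, 10, gap=8.0, seed=2)
        coded, _ = encode_labels(y, 1)
        model = fit_pls(X, coded, 2)
        peaks = top_weighted_peaks(model, 5, bin_centers=np.arange(X.shape[1]))
        assert peaks.iloc[0]["bin_index"] == 0
        assert peaks.iloc[0]["direction"] == "up"

    def test_requested_count_returned(self, small_matrix, small_cohort):
        coded, _ = encode_labels(small_cohort.labels, 0)
        model = fit_pls(small_matrix, coded, 2)
        assert len(top_weighted_peaks(model, 20)) == 20
        with pytest.raises(ValueError):
            top_weighted_peaks(model, small_matrix.n_bins + 1)

    def test_ranking_invariant_to_duplicate_junk_column(self, rng):
        X, y = _separable(10, 10, gap=5.0, seed=8)
        coded, _ = encode_labels(y, 1)
        peaks = top_weighted_peaks(fit_pls(X, coded, 2), 5)
        X2 = np.column_stack([X, X[:, -1]])  # duplicate an uninformative bin
        peaks2 = top_weighted_peaks(fit_pls(X2, coded, 2), 5)
        assert peaks["bin_index"].tolist() == peaks2["bin_index"].tolist()


def test_fisher_direction_agreement():
    # one-component PLS-DA on +/-1 labels points near the Fisher LDA
    # direction for equal-covariance Gaussian classes
    rng = np.random.default_rng(0)
    n, p = 400, 10
    mu = np.zeros(p)
    mu[:3] = 1.0
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p)) + np.outer(y, mu)
    coded, _ = encode_labels(y, 1)
    model = fit_pls(X, coded, 1)
    # population Fisher direction: with identity within-class covariance it
    # is the mean-difference direction itself
    fisher = mu
    cos = abs(fisher @ model.x_weights[:, 0]) / np.linalg.norm(fisher)
    assert np.degrees(np.arccos(min(cos, 1.0))) < 15.0
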