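import numpy as np
import pytest

from phenothz.plsda import (PLSModel, encode_classes, explained_y_variance,
                            fit_pls, fit_plsda, scores_loadings)


class TestEncodeClasses:
    def test_indicator_matrix(self):
        Y, vocab = encode_classes(["A", "B", "A"])
        assert vocab == ["A", "B"]
        np.testing.assert_array_equal(Y, [[1, 0], [0, 1], [1, 0]])

    def test_sorted_vocabulary_order(self):
        Y, vocab = encode_classes(["B", "A"])
        assert vocab == ["A", "B"]
        np.testing.assert_array_equal(Y, [[0, 1], [1, 0]])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            encode_classes(["A", "A", "A"])


class TestFitPLS:
    def test_weight_concentrates_on_informative_variable(self):
        rng = np.random.default_rng(0)
        y = np.tile([0.0, 1.0], 10)
        X = rng.normal(0, 0.01, size=(20, 5))
        X[:, 3] += y  # only variable 3 carries the classes
        Y, vocab = encode_classes(["A" if v == 0 else "B" for v in y])
        m = fit_pls(X, Y, 1, vocab=vocab)
        w = np.abs(m.weights[:, 0])
        assert np.argmax(w) == 3
        # oracle: first weight is proportional to X_c^T y_c
        Xc = X - X.mean(0)
        yc = Y[:, :1] - Y[:, :1].mean(0)
        ref = (Xc.T @ yc).ravel()
        ref /= np.linalg.norm(ref)
        cos = abs(float(w @ np.abs(ref)) / np.linalg.norm(w))
        assert cos > 0.999

    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 4))
        Y, vocab = encode_classes(list("ABABAB"))
        m = fit_pls(X, Y, 4, vocab=vocab)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        np.testing.assert_allclose(m.predict(X), Xc @ B + Y.mean(0), atol=1e-6)

    def test_random_labels_explain_little(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 30))
        labels = list(rng.choice(["A", "B"], size=60))
        m = fit_plsda(X, labels, 1)
        assert m.explained_y_variance[0] < 30.0

    def test_score_orthogonality(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 12))
        Y = rng.normal(size=(25, 2))
        m = fit_pls(X, Y, 6)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_deflation_residual_orthogonal_to_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 8))
        Y = rng.normal(size=(20, 2))
        m = fit_pls(X, Y, 4)
        Xc = X - m.x_mean
        E = Xc - m.scores @ m.x_loadings.T   # residual after deflation
        assert np.max(np.abs(m.scores.T @ E)) < 1e-9

    def test_zero_variance_column_harmless(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        X[:, 2] = 3.14
        m = fit_plsda(X, list("ABABABABAB"), 2)
        assert np.all(np.isfinite(m.coefficients()))
        assert np.allclose(m.weights[2, :], 0.0)

    def test_constant_shift_of_one_variable_changes_nothing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 5))
        labels = list("ABABABABABAB")
        m1 = fit_plsda(X, labels, 3)
        X2 = X.copy()
        X2[:, 1] += 42.0
        m2 = fit_plsda(X2, labels, 3)
        np.testing.assert_allclose(m1.predict(X), m2.predict(X2), atol=1e-9)

    def test_excessive_n_lv_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError):
            fit_pls(X, np.zeros((5, 2)), 5)

    def test_reference_implementation_agreement(self):
        """Predictions match scikit-learn's NIPALS run to its fixed point."""
        from sklearn.cross_decomposition import PLSRegression
        import warnings
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(8, 25))
            p = int(rng.integers(4, 15))
            a = int(rng.integers(1, min(n - 1, p) + 1))
            m = int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            Y = rng.normal(size=(n, m))
            mine = fit_pls(X, Y, a)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = PLSRegression(n_components=a, scale=False, tol=1e-20,
                                    max_iter=20000).fit(X, Y)
            np.testing.assert_allclose(mine.predict(X), ref.predict(X),
                                       atol=1e-6)


class TestClassify:
    def _separable(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 0.05, size=(10, 3))
        X[5:, 0] += 2.0
        labels = ["A"] * 5 + ["B"] * 5
        return X, labels

    def test_calibration_samples_recovered(self):
        X, labels = self._separable()
        m = fit_plsda(X, labels, 2)
        assert m.classify(X) == labels

    def test_tie_goes_to_first_vocabulary_class(self):
        # symmetric two-class toy; probing the centroid midpoint ties
        X = np.array([[0.0], [2.0]])
        m = fit_plsda(X, ["B", "A"], 1)
        assert m.classify(np.array([[1.0]])) == ["A"]

    def test_shift_orthogonal_to_coefficients_preserves_labels(self):
        X, labels = self._separable()
        m = fit_plsda(X, labels, 1)
        B = m.coefficients()
        # direction orthogonal to both coefficient columns
        null = np.linalg.svd(B.T)[2][-1]
        assert np.max(np.abs(B.T @ null)) < 1e-10
        assert m.classify(X + 3.0 * null) == m.classify(X)


class TestScoresLoadings:
    def test_calibration_scores_self_consistent(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 6))
        m = fit_plsda(X, list("ABABABABABABABA"), 3)
        scores, loadings = scores_loadings(m, X)
        np.testing.assert_allclose(scores, m.scores, atol=1e-8)
        assert loadings.shape == (6, 3)

    def test_mean_input_gives_zero_scores(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 4))
        m = fit_plsda(X, list("ABABABABAB"), 2)
        probe = np.tile(m.x_mean, (3, 1))
        np.testing.assert_allclose(m.transform(probe), 0.0, atol=1e-10)


class TestExplainedVariance:
    def test_full_rank_reaches_100(self):
        rng = np.random.default_rng(10)
        T = rng.normal(size=(12, 3))
        P = rng.normal(size=(5, 3))
        X = T @ P.T
        Y = T @ rng.normal(size=(3, 2))  # Y lives in the LV span of X
        m = fit_pls(X, Y, 3)
        assert m.explained_y_variance[-1] == pytest.approx(100.0, abs=1e-6)

    def test_noise_free_separable_lv1_is_100(self):
        # y proportional to the single X direction
        rng = np.random.default_rng(11)
        direction = rng.normal(size=4)
        t = np.array([-1.5, -0.5, 0.5, 1.5, -1.0, 1.0])
        X = np.outer(t, direction)
        Y = np.column_stack([t, -t])
        m = fit_pls(X, Y, 1)
        assert m.explained_y_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_increments_non_negative(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 10))
        Y = rng.normal(size=(20, 2))
        m = fit_pls(X, Y, 6)
        assert np.all(np.diff(np.concatenate([[0.0],
                                              m.explained_y_variance])) >= 0)
        assert np.array_equal(explained_y_variance(m), m.explained_y_variance)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 5))
        m = fit_plsda(X, list("ABABABABAB"), 3)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = PLSModel.from_json(path)
        np.testing.assert_allclose(back.predict(X), m.predict(X), atol=1e-12)
        assert back.vocab == m.vocab
        assert back.classify(X) == m.classify(X)
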