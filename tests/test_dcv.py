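import numpy as np
import pytest

from phenothz.dcv import (DCVResult, case_study_arrays, double_cv, final_model,
                          inner_select_lv, make_folds, overall_accuracy,
                          per_compound_rates)
from phenothz.core import RANGES
from phenothz.pipeline import preprocess_for_analysis
from phenothz.synthetic import SyntheticConfig, simulate_dataset
from phenothz import average_replicates, average_suppliers


LABELS_39 = ["flavonoid"] * 26 + ["phenolic_acid"] * 13


class TestMakeFolds:
    def test_stratification_contract(self):
        folds = make_folds(LABELS_39, k=5, seed=0)
        sizes = np.bincount(folds, minlength=5)
        assert sorted(sizes) == [7, 8, 8, 8, 8]
        minority = np.array(LABELS_39) == "phenolic_acid"
        for f in range(5):
            in_fold = minority[folds == f].sum()
            assert in_fold in (2, 3)

    def test_leave_one_out_degenerate(self):
        folds = make_folds(list("ABABAB"), k=6, seed=1)
        assert sorted(folds) == list(range(6))

    def test_deterministic(self):
        a = make_folds(LABELS_39, k=5, seed=7)
        b = make_folds(LABELS_39, k=5, seed=7)
        assert np.array_equal(a, b)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["A", "B"], k=3, seed=0)


class TestOverallAccuracy:
    @pytest.mark.parametrize("true,pred,expected", [
        (list("AAB"), list("AAB"), 1.0),
        (list("AAB"), list("BBA"), 0.0),
    ])
    def test_extremes(self, true, pred, expected):
        assert overall_accuracy(true, pred) == expected

    def test_35_of_39(self):
        true = ["A"] * 39
        pred = ["A"] * 35 + ["B"] * 4
        assert overall_accuracy(true, pred) == pytest.approx(0.897, abs=5e-4)


class TestInnerSelectLV:
    def test_separable_picks_smallest_perfect_lv(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.05, size=(20, 6))
        X[10:, 0] += 3.0
        labels = ["A"] * 10 + ["B"] * 10
        folds = make_folds(labels, k=4, seed=0)
        lv = inner_select_lv(X, labels, folds, range(1, 6))
        assert lv == 1  # LV1 already reaches OA 1.0; ties go to the smallest

    def test_candidates_truncated_to_feasible(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 30))
        labels = list("ABABABAB")
        folds = make_folds(labels, k=4, seed=0)
        # training sets have 6 samples: candidates cap at 5
        lv = inner_select_lv(X, labels, folds, range(1, 21))
        assert 1 <= lv <= 5


def _mock_result(chosen, correct=None, sample_ids=None):
    reps, k = chosen.shape
    n = 4 if correct is None else correct.shape[1]
    return DCVResult(
        oa_per_rep=np.ones(reps) if correct is None else correct.mean(axis=1),
        chosen_lv=chosen,
        correct=np.ones((reps, n), dtype=bool) if correct is None else correct,
        sample_ids=list(range(n)) if sample_ids is None else sample_ids,
        seeds=list(range(reps)), lv_range=(1, 20))


class TestFinalModel:
    def test_modal_lv(self):
        res = _mock_result(np.array([[3, 3, 5]]))
        assert res.modal_lv == 3

    def test_mode_tie_takes_smallest(self):
        res = _mock_result(np.array([[2, 4]]))
        assert res.modal_lv == 2

    def test_final_model_exports_scores_and_loadings(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 0.1, size=(12, 5))
        X[6:, 1] += 2.0
        labels = ["A"] * 6 + ["B"] * 6
        res = _mock_result(np.array([[2, 2, 3]]))
        model = final_model(X, labels, res)
        assert model.n_lv == 2
        assert model.scores.shape == (12, 2)
        assert model.x_loadings.shape == (5, 2)


class TestPerSampleRates:
    def test_rate_arithmetic(self):
        correct = np.ones((30, 3), dtype=bool)
        correct[:7, 1] = False          # sample 1 correct in 23 of 30 reps
        res = _mock_result(np.ones((30, 5), dtype=int), correct,
                           sample_ids=["a", "b", "c"])
        rates = per_compound_rates(res)
        assert set(rates) == {"a", "b", "c"}
        assert rates["a"] == 1.0
        assert rates["b"] == pytest.approx(0.767, abs=5e-4)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(3)
    X = rng.normal(0, 0.05, size=(24, 8))
    X[12:, 2] += 2.0
    labels = ["A"] * 12 + ["B"] * 12
    return X, labels


class TestDoubleCV:
    def test_separable_toy_perfect(self, toy):
        X, labels = toy
        res = double_cv(X, labels, reps=3, lv_range=range(1, 6), base_seed=0)
        assert res.mean_oa == 1.0
        assert res.oa_per_rep.shape == (3,)
        assert res.chosen_lv.shape == (3, 5)

    def test_deterministic_from_base_seed(self, toy):
        X, labels = toy
        a = double_cv(X, labels, reps=1, lv_range=range(1, 6), base_seed=9)
        b = double_cv(X, labels, reps=1, lv_range=range(1, 6), base_seed=9)
        assert np.array_equal(a.oa_per_rep, b.oa_per_rep)
        assert np.array_equal(a.chosen_lv, b.chosen_lv)
        assert np.array_equal(a.correct, b.correct)
        assert a.seeds == b.seeds

    def test_no_leakage_from_test_fold(self, toy):
        """Corrupting an outer test fold cannot change that fold's tuning:
        the LV chosen for it is computed from the other folds only."""
        X, labels = toy
        res1 = double_cv(X, labels, reps=1, lv_range=range(1, 6), base_seed=4)
        folds = make_folds(labels, k=5, seed=res1.seeds[0])
        target = 0
        X2 = X.copy()
        X2[folds == target] = 1e3  # garbage in the withheld fold
        res2 = double_cv(X2, labels, reps=1, lv_range=range(1, 6), base_seed=4)
        assert res1.chosen_lv[0, target] == res2.chosen_lv[0, target]

    def test_permuted_labels_near_chance(self, toy):
        X, labels = toy
        rng = np.random.default_rng(5)
        perm = list(rng.permutation(labels))
        res = double_cv(X, perm, reps=5, lv_range=range(1, 6), base_seed=6)
        assert 0.2 <= res.mean_oa <= 0.8

    def test_mean_oa_is_mean_of_reps(self, toy):
        X, labels = toy
        res = double_cv(X, labels, reps=3, lv_range=range(1, 4), base_seed=7)
        assert res.mean_oa == pytest.approx(res.oa_per_rep.mean())
        assert res.min_oa == res.oa_per_rep.min()
        assert res.max_oa == res.oa_per_rep.max()


class TestCaseStudies:
    def test_case_study_membership(self, compound_dataset):
        pre = preprocess_for_analysis(compound_dataset, RANGES["R1"])
        X, labels, ids = case_study_arrays(pre, "CS1")
        assert X.shape[0] == 39
        assert labels.count("flavonoid") == 26
        assert labels.count("phenolic_acid") == 13
        X2, labels2, _ = case_study_arrays(pre, "CS2")
        assert X2.shape[0] == 26
        assert labels2.count("flavonol") == 9
        X3, labels3, _ = case_study_arrays(pre, "CS3")
        assert X3.shape[0] == 13
        assert labels3.count("hydroxycinnamic_acid") == 5

    def test_separation_never_hurts_accuracy(self):
        """More between-class band amplitude never lowers mean OA."""
        oas = []
        for amp in (0.0, 0.06, 0.15):
            cfg = SyntheticConfig(seed=6, motif_amplitude=amp)
            ds = simulate_dataset(cfg)
            avg = average_suppliers(average_replicates(ds))
            pre = preprocess_for_analysis(avg, RANGES["R1"])
            X, labels, _ = case_study_arrays(pre, "CS1")
            res = double_cv(X, labels, reps=5, base_seed=1)
            oas.append(res.mean_oa)
        assert oas[0] <= oas[1] + 1e-9 <= oas[2] + 2e-9
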