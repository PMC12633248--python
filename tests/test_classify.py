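"""Feature assembly, penalty path, cross-validated selection and
evaluation of the sparse logistic classifier."""

import numpy as np
import pandas as pd
import pytest

from eegcrit.banding import make_bands
from eegcrit.classify import (
    assemble_features,
    auc_rank,
    cv_select,
    evaluate,
    fit_lasso_classifier,
    lambda_grid,
    lasso_path,
    split_stratified,
)


def _metric_table(n=40, seed=0, signal=0.0):
    """Synthetic subject-level table with the full metric x band layout."""
    rng = np.random.default_rng(seed)
    bands = make_bands()
    y = np.repeat([0, 1], n // 2)
    rows = []
    for i in range(n):
        row = {
            "subject_id": f"S{i:03d}",
            "group": "MDD" if y[i] else "HC",
            "age": rng.normal(47, 16),
            "sex": "male" if rng.random() < 0.4 else "female",
        }
        for m in ("bis", "dfa", "ei_hlp", "fei", "ei_hls"):
            for j, lab in enumerate(bands.labels()):
                val = rng.standard_normal()
                if signal and m == "bis" and j == 4:
                    val += signal * y[i]
                row[f"{m}@{lab}"] = val
        row["lzc"] = rng.standard_normal()
        rows.append(row)
    return pd.DataFrame(rows)


class TestAssembleFeatures:
    def test_default_pool_is_43_columns(self):
        fm = assemble_features(_metric_table())
        assert len(fm.columns) == 43  # 4 metrics x 10 bands + lzc + age + sex
        assert fm.X.shape[1] == 43
        assert not any(c.startswith("dfa@") for c in fm.columns)
        assert not any("45.0" in c or "57.3" in c for c in fm.columns)

    def test_dfa_inclusion_adds_ten_bands(self):
        fm = assemble_features(_metric_table(), include_dfa=True)
        assert len(fm.columns) == 53

    def test_full_band_pool(self):
        fm = assemble_features(_metric_table(), max_band_hz=73.0)
        assert len(fm.columns) == 4 * 13 + 3

    def test_missing_values_preserved_for_training_imputation(self):
        table = _metric_table()
        table.loc[3, "fei@1.0-4.0"] = np.nan
        fm = assemble_features(table)
        j = fm.columns.index("fei@1.0-4.0")
        assert np.isnan(fm.X[3, j])
        assert fm.impute_mask[3, j]


class TestSplit:
    def test_proportions_partition_and_determinism(self):
        y = np.array([0] * 133 + [1] * 183)
        tr, te = split_stratified(y, rng=3)
        assert np.intersect1d(tr, te).size == 0
        assert tr.size + te.size == y.size
        assert abs((y[tr] == 0).sum() - 93) <= 1
        assert abs((y[tr] == 1).sum() - 128) <= 1
        tr2, te2 = split_stratified(y, rng=3)
        assert np.array_equal(tr, tr2) and np.array_equal(te, te2)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            split_stratified(np.array([0, 1, 1, 1]))


class TestLassoPath:
    @staticmethod
    def _xy(n=60, p=8, seed=0, informative=None):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        if informative is None:
            y = (rng.random(n) < 0.5).astype(int)
        else:
            z = 2.0 * X[:, informative]
            y = (rng.random(n) < 1 / (1 + np.exp(-z))).astype(int)
        X = (X - X.mean(0)) / X.std(0)
        return X, y

    def test_all_zero_at_lambda_max(self):
        X, y = self._xy(informative=2)
        lams = lambda_grid(X, y, n=5)
        path = lasso_path(X, y, lams[:1])
        assert np.allclose(path[0, 1:], 0.0, atol=1e-6)

    def test_unregularized_limit_fits_separable_data(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)  # separable on column 0
        X = (X - X.mean(0)) / X.std(0)
        lams = lambda_grid(X, y, n=10, decades=3.0)
        path = lasso_path(X, y, lams)
        p = 1 / (1 + np.exp(-(path[-1, 0] + X @ path[-1, 1:])))
        assert np.mean((p > 0.5) == y) == 1.0

    def test_informative_column_enters_first(self):
        X, y = self._xy(n=200, informative=3, seed=5)
        lams = lambda_grid(X, y, n=40, decades=2.0)
        path = lasso_path(X, y, lams)
        entering = next(i for i in range(len(lams)) if np.any(np.abs(path[i, 1:]) > 1e-8))
        first = int(np.argmax(np.abs(path[entering, 1:])))
        # matches the univariate score ordering
        assert first == int(np.argmax(np.abs(X.T @ (y - y.mean()))))
        assert first == 3


class TestCvSelect:
    def test_one_se_never_below_min(self):
        X, y = TestLassoPath._xy(n=80, informative=1, seed=2)
        lams = lambda_grid(X, y, n=25, decades=2.5)
        lam_1se, _ = cv_select(X, y, lams, folds=5, rule="1se", rng=0)
        lam_min, _ = cv_select(X, y, lams, folds=5, rule="min", rng=0)
        assert lam_1se >= lam_min

    def test_pure_noise_selects_null_model(self):
        selected_null = 0
        reps = 10
        for r in range(reps):
            X, y = TestLassoPath._xy(n=60, p=10, seed=100 + r)
            lams = lambda_grid(X, y, n=30, decades=2.5)
            lam, _ = cv_select(X, y, lams, folds=5, rule="1se", rng=r)
            path = lasso_path(X, y, np.array([lam]))
            if np.allclose(path[0, 1:], 0.0, atol=1e-6):
                selected_null += 1
        assert selected_null >= 0.8 * reps

    def test_seeded_reproducibility(self):
        X, y = TestLassoPath._xy(n=80, informative=0, seed=4)
        lams = lambda_grid(X, y, n=15, decades=2.0)
        a, ta = cv_select(X, y, lams, folds=5, rng=9)
        b, tb = cv_select(X, y, lams, folds=5, rng=9)
        assert a == b
        pd.testing.assert_frame_equal(ta, tb)


class TestEvaluateAndLeakage:
    def test_auc_trivial_cases(self):
        y = np.array([0, 0, 1, 1])
        assert auc_rank(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        rng = np.random.default_rng(0)
        yy = (rng.random(4000) < 0.5).astype(int)
        assert abs(auc_rank(rng.random(4000), yy) - 0.5) < 0.05

    def test_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 5, 30).astype(float)  # ties on purpose
        y = (rng.random(30) < 0.5).astype(int)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
        assert np.isclose(auc_rank(scores, y), wins / (pos.size * neg.size))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.random(50)
        y = (rng.random(50) < 0.5).astype(int)
        a = auc_rank(scores, y)
        assert np.isclose(auc_rank(np.exp(5 * scores), y), a)
        assert np.isclose(auc_rank(np.log(scores + 1e-9), y), a)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(ValueError):
            auc_rank(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_no_leakage_from_test_rows(self):
        table = _metric_table(n=60, signal=2.0, seed=6)
        fm = assemble_features(table)
        tr, te = split_stratified(fm.y, rng=1)
        model_a = fit_lasso_classifier(fm, tr, folds=4, rng=2)
        # corrupt every test row wildly; the fitted model must be identical
        fm.X[te] = fm.X[te] * 1e3 + 77.7
        model_b = fit_lasso_classifier(fm, tr, folds=4, rng=2)
        assert model_a.lam == model_b.lam
        np.testing.assert_array_equal(model_a.coef, model_b.coef)
        np.testing.assert_array_equal(model_a.train_mean, model_b.train_mean)
        np.testing.assert_array_equal(model_a.impute_values, model_b.impute_values)

    def test_end_to_end_on_strong_synthetic_signal(self):
        table = _metric_table(n=120, signal=3.0, seed=7)
        fm = assemble_features(table)
        tr, te = split_stratified(fm.y, rng=0)
        model = fit_lasso_classifier(fm, tr, folds=5, rng=0)
        rep = evaluate(model, fm.X[te], fm.y[te])
        assert rep.auc > 0.8
        assert ("bis@8.3-10.5", ) [0] in [c for c, _ in model.nonzero]
        # ROC endpoints and monotonicity
        assert rep.roc["fpr"].iloc[0] == 0.0 and rep.roc["tpr"].iloc[-1] == 1.0
        assert rep.roc["tpr"].is_monotonic_increasing
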