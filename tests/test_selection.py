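import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold
from sklearn.preprocessing import PowerTransformer

from cardiopsych.errors import ParameterError
from cardiopsych.selection import (SelectionConfig, drop_collinear,
                                   evaluate_heldout, fit_pipeline,
                                   forward_select, impute_missing,
                                   remove_outliers, run_selection,
                                   split_train_test, _ols_beta, _r2)
from cardiopsych.synth import CohortSpec, generate_cohort

from conftest import planted_cohort

FAST = SelectionConfig(max_features=6, outlier_contamination=0.0,
                       feature_transformers=("none",),
                       target_transformers=("none",), seed=0)


@pytest.fixture(scope="module")
def cohort90():
    return planted_cohort(0)


class TestSplit:
    def test_partition_arithmetic(self, cohort90):
        feats, targets, _ = cohort90
        xtr, ytr, xte, yte, test_idx = split_train_test(feats,
                                                        targets["beck"], FAST)
        assert len(xte) in (22, 23)
        assert len(xtr) + len(xte) == 90
        assert set(xtr.index).isdisjoint(set(xte.index))
        assert list(test_idx) == list(xte.index)

    def test_determinism(self, cohort90):
        feats, targets, _ = cohort90
        a = split_train_test(feats, targets["beck"], FAST)[4]
        b = split_train_test(feats, targets["beck"], FAST)[4]
        assert list(a) == list(b)

    def test_small_n_fallback(self):
        feats = pd.DataFrame({"f": np.arange(6.0)})
        target = pd.Series([1.0, 1.0, 1.0, 1.0, 1.0, 2.0])
        xtr, ytr, xte, yte, _ = split_train_test(feats, target, FAST)
        assert len(xtr) + len(xte) == 6


class TestOutliers:
    def test_zero_contamination(self, cohort90):
        feats, _, _ = cohort90
        mask, counts = remove_outliers(feats, 0.0, 0)
        assert mask.all()
        assert counts == {"total": 90, "detected": 0, "processed": 90}

    def test_planted_gross_outlier_flagged(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((90, 10))
            x[13] = 10.0
            table = pd.DataFrame(x)
            mask, counts = remove_outliers(table, 1.0 / 90.0, seed)
            assert counts["detected"] == 1
            hits += int(not mask.iloc[13])
        assert hits >= 18

    def test_bookkeeping_identity(self, cohort90):
        feats, _, _ = cohort90
        for contamination in (0.05, 0.1, 0.2):
            _, counts = remove_outliers(feats, contamination, 1)
            assert counts["processed"] == counts["total"] - counts["detected"]

    def test_contamination_bound(self, cohort90):
        feats, _, _ = cohort90
        with pytest.raises(ParameterError):
            remove_outliers(feats, 0.5, 0)


class TestImpute:
    def test_identity_when_complete(self, cohort90):
        feats, _, _ = cohort90
        tr, te = feats.iloc[:60], feats.iloc[60:]
        tr2, te2, fills, dropped = impute_missing(tr, te)
        assert tr2.equals(tr) and te2.equals(te) and dropped == []

    def test_train_median_applied_to_test(self):
        tr = pd.DataFrame({"a": [1.0, 3.0, np.nan]})
        te = pd.DataFrame({"a": [np.nan, 7.0]})
        tr2, te2, fills, _ = impute_missing(tr, te)
        assert fills["a"] == 2.0
        assert te2["a"].tolist() == [2.0, 7.0]
        assert tr2["a"].tolist() == [1.0, 3.0, 2.0]

    def test_no_test_leakage(self):
        tr = pd.DataFrame({"a": [1.0, 3.0, np.nan], "b": [1.0, 2.0, 3.0]})
        te1 = pd.DataFrame({"a": [np.nan, 7.0], "b": [0.0, 1.0]})
        te2 = pd.DataFrame({"a": [np.nan, 9999.0], "b": [-50.0, 3.0]})
        _, _, fills1, _ = impute_missing(tr, te1)
        _, _, fills2, _ = impute_missing(tr, te2)
        assert fills1.equals(fills2)

    def test_all_missing_column_dropped(self):
        tr = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        te = pd.DataFrame({"a": [5.0], "b": [3.0]})
        tr2, te2, _, dropped = impute_missing(tr, te)
        assert dropped == ["a"]
        assert "a" not in tr2.columns and "a" not in te2.columns


class TestCollinearity:
    def test_duplicate_column_single_copy(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        table = pd.DataFrame({"a": x, "b": x.copy(),
                              "c": rng.standard_normal(50)})
        y = pd.Series(x + 0.1 * rng.standard_normal(50))
        kept = drop_collinear(table, y)
        assert sum(c in kept for c in ("a", "b")) == 1
        assert "c" in kept

    def test_informative_member_retained(self):
        wins = 0
        for seed in range(20):
            spec = CohortSpec(n_subjects=90, n_features=6,
                              informative={"beck": [(0, 1.0)]},
                              noise_sd={"beck": 0.5},
                              collinear_pairs=((0, 1, 0.9),), seed=seed)
            feats, targets, _ = generate_cohort(spec)
            kept = drop_collinear(feats, targets["beck"])
            if "feat_000" in kept and "feat_001" not in kept:
                wins += 1
        assert wins >= 15

    def test_postcondition_max_abs_r(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((60, 4))
        cols = {f"c{i}": base[:, i % 4] + 0.3 * rng.standard_normal(60)
                for i in range(12)}
        table = pd.DataFrame(cols)
        y = pd.Series(rng.standard_normal(60))
        kept = drop_collinear(table, y, threshold=0.7)
        corr = table[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.7 + 1e-12


class TestForwardSelect:
    def test_first_feature_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.standard_normal((80, 10)),
                         columns=[f"x{i}" for i in range(10)])
        y = pd.Series(2.0 * x["x1"] + 0.01 * rng.standard_normal(80))
        path = forward_select(x, y, FAST)
        assert path.features[0] == "x1"
        # exhaustive size-1 subset oracle with the same folds
        kf = KFold(n_splits=FAST.cv_folds, shuffle=True,
                   random_state=FAST.seed)
        folds = list(kf.split(x))
        best_col, best_score = None, -np.inf
        for col in x.columns:
            scores = []
            for tr, va in folds:
                b = _ols_beta(x[[col]].to_numpy()[tr], y.to_numpy()[tr])
                pred = b[0] + x[[col]].to_numpy()[va] @ b[1:]
                scores.append(_r2(y.to_numpy()[va], pred))
            if np.mean(scores) > best_score:
                best_col, best_score = col, float(np.mean(scores))
        assert path.features[0] == best_col
        assert path.step_mean[0] == pytest.approx(best_score, abs=1e-12)

    def test_insample_r2_nondecreasing_along_path(self, cohort90):
        feats, targets, _ = cohort90
        path = forward_select(feats.iloc[:, :20], targets["beck"], FAST)
        x, y = feats.iloc[:, :20], targets["beck"].to_numpy()
        last = -np.inf
        for k in range(1, len(path.features) + 1):
            sub = x[path.features[:k]].to_numpy()
            beta = _ols_beta(sub, y)
            r2 = _r2(y, beta[0] + sub @ beta[1:])
            assert r2 >= last - 1e-10
            last = r2

    def test_path_nested_and_unique(self, cohort90):
        feats, targets, _ = cohort90
        path = forward_select(feats.iloc[:, :15], targets["beck"], FAST)
        assert len(set(path.features)) == len(path.features)
        assert path.chosen_features == path.features[:path.chosen_k]
        assert path.chosen_k <= path.best_k

    def test_column_permutation_invariance(self, cohort90):
        feats, targets, _ = cohort90
        sub = feats.iloc[:, :12]
        a = forward_select(sub, targets["beck"], FAST)
        b = forward_select(sub[list(sub.columns[::-1])], targets["beck"], FAST)
        assert set(a.features) == set(b.features)

    def test_one_se_vs_argmax(self, cohort90):
        feats, targets, _ = cohort90
        plain = forward_select(feats, targets["beck"],
                               SelectionConfig(max_features=10,
                                               feature_transformers=("none",),
                                               target_transformers=("none",),
                                               one_se_rule=False, seed=0))
        assert plain.chosen_k == plain.best_k

    def test_empty_candidates(self, cohort90):
        feats, targets, _ = cohort90
        with pytest.raises(ParameterError):
            forward_select(feats.iloc[:, :0], targets["beck"], FAST)


class TestTransformers:
    def test_yeo_johnson_lambda_one_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 1))
        pt = PowerTransformer(method="yeo-johnson", standardize=False)
        pt.fit(x)
        pt.lambdas_ = np.array([1.0])
        np.testing.assert_allclose(pt.transform(x), x, atol=1e-12)

    def test_box_cox_skipped_on_nonpositive_target(self, cohort90):
        feats, targets, _ = cohort90
        y = targets["beck"] - targets["beck"].min()  # contains an exact 0
        cfg = SelectionConfig(max_features=3, outlier_contamination=0.0,
                              feature_transformers=("none",),
                              target_transformers=("none", "box-cox"), seed=0)
        res = fit_pipeline(feats.iloc[:, :10], y, cfg)
        assert any("box-cox" in s[1] for s in res.skipped_cells)
        assert len(res.grid) == 2  # skipped cell still present in the grid
        assert res.grid[res.grid.skipped].shape[0] == 1

    def test_none_none_near_best_on_gaussian_data(self):
        gaps = []
        for seed in range(8):
            feats, targets, _ = planted_cohort(700 + seed, n_features=12)
            cfg = SelectionConfig(max_features=5, outlier_contamination=0.0,
                                  seed=seed)
            xtr, ytr, _, _, _ = split_train_test(feats, targets["beck"], cfg)
            res = fit_pipeline(xtr, ytr, cfg)
            grid = res.grid[~res.grid.skipped]
            best = grid.cv_r2.max()
            none_row = grid[(grid.feature_transformer == "none")
                            & (grid.target_transformer == "none")]
            se = float(np.std(res.path.step_fold_scores[res.path.best_k - 1],
                              ddof=1) / np.sqrt(cfg.cv_folds))
            gaps.append(float(best - none_row.cv_r2.iloc[0]) - se)
        assert np.median(gaps) <= 0.0


class TestPipeline:
    def test_evaluate_on_train_returns_insample_r2(self, cohort90):
        feats, targets, _ = cohort90
        res = fit_pipeline(feats, targets["beck"], FAST)
        r2_eval = evaluate_heldout(res.fitted, feats, targets["beck"])
        pred = res.fitted.predict(feats)
        assert r2_eval == pytest.approx(
            _r2(targets["beck"].to_numpy(), pred), abs=1e-12)
        # independent refit of the final OLS on the selected features
        sub = feats[res.fitted.selected_features].to_numpy()
        beta = _ols_beta(sub, targets["beck"].to_numpy())
        np.testing.assert_allclose(beta, res.fitted.beta, atol=1e-8)

    def test_leakage_guard(self, cohort90):
        feats, targets, _ = cohort90
        xtr, ytr, xte, yte, _ = split_train_test(feats, targets["beck"], FAST)
        res = fit_pipeline(xtr, ytr, FAST)
        rng = np.random.default_rng(0)
        noise = pd.Series(rng.standard_normal(len(yte)), index=yte.index)
        res2 = fit_pipeline(xtr, ytr, FAST)
        assert res.fitted.selected_features == res2.fitted.selected_features
        np.testing.assert_array_equal(res.fitted.beta, res2.fitted.beta)
        # evaluating on noise only changes the held-out score
        r2_true_y = evaluate_heldout(res.fitted, xte, yte)
        r2_noise = evaluate_heldout(res.fitted, xte, noise)
        assert r2_true_y != r2_noise

    def test_deterministic_rerun(self, cohort90):
        feats, targets, _ = cohort90
        a = run_selection(feats, targets["beck"], FAST)
        b = run_selection(feats, targets["beck"], FAST)
        assert a.selected_features == b.selected_features
        assert a.test_r2 == b.test_r2
        np.testing.assert_array_equal(a.path.step_mean, b.path.step_mean)

    def test_result_bookkeeping(self, cohort90):
        feats, targets, _ = cohort90
        cfg = SelectionConfig(max_features=5, outlier_contamination=0.08,
                              feature_transformers=("none",),
                              target_transformers=("none",), seed=1)
        res = run_selection(feats, targets["beck"], cfg, target_name="beck")
        c = res.outlier_counts
        assert c["processed"] == c["total"] - c["detected"]
        assert res.target == "beck"
        top = res.top_features(3)
        assert list(top.columns) == ["rank", "feature", "coefficient"]
        assert len(top) == min(3, len(res.selected_features))
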