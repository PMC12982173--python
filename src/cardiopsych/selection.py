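"""Nested forward feature selection with held-out evaluation.

Pipeline order (all statistics fitted on training data only):

    split -> outlier removal (isolation forest) -> median imputation ->
    collinearity filter (|r| > threshold) -> transformer grid ->
    forward sequential selection (OLS, 5-fold CV R^2) -> one held-out score

The base model is ordinary least squares; the number of selected features is
the smallest one within one standard error of the best mean CV R^2 (the
"prefer fewer features" rule), or the plain argmax when ``one_se_rule`` is
off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest
from sklearn.model_selection import KFold, train_test_split
from sklearn.preprocessing import PowerTransformer, QuantileTransformer

from cardiopsych.errors import (ConfigurationError, InsufficientDataError,
                                ParameterError)

log = logging.getLogger(__name__)

FEATURE_TRANSFORMERS = ("none", "quantile", "yeo-johnson")
TARGET_TRANSFORMERS = ("none", "box-cox", "yeo-johnson")


@dataclass(frozen=True)
class SelectionConfig:
    max_features: int = 40
    cv_folds: int = 5
    collinearity_threshold: float = 0.7
    outlier_contamination: float = 0.08
    test_fraction: float = 0.25
    feature_transformers: tuple = FEATURE_TRANSFORMERS
    target_transformers: tuple = TARGET_TRANSFORMERS
    one_se_rule: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_features < 1:
            raise ParameterError("max_features must be >= 1")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if not 0.0 < self.collinearity_threshold < 1.0:
            raise ParameterError("collinearity_threshold must be in (0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ParameterError("test_fraction must be in (0, 1)")
        for t in self.feature_transformers:
            if t not in FEATURE_TRANSFORMERS:
                raise ParameterError(f"unknown feature transformer {t!r}")
        for t in self.target_transformers:
            if t not in TARGET_TRANSFORMERS:
                raise ParameterError(f"unknown target transformer {t!r}")


# --- split ------------------------------------------------------------------

def split_train_test(features: pd.DataFrame, target: pd.Series,
                     config: SelectionConfig):
    """Seed-deterministic split, stratified by target quartile when possible."""
    idx = features.index
    strata = None
    try:
        labels = pd.qcut(target, 4, labels=False, duplicates="drop")
        if labels.value_counts().min() >= 2 and labels.nunique() >= 2:
            strata = labels
    except ValueError:
        pass
    try:
        if strata is None:
            raise ValueError("no strata")
        train_idx, test_idx = train_test_split(
            np.asarray(idx), test_size=config.test_fraction,
            random_state=config.seed, stratify=np.asarray(strata))
    except ValueError:
        log.warning("stratification by target quartile not possible; "
                    "falling back to a simple random split")
        train_idx, test_idx = train_test_split(
            np.asarray(idx), test_size=config.test_fraction,
            random_state=config.seed)
    train_idx = pd.Index(train_idx)
    test_idx = pd.Index(test_idx)
    return (features.loc[train_idx], target.loc[train_idx],
            features.loc[test_idx], target.loc[test_idx], test_idx)


# --- outliers ---------------------------------------------------------------

def remove_outliers(train: pd.DataFrame, contamination: float, seed: int
                    ) -> tuple[pd.Series, dict]:
    """Isolation-forest keep-mask over training rows plus Table-1-style counts."""
    if contamination >= 0.5:
        raise ParameterError("contamination must be below 0.5")
    n = len(train)
    if contamination <= 0.0:
        mask = pd.Series(True, index=train.index)
        return mask, {"total": n, "detected": 0, "processed": n}
    filled = train.fillna(train.median(numeric_only=True)).fillna(0.0)
    forest = IsolationForest(n_estimators=200, contamination=contamination,
                             random_state=seed)
    flags = forest.fit_predict(filled.to_numpy(dtype=float))
    mask = pd.Series(flags == 1, index=train.index)
    detected = int((~mask).sum())
    return mask, {"total": n, "detected": detected, "processed": n - detected}


# --- imputation -------------------------------------------------------------

def impute_missing(train: pd.DataFrame, test: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, list]:
    """Train-median fill applied to both tables; all-missing columns dropped."""
    if list(train.columns) != list(test.columns):
        test = test[train.columns]
    dropped = [c for c in train.columns if train[c].isna().all()]
    if dropped:
        log.warning("dropping all-missing training columns: %s", dropped)
        train = train.drop(columns=dropped)
        test = test.drop(columns=dropped)
    fills = train.median()
    return train.fillna(fills), test.fillna(fills), fills, dropped


# --- collinearity -----------------------------------------------------------

def drop_collinear(train: pd.DataFrame, target: pd.Series,
                   threshold: float = 0.7) -> list[str]:
    """Greedy collinearity filter.

    Features are visited in decreasing |Pearson r with the training target|
    (ties by column order); a feature is kept only if its |r| with every
    already-kept feature stays at or below the threshold — so within any
    over-threshold pair the member more correlated with the target survives.
    """
    cols = list(train.columns)
    x = train.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = x - np.nanmean(x, axis=0)
        ym = y - np.mean(y)
        sx = np.sqrt(np.nansum(xm ** 2, axis=0))
        r_target = np.nansum(xm * ym[:, None], axis=0) / (sx * np.sqrt(np.sum(ym ** 2)))
    r_target = np.where(np.isfinite(r_target), np.abs(r_target), -1.0)

    corr = np.abs(np.corrcoef(np.nan_to_num(xm, nan=0.0), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)

    order = sorted(range(len(cols)), key=lambda j: (-r_target[j], j))
    kept: list[int] = []
    for j in order:
        if all(corr[j, k] <= threshold for k in kept):
            kept.append(j)
    kept_set = set(kept)
    return [c for j, c in enumerate(cols) if j in kept_set]


# --- OLS + cross-validation helpers ----------------------------------------

def _ols_beta(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xd = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(xd, y, rcond=None)
    return beta


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - np.mean(y_true)) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _cv_scores(x: np.ndarray, y: np.ndarray, folds: list) -> np.ndarray:
    scores = np.empty(len(folds))
    for i, (tr, va) in enumerate(folds):
        beta = _ols_beta(x[tr], y[tr])
        pred = beta[0] + x[va] @ beta[1:]
        scores[i] = _r2(y[va], pred)
    return scores


# --- forward selection ------------------------------------------------------

@dataclass
class ForwardPath:
    """Nested selection path with per-step CV scores."""

    features: list                 # column names in selection order
    step_mean: np.ndarray          # mean CV R^2 after adding feature k+1
    step_fold_scores: list         # per-step fold-score arrays
    chosen_k: int                  # 1-based size of the chosen model
    best_k: int                    # plain argmax size

    @property
    def chosen_features(self) -> list:
        return self.features[:self.chosen_k]

    @property
    def train_cv_r2(self) -> float:
        return float(self.step_mean[self.chosen_k - 1])


def forward_select(train: pd.DataFrame, target: pd.Series,
                   config: SelectionConfig) -> ForwardPath:
    """Stepwise forward selection by mean K-fold CV R^2 of OLS."""
    cols = list(train.columns)
    if len(cols) < 1:
        raise ParameterError("forward selection needs at least one candidate")
    x = train.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(kf.split(x))
    min_fold_train = min(len(tr) for tr, _ in folds)
    cap = min(config.max_features, len(cols), max(min_fold_train - 2, 1))

    selected: list[int] = []
    remaining = list(range(len(cols)))
    step_mean: list[float] = []
    step_folds: list[np.ndarray] = []
    for _ in range(cap):
        best_j, best_mean, best_scores = None, -np.inf, None
        for j in remaining:  # ascending column index -> deterministic ties
            scores = _cv_scores(x[:, selected + [j]], y, folds)
            m = float(scores.mean())
            if m > best_mean:
                best_j, best_mean, best_scores = j, m, scores
        selected.append(best_j)
        remaining.remove(best_j)
        step_mean.append(best_mean)
        step_folds.append(best_scores)

    means = np.array(step_mean)
    best_idx = int(np.argmax(means))  # first max -> smaller model on ties
    chosen_idx = best_idx
    if config.one_se_rule:
        se = float(np.std(step_folds[best_idx], ddof=1)
                   / math.sqrt(config.cv_folds))
        within = np.flatnonzero(means >= means[best_idx] - se)
        chosen_idx = int(within[0])
    return ForwardPath(features=[cols[j] for j in selected],
                       step_mean=means, step_fold_scores=step_folds,
                       chosen_k=chosen_idx + 1, best_k=best_idx + 1)


# --- transformers -----------------------------------------------------------

def make_feature_transformer(name: str, seed: int, n_samples: int):
    if name == "none":
        return None
    if name == "quantile":
        return QuantileTransformer(output_distribution="normal",
                                   n_quantiles=min(n_samples, 1000),
                                   random_state=seed)
    if name == "yeo-johnson":
        return PowerTransformer(method="yeo-johnson")
    raise ConfigurationError(f"unknown feature transformer {name!r}")


def make_target_transformer(name: str):
    if name == "none":
        return None
    if name == "box-cox":
        return PowerTransformer(method="box-cox")
    if name == "yeo-johnson":
        return PowerTransformer(method="yeo-johnson")
    raise ConfigurationError(f"unknown target transformer {name!r}")


@dataclass
class FittedPipeline:
    """Everything fitted on training data, applicable to unseen rows."""

    fills: pd.Series
    dropped_columns: list
    retained_columns: list
    feature_transformer_name: str
    target_transformer_name: str
    feature_transformer: object
    target_transformer: object
    selected_features: list
    beta: np.ndarray               # [intercept, coefs] in transformed space

    def _transform_features(self, features: pd.DataFrame) -> pd.DataFrame:
        x = features.drop(columns=[c for c in self.dropped_columns
                                   if c in features.columns])
        x = x[self.retained_columns].fillna(self.fills[self.retained_columns])
        if self.feature_transformer is not None:
            vals = self.feature_transformer.transform(x.to_numpy(dtype=float))
            x = pd.DataFrame(vals, index=x.index, columns=self.retained_columns)
        return x

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = self._transform_features(features)[self.selected_features]
        pred = self.beta[0] + x.to_numpy(dtype=float) @ self.beta[1:]
        if self.target_transformer is not None:
            pred = self.target_transformer.inverse_transform(
                pred.reshape(-1, 1)).ravel()
        return pred

    @property
    def coefficients(self) -> dict:
        return {name: float(b)
                for name, b in zip(self.selected_features, self.beta[1:])}


def evaluate_heldout(fitted: FittedPipeline, features: pd.DataFrame,
                     target: pd.Series) -> float:
    """R^2 on the held-out set, on the original target scale (may be negative)."""
    if len(target) < 3:
        raise InsufficientDataError("held-out evaluation needs >= 3 subjects")
    pred = fitted.predict(features)
    return _r2(target.to_numpy(dtype=float), pred)


# --- transformer grid + full training-side pipeline -------------------------

@dataclass
class SelectionResult:
    target: str
    path: ForwardPath
    fitted: FittedPipeline
    grid: pd.DataFrame
    skipped_cells: list
    outlier_counts: dict
    train_cv_r2: float
    test_r2: float | None
    test_index: pd.Index | None
    config: SelectionConfig

    @property
    def selected_features(self) -> list:
        return self.fitted.selected_features

    def top_features(self, k: int = 10) -> pd.DataFrame:
        rows = [{"rank": i + 1, "feature": f,
                 "coefficient": self.fitted.coefficients[f]}
                for i, f in enumerate(self.selected_features[:k])]
        return pd.DataFrame(rows, columns=["rank", "feature", "coefficient"])


def fit_pipeline(train: pd.DataFrame, y_train: pd.Series,
                 config: SelectionConfig, target_name: str = "target"
                 ) -> SelectionResult:
    """Run every training-side stage; no test data enters here."""
    mask, counts = remove_outliers(train, config.outlier_contamination,
                                   config.seed)
    train = train.loc[mask[mask].index]
    y_train = y_train.loc[train.index]

    dropped_all_missing = [c for c in train.columns if train[c].isna().all()]
    if dropped_all_missing:
        log.warning("dropping all-missing columns: %s", dropped_all_missing)
        train = train.drop(columns=dropped_all_missing)
    fills = train.median()
    train_filled = train.fillna(fills)

    constant = [c for c in train_filled.columns
                if train_filled[c].nunique(dropna=True) <= 1]
    if constant:
        log.warning("dropping constant columns: %s", constant)
        train_filled = train_filled.drop(columns=constant)
        dropped_all_missing = dropped_all_missing + constant

    retained = drop_collinear(train_filled, y_train,
                              config.collinearity_threshold)
    train_ret = train_filled[retained]

    grid_rows, skipped, cells = [], [], []
    for ft_name in config.feature_transformers:
        for tt_name in config.target_transformers:
            if tt_name == "box-cox" and (y_train <= 0).any():
                msg = ("box-cox skipped: training target has non-positive "
                       "values")
                log.warning("%s/%s: %s", ft_name, tt_name, msg)
                skipped.append((ft_name, tt_name, msg))
                grid_rows.append({"feature_transformer": ft_name,
                                  "target_transformer": tt_name,
                                  "cv_r2": np.nan, "n_features": 0,
                                  "skipped": True})
                continue
            ft = make_feature_transformer(ft_name, config.seed, len(train_ret))
            tt = make_target_transformer(tt_name)
            if ft is not None:
                xvals = ft.fit_transform(train_ret.to_numpy(dtype=float))
                xdf = pd.DataFrame(xvals, index=train_ret.index,
                                   columns=retained)
            else:
                xdf = train_ret
            if tt is not None:
                yvals = tt.fit_transform(
                    y_train.to_numpy(dtype=float).reshape(-1, 1)).ravel()
                yt = pd.Series(yvals, index=y_train.index)
            else:
                yt = y_train
            path = forward_select(xdf, yt, config)
            best_mean = float(path.step_mean[path.best_k - 1])
            cells.append((ft_name, tt_name, ft, tt, xdf, yt, path, best_mean))
            grid_rows.append({"feature_transformer": ft_name,
                              "target_transformer": tt_name,
                              "cv_r2": best_mean,
                              "n_features": path.chosen_k, "skipped": False})
    if not cells:
        raise ConfigurationError("transformer grid empty after skips")

    ft_name, tt_name, ft, tt, xdf, yt, path, _ = max(
        cells, key=lambda c: c[7])
    chosen = path.chosen_features
    beta = _ols_beta(xdf[chosen].to_numpy(dtype=float),
                     yt.to_numpy(dtype=float))
    fitted = FittedPipeline(
        fills=fills, dropped_columns=dropped_all_missing,
        retained_columns=retained,
        feature_transformer_name=ft_name, target_transformer_name=tt_name,
        feature_transformer=ft, target_transformer=tt,
        selected_features=chosen, beta=beta)
    return SelectionResult(
        target=target_name, path=path, fitted=fitted,
        grid=pd.DataFrame(grid_rows), skipped_cells=skipped,
        outlier_counts=counts, train_cv_r2=path.train_cv_r2,
        test_r2=None, test_index=None, config=config)


def run_selection(features: pd.DataFrame, target: pd.Series,
                  config: SelectionConfig, target_name: str = "target"
                  ) -> SelectionResult:
    """Split, fit every training-side stage, then score the held-out set once."""
    x_tr, y_tr, x_te, y_te, test_idx = split_train_test(features, target,
                                                        config)
    result = fit_pipeline(x_tr, y_tr, config, target_name=target_name)
    result.test_r2 = evaluate_heldout(result.fitted, x_te, y_te)
    result.test_index = test_idx
    return result


def default_config_variants(config: SelectionConfig, seed: int
                            ) -> SelectionConfig:
    """Convenience: re-seed a config (frozen dataclass)."""
    return replace(config, seed=seed)
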