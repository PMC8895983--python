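"""Predicting kernel color from carotenoid BLUEs.

Compares ordinary least-squares models (with and without a family term)
against a 1,000-tree random forest on a 70/30 train/test split repeated over
multiple seeds, and reports trait-trait Pearson correlations of untransformed
BLUEs. Baseline Error is the mean absolute prediction error on the test set;
Percent Accuracy is 100 minus 100 x |error| / test value, averaged per test
observation (near-zero test values are excluded from the accuracy average
and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split


def _design_matrix(blues: pd.DataFrame, predictors: Sequence[str],
                   include_family: bool, onehot: bool) -> pd.DataFrame:
    X = blues[list(predictors)].astype(float).copy()
    if include_family:
        if onehot:
            fam = pd.get_dummies(blues["family"].astype(str),
                                 prefix="family", drop_first=True)
            X = pd.concat([X, fam.astype(float)], axis=1)
        else:
            X["family"] = pd.factorize(blues["family"])[0].astype(float)
    return X


def compare_linear_models(blues: pd.DataFrame, response: str,
                          model_specs: Mapping[str, dict]) -> pd.DataFrame:
    """OLS comparison across model specifications.

    ``model_specs`` maps a model name to {"predictors": [...],
    "family": bool}. Rows with any missing value among response and
    predictors are dropped listwise per model. Family enters one-hot with a
    reference level. Rank-deficient specs are reported (r2 = NaN), not fatal.
    """
    rows = []
    for name, spec in model_specs.items():
        preds = list(spec["predictors"])
        with_fam = bool(spec.get("family", False))
        cols = [response] + preds + (["family"] if with_fam else [])
        sub = blues[cols].dropna()
        X = _design_matrix(sub, preds, with_fam, onehot=True)
        Xc = sm.add_constant(X.to_numpy(dtype=float))
        try:
            if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                raise np.linalg.LinAlgError("rank deficient design")
            fit = sm.OLS(sub[response].to_numpy(dtype=float), Xc).fit()
            rows.append((name, ",".join(preds), with_fam, len(sub),
                         float(fit.rsquared), float(fit.aic), float(fit.bic),
                         "ok"))
        except np.linalg.LinAlgError as e:
            rows.append((name, ",".join(preds), with_fam, len(sub),
                         np.nan, np.nan, np.nan, f"failed: {e}"))
    return pd.DataFrame(rows, columns=["model", "predictors", "family_term",
                                       "n", "r2", "aic", "bic", "status"])


@dataclass
class RFReport:
    test_fraction: float
    n_trees: int
    n_seeds: int
    rf_r2_test: float
    linear_r2_test: float
    baseline_error: float
    percent_accuracy: float
    n_excluded_accuracy: int
    importances: pd.Series = dc_field(default=None)
    per_seed: pd.DataFrame = dc_field(default=None)


def fit_random_forest(blues: pd.DataFrame, response: str,
                      predictors: Sequence[str], include_family: bool = True,
                      test_fraction: float = 0.3, n_trees: int = 1000,
                      seeds: Sequence[int] = tuple(range(30)),
                      ) -> RFReport:
    """Random forest vs linear model on identical train/test splits.

    Per seed: split (test_fraction held out), fit a random forest
    (``n_trees`` trees; family passed as integer codes) and a linear model
    (family one-hot) on the same training rows, and compute test R^2,
    Baseline Error and Percent Accuracy. Metrics and impurity importances
    are averaged over seeds.
    """
    cols = [response] + list(predictors) + (["family"] if include_family else [])
    sub = blues[cols].dropna().reset_index(drop=True)
    vals = sub[list(predictors)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite feature values")
    y = sub[response].to_numpy(dtype=float)
    X_rf = _design_matrix(sub, predictors, include_family, onehot=False)
    X_lm = _design_matrix(sub, predictors, include_family, onehot=True)
    feat_names = list(X_rf.columns)
    rows, importances = [], []
    n_excluded = 0
    for seed in seeds:
        idx_train, idx_test = train_test_split(
            np.arange(len(sub)), test_size=test_fraction, random_state=seed)
        rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed,
                                   n_jobs=1)
        rf.fit(X_rf.iloc[idx_train], y[idx_train])
        yhat_rf = rf.predict(X_rf.iloc[idx_test])
        lm = LinearRegression()
        lm.fit(X_lm.iloc[idx_train], y[idx_train])
        yhat_lm = lm.predict(X_lm.iloc[idx_test])
        y_test = y[idx_test]
        abs_err = np.abs(yhat_rf - y_test)
        usable = np.abs(y_test) >= 1e-6
        n_excluded += int((~usable).sum())
        pacc = float(np.mean(100.0 - 100.0 * abs_err[usable]
                             / np.abs(y_test[usable])))
        rows.append((seed, r2_score(y_test, yhat_rf),
                     r2_score(y_test, yhat_lm), float(abs_err.mean()), pacc))
        importances.append(rf.feature_importances_)
    per_seed = pd.DataFrame(rows, columns=["seed", "rf_r2", "linear_r2",
                                           "baseline_error",
                                           "percent_accuracy"])
    imp = pd.Series(np.mean(importances, axis=0), index=feat_names)
    imp /= imp.sum()
    return RFReport(
        test_fraction=test_fraction, n_trees=n_trees, n_seeds=len(seeds),
        rf_r2_test=float(per_seed["rf_r2"].mean()),
        linear_r2_test=float(per_seed["linear_r2"].mean()),
        baseline_error=float(per_seed["baseline_error"].mean()),
        percent_accuracy=float(per_seed["percent_accuracy"].mean()),
        n_excluded_accuracy=n_excluded, importances=imp, per_seed=per_seed)


def trait_correlation_matrix(blues: pd.DataFrame,
                             traits: Sequence[str]) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between untransformed BLUEs.

    Symmetric with unit diagonal; cells with fewer than 3 complete pairs or a
    zero-variance trait are NaN (untestable).
    """
    sub = blues[list(traits)].astype(float)
    corr = sub.corr(method="pearson", min_periods=3)
    sds = sub.std()
    for t in traits:
        if not sds[t] > 0:
            corr.loc[t, :] = np.nan
            corr.loc[:, t] = np.nan
        else:
            corr.loc[t, t] = 1.0
    return corr
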