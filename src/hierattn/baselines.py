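"""Cross-sectional comparators: logistic regression, random forest and
gradient-boosted trees on each patient's first observed year of features,
with age/sex mean-mode imputation, evaluated with the same splits, threshold
and bootstrap protocol as the longitudinal model."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from . import evaluation
from .schema import FeatureSchema
from .tensorize import FeatureTensor
from .training import SplitPlan

logger = logging.getLogger(__name__)

BASELINE_MODELS = ("logistic", "random_forest", "boosted_trees")


def build_cross_section(tensor: FeatureTensor, statics: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: the first real (unmasked) period's feature vector
    plus statics; cells unrecorded in that year are NaN, to be imputed."""
    n, t_max, V = tensor.X.shape
    hist = tensor.period_mask.sum(axis=1).astype(int)
    if np.any(hist == 0):
        raise ValueError("patients with zero real periods cannot be cross-sectioned")
    first = t_max - hist                               # right-aligned histories
    rows = np.arange(n)
    x0 = tensor.X[rows, first, :].astype(float)
    m0 = tensor.value_mask[rows, first, :] > 0
    x0[~m0] = np.nan

    df = pd.DataFrame(x0, columns=tensor.variable_index)
    df.insert(0, "patient_id", tensor.patient_ids)
    first_year = tensor.entry_year
    st = statics.set_index("patient_id").loc[tensor.patient_ids]
    birth_year = pd.to_datetime(st["birth_date"]).dt.year.values
    df["age"] = (first_year - birth_year).astype(int)
    df["sex"] = st["sex"].values
    df["ses_quintile"] = st["ses_quintile"].values
    return df


@dataclass
class ImputationModel:
    """Mean (numeric) / mode (categorical) lookups learned from training rows,
    keyed by (age, sex) with fallbacks: same sex & age±2 -> sex only -> global."""
    numeric_cols: list[str]
    categorical_cols: list[str]
    cell_stats: pd.DataFrame         # indexed by (age, sex)
    sex_stats: pd.DataFrame          # indexed by sex
    global_stats: pd.Series


def _mode(series: pd.Series):
    s = series.dropna()
    if s.empty:
        return np.nan
    counts = s.value_counts()
    top = counts[counts == counts.iloc[0]]
    return top.index.min()           # ties -> smallest category


def fit_imputer(table: pd.DataFrame, train_ids, schema: FeatureSchema) -> ImputationModel:
    tr = table.loc[table["patient_id"].isin(set(map(int, train_ids)))]
    cat_cols = [v.variable_id for v in schema.variables if v.value_type == "categorical"]
    cat_cols = [c for c in cat_cols if c in table.columns] + ["ses_quintile"]
    num_cols = [c for c in table.columns
                if c not in cat_cols + ["patient_id", "sex", "age"]]

    def agg(g: pd.DataFrame) -> pd.Series:
        out = g[num_cols].mean()
        for c in cat_cols:
            out[c] = _mode(g[c])
        return out

    cell = tr.groupby(["age", "sex"], sort=True).apply(agg, include_groups=False)
    by_sex = tr.groupby("sex", sort=True).apply(agg, include_groups=False)
    glob = agg(tr)
    return ImputationModel(numeric_cols=num_cols, categorical_cols=cat_cols,
                           cell_stats=cell, sex_stats=by_sex, global_stats=glob)


def impute_age_sex(table: pd.DataFrame, train_ids, schema: FeatureSchema
                   ) -> tuple[pd.DataFrame, pd.DataFrame, ImputationModel]:
    """Fill missing cells with the training-set mean/mode of patients of the
    same age (integer years) and sex; empty cells fall back to age±2 within
    the same sex, then sex only, then the global training value.

    Returns (imputed table, imputation flags, fitted lookup model).
    """
    model = fit_imputer(table, train_ids, schema)
    cols = model.numeric_cols + model.categorical_cols
    flags = table[cols].isna()
    out = table.copy()

    cell = model.cell_stats
    for (age, sex), group in table.groupby(["age", "sex"], sort=False):
        fills = None
        if (age, sex) in cell.index:
            fills = cell.loc[(age, sex)]
        else:
            near = [a for a in range(int(age) - 2, int(age) + 3)
                    if (a, sex) in cell.index]
            if near:
                fills = cell.loc[[(a, sex) for a in near]].mean()
        base = model.sex_stats.loc[sex] if sex in model.sex_stats.index else model.global_stats
        fills = base if fills is None else fills.fillna(base)
        fills = fills.fillna(model.global_stats)
        out.loc[group.index, cols] = group[cols].fillna(fills)
    still = out[cols].isna()
    if still.any().any():
        logger.warning("global fallback left %d cells missing; filled with 0",
                       int(still.sum().sum()))
        out[cols] = out[cols].fillna(0.0)
    return out, flags, model


def _design_matrix(table: pd.DataFrame) -> np.ndarray:
    X = table.drop(columns=["patient_id"]).copy()
    X["sex"] = (X["sex"] == "F").astype(float)
    return X.values.astype(np.float64)


def make_estimator(model: str, seed: int = 0):
    """Library-default estimators (seeded); defaults recorded via get_params."""
    if model == "logistic":
        return LogisticRegression(max_iter=1000)
    if model == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if model == "boosted_trees":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss")
    raise KeyError(f"unknown baseline model {model!r}")


def fit_baseline(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    plan: SplitPlan,
    model: str,
    schema: FeatureSchema,
    seed: int = 0,
    threshold: float = evaluation.DEFAULT_THRESHOLD,
    n_bootstrap: int = 1000,
):
    """Impute, fit one comparator on train+validation patients, and evaluate
    on the test set with bootstrap CIs.

    Returns (estimator, MetricsReport, test probabilities, run_log).
    """
    y = pd.Series(np.asarray(labels, dtype=int), index=table["patient_id"].values)
    fit_ids = np.concatenate([plan.train_ids, plan.val_ids])
    imputed, flags, _ = impute_age_sex(table, fit_ids, schema)

    pid = imputed["patient_id"].values
    in_fit = np.isin(pid, fit_ids)
    in_test = np.isin(pid, plan.test_ids)
    X = _design_matrix(imputed)
    est = make_estimator(model, seed=seed)
    y_fit = y.loc[pid[in_fit]].values
    if len(np.unique(y_fit)) < 2:
        raise ValueError("single-class training labels; baseline undefined")
    est.fit(X[in_fit], y_fit)
    p_test = est.predict_proba(X[in_test])[:, 1]
    y_test = y.loc[pid[in_test]].values
    report = evaluation.bootstrap_report(y_test, p_test, threshold=threshold,
                                         n_bootstrap=n_bootstrap, seed=seed)
    run_log = {"model": model, "hyperparameters": {
        k: v for k, v in est.get_params().items()
        if isinstance(v, (int, float, str, bool, type(None)))
    }, "n_imputed_cells": int(flags.values.sum())}
    return est, report, p_test, run_log


def fit_all_baselines(table, labels, plan, schema, seed=0, threshold=0.5,
                      n_bootstrap=1000) -> dict[str, dict]:
    out = {}
    for model in BASELINE_MODELS:
        est, report, p_test, run_log = fit_baseline(
            table, labels, plan, model, schema, seed=seed,
            threshold=threshold, n_bootstrap=n_bootstrap)
        out[model] = {"report": report, "p_test": p_test, "run_log": run_log}
    return out
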