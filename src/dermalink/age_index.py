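"""Skin age indices and microbial prediction of skin phenotypes.

Out-of-fold random-forest regression of chronological age on skin
imaging phenotypes (SPA), microbial species profiles (SMA), or their
combination (SIA); cross-group model transfer; and random-forest
prediction of individual SIP scores from species abundances with a
normalized mean absolute error.

The forests are scikit-learn RandomForestRegressors (500 trees by
default) inside a seeded 5-fold cross-validation; every sample receives
exactly one out-of-fold prediction, which *is* its skin age.  Feature
importance is permutation importance on the held-out fold, averaged
across folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

__all__ = [
    "AgeIndexResult",
    "SipPredictionResult",
    "fit_age_index",
    "cross_group_transfer",
    "predict_sip_from_species",
    "normalized_mae",
    "combine_features",
]


@dataclass
class AgeIndexResult:
    predictions: pd.Series  # out-of-fold predicted age per sample (years)
    folds: pd.Series  # fold index per sample
    fold_r2: np.ndarray  # held-out R^2 per fold, percent
    mae: float  # years, over all out-of-fold predictions
    importances: pd.DataFrame  # feature, importance_mean, importance_sd


@dataclass
class SipPredictionResult:
    predictions: pd.Series
    fold_r2: np.ndarray  # percent
    mae: float
    normalized_mae: float


def _features_frame(features) -> pd.DataFrame:
    df = pd.DataFrame(features)
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise ValueError("features contain non-finite values")
    return df


def _cv_regression(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    n_trees: int,
    seed: int,
    compute_importance: bool,
    transfer_X: np.ndarray | None = None,
):
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    n = len(y)
    if n < 2 * n_folds:
        raise ValueError("need at least 2 * n_folds samples")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty(n)
    folds = np.empty(n, dtype=int)
    r2 = []
    importances = []
    transfer_preds = []
    for k, (train, test) in enumerate(kf.split(X)):
        model = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed + k, n_jobs=1
        )
        model.fit(X[train], y[train])
        preds[test] = model.predict(X[test])
        folds[test] = k
        r2.append(100.0 * model.score(X[test], y[test]))
        if compute_importance:
            imp = permutation_importance(
                model, X[test], y[test], n_repeats=5, random_state=seed + k, n_jobs=1
            )
            importances.append(imp.importances_mean)
        if transfer_X is not None and len(transfer_X):
            transfer_preds.append(model.predict(transfer_X))
    imp_arr = np.array(importances) if compute_importance else None
    return preds, folds, np.array(r2), imp_arr, transfer_preds


def fit_age_index(
    features,
    ages,
    n_folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
    compute_importance: bool = True,
) -> AgeIndexResult:
    """Cross-validated random-forest age regression.

    Each sample's out-of-fold predicted age is its skin age index.
    Held-out R^2 is reported per fold (percent), MAE over all samples,
    and permutation importances are averaged over folds with their sd.
    """
    df = _features_frame(features)
    y = np.asarray(ages, dtype=float)
    if len(df) != len(y):
        raise ValueError("features and ages must be row-aligned")
    X = df.to_numpy(dtype=float)
    preds, folds, r2, imp, _ = _cv_regression(
        X, y, n_folds, n_trees, seed, compute_importance
    )
    importances = (
        pd.DataFrame(
            {
                "feature": df.columns,
                "importance_mean": imp.mean(axis=0),
                "importance_sd": imp.std(axis=0, ddof=1),
            }
        )
        if imp is not None
        else pd.DataFrame(columns=["feature", "importance_mean", "importance_sd"])
    )
    return AgeIndexResult(
        predictions=pd.Series(preds, index=df.index, name="predicted_age"),
        folds=pd.Series(folds, index=df.index, name="fold"),
        fold_r2=r2,
        mae=float(np.abs(preds - y).mean()),
        importances=importances,
    )


def cross_group_transfer(
    features,
    ages,
    train_mask,
    transfer_mask,
    n_folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[AgeIndexResult, pd.Series]:
    """Train the cross-validated age index on one subgroup and apply it
    to another (e.g. train on females, predict males).

    In each fold the trained model also predicts every transfer sample;
    the final transfer prediction is the mean over the folds' models.
    Returns (train-side AgeIndexResult, transfer predictions).
    """
    df = _features_frame(features)
    y = np.asarray(ages, dtype=float)
    train_mask = np.asarray(train_mask, dtype=bool)
    transfer_mask = np.asarray(transfer_mask, dtype=bool)
    if np.any(train_mask & transfer_mask):
        raise ValueError("train and transfer masks overlap")
    X = df.to_numpy(dtype=float)
    Xt = X[transfer_mask]
    preds, folds, r2, imp, transfer_preds = _cv_regression(
        X[train_mask], y[train_mask], n_folds, n_trees, seed, True, transfer_X=Xt
    )
    train_index = df.index[train_mask]
    result = AgeIndexResult(
        predictions=pd.Series(preds, index=train_index, name="predicted_age"),
        folds=pd.Series(folds, index=train_index, name="fold"),
        fold_r2=r2,
        mae=float(np.abs(preds - y[train_mask]).mean()),
        importances=pd.DataFrame(
            {
                "feature": df.columns,
                "importance_mean": imp.mean(axis=0),
                "importance_sd": imp.std(axis=0, ddof=1),
            }
        ),
    )
    if Xt.shape[0] == 0:
        transfer = pd.Series([], dtype=float, name="predicted_age")
    else:
        transfer = pd.Series(
            np.mean(transfer_preds, axis=0),
            index=df.index[transfer_mask],
            name="predicted_age",
        )
    return result, transfer


def normalized_mae(predicted, observed) -> float:
    """mean(|pred - obs| / obs); defined only for strictly positive obs."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if np.any(o <= 0):
        raise ValueError(
            "normalized MAE divides by the observed value; all observations must be > 0"
        )
    return float(np.mean(np.abs(p - o) / o))


def predict_sip_from_species(
    species,
    sip_scores,
    n_folds: int = 5,
    n_trees: int = 500,
    seed: int = 0,
) -> SipPredictionResult:
    """Random-forest prediction of one SIP score from species profiles.

    Same cross-validation machinery as the age indices, with the SIP as
    the regression target.  ``species`` is features x samples (the usual
    abundance-table orientation) or samples x features.
    """
    df = pd.DataFrame(species)
    y = np.asarray(sip_scores, dtype=float)
    if df.shape[0] != len(y) and df.shape[1] == len(y):
        df = df.T  # accept feature-by-sample tables
    if np.any(y <= 0):
        raise ValueError(
            "normalized MAE divides by the observed score; all observed scores must be > 0"
        )
    res = fit_age_index(
        df, y, n_folds=n_folds, n_trees=n_trees, seed=seed, compute_importance=False
    )
    return SipPredictionResult(
        predictions=res.predictions.rename("predicted_score"),
        fold_r2=res.fold_r2,
        mae=res.mae,
        normalized_mae=normalized_mae(res.predictions.to_numpy(), y),
    )


def combine_features(phenome: pd.DataFrame, species: pd.DataFrame) -> pd.DataFrame:
    """Feature table for the integrated age index: z-scored SIP columns
    concatenated with species relative abundances (samples x features)."""
    z = (phenome - phenome.mean()) / phenome.std(ddof=1)
    sp = species.T if not species.index.equals(phenome.index) else species
    sp = sp.loc[phenome.index]
    return pd.concat([z, sp], axis=1)
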