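"""PLS-DA feature reduction and recursive feature elimination ranking.

PLS-DA fits partial least squares against one-hot class indicators (NIPALS,
via scikit-learn's PLSRegression) and summarizes each feature's contribution
as the sum over components of its squared loading weights. R² measures how
much of the class-indicator variation the fit explains on the training data;
Q² is the same quantity computed from cross-validated predictions, so it
estimates predictive rather than descriptive power.

RFE ranks model features by repeatedly fitting a linear classifier and
discarding the feature with the smallest absolute weight, one at a time; the
last survivor ranks 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureMatrix

__all__ = ["PLSDAResult", "plsda_fit", "plsda_reduce", "permutation_q2",
           "rfe_rank"]


@dataclass
class PLSDAResult:
    """Fitted PLS-DA summary: scores, loading weights, importances, R², Q²."""

    scores: np.ndarray            # samples × components
    x_weights: np.ndarray         # features × components
    importance: pd.Series         # per-feature, sum of squared weights
    r2: float
    q2: float
    n_components: int


def _one_hot(labels: pd.Series) -> np.ndarray:
    classes = np.unique(np.asarray(labels))
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    return (np.asarray(labels)[:, None] == classes[None, :]).astype(float)


def _r2_score_matrix(Y: np.ndarray, Yhat: np.ndarray) -> float:
    ss_res = float(((Y - Yhat) ** 2).sum())
    ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def plsda_fit(matrix: FeatureMatrix, labels: pd.Series | None = None,
              n_components: int = 2, cv_folds: int = 5,
              seed: int = 0) -> PLSDAResult:
    """Fit PLS-DA on a complete matrix against one-hot class indicators.

    R² is the explained-variation fraction of the class indicators on the
    training data; Q² is the cross-validated analogue (1 − PRESS/SS) from
    ``cv_folds`` stratified folds.
    """
    if labels is None:
        labels = matrix.labels
    X = matrix.intensities.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PLS-DA requires a complete (imputed) matrix")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate matrix: all features constant")
    Y = _one_hot(labels)
    n_components = int(n_components)
    if not 1 <= n_components < min(X.shape):
        raise ValueError("n_components must satisfy 1 <= c < min(samples, features)")

    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, Y)
    r2 = _r2_score_matrix(Y, pls.predict(X))

    # cross-validated predictions for Q2
    y_strat = np.asarray(labels)
    cv_folds = min(cv_folds, int(np.bincount(pd.factorize(y_strat)[0]).min()))
    if cv_folds >= 2:
        press = 0.0
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(X, y_strat):
            fold = PLSRegression(n_components=min(n_components, len(tr) - 1),
                                 scale=True)
            fold.fit(X[tr], Y[tr])
            press += float(((Y[te] - fold.predict(X[te])) ** 2).sum())
        ss_tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
        q2 = 1.0 - press / ss_tot
    else:
        q2 = float("nan")

    importance = pd.Series((pls.x_weights_ ** 2).sum(axis=1),
                           index=matrix.intensities.columns, name="importance")
    return PLSDAResult(scores=pls.x_scores_, x_weights=pls.x_weights_,
                       importance=importance, r2=r2, q2=q2,
                       n_components=n_components)


def permutation_q2(matrix: FeatureMatrix, labels: pd.Series | None = None,
                   n_components: int = 2, n_permutations: int = 20,
                   seed: int = 0) -> float:
    """Mean Q² over label permutations — the PLS-DA overfitting null."""
    if labels is None:
        labels = matrix.labels
    rng = np.random.default_rng(seed)
    vals = []
    lab = np.asarray(labels)
    for p in range(n_permutations):
        perm = pd.Series(rng.permutation(lab), index=matrix.intensities.index)
        res = plsda_fit(matrix, perm, n_components=n_components, seed=seed + p)
        vals.append(res.q2)
    return float(np.mean(vals))


def plsda_reduce(matrix: FeatureMatrix, result: PLSDAResult,
                 n_keep: int) -> FeatureMatrix:
    """Keep the top ``n_keep`` features by PLS-DA importance, order preserved."""
    if not 1 <= n_keep <= matrix.n_features:
        raise ValueError(f"n_keep must be in [1, {matrix.n_features}]")
    imp = result.importance
    # rank by (importance desc, feature id) for a deterministic cut
    order = sorted(imp.index, key=lambda f: (-imp[f], str(f)))
    chosen = set(order[:n_keep])
    keep = [f for f in matrix.feature_ids if f in chosen]
    return matrix.select_features(keep)


def rfe_rank(matrix: FeatureMatrix, labels: pd.Series | None = None,
             trainer: Callable | None = None, step: int = 1) -> pd.DataFrame:
    """Recursive feature elimination ranking of linear-model features.

    ``trainer(X_df, labels) -> (intercept, coefficients)`` must return one
    weight per column of ``X_df``. Each round drops the ``step`` features with
    the smallest absolute weight (ties broken toward the lexicographically
    first feature id); the last survivor gets rank 1. Returns a DataFrame
    ``feature_id, rank, weight_at_elimination`` sorted by rank.
    """
    if labels is None:
        labels = matrix.labels
    if trainer is None:
        from .cdai import train_cdai

        def trainer(X_df, labs):  # noqa: F811 - default tier-1 trainer
            fm = FeatureMatrix(X_df, labs.loc[X_df.index])
            model = train_cdai(fm, labs.loc[X_df.index])
            return model.intercept, model.coefficients

    if step < 1:
        raise ValueError("step must be >= 1")
    X = matrix.intensities.copy()
    records = []
    remaining = list(X.columns)
    while remaining:
        _b, coefs = trainer(X[remaining], labels)
        coefs = np.asarray(coefs, dtype=float)
        if coefs.shape[0] != len(remaining):
            raise ValueError("trainer returned a weight vector of the wrong length")
        n = len(remaining)
        if n == 1:
            records.append((remaining[0], 1, float(coefs[0])))
            break
        # sort by (|weight| asc, feature id asc): drop the weakest `step`
        order = sorted(range(n), key=lambda i: (abs(coefs[i]), str(remaining[i])))
        n_drop = min(step, n - 1)
        dropped = [(remaining[i], coefs[i]) for i in order[:n_drop]]
        # within one round, the weaker feature gets the worse (higher) rank
        for offset, (fid, w) in enumerate(dropped):
            records.append((fid, n - offset, float(w)))
        dropped_set = {fid for fid, _ in dropped}
        remaining = [f for f in remaining if f not in dropped_set]
    out = pd.DataFrame(records, columns=["feature_id", "rank",
                                         "weight_at_elimination"])
    return out.sort_values("rank", kind="mergesort").reset_index(drop=True)
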