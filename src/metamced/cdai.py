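"""Tier-1 Cancer Detection (CDAI) binary scorer.

A regularized logistic regression over the preprocessed feature matrix,
exposed as the affine score

    y_score = x0 + x1·I1 + x2·I2 + ... + xn·In

with a threshold-0 decision: positive scores call cancer, negative scores
call normal. Class weights inverse to class frequency compensate the
cancer-heavy imbalance of a screening cohort when ``balance`` is set.

The solver standardizes features internally for conditioning and folds the
standardization back into the published (x0, x1..xn), so the score contract
holds on the input intensity scale. Missing intensities at scoring time are
taken at the training mean (equivalently 0 on the standardized scale).

Cross-validation repeats stratified random train/test splits — refitting the
full preprocessing recipe on each training half — and summarizes sensitivity,
specificity and accuracy with percentile 95% confidence intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit

from .containers import FeatureMatrix
from .evaluation import ConfusionCounts, accuracy, sensitivity, specificity

logger = logging.getLogger(__name__)

__all__ = ["CANCER", "NORMAL", "CDAIModel", "CVSummary", "binarize_labels",
           "train_cdai", "cdai_score", "cdai_score_matrix", "cdai_classify",
           "cross_validate_cdai"]

CANCER = "cancer"
NORMAL = "normal"


def binarize_labels(labels: pd.Series, normal_label: str = NORMAL) -> pd.Series:
    """Collapse the 16-class cohort labels to cancer vs normal."""
    return labels.map(lambda v: NORMAL if v == normal_label else CANCER)


@dataclass
class CDAIModel:
    """Affine cancer score: intercept x0 plus one coefficient per feature."""

    intercept: float
    coefficients: np.ndarray
    feature_ids: list
    threshold: float = 0.0
    feature_means: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape[0] != len(self.feature_ids):
            raise ValueError("coefficient vector length != feature count")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.feature_means is None:
            self.feature_means = np.zeros_like(self.coefficients)
        else:
            self.feature_means = np.asarray(self.feature_means, dtype=float)

    def to_json(self, path) -> None:
        payload = {
            "model": "cdai",
            "intercept": self.intercept,
            "threshold": self.threshold,
            "features": [
                {"feature_id": f, "coefficient": float(c), "train_mean": float(m)}
                for f, c, m in zip(self.feature_ids, self.coefficients,
                                   self.feature_means)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CDAIModel":
        with open(path) as fh:
            d = json.load(fh)
        feats = d["features"]
        return cls(
            intercept=float(d["intercept"]),
            coefficients=np.array([f["coefficient"] for f in feats]),
            feature_ids=[f["feature_id"] for f in feats],
            threshold=float(d["threshold"]),
            feature_means=np.array([f["train_mean"] for f in feats]),
        )


def train_cdai(matrix: FeatureMatrix, labels: pd.Series | None = None,
               regularization: float = 1.0, balance: bool = True,
               seed: int = 0) -> CDAIModel:
    """Fit the tier-1 scorer on (preprocessed) training data.

    ``labels`` may be the 16-class cohort labels (binarized internally) or
    already binary {cancer, normal}. ``regularization`` is the inverse L2
    penalty strength (sklearn's C). With ``balance``, per-class weights are
    inverse to class frequency.
    """
    if regularization <= 0:
        raise ValueError("regularization must be > 0")
    if labels is None:
        labels = matrix.labels
    y = binarize_labels(labels.loc[matrix.intensities.index])
    classes = set(y)
    if len(classes) < 2:
        raise ValueError(f"training needs both classes, got only {classes}")
    X = matrix.intensities.to_numpy(dtype=float)
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Xs = (X - means) / sds
    Xs = np.where(np.isnan(Xs), 0.0, Xs)  # missing -> training mean

    clf = LogisticRegression(
        C=regularization,
        class_weight="balanced" if balance else None,
        solver="lbfgs", max_iter=5000, tol=1e-8, random_state=seed,
    )
    clf.fit(Xs, (y == CANCER).astype(int))
    w_std = clf.coef_.ravel()
    b_std = float(clf.intercept_[0])
    # fold internal standardization back onto the input intensity scale
    coefs = w_std / sds
    intercept = b_std - float(np.sum(w_std * means / sds))
    return CDAIModel(intercept=intercept, coefficients=coefs,
                     feature_ids=matrix.feature_ids, threshold=0.0,
                     feature_means=means)


def cdai_score(model: CDAIModel, sample: pd.Series | np.ndarray) -> float:
    """y_score = x0 + Σ x_i·I_i; missing intensities taken at the train mean."""
    if isinstance(sample, pd.Series):
        if list(sample.index) != list(model.feature_ids):
            raise ValueError("sample features are misaligned with the model")
        v = sample.to_numpy(dtype=float)
    else:
        v = np.asarray(sample, dtype=float)
        if v.shape[0] != len(model.feature_ids):
            raise ValueError("sample vector length != model feature count")
    v = np.where(np.isnan(v), model.feature_means, v)
    return float(model.intercept + v @ model.coefficients)


def cdai_score_matrix(model: CDAIModel, matrix: FeatureMatrix) -> pd.Series:
    """Vectorized y_score over all samples of a matrix."""
    if list(matrix.feature_ids) != list(model.feature_ids):
        raise ValueError("matrix features are misaligned with the model")
    X = matrix.intensities.to_numpy(dtype=float)
    X = np.where(np.isnan(X), model.feature_means[None, :], X)
    return pd.Series(model.intercept + X @ model.coefficients,
                     index=matrix.intensities.index, name="y_score")


def cdai_classify(score: float, threshold: float = 0.0) -> str:
    """Threshold decision: score above (or exactly at) threshold → cancer."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return CANCER if score >= threshold else NORMAL


@dataclass
class CVSummary:
    """Repeated-split cross-validation summary (percentages, percentile CIs)."""

    n_splits: int
    sensitivities: np.ndarray
    specificities: np.ndarray
    accuracies: np.ndarray

    def _summary(self, values: np.ndarray) -> dict:
        return {
            "mean": float(np.mean(values)),
            "ci_low": float(np.percentile(values, 2.5)),
            "ci_high": float(np.percentile(values, 97.5)),
        }

    @property
    def sensitivity(self) -> dict:
        return self._summary(self.sensitivities)

    @property
    def specificity(self) -> dict:
        return self._summary(self.specificities)

    @property
    def accuracy(self) -> dict:
        return self._summary(self.accuracies)

    def to_dict(self) -> dict:
        return {"n_splits": self.n_splits,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy}


def cross_validate_cdai(matrix: FeatureMatrix, labels: pd.Series | None = None,
                        n_splits: int = 1000, split_fraction: float = 0.5,
                        seed: int = 0, preprocess: bool = True,
                        min_prevalence: float = 0.1, k: int = 5,
                        regularization: float = 1.0,
                        balance: bool = True) -> CVSummary:
    """Repeated stratified random-split cross-validation of the tier-1 model.

    Each split partitions samples into train/test halves stratified by the
    full class label, refits the entire binary-tier preprocessing recipe on
    the training half only (when ``preprocess``), trains, and scores the test
    half at threshold 0. Splits that end up single-class are resampled.
    """
    from .preprocess import preprocess_cdai_apply, preprocess_cdai_fit

    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if labels is None:
        labels = matrix.labels
    strat = labels.loc[matrix.intensities.index]
    y_bin = binarize_labels(strat)
    sens, spec, acc = [], [], []
    sss = StratifiedShuffleSplit(n_splits=n_splits,
                                 test_size=1.0 - split_fraction,
                                 random_state=seed)
    idx = np.arange(matrix.n_samples)
    resample_rng = np.random.default_rng(seed)
    for train_idx, test_idx in sss.split(idx, strat.to_numpy()):
        for _attempt in range(100):
            yb_tr = y_bin.iloc[train_idx]
            yb_te = y_bin.iloc[test_idx]
            if yb_tr.nunique() == 2 and yb_te.nunique() == 2:
                break
            logger.info("resampling a split with a missing class")
            perm = resample_rng.permutation(idx)
            cut = len(train_idx)
            train_idx, test_idx = perm[:cut], perm[cut:]
        train = matrix.select_samples(matrix.intensities.index[train_idx])
        test = matrix.select_samples(matrix.intensities.index[test_idx])
        if preprocess:
            state, train_proc = preprocess_cdai_fit(train, min_prevalence, k)
            test_proc = preprocess_cdai_apply(state, test)
        else:
            train_proc, test_proc = train, test
        model = train_cdai(train_proc, labels=y_bin.iloc[train_idx],
                           regularization=regularization, balance=balance,
                           seed=seed)
        scores = cdai_score_matrix(model, test_proc)
        calls = scores.map(cdai_classify)
        counts = ConfusionCounts.from_calls(calls, y_bin.iloc[test_idx],
                                            positive=CANCER)
        sens.append(sensitivity(counts))
        spec.append(specificity(counts))
        acc.append(accuracy(counts))
    return CVSummary(n_splits, np.array(sens), np.array(spec), np.array(acc))
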