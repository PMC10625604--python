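"""Tier-2 Tissue-Of-Origin (TOOAI) multiclass scorer.

One linear one-vs-rest scorer per cancer class; the sigmoid of each class's
affine score yields 15 independent probability-style scores per sample,

    P(class k) = 1 / (1 + exp(a_k + Σ_i y_ki · I_i)),

deliberately NOT renormalized across classes. Decisions are taken from the
score ranking: top-1 for single-class prediction, the two largest scores for
the double-class prediction whose accuracy statistic credits a sample when
its true class appears among the top two.

The default model family is a linear max-margin (SVM) one-vs-rest bank with
a small hyperparameter grid chosen by held-out single-class accuracy; a
logistic one-vs-rest family is available as the alternative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import LinearSVC

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["TOOAIModel", "ClassProbabilities", "train_tooai", "tooai_predict",
           "tooai_predict_matrix", "double_class_accuracy",
           "double_class_confusion", "cross_validate_tooai", "TOOAICVSummary"]


@dataclass
class TOOAIModel:
    """Per-class intercepts and weight vectors of the one-vs-rest bank.

    ``intercepts[k] + weights[k] · I`` is the linear score of class
    ``class_labels[k]``; its sigmoid is the class's probability score.
    """

    class_labels: list
    intercepts: np.ndarray        # (K,)
    weights: np.ndarray           # (K, p)
    feature_ids: list
    feature_means: np.ndarray     # (p,) training means, fill-in for missing

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.class_labels), len(self.feature_ids)):
            raise ValueError("weight matrix shape mismatch")
        if not (np.isfinite(self.intercepts).all() and np.isfinite(self.weights).all()):
            raise ValueError("model parameters must be finite")
        if self.feature_means is None:
            self.feature_means = np.zeros(len(self.feature_ids))
        self.feature_means = np.asarray(self.feature_means, dtype=float)

    def to_json(self, path) -> None:
        payload = {
            "model": "tooai",
            "feature_ids": list(self.feature_ids),
            "feature_means": self.feature_means.tolist(),
            "classes": [
                {"label": lab, "intercept": float(b), "weights": w.tolist()}
                for lab, b, w in zip(self.class_labels, self.intercepts,
                                     self.weights)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TOOAIModel":
        with open(path) as fh:
            d = json.load(fh)
        classes = d["classes"]
        return cls(
            class_labels=[c["label"] for c in classes],
            intercepts=np.array([c["intercept"] for c in classes]),
            weights=np.array([c["weights"] for c in classes]),
            feature_ids=list(d["feature_ids"]),
            feature_means=np.array(d["feature_means"]),
        )


@dataclass
class ClassProbabilities:
    """One sample's per-class scores with top-1 / top-2 decisions."""

    scores: dict                 # label -> score in (0, 1)
    top1: str
    top2: tuple                  # (best, second best)


def _rank_labels(scores: dict) -> list:
    """Labels by descending score, lexicographic label on ties."""
    return sorted(scores, key=lambda lab: (-scores[lab], lab))


def train_tooai(matrix: FeatureMatrix, labels: pd.Series | None = None,
                model_family: str = "max-margin", grid=None, seed: int = 0,
                expected_classes=None, val_fraction: float = 0.25) -> TOOAIModel:
    """Fit the one-vs-rest tissue-of-origin bank on (preprocessed) cancer rows.

    The small regularization grid is selected by single-class (top-1)
    accuracy on an internal stratified hold-out, then the winner is refit on
    the full training set. Features are standardized internally and the
    standardization folded back into the stored intercepts/weights.
    """
    if labels is None:
        labels = matrix.labels
    labels = labels.loc[matrix.intensities.index]
    observed = sorted(set(labels))
    if expected_classes is not None:
        absent = sorted(set(expected_classes) - set(observed))
        if absent:
            raise ValueError(f"training set is missing classes: {absent}")
    if len(observed) < 2:
        raise ValueError("tissue-of-origin training needs >= 2 classes")
    if grid is None:
        grid = {"C": [0.01, 0.1, 1.0]}

    X = matrix.intensities.to_numpy(dtype=float)
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    Xs = np.where(np.isnan(X), 0.0, (X - means) / sds)
    y = labels.to_numpy()

    def make(C):
        if model_family == "max-margin":
            return OneVsRestClassifier(LinearSVC(C=C, max_iter=20000,
                                                 random_state=seed))
        if model_family == "logistic-ovr":
            return OneVsRestClassifier(LogisticRegression(
                C=C, max_iter=5000, solver="lbfgs", random_state=seed))
        raise ValueError(f"unknown model family {model_family!r}")

    Cs = list(grid.get("C", [1.0]))
    best_C = Cs[0]
    if len(Cs) > 1:
        counts = pd.Series(y).value_counts()
        if counts.min() >= 2 and len(y) * val_fraction >= len(observed):
            tr, va = train_test_split(np.arange(len(y)), test_size=val_fraction,
                                      stratify=y, random_state=seed)
            best_acc = -1.0
            for C in Cs:
                clf = make(C).fit(Xs[tr], y[tr])
                acc = float(np.mean(clf.predict(Xs[va]) == y[va]))
                if acc > best_acc:
                    best_acc, best_C = acc, C
            logger.info("grid selection: C=%s (held-out top-1 %.3f)",
                        best_C, best_acc)
        else:
            logger.warning("classes too small for grid hold-out; using C=%s",
                           best_C)

    clf = make(best_C).fit(Xs, y)
    class_order = list(clf.classes_)
    if len(clf.estimators_) == 1 and len(class_order) == 2:
        # sklearn collapses 2-class OvR to one binary scorer for classes_[1]
        w = clf.estimators_[0].coef_.ravel()
        b = float(clf.estimators_[0].intercept_[0])
        W_std = np.vstack([-w, w])
        b_std = np.array([-b, b])
    else:
        W_std = np.vstack([est.coef_.ravel() for est in clf.estimators_])
        b_std = np.array([float(est.intercept_[0]) for est in clf.estimators_])
    weights = W_std / sds[None, :]
    intercepts = b_std - (W_std * (means / sds)[None, :]).sum(axis=1)
    # reorder rows into the observed-label order for a stable contract
    order = [class_order.index(lab) for lab in observed]
    return TOOAIModel(class_labels=observed, intercepts=intercepts[order],
                      weights=weights[order], feature_ids=matrix.feature_ids,
                      feature_means=means)


def _linear_scores(model: TOOAIModel, X: np.ndarray) -> np.ndarray:
    X = np.where(np.isnan(X), model.feature_means[None, :], X)
    return model.intercepts[None, :] + X @ model.weights.T


def tooai_predict(model: TOOAIModel,
                  sample: pd.Series | np.ndarray) -> ClassProbabilities:
    """Score one sample: sigmoid per class, top-1/top-2 by descending score.

    Missing intensities enter at the training mean (0 on the standardized
    scale of the tissue-of-origin recipe) — the non-imputed-test convention.
    """
    if isinstance(sample, pd.Series):
        if list(sample.index) != list(model.feature_ids):
            raise ValueError("sample features are misaligned with the model")
        v = sample.to_numpy(dtype=float)
    else:
        v = np.asarray(sample, dtype=float)
        if v.shape[0] != len(model.feature_ids):
            raise ValueError("sample vector length != model feature count")
    lin = _linear_scores(model, v[None, :])[0]
    probs = 1.0 / (1.0 + np.exp(-lin))
    scores = dict(zip(model.class_labels, probs.astype(float)))
    ranked = _rank_labels(scores)
    return ClassProbabilities(scores=scores, top1=ranked[0],
                              top2=(ranked[0], ranked[1]))


def tooai_predict_matrix(model: TOOAIModel, matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-sample score table with ``top1``/``top2_second`` decision columns."""
    if list(matrix.feature_ids) != list(model.feature_ids):
        raise ValueError("matrix features are misaligned with the model")
    lin = _linear_scores(model, matrix.intensities.to_numpy(dtype=float))
    probs = 1.0 / (1.0 + np.exp(-lin))
    df = pd.DataFrame(probs, index=matrix.intensities.index,
                      columns=model.class_labels)
    top1, top2 = [], []
    for _, row in df.iterrows():
        ranked = _rank_labels(row.to_dict())
        top1.append(ranked[0])
        top2.append(ranked[1])
    df["top1"] = top1
    df["top2_second"] = top2
    return df


def _as_prediction_list(predictions) -> list:
    if isinstance(predictions, pd.DataFrame):
        return [ClassProbabilities(scores={}, top1=r["top1"],
                                   top2=(r["top1"], r["top2_second"]))
                for _, r in predictions.iterrows()]
    return list(predictions)


def double_class_accuracy(predictions, truths):
    """Percentage of samples whose true class is among the top two predictions.

    Accepts :func:`tooai_predict_matrix` output or a list of
    :class:`ClassProbabilities`. Returns ``(overall_pct, per_class)`` where
    ``per_class`` tabulates tested / correct / incorrect counts and the
    per-class sensitivity percentage.
    """
    known = None
    if isinstance(predictions, pd.DataFrame):
        known = set(predictions.columns) - {"top1", "top2_second"}
    elif predictions and getattr(predictions[0], "scores", None):
        known = set().union(*(p.scores for p in predictions))
    preds = _as_prediction_list(predictions)
    truths = list(truths)
    if len(preds) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if known is not None:
        unknown = sorted(set(truths) - known)
        if unknown:
            raise ValueError(f"truth labels outside the model's classes: {unknown}")
    rows = {}
    for p, t in zip(preds, truths):
        tested, correct = rows.get(t, (0, 0))
        rows[t] = (tested + 1, correct + (1 if t in p.top2 else 0))
    per_class = pd.DataFrame(
        [(lab, n, c, n - c, 100.0 * c / n) for lab, (n, c) in sorted(rows.items())],
        columns=["class_label", "tested", "correct", "incorrect",
                 "sensitivity_pct"],
    ).set_index("class_label")
    total = int(per_class["tested"].sum())
    correct = int(per_class["correct"].sum())
    return 100.0 * correct / total, per_class


def double_class_confusion(predictions, truths, class_labels=None) -> pd.DataFrame:
    """Confusion counts under the double-class crediting convention.

    A sample whose truth appears in its top two predictions counts on the
    diagonal; otherwise it counts at (truth, top-1). Row sums equal per-class
    sample counts.
    """
    preds = _as_prediction_list(predictions)
    truths = list(truths)
    if len(preds) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if class_labels is None:
        class_labels = sorted(set(truths) | {p.top1 for p in preds})
    if set(truths) - set(class_labels):
        raise ValueError("truth labels outside the given class list")
    table = pd.DataFrame(0, index=list(class_labels), columns=list(class_labels))
    for p, t in zip(preds, truths):
        if t in p.top2:
            table.loc[t, t] += 1
        else:
            table.loc[t, p.top1] += 1
    return table


@dataclass
class TOOAICVSummary:
    """Repeated-split summary of top-1 and double-class accuracy (percent)."""

    n_splits: int
    top1_accuracies: np.ndarray
    double_accuracies: np.ndarray

    def _summary(self, values) -> dict:
        return {"mean": float(np.mean(values)),
                "ci_low": float(np.percentile(values, 2.5)),
                "ci_high": float(np.percentile(values, 97.5))}

    @property
    def top1(self) -> dict:
        return self._summary(self.top1_accuracies)

    @property
    def double(self) -> dict:
        return self._summary(self.double_accuracies)

    def to_dict(self) -> dict:
        return {"n_splits": self.n_splits, "top1_accuracy": self.top1,
                "double_class_accuracy": self.double}


def cross_validate_tooai(matrix: FeatureMatrix, labels: pd.Series | None = None,
                         n_splits: int = 100, split_fraction: float = 0.5,
                         seed: int = 0, preprocess: bool = True, k: int = 5,
                         model_family: str = "max-margin",
                         grid=None) -> TOOAICVSummary:
    """Repeated stratified random-split cross-validation of the tier-2 model.

    Cancer rows only; each split refits the tissue-of-origin recipe on the
    training half (test half kept non-imputed) and evaluates top-1 and
    double-class accuracy on the test half.
    """
    from .preprocess import preprocess_tooai_apply, preprocess_tooai_fit
    from sklearn.model_selection import StratifiedShuffleSplit

    if labels is None:
        labels = matrix.labels
    labels = labels.loc[matrix.intensities.index]
    top1_acc, double_acc = [], []
    sss = StratifiedShuffleSplit(n_splits=n_splits,
                                 test_size=1.0 - split_fraction,
                                 random_state=seed)
    ids = matrix.intensities.index
    for train_idx, test_idx in sss.split(np.zeros(len(ids)), labels.to_numpy()):
        train = matrix.select_samples(ids[train_idx])
        test = matrix.select_samples(ids[test_idx])
        if preprocess:
            state, train_proc = preprocess_tooai_fit(train, k=k)
            test_proc = preprocess_tooai_apply(state, test)
        else:
            train_proc, test_proc = train, test
        model = train_tooai(train_proc, model_family=model_family, grid=grid,
                            seed=seed)
        pred = tooai_predict_matrix(model, test_proc)
        truths = labels.iloc[test_idx]
        top1_acc.append(100.0 * float(np.mean(pred["top1"].to_numpy()
                                              == truths.to_numpy())))
        overall, _ = double_class_accuracy(pred, truths)
        double_acc.append(overall)
    return TOOAICVSummary(n_splits, np.array(top1_acc), np.array(double_acc))
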