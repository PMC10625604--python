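"""Normalization, standardization and imputation for the two-tier models.

Two fixed recipes are provided, differing exactly where the two model tiers
differ:

* binary cancer-detection (CDAI) recipe:
  prevalence filter → quantile normalization → uniform KNN imputation;
* tissue-of-origin (TOOAI) recipe:
  log10 transform → quantile normalization → standard scaling → selective
  (within-class) KNN imputation of training rows, test rows left non-imputed.

Quantile normalization is adapted for single-sample inference: the training
set yields a frozen reference distribution (positionwise means of the sorted
training rows) and any later sample — one at a time — is mapped onto it by
rank substitution. Fit steps accept training data only; nothing about a test
sample ever enters a fitted state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QuantileReference", "ScalerState",
    "filter_features", "quantile_fit", "quantile_apply", "quantile_apply_matrix",
    "log10_transform", "default_pseudocount",
    "scale_fit", "scale_apply",
    "knn_impute", "knn_transform",
    "CDAIPreprocessState", "preprocess_cdai_fit", "preprocess_cdai_apply",
    "TOOAIPreprocessState", "preprocess_tooai_fit", "preprocess_tooai_apply",
]


# ---------------------------------------------------------------------------
# feature filtering
# ---------------------------------------------------------------------------

def filter_features(matrix: FeatureMatrix, min_prevalence: float = 0.1):
    """Drop features observed in fewer than ``min_prevalence`` of samples.

    Returns ``(filtered_matrix, removed_feature_ids)``.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = matrix.intensities.notna().mean(axis=0)
    keep = prevalence[prevalence >= min_prevalence].index.tolist()
    removed = [f for f in matrix.feature_ids if f not in set(keep)]
    if not keep:
        raise RuntimeError(
            f"prevalence filter at {min_prevalence} removed all "
            f"{matrix.n_features} features")
    if removed:
        logger.info("prevalence filter removed %d/%d features",
                    len(removed), matrix.n_features)
    return matrix.select_features(keep), removed


# ---------------------------------------------------------------------------
# quantile normalization with a frozen training reference
# ---------------------------------------------------------------------------

@dataclass
class QuantileReference:
    """Pooled training quantiles: positionwise means of sorted training rows."""

    reference_quantiles: np.ndarray
    n_train_features: int

    def __post_init__(self) -> None:
        q = np.asarray(self.reference_quantiles, dtype=float)
        if np.any(np.diff(q) < 0):
            raise ValueError("reference quantiles must be nondecreasing")
        self.reference_quantiles = q

    def to_dict(self) -> dict:
        return {"reference_quantiles": self.reference_quantiles.tolist(),
                "n_train_features": int(self.n_train_features)}

    @classmethod
    def from_dict(cls, d: dict) -> "QuantileReference":
        return cls(np.asarray(d["reference_quantiles"], dtype=float),
                   int(d["n_train_features"]))


def quantile_fit(train: FeatureMatrix | pd.DataFrame) -> QuantileReference:
    """Pool training rows into a reference distribution.

    Each training sample's observed intensities are sorted; rows with missing
    cells are interpolated onto the full-length quantile grid so that missing
    cells never enter the pooling. The reference is the positionwise mean of
    these sorted vectors.
    """
    X = train.intensities if isinstance(train, FeatureMatrix) else train
    n_features = X.shape[1]
    if X.shape[0] == 0 or n_features == 0:
        raise ValueError("empty training matrix")
    if X.shape[0] == 1:
        logger.warning("quantile_fit on a single training sample")
    grid = np.linspace(0.0, 1.0, n_features)
    sorted_rows = np.empty((X.shape[0], n_features))
    values = X.to_numpy(dtype=float)
    for i in range(values.shape[0]):
        obs = np.sort(values[i][~np.isnan(values[i])])
        m = obs.size
        if m == 0:
            raise ValueError(f"training sample {X.index[i]!r} has no observed values")
        if m == n_features:
            sorted_rows[i] = obs
        elif m == 1:
            sorted_rows[i] = obs[0]
        else:
            sorted_rows[i] = np.interp(grid, np.linspace(0.0, 1.0, m), obs)
    return QuantileReference(sorted_rows.mean(axis=0), n_features)


def quantile_apply(sample: pd.Series | np.ndarray,
                   reference: QuantileReference) -> np.ndarray | pd.Series:
    """Map one sample onto the reference distribution by rank substitution.

    Each observed value is replaced by the reference quantile at its
    within-sample rank; tied values share their averaged rank, and when some
    cells are missing the ranks of the observed values are interpolated
    linearly over the reference grid. Missing cells stay missing. Applying a
    second time is a no-op (the mapping is rank-preserving).
    """
    is_series = isinstance(sample, pd.Series)
    v = sample.to_numpy(dtype=float) if is_series else np.asarray(sample, dtype=float)
    out = np.full(v.shape, np.nan)
    obs = ~np.isnan(v)
    m = int(obs.sum())
    if m == 0:
        raise ValueError("cannot quantile-normalize an all-missing sample")
    ref = reference.reference_quantiles
    n = ref.size
    ranks = rankdata(v[obs], method="average")  # 1..m, ties averaged
    pos = (ranks - 1.0) / (m - 1.0) if m > 1 else np.array([0.5])
    out[obs] = np.interp(pos, np.linspace(0.0, 1.0, n), ref)
    if is_series:
        return pd.Series(out, index=sample.index, name=sample.name)
    return out


def quantile_apply_matrix(matrix: FeatureMatrix,
                          reference: QuantileReference) -> FeatureMatrix:
    """Quantile-normalize every row independently (one sample at a time)."""
    X = matrix.intensities
    out = np.vstack([quantile_apply(X.iloc[i].to_numpy(), reference)
                     for i in range(X.shape[0])])
    return matrix.with_intensities(
        pd.DataFrame(out, index=X.index, columns=X.columns))


# ---------------------------------------------------------------------------
# log10 transform and standard scaling
# ---------------------------------------------------------------------------

def default_pseudocount(train: FeatureMatrix | pd.DataFrame) -> float:
    """Half the smallest nonzero training intensity (0.5 if none observed)."""
    X = train.intensities if isinstance(train, FeatureMatrix) else train
    v = X.to_numpy(dtype=float)
    pos = v[np.isfinite(v) & (v > 0)]
    return float(pos.min() / 2.0) if pos.size else 0.5


def log10_transform(matrix: FeatureMatrix, pseudocount: float) -> FeatureMatrix:
    """log10(value + pseudocount) on observed cells; missing cells untouched."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    X = matrix.intensities
    v = X.to_numpy(dtype=float)
    if np.nanmin(v) < 0:
        raise ValueError("negative intensities cannot be log-transformed")
    with np.errstate(divide="ignore"):
        out = np.where(np.isnan(v), np.nan, np.log10(v + pseudocount))
    return matrix.with_intensities(pd.DataFrame(out, index=X.index, columns=X.columns))


@dataclass
class ScalerState:
    """Per-feature training mean and standard deviation."""

    means: pd.Series
    sds: pd.Series
    zero_variance: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"feature_ids": self.means.index.tolist(),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "zero_variance": list(self.zero_variance)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        idx = pd.Index(d["feature_ids"])
        return cls(pd.Series(d["means"], index=idx),
                   pd.Series(d["sds"], index=idx),
                   list(d["zero_variance"]))


def scale_fit(train: FeatureMatrix | pd.DataFrame) -> ScalerState:
    """Per-feature mean/sd over observed training cells.

    Zero-variance (or single-observation) features are flagged and their sd
    treated as 1 so they pass through centered.
    """
    X = train.intensities if isinstance(train, FeatureMatrix) else train
    means = X.mean(axis=0, skipna=True)
    sds = X.std(axis=0, skipna=True, ddof=0)
    flagged = sds.index[(sds == 0) | sds.isna()].tolist()
    if flagged:
        logger.warning("scale_fit: %d zero-variance feature(s) flagged", len(flagged))
    sds = sds.mask((sds == 0) | sds.isna(), 1.0)
    means = means.fillna(0.0)
    return ScalerState(means, sds, flagged)


def scale_apply(matrix: FeatureMatrix, state: ScalerState) -> FeatureMatrix:
    """(value − train mean) / train sd per feature; missing stays missing."""
    X = matrix.intensities
    unknown = [f for f in X.columns if f not in state.means.index]
    if unknown:
        raise ValueError(f"features absent from scaler state: {unknown[:5]}")
    out = (X - state.means[X.columns]) / state.sds[X.columns]
    return matrix.with_intensities(out)


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def _pairwise_nan_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Root-mean-square difference over mutually observed features.

    ``D[i, j] = sqrt(mean_f (A[i,f] − B[j,f])²)`` over features observed in
    both rows; pairs with no mutually observed feature get ``inf``.
    """
    Ma = ~np.isnan(A)
    Mb = ~np.isnan(B)
    Az = np.where(Ma, A, 0.0)
    Bz = np.where(Mb, B, 0.0)
    counts = Ma.astype(float) @ Mb.T.astype(float)
    ss = ((Az ** 2) @ Mb.T + Ma @ (Bz ** 2).T - 2.0 * (Az @ Bz.T))
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = ss / counts
    d2 = np.where(counts > 0, np.maximum(d2, 0.0), np.inf)
    return np.sqrt(d2)


def _fill_from_donors(target: np.ndarray, donors: np.ndarray,
                      dist: np.ndarray, k: int, exclude_self: int | None = None
                      ) -> np.ndarray:
    """Fill one row's missing cells from its k nearest donors per feature."""
    out = target.copy()
    missing_feats = np.nonzero(np.isnan(target))[0]
    if missing_feats.size == 0:
        return out
    order = np.argsort(dist, kind="stable")  # stable -> row order breaks ties
    for f in missing_feats:
        vals = []
        for j in order:
            if exclude_self is not None and j == exclude_self:
                continue
            if not np.isfinite(dist[j]):
                break
            if not np.isnan(donors[j, f]):
                vals.append(donors[j, f])
                if len(vals) == k:
                    break
        if vals:
            out[f] = float(np.mean(vals))
    return out


def _impute_pool(X: np.ndarray, k: int) -> np.ndarray:
    """Impute all rows of X using the other rows of X as donors."""
    D = _pairwise_nan_distance(X, X)
    out = X.copy()
    for i in range(X.shape[0]):
        out[i] = _fill_from_donors(X[i], X, D[i], k, exclude_self=i)
    return out


def knn_impute(matrix: FeatureMatrix, k: int = 5, policy: str = "uniform",
               test_samples=None) -> FeatureMatrix:
    """K-nearest-neighbour imputation of missing cells.

    Distance between rows is the root-mean-square difference over mutually
    observed features; a missing cell is filled with the mean of that feature
    across the ``k`` nearest donor rows that observed it (all available donors
    when fewer than ``k`` exist). Observed cells are never altered.

    ``policy='uniform'`` imputes every row against the whole matrix.
    ``policy='selective'`` imputes each row only against donors of its own
    class, and rows listed in ``test_samples`` are returned untouched — the
    non-imputed test convention of the tissue-of-origin recipe.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = matrix.intensities.to_numpy(dtype=float)
    if np.any(np.all(np.isnan(X), axis=1)):
        bad = matrix.intensities.index[np.all(np.isnan(X), axis=1)].tolist()
        raise ValueError(f"rows with no observed features: {bad[:5]}")
    if not np.isnan(X).any():
        return matrix.copy()
    if policy == "uniform":
        out = _impute_pool(X, k)
    elif policy == "selective":
        test_set = set(test_samples) if test_samples is not None else set()
        is_test = np.array([s in test_set for s in matrix.sample_ids])
        out = X.copy()
        labels = matrix.labels.to_numpy()
        for lab in pd.unique(labels[~is_test]):
            rows = np.nonzero((labels == lab) & ~is_test)[0]
            out[rows] = _impute_pool(X[rows], k)
    else:
        raise ValueError(f"unknown imputation policy {policy!r}")
    df = pd.DataFrame(out, index=matrix.intensities.index,
                      columns=matrix.intensities.columns)
    return matrix.with_intensities(df)


def knn_transform(train_complete: pd.DataFrame, target: pd.DataFrame,
                  k: int = 5) -> pd.DataFrame:
    """Impute target rows using (already imputed) training rows as donors.

    Used when applying the binary-tier recipe to new samples one at a time:
    donors come exclusively from the training pool, so test samples never
    inform each other.
    """
    Xt = target.to_numpy(dtype=float)
    Xd = train_complete.to_numpy(dtype=float)
    if not np.isnan(Xt).any():
        return target.copy()
    D = _pairwise_nan_distance(Xt, Xd)
    out = Xt.copy()
    for i in range(Xt.shape[0]):
        out[i] = _fill_from_donors(Xt[i], Xd, D[i], k)
    return pd.DataFrame(out, index=target.index, columns=target.columns)


# ---------------------------------------------------------------------------
# the two recipes
# ---------------------------------------------------------------------------

@dataclass
class CDAIPreprocessState:
    """Frozen training-side state of the binary-tier recipe."""

    feature_ids: list
    quantile_reference: QuantileReference
    train_imputed: pd.DataFrame  # donor pool for imputing new samples
    k: int = 5

    def to_dict(self) -> dict:
        return {"recipe": "cdai", "k": self.k,
                "feature_ids": list(self.feature_ids),
                "quantile_reference": self.quantile_reference.to_dict(),
                "train_imputed": {
                    "index": self.train_imputed.index.tolist(),
                    "values": self.train_imputed.to_numpy().tolist()}}

    @classmethod
    def from_dict(cls, d: dict) -> "CDAIPreprocessState":
        feats = list(d["feature_ids"])
        train = pd.DataFrame(np.asarray(d["train_imputed"]["values"], dtype=float),
                             index=d["train_imputed"]["index"], columns=feats)
        return cls(feats, QuantileReference.from_dict(d["quantile_reference"]),
                   train, int(d["k"]))


def preprocess_cdai_fit(train: FeatureMatrix, min_prevalence: float = 0.1,
                        k: int = 5):
    """Fit the binary-tier recipe on training data.

    filter → quantile fit/apply → uniform KNN imputation. Returns
    ``(state, processed_training_matrix)``.
    """
    filtered, _removed = filter_features(train, min_prevalence)
    qref = quantile_fit(filtered)
    normalized = quantile_apply_matrix(filtered, qref)
    imputed = knn_impute(normalized, k=k, policy="uniform")
    state = CDAIPreprocessState(imputed.feature_ids, qref,
                                imputed.intensities.copy(), k)
    return state, imputed


def preprocess_cdai_apply(state: CDAIPreprocessState,
                          matrix: FeatureMatrix) -> FeatureMatrix:
    """Apply the fitted binary-tier recipe to new samples, one at a time."""
    sub = matrix.select_features(
        [f for f in state.feature_ids if f in set(matrix.feature_ids)])
    # features the new data never saw become missing columns, then imputed
    X = sub.intensities.reindex(columns=state.feature_ids)
    sub = FeatureMatrix(X, sub.labels, sub.batches)
    normalized = quantile_apply_matrix(sub, state.quantile_reference)
    filled = knn_transform(state.train_imputed, normalized.intensities, k=state.k)
    return normalized.with_intensities(filled)


@dataclass
class TOOAIPreprocessState:
    """Frozen training-side state of the tissue-of-origin recipe."""

    feature_ids: list
    pseudocount: float
    quantile_reference: QuantileReference
    scaler: ScalerState
    k: int = 5

    def to_dict(self) -> dict:
        return {"recipe": "tooai", "k": self.k,
                "feature_ids": list(self.feature_ids),
                "pseudocount": self.pseudocount,
                "quantile_reference": self.quantile_reference.to_dict(),
                "scaler": self.scaler.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TOOAIPreprocessState":
        return cls(list(d["feature_ids"]), float(d["pseudocount"]),
                   QuantileReference.from_dict(d["quantile_reference"]),
                   ScalerState.from_dict(d["scaler"]), int(d["k"]))


def preprocess_tooai_fit(train: FeatureMatrix, k: int = 5):
    """Fit the tissue-of-origin recipe on training data.

    log10 → quantile fit/apply → standard scaling → selective within-class
    KNN imputation. Returns ``(state, processed_training_matrix)``; any cells
    still missing after within-class imputation are left missing (scored as 0
    downstream, i.e. at the training mean).
    """
    pc = default_pseudocount(train)
    logged = log10_transform(train, pc)
    qref = quantile_fit(logged)
    normalized = quantile_apply_matrix(logged, qref)
    scaler = scale_fit(normalized)
    scaled = scale_apply(normalized, scaler)
    imputed = knn_impute(scaled, k=k, policy="selective")
    state = TOOAIPreprocessState(imputed.feature_ids, pc, qref, scaler, k)
    return state, imputed


def preprocess_tooai_apply(state: TOOAIPreprocessState,
                           matrix: FeatureMatrix) -> FeatureMatrix:
    """Apply the fitted tissue-of-origin recipe to test samples.

    Test rows are kept non-imputed: missing cells survive to scoring, where
    they enter the linear probability formulas as 0 (the training mean on the
    standardized scale).
    """
    X = matrix.intensities.reindex(columns=state.feature_ids)
    sub = FeatureMatrix(X, matrix.labels, matrix.batches)
    logged = log10_transform(sub, state.pseudocount)
    normalized = quantile_apply_matrix(logged, state.quantile_reference)
    return scale_apply(normalized, state.scaler)
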