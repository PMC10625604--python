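"""Shared in-memory containers for the two-tier metabolomics pipeline.

The central object is :class:`FeatureMatrix`: a samples × features intensity
table (NaN marks a missing cell) with per-sample class labels and batch ids.
Every pipeline stage consumes and returns this container, so downstream code
never has to re-join intensities with their sample annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """Samples × features intensity table with sample annotations.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id with one column per feature id.
        ``NaN`` entries are missing cells (feature not observed in that
        sample); they carry no intensity value.
    labels
        Per-sample class label, indexed like ``intensities``.
    batches
        Per-sample batch identifier, indexed like ``intensities``.
    """

    intensities: pd.DataFrame
    labels: pd.Series
    batches: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.batches is None:
            self.batches = pd.Series(0, index=self.intensities.index, name="batch_id")
        if not self.intensities.index.is_unique:
            raise ValueError("duplicate sample ids in feature matrix")
        if not self.intensities.columns.is_unique:
            raise ValueError("duplicate feature ids in feature matrix")
        for ann, name in ((self.labels, "labels"), (self.batches, "batches")):
            if not self.intensities.index.equals(ann.index):
                raise ValueError(f"{name} index does not match sample ids")

    # -- basic geometry -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean table, True where the cell is missing."""
        return self.intensities.isna()

    # -- subsetting -----------------------------------------------------
    def select_samples(self, sample_ids) -> "FeatureMatrix":
        ids = list(sample_ids)
        return FeatureMatrix(
            self.intensities.loc[ids].copy(),
            self.labels.loc[ids].copy(),
            self.batches.loc[ids].copy(),
        )

    def select_features(self, feature_ids) -> "FeatureMatrix":
        ids = list(feature_ids)
        return FeatureMatrix(
            self.intensities.loc[:, ids].copy(),
            self.labels.copy(),
            self.batches.copy(),
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "FeatureMatrix":
        """Same samples/annotations, new intensity table."""
        return FeatureMatrix(intensities, self.labels.copy(), self.batches.copy())

    def copy(self) -> "FeatureMatrix":
        return self.with_intensities(self.intensities.copy())

    # -- serialization --------------------------------------------------
    def to_tsv(self, matrix_path, samples_path) -> None:
        """Write intensities and the sample sidecar as tab-delimited text."""
        self.intensities.rename_axis("sample_id").to_csv(matrix_path, sep="\t")
        sidecar = pd.DataFrame(
            {"class_label": self.labels, "batch_id": self.batches}
        ).rename_axis("sample_id")
        sidecar.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, matrix_path, samples_path) -> "FeatureMatrix":
        intensities = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
        sidecar = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        sidecar = sidecar.loc[intensities.index]
        return cls(
            intensities,
            sidecar["class_label"],
            sidecar["batch_id"],
        )

    @classmethod
    def from_arrays(cls, X: np.ndarray, sample_ids, feature_ids, labels,
                    batches=None) -> "FeatureMatrix":
        df = pd.DataFrame(np.asarray(X, dtype=float), index=list(sample_ids),
                          columns=list(feature_ids))
        lab = pd.Series(list(labels), index=df.index, name="class_label")
        bat = None
        if batches is not None:
            bat = pd.Series(list(batches), index=df.index, name="batch_id")
        return cls(df, lab, bat)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
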