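"""Virtual-lock-mass (VLM) feature alignment.

Mass errors in untargeted LC-MS grow proportionally with mass, so the same
metabolite surfaces at slightly different m/z across runs. VLM alignment
counters this by laying a ppm-width mass window (a "box") around each
reference metabolite mass and assigning every observed peak to the box whose
center it matches best in ppm terms. The assignments across all samples are
then assembled into the pipeline's central samples × features matrix.

Boxes are mass-only: retention time is carried through the peak lists but not
used for matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["VLMBoxSet", "build_boxes", "assign_peaks", "assemble_matrix",
           "trim_matrix", "align_cohort"]


@dataclass
class VLMBoxSet:
    """ppm-tolerance mass windows, one per reference metabolite.

    ``boxes`` is sorted by center mass with columns ``box_id``
    (equal to the reference ``metabolite_id``, so matrix features resolve
    directly to reference rows), ``center_mass``, ``mass_low``, ``mass_high``.
    """

    boxes: pd.DataFrame
    tol_ppm: float

    def __len__(self) -> int:
        return len(self.boxes)

    def overlapping_pairs(self) -> list:
        """All (box_id, box_id) pairs whose mass windows overlap.

        Windows are sorted and their widths grow with mass, so overlap chains
        are contiguous; each box is compared against its successors until the
        windows separate.
        """
        lows = self.boxes["mass_low"].to_numpy()
        highs = self.boxes["mass_high"].to_numpy()
        ids = self.boxes["box_id"].to_numpy()
        pairs = []
        n = len(ids)
        for i in range(n):
            j = i + 1
            while j < n and lows[j] <= highs[i]:
                pairs.append((ids[i], ids[j]))
                j += 1
        return pairs

    def report(self) -> dict:
        return {
            "n_boxes": len(self),
            "tol_ppm": self.tol_ppm,
            "n_overlapping_pairs": len(self.overlapping_pairs()),
        }

    def to_tsv(self, path) -> None:
        self.boxes.to_csv(path, sep="\t", index=False)


def build_boxes(reference: pd.DataFrame, tol_ppm: float = 5.0) -> VLMBoxSet:
    """Create one ppm-width VLM box per reference metabolite.

    The window around a center mass c spans ``[c·(1−tol·1e−6), c·(1+tol·1e−6)]``,
    so absolute width grows linearly with mass — the defining property of a
    ppm error model.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if len(reference) == 0:
        raise ValueError("empty metabolite reference")
    centers = reference["monoisotopic_mass"].to_numpy(dtype=float)
    df = pd.DataFrame({
        "box_id": reference["metabolite_id"].to_numpy(),
        "center_mass": centers,
        "mass_low": centers * (1.0 - tol_ppm * 1e-6),
        "mass_high": centers * (1.0 + tol_ppm * 1e-6),
    }).sort_values("center_mass", kind="mergesort").reset_index(drop=True)
    box_set = VLMBoxSet(df, tol_ppm)
    n_overlap = len(box_set.overlapping_pairs())
    if n_overlap:
        logger.info("VLM box set has %d overlapping window pair(s)", n_overlap)
    return box_set


def assign_peaks(peaklist: pd.DataFrame, boxes: VLMBoxSet):
    """Assign one sample's peaks to VLM boxes.

    Each peak lands in at most one box: among the windows containing its m/z,
    the one with the smallest absolute ppm deviation from center wins, ties
    going to the lower-mass box. Multiple peaks landing in the same box keep
    the maximum intensity. Returns ``(mapping, n_unmatched)`` where mapping is
    ``{box_id: intensity}``; peaks matching no window are only counted.

    The result is independent of peak order within the sample.
    """
    if len(peaklist) == 0:
        raise ValueError("empty peak list")
    mz = peaklist["mz"].to_numpy(dtype=float)
    inten = peaklist["intensity"].to_numpy(dtype=float)
    lows = boxes.boxes["mass_low"].to_numpy()
    highs = boxes.boxes["mass_high"].to_numpy()
    centers = boxes.boxes["center_mass"].to_numpy()
    ids = boxes.boxes["box_id"].to_numpy()

    # windows are monotone in center mass, so the candidate boxes for a peak
    # form the contiguous index range [first high >= mz, last low <= mz]
    i0 = np.searchsorted(highs, mz, side="left")
    i1 = np.searchsorted(lows, mz, side="right")

    best: dict = {}
    n_unmatched = 0
    for p in range(len(mz)):
        a, b = i0[p], i1[p]
        if a >= b:
            n_unmatched += 1
            continue
        dev = np.abs(mz[p] - centers[a:b]) / centers[a:b]
        # argmin takes the first minimum -> lower-mass box on exact ppm ties
        j = a + int(np.argmin(dev))
        bid = ids[j]
        if bid not in best or inten[p] > best[bid]:
            best[bid] = inten[p]
    return best, n_unmatched


def assemble_matrix(assignments: Mapping[str, Mapping[str, float]],
                    labels: Mapping[str, str],
                    batch_ids: Mapping[str, object] | None = None,
                    boxes: VLMBoxSet | None = None) -> FeatureMatrix:
    """Stack per-sample box assignments into a FeatureMatrix.

    The feature set is the union of boxes observed in at least one sample
    (ordered by box mass when ``boxes`` is given, else lexicographically);
    cells for boxes a sample did not observe are missing (NaN).
    """
    sample_ids = list(assignments)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in assignments")
    missing_labels = [s for s in sample_ids if s not in labels]
    if missing_labels:
        raise ValueError(f"samples without labels: {missing_labels[:5]}")
    observed = set()
    for mapping in assignments.values():
        observed.update(mapping)
    if boxes is not None:
        order = [b for b in boxes.boxes["box_id"] if b in observed]
    else:
        order = sorted(observed)
    X = pd.DataFrame(np.nan, index=pd.Index(sample_ids, name="sample_id"),
                     columns=order, dtype=float)
    for sid, mapping in assignments.items():
        if mapping:
            X.loc[sid, list(mapping)] = list(mapping.values())
    lab = pd.Series({s: labels[s] for s in sample_ids}, name="class_label")
    bat = None
    if batch_ids is not None:
        bat = pd.Series({s: batch_ids[s] for s in sample_ids}, name="batch_id")
    return FeatureMatrix(X, lab.loc[X.index], None if bat is None else bat.loc[X.index])


def trim_matrix(matrix: FeatureMatrix, reference: pd.DataFrame) -> FeatureMatrix:
    """Drop drug- and plant-derived features, keeping endogenous ones only.

    Feature ids must resolve to reference metabolite ids (they do, since box
    ids equal metabolite ids); an unresolvable feature is a consistency error.
    """
    flags = reference.set_index("metabolite_id")["origin_flag"]
    unknown = [f for f in matrix.feature_ids if f not in flags.index]
    if unknown:
        raise ValueError(f"feature ids not in reference: {unknown[:5]}")
    keep = [f for f in matrix.feature_ids if flags[f] == "endogenous"]
    logger.info("trim: %d features -> %d endogenous", matrix.n_features, len(keep))
    return matrix.select_features(keep)


def align_cohort(peaks: pd.DataFrame, truth: pd.DataFrame,
                 boxes: VLMBoxSet) -> FeatureMatrix:
    """Assign every sample's peaks and assemble the cohort feature matrix."""
    labels = dict(zip(truth["sample_id"], truth["class_label"]))
    batches = dict(zip(truth["sample_id"], truth["batch_id"]))
    assignments = {}
    total_unmatched = 0
    for sid, group in peaks.groupby("sample_id", sort=False):
        mapping, n_un = assign_peaks(group, boxes)
        assignments[sid] = mapping
        total_unmatched += n_un
    # samples that lost every peak still get an (all-missing) row
    for sid in truth["sample_id"]:
        assignments.setdefault(sid, {})
    if total_unmatched:
        logger.info("alignment left %d peak(s) unmatched", total_unmatched)
    return assemble_matrix(assignments, labels, batches, boxes)
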