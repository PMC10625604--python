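"""Confusion-count metrics, ROC-AUC and the repeated-run robustness harness.

Sensitivity, specificity and accuracy are computed exactly from integer
confusion counts (as rationals, converted to float percentages) and rounded
to one decimal with round-half-even only at report time, matching the
precision convention of screening-study tables.

The robustness harness emulates re-running a frozen detection model on the
same sample panel across repeated instrument batches: the cohort is
regenerated identically except for fresh batch-level drift, scored each
time, and the coefficient of variation (CV) of the pooled ("net") detection
sensitivity across runs quantifies batch robustness.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "sensitivity", "specificity", "accuracy",
           "round1", "roc_auc", "RobustnessReport", "robustness_harness"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN integer counts of a binary decision."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_calls(cls, calls: pd.Series, truths: pd.Series,
                   positive) -> "ConfusionCounts":
        c = np.asarray(calls) == positive
        t = np.asarray(truths) == positive
        return cls(tp=int(np.sum(c & t)), tn=int(np.sum(~c & ~t)),
                   fp=int(np.sum(c & ~t)), fn=int(np.sum(~c & t)))


def _pct(num: int, den: int, what: str) -> float:
    if den <= 0:
        raise ZeroDivisionError(f"{what} undefined: zero denominator")
    return float(Fraction(num, den) * 100)


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN), as a percentage."""
    return _pct(counts.tp, counts.tp + counts.fn, "sensitivity")


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP), as a percentage."""
    return _pct(counts.tn, counts.tn + counts.fp, "specificity")


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total, as a percentage."""
    return _pct(counts.tp + counts.tn, counts.total, "accuracy")


def round1(value: float) -> float:
    """Round to one decimal, half to even — the tables' reporting precision."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"),
                                               rounding=ROUND_HALF_EVEN))


def roc_auc(scores, labels, positive="cancer") -> float:
    """Rank-based ROC-AUC with tie correction.

    Equals the Mann–Whitney U statistic divided by n₊·n₋: the probability a
    random positive outscores a random negative, ties counting half.
    Invariant under any strictly monotone transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC needs both classes present")
    ranks = rankdata(s, method="average")
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# repeated-run robustness harness
# ---------------------------------------------------------------------------

@dataclass
class RobustnessReport:
    """Per-run, per-class detection bookkeeping across repeated batch runs."""

    per_class: pd.DataFrame       # index class, columns run_1..run_n (sensitivity %)
    detected: pd.DataFrame        # same shape, correct-detection counts
    tested: pd.Series             # per-class sample counts
    net_sensitivities: np.ndarray  # pooled % per run
    cv_net_sensitivity: float

    def to_dict(self) -> dict:
        return {
            "net_sensitivities_pct": [float(v) for v in self.net_sensitivities],
            "cv_net_sensitivity": float(self.cv_net_sensitivity),
            "tested_per_class": {str(k): int(v) for k, v in self.tested.items()},
        }


#: Per-class panel sizes of the repeated-run robustness experiment
#: (breast, endometrial, cervical, ovarian, lung, aml, thyroid, melanoma,
#:  colorectal, kidney, nhl, pancreatic, head_neck, gastric, liver_bile).
ROBUSTNESS_PANEL_COUNTS = (25, 25, 23, 25, 24, 24, 15, 12, 15, 12, 10, 12, 15, 15, 15)


def robustness_harness(model, preprocess_state, boxes, reference, profiles,
                       config, n_runs: int = 10,
                       batch_shift_sd: float | None = None,
                       seed: int = 0) -> RobustnessReport:
    """Score a frozen tier-1 model on repeated regenerations of one cohort.

    Each run regenerates the identical cohort under fresh batch-level drift
    (everything else — sample roster, baselines, noise, dropout, mass errors —
    is pinned by ``config.seed``), aligns and preprocesses it with the frozen
    state, scores it, and tabulates per-class and pooled ("net") sensitivity.
    With ``batch_shift_sd == 0`` every run is identical and the CV is 0.
    """
    from .cdai import CANCER, cdai_classify, cdai_score_matrix
    from .preprocess import preprocess_cdai_apply
    from .synthetic import generate_cohort
    from .vlm import align_cohort, trim_matrix

    if model is None:
        raise ValueError("a trained tier-1 model is required")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = config if batch_shift_sd is None else config.replace(
        batch_shift_sd=batch_shift_sd)

    class_order = [lab for lab in cfg.samples_per_class if lab != "normal"]
    detected = {}
    tested = None
    net = []
    for r in range(n_runs):
        peaks, truth = generate_cohort(reference, profiles, cfg,
                                       batch_seed=seed + 1000 + r)
        matrix = trim_matrix(align_cohort(peaks, truth, boxes), reference)
        processed = preprocess_cdai_apply(preprocess_state, matrix)
        calls = cdai_score_matrix(model, processed).map(cdai_classify)
        labels = matrix.labels
        run_detected = {}
        run_tested = {}
        for lab in class_order:
            in_class = labels == lab
            run_tested[lab] = int(in_class.sum())
            run_detected[lab] = int((calls[in_class] == CANCER).sum())
        detected[f"run_{r + 1}"] = run_detected
        if tested is None:
            tested = pd.Series(run_tested)
        pooled_correct = sum(run_detected.values())
        pooled_tested = sum(run_tested.values())
        net.append(_pct(pooled_correct, pooled_tested, "net sensitivity"))
    detected_df = pd.DataFrame(detected).loc[class_order]
    per_class = 100.0 * detected_df.div(tested.loc[class_order], axis=0)
    net_arr = np.array(net)
    mean_net = float(net_arr.mean())
    cv = float(net_arr.std(ddof=1) / mean_net) if n_runs > 1 and mean_net > 0 else 0.0
    return RobustnessReport(per_class=per_class, detected=detected_df,
                            tested=tested.loc[class_order],
                            net_sensitivities=net_arr,
                            cv_net_sensitivity=cv)
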