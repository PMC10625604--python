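"""End-to-end tiered pipeline driver.

Binds the stages in the order the method runs: (optional) cohort simulation →
VLM alignment and trimming → train/test split → binary-tier preprocessing and
cancer detection → routing of tier-1 positives → tissue-of-origin training
and double-class prediction → evaluation. Every run writes its artifacts and
a manifest (versions, seeds, parameters, per-stage sample/feature counts)
into one run directory.

The tiered contract is strict: a sample the detection tier calls normal never
reaches the tissue-of-origin tier.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .cdai import (CANCER, binarize_labels, cdai_classify, cdai_score_matrix,
                   train_cdai)
from .containers import FeatureMatrix, ensure_dir
from .evaluation import ConfusionCounts, accuracy, roc_auc, round1, sensitivity, \
    specificity
from .preprocess import (preprocess_cdai_apply, preprocess_cdai_fit,
                         preprocess_tooai_apply, preprocess_tooai_fit)
from .synthetic import (CANCER_CLASSES, NORMAL_LABEL, CohortConfig,
                        generate_cohort, generate_reference, make_class_profiles)
from .tooai import double_class_accuracy, double_class_confusion, \
    tooai_predict_matrix, train_tooai
from .vlm import align_cohort, build_boxes, trim_matrix

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; defaults match the method's design."""

    out_dir: str = "run"
    # simulation (used when peaks_path is None)
    simulate: bool = True
    n_metabolites: int = 300
    samples_per_class: dict = field(default_factory=dict)  # empty -> 40 each
    n_affected: int = 30
    effect: float = 0.5
    intensity_noise_sd: float = 0.2
    dropout_rate: float = 0.1
    batch_shift_sd: float = 0.05
    ppm_error_sd: float = 1.5
    n_batches: int = 3
    # real-data inputs (override simulation)
    peaks_path: str | None = None
    truth_path: str | None = None
    reference_path: str | None = None
    # alignment
    tol_ppm: float = 5.0
    # preprocessing
    min_prevalence: float = 0.1
    knn_k: int = 5
    # models
    split_fraction: float = 0.5
    regularization: float = 1.0
    balance: bool = True
    tooai_family: str = "max-margin"
    threshold: float = 0.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)


def _stage(name: str):
    logger.info("stage: %s", name)
    return name


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full tiered workflow; returns the manifest dict.

    Artifacts (all delimited text / JSON) land in ``config.out_dir``.
    """
    out = ensure_dir(config.out_dir)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": dataclasses.asdict(config), "stages": {}}
    stage = "setup"
    try:
        # ------------------------------------------------ simulate / load
        if config.peaks_path is None:
            stage = _stage("simulate")
            spc = dict(config.samples_per_class) or \
                {**{c: 40 for c in CANCER_CLASSES}, NORMAL_LABEL: 40}
            reference = generate_reference(config.n_metabolites,
                                           seed=config.seed)
            profiles = make_class_profiles(
                reference, [c for c in spc if c != NORMAL_LABEL],
                n_affected=config.n_affected, effect=config.effect,
                seed=config.seed + 1)
            cohort_cfg = CohortConfig(
                samples_per_class=spc, n_batches=config.n_batches,
                ppm_error_sd=config.ppm_error_sd,
                batch_shift_sd=config.batch_shift_sd,
                dropout_rate=config.dropout_rate,
                intensity_noise_sd=config.intensity_noise_sd,
                seed=config.seed + 2)
            peaks, truth = generate_cohort(reference, profiles, cohort_cfg)
            io.write_reference(reference, out / "reference.tsv")
            io.write_peaks(peaks, out / "peaks.tsv")
            io.write_truth(truth, out / "truth.tsv")
            manifest["stages"]["simulate"] = {
                "n_samples": len(truth), "n_peaks": len(peaks),
                "n_metabolites": len(reference)}
        else:
            stage = _stage("load")
            peaks = io.read_peaks(config.peaks_path)
            truth = io.read_truth(config.truth_path)
            reference = io.read_reference(config.reference_path)
            manifest["stages"]["load"] = {
                "n_samples": len(truth), "n_peaks": len(peaks)}

        # ------------------------------------------------ align
        stage = _stage("align")
        boxes = build_boxes(reference, tol_ppm=config.tol_ppm)
        matrix = align_cohort(peaks, truth, boxes)
        n_before = matrix.n_features
        matrix = trim_matrix(matrix, reference)
        matrix.to_tsv(out / "matrix.tsv", out / "samples.tsv")
        manifest["stages"]["align"] = {
            "n_boxes": len(boxes), "tol_ppm": config.tol_ppm,
            "features_before_trim": n_before,
            "features_after_trim": matrix.n_features,
            **boxes.report()}

        # ------------------------------------------------ split
        stage = _stage("split")
        rng = np.random.default_rng(config.seed + 3)
        ids = np.asarray(matrix.sample_ids, dtype=object)
        labels = matrix.labels
        train_ids, test_ids = [], []
        for lab in pd.unique(labels):
            members = ids[labels.to_numpy() == lab]
            perm = rng.permutation(members)
            cut = int(round(config.split_fraction * len(members)))
            train_ids.extend(perm[:cut])
            test_ids.extend(perm[cut:])
        train = matrix.select_samples(train_ids)
        test = matrix.select_samples(test_ids)
        manifest["stages"]["split"] = {"n_train": train.n_samples,
                                       "n_test": test.n_samples}

        # ------------------------------------------------ tier 1: detection
        stage = _stage("cdai")
        cdai_state, train_cdai_proc = preprocess_cdai_fit(
            train, config.min_prevalence, config.knn_k)
        test_cdai_proc = preprocess_cdai_apply(cdai_state, test)
        model1 = train_cdai(train_cdai_proc,
                            regularization=config.regularization,
                            balance=config.balance, seed=config.seed)
        model1.to_json(out / "cdai_model.json")
        scores = cdai_score_matrix(model1, test_cdai_proc)
        calls = scores.map(lambda s: cdai_classify(s, config.threshold))
        y_bin = binarize_labels(test.labels)
        counts = ConfusionCounts.from_calls(calls, y_bin, positive=CANCER)
        manifest["stages"]["cdai"] = {
            "n_features": len(model1.feature_ids),
            "sensitivity_pct": round1(sensitivity(counts)),
            "specificity_pct": round1(specificity(counts)),
            "accuracy_pct": round1(accuracy(counts)),
            "roc_auc": round(roc_auc(scores, y_bin, positive=CANCER), 4),
        }

        # ------------------------------------------------ route positives
        stage = _stage("route")
        positives = scores.index[calls == CANCER]
        manifest["stages"]["route"] = {"n_positive": len(positives),
                                       "n_rejected": test.n_samples - len(positives)}

        # ------------------------------------------------ tier 2: tissue of origin
        stage = _stage("tooai")
        cancer_train = train.select_samples(
            train.labels.index[train.labels != NORMAL_LABEL])
        tooai_state, train_tooai_proc = preprocess_tooai_fit(cancer_train,
                                                             k=config.knn_k)
        model2 = train_tooai(train_tooai_proc, model_family=config.tooai_family,
                             seed=config.seed)
        model2.to_json(out / "tooai_model.json")
        routed = test.select_samples(positives)
        routed_proc = preprocess_tooai_apply(tooai_state, routed)
        pred = tooai_predict_matrix(model2, routed_proc)

        report = pd.DataFrame({
            "y_score": scores,
            "cdai_call": calls,
            "true_label": test.labels,
        })
        pred_out = report.join(pred, how="left")
        pred_out.rename_axis("sample_id").to_csv(out / "predictions.tsv", sep="\t")
        manifest["stages"]["tooai"] = {"n_scored": len(pred),
                                       "n_classes": len(model2.class_labels)}

        # ------------------------------------------------ evaluate
        stage = _stage("evaluate")
        routed_cancer = routed.labels != NORMAL_LABEL
        eval_pred = pred.loc[routed_cancer[routed_cancer].index]
        truths = routed.labels[routed_cancer]
        if len(eval_pred):
            double_pct, per_class = double_class_accuracy(eval_pred, truths)
            top1_pct = 100.0 * float(np.mean(
                eval_pred["top1"].to_numpy() == truths.to_numpy()))
            confusion = double_class_confusion(eval_pred, truths,
                                               model2.class_labels)
            confusion.rename_axis("true_label").to_csv(
                out / "tooai_confusion.tsv", sep="\t")
            per_class.to_csv(out / "tooai_per_class.tsv", sep="\t")
        else:
            double_pct, top1_pct = float("nan"), float("nan")
        manifest["stages"]["evaluate"] = {
            "tooai_top1_accuracy_pct": round1(top1_pct),
            "tooai_double_class_accuracy_pct": round1(double_pct),
        }

        io.write_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        io.write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
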