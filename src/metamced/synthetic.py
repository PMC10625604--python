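"""Synthetic serum-metabolomics cohort generator.

Emulates the statistical structure a multi-cancer serum study presents to the
analysis pipeline: a metabolite mass reference (standing in for an HMDB-style
lookup), per-sample peak lists with ppm-scale mass error, class-specific
intensity shifts, batch-level drift, and dropout. Every draw is controlled by
explicit seeds so a cohort is bit-exact reproducible.

Model in brief (all on the log10 intensity scale):

    log10 I[s, m] = baseline[m] + class_shift[label(s), m]
                    + batch_shift[batch(s), m] + noise[s, m]

and the observed m/z of metabolite ``m`` in sample ``s`` is

    mz[s, m] = mass[m] * (1 + eps[s, m] * 1e-6),   eps ~ Normal(0, ppm_error_sd)

clipped to the instrument scan range. Dropout removes a (sample, metabolite)
peak independently with probability ``dropout_rate``, optionally tilted by a
logistic weighting so dimmer peaks drop more often.

Batch shifts are drawn from a dedicated stream (``batch_seed``) so a
robustness harness can regenerate the identical cohort under fresh batch-level
perturbations only.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CANCER_CLASSES",
    "NORMAL_LABEL",
    "SCAN_RANGE",
    "ClassEffectProfile",
    "CohortConfig",
    "generate_reference",
    "make_class_profiles",
    "generate_cohort",
]

#: The 15 cancer classes of the study, plus the normal-control label.
CANCER_CLASSES: tuple = (
    "breast", "endometrial", "cervical", "ovarian", "lung",
    "aml", "thyroid", "melanoma", "colorectal", "kidney",
    "nhl", "pancreatic", "head_neck", "gastric", "liver_bile",
)
NORMAL_LABEL = "normal"

#: Instrument scan range in Da (positive-mode UPLC-MS serum metabolomics).
SCAN_RANGE = (66.7, 1000.0)

ORIGIN_FLAGS = ("endogenous", "drug", "plant")


@dataclass(frozen=True)
class ClassEffectProfile:
    """Log10 fold shifts a disease class imposes on selected metabolites."""

    class_label: str
    effect_map: Mapping[str, float]

    @property
    def n_affected(self) -> int:
        return sum(1 for v in self.effect_map.values() if v != 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the cohort generator; the defaults define the study conditions.

    ``ppm_error_sd`` defaults to 5 ppm, the stated mass accuracy of the
    instrument class being emulated. ``seed`` fixes the full cohort bit-exactly;
    batch-level drift draws come from a separate stream (see
    :func:`generate_cohort`).
    """

    samples_per_class: Mapping[str, int]
    n_batches: int = 3
    ppm_error_sd: float = 5.0
    batch_shift_sd: float = 0.05
    dropout_rate: float = 0.10
    intensity_noise_sd: float = 0.20
    dropout_intensity_slope: float = 0.0
    mass_low: float = SCAN_RANGE[0]
    mass_high: float = SCAN_RANGE[1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.ppm_error_sd < 0 or self.batch_shift_sd < 0 or self.intensity_noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if any(c < 0 for c in self.samples_per_class.values()):
            raise ValueError("sample counts must be >= 0")

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


def generate_reference(n_metabolites: int, mass_low: float = SCAN_RANGE[0],
                       mass_high: float = SCAN_RANGE[1], seed: int = 0,
                       frac_drug: float = 0.10, frac_plant: float = 0.10,
                       baseline_mean: float = 5.0,
                       baseline_sd: float = 1.0) -> pd.DataFrame:
    """Generate a metabolite mass reference table.

    Returns a DataFrame with columns ``metabolite_id``, ``name``,
    ``monoisotopic_mass`` (Da, strictly inside ``[mass_low, mass_high]``),
    ``origin_flag`` in {endogenous, drug, plant}, plus two physical
    properties of each metabolite used by the cohort simulator:
    ``baseline_log10`` (characteristic serum log10 abundance,
    Normal(``baseline_mean``, ``baseline_sd``)) and ``rt_seconds``
    (characteristic retention time). Roughly ``frac_drug`` / ``frac_plant``
    of entries carry the non-endogenous flags (at least one of each when
    ``n_metabolites`` allows), mirroring the exogenous entries an HMDB-style
    lookup returns that are trimmed before modelling.
    """
    if n_metabolites < 1:
        raise ValueError("n_metabolites must be >= 1")
    if not 0 < mass_low < mass_high:
        raise ValueError(f"invalid mass range ({mass_low}, {mass_high})")
    if frac_drug + frac_plant > 1.0:
        raise ValueError("frac_drug + frac_plant must be <= 1")
    rng = np.random.default_rng(seed)
    masses = np.sort(rng.uniform(mass_low, mass_high, size=n_metabolites))
    n_drug = int(round(frac_drug * n_metabolites))
    n_plant = int(round(frac_plant * n_metabolites))
    if n_metabolites >= 3:
        n_drug = max(n_drug, 1)
        n_plant = max(n_plant, 1)
    flags = np.array(["endogenous"] * n_metabolites, dtype=object)
    exo = rng.choice(n_metabolites, size=min(n_drug + n_plant, n_metabolites),
                     replace=False)
    flags[exo[:n_drug]] = "drug"
    flags[exo[n_drug:]] = "plant"
    width = len(str(n_metabolites))
    ids = [f"MET{i:0{width}d}" for i in range(n_metabolites)]
    alphabet = np.array(list(string.ascii_uppercase))
    names = ["".join(rng.choice(alphabet, size=6)) for _ in range(n_metabolites)]
    return pd.DataFrame({
        "metabolite_id": ids,
        "name": names,
        "monoisotopic_mass": masses,
        "origin_flag": flags,
        "baseline_log10": rng.normal(baseline_mean, baseline_sd,
                                     size=n_metabolites),
        "rt_seconds": rng.uniform(30.0, 840.0, size=n_metabolites),
    })


def make_class_profiles(reference: pd.DataFrame,
                        classes: Sequence[str] = CANCER_CLASSES,
                        n_affected: int = 30, effect: float = 0.5,
                        shared_fraction: float = 0.5, seed: int = 0,
                        include_normal: bool = True) -> list:
    """Draw one disease signature per cancer class from the endogenous pool.

    Each class's signature holds ``n_affected`` endogenous metabolites shifted
    by ``effect`` log10 units, split into a component shared by every cancer
    class (``shared_fraction`` of the signature) and a class-specific
    remainder drawn independently per class. The shared component models the
    common metabolic reprogramming that lets a single binary score separate
    pooled cancers from normals — without it the cancer classes share no
    signal axis; the specific components carry the tissue-of-origin
    information. The normal class carries an empty (all-zero) effect map by
    convention.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    endo = reference.loc[reference["origin_flag"] == "endogenous",
                         "metabolite_id"].to_numpy()
    n_shared = int(round(shared_fraction * n_affected))
    n_specific = n_affected - n_shared
    if n_shared + len(classes) * n_specific > len(endo):
        raise ValueError("signatures exceed the endogenous metabolite pool")
    pool = rng.permutation(endo)
    shared = pool[:n_shared]
    rest = pool[n_shared:]
    profiles = []
    for i, label in enumerate(classes):
        specific = rest[i * n_specific:(i + 1) * n_specific]
        effect_map = {m: effect for m in shared}
        effect_map.update({m: effect for m in specific})
        profiles.append(ClassEffectProfile(label, effect_map))
    if include_normal:
        profiles.append(ClassEffectProfile(NORMAL_LABEL, {}))
    return profiles


def _dropout_probabilities(cfg: CohortConfig, log10_intensity: np.ndarray,
                           midpoint: float) -> np.ndarray:
    """Per-cell dropout probability; uniform unless the logistic tilt is on."""
    if cfg.dropout_rate <= 0.0:
        return np.zeros_like(log10_intensity)
    if cfg.dropout_rate >= 1.0:
        return np.ones_like(log10_intensity)
    if cfg.dropout_intensity_slope == 0.0:
        return np.full_like(log10_intensity, cfg.dropout_rate)
    # logistic weighting centred on the cohort's mean abundance: dim peaks
    # drop more often
    tilt = cfg.dropout_intensity_slope * (midpoint - log10_intensity)
    return expit(logit(cfg.dropout_rate) + tilt)


def generate_cohort(reference: pd.DataFrame,
                    profiles: Sequence[ClassEffectProfile],
                    config: CohortConfig,
                    batch_seed: int | None = None):
    """Simulate per-sample peak lists and the matching ground-truth table.

    Returns ``(peaks, truth)``:

    * ``peaks`` — long-format DataFrame with one row per surviving peak:
      ``sample_id, batch_id, rt_seconds, mz, intensity, metabolite_id``. The
      last column is ground-truth annotation for validation only; the
      alignment stage never reads it.
    * ``truth`` — one row per sample: ``sample_id, class_label, batch_id``.

    Baseline abundances and retention times are fixed properties of the
    metabolites, read from the reference table; all sample-level randomness
    (batch membership, mass errors, intensity noise, dropout) derives from
    ``config.seed``. Batch-shift values alone come from ``batch_seed``
    (default ``config.seed + 1``), so regenerating with a different
    ``batch_seed`` yields the same cohort under fresh batch-level drift —
    and with ``batch_shift_sd == 0`` the cohort is identical for every
    ``batch_seed``.
    """
    profile_by_label = {p.class_label: p for p in profiles}
    missing = [lab for lab, n in config.samples_per_class.items()
               if n > 0 and lab not in profile_by_label]
    if missing:
        raise ValueError(f"no ClassEffectProfile for classes: {missing}")
    ref_ids = reference["metabolite_id"].to_numpy()
    ref_index = {m: i for i, m in enumerate(ref_ids)}
    for p in profiles:
        unknown = set(p.effect_map) - set(ref_index)
        if unknown:
            raise ValueError(f"profile {p.class_label} references unknown "
                             f"metabolites: {sorted(unknown)[:5]}")

    masses = reference["monoisotopic_mass"].to_numpy(dtype=float)
    n_met = len(masses)
    for col in ("baseline_log10", "rt_seconds"):
        if col not in reference.columns:
            raise ValueError(f"reference lacks the {col!r} column "
                             "(regenerate it with generate_reference)")
    baselines = reference["baseline_log10"].to_numpy(dtype=float)
    rts = reference["rt_seconds"].to_numpy(dtype=float)

    rng = np.random.default_rng(config.seed)
    if batch_seed is None:
        batch_seed = config.seed + 1
    rng_batch = np.random.default_rng(batch_seed)

    # sample roster, classes in mapping order
    labels: list = []
    for lab, n in config.samples_per_class.items():
        labels.extend([lab] * n)
    n_samples = len(labels)
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    batch_ids = rng.integers(0, config.n_batches, size=n_samples)

    # per-class shift vectors
    class_shift = {}
    for lab in config.samples_per_class:
        vec = np.zeros(n_met)
        for m, eff in profile_by_label.get(lab, ClassEffectProfile(lab, {})).effect_map.items():
            vec[ref_index[m]] = eff
        class_shift[lab] = vec
    shift_rows = np.vstack([class_shift[lab] for lab in labels]) if n_samples \
        else np.zeros((0, n_met))

    eps_ppm = rng.normal(0.0, config.ppm_error_sd, size=(n_samples, n_met))
    noise = rng.normal(0.0, config.intensity_noise_sd, size=(n_samples, n_met))
    drop_u = rng.uniform(size=(n_samples, n_met))

    # batch-level drift: its own stream, one shift per (batch, metabolite)
    batch_shifts = rng_batch.normal(0.0, 1.0, size=(config.n_batches, n_met)) \
        * config.batch_shift_sd

    log10_int = (baselines[None, :] + shift_rows
                 + batch_shifts[batch_ids, :] + noise)
    drop_p = _dropout_probabilities(config, log10_int, float(baselines.mean()))
    kept = drop_u >= drop_p

    mz = masses[None, :] * (1.0 + eps_ppm * 1e-6)
    np.clip(mz, config.mass_low, config.mass_high, out=mz)

    s_idx, m_idx = np.nonzero(kept)
    peaks = pd.DataFrame({
        "sample_id": np.asarray(sample_ids, dtype=object)[s_idx],
        "batch_id": batch_ids[s_idx],
        "rt_seconds": rts[m_idx],
        "mz": mz[s_idx, m_idx],
        "intensity": 10.0 ** log10_int[s_idx, m_idx],
        "metabolite_id": ref_ids[m_idx],
    })
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "class_label": labels,
        "batch_id": batch_ids,
    })
    return peaks, truth
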