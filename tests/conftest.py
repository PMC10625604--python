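import numpy as np
import pandas as pd
import pytest

from metamced import (CohortConfig, FeatureMatrix, build_boxes,
                      generate_reference, make_class_profiles)
from metamced.synthetic import CANCER_CLASSES, NORMAL_LABEL


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference(60, seed=11)


@pytest.fixture(scope="session")
def small_boxes(small_reference):
    return build_boxes(small_reference, tol_ppm=5.0)


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    """Three cancer classes + normals, strong planted signatures."""
    classes = ["breast", "ovarian", "lung"]
    profiles = make_class_profiles(small_reference, classes, n_affected=8,
                                   effect=0.8, seed=5)
    config = CohortConfig(
        samples_per_class={**{c: 12 for c in classes}, NORMAL_LABEL: 12},
        ppm_error_sd=1.0, dropout_rate=0.05, intensity_noise_sd=0.15,
        seed=7)
    from metamced import generate_cohort
    peaks, truth = generate_cohort(small_reference, profiles, config)
    return peaks, truth, profiles, config


@pytest.fixture(scope="session")
def small_matrix(small_cohort, small_boxes, small_reference):
    from metamced import align_cohort, trim_matrix
    peaks, truth, _, _ = small_cohort
    return trim_matrix(align_cohort(peaks, truth, small_boxes), small_reference)


def random_matrix(n_samples, n_features, missing_rate=0.0, seed=0,
                  labels=None) -> FeatureMatrix:
    """Small random FeatureMatrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(1.0, 100.0, size=(n_samples, n_features))
    if missing_rate > 0:
        mask = rng.uniform(size=X.shape) < missing_rate
        # keep at least one observed value per row
        for i in range(n_samples):
            if mask[i].all():
                mask[i, rng.integers(n_features)] = False
        X = np.where(mask, np.nan, X)
    if labels is None:
        labels = ["a" if i % 2 == 0 else "b" for i in range(n_samples)]
    return FeatureMatrix.from_arrays(
        X, [f"S{i}" for i in range(n_samples)],
        [f"F{j}" for j in range(n_features)], labels)
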