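"""Shared fixtures: small seeded cohorts and their feature matrices.

Cohorts are generated programmatically; nothing is read from disk.
Session scope keeps the expensive signal synthesis and feature
extraction to one pass per test run.
"""

import numpy as np
import pytest

from archepsy import CohortConfig, extract_cohort_features, generate_cohort, sam_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects, all eight classes, full-length epochs."""
    return generate_cohort(CohortConfig(n_subjects=4, seed=42))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort)


@pytest.fixture(scope="session")
def small_sam(small_cohort):
    return sam_matrix(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
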