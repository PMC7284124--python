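import numpy as np
import pytest

from morphotype import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with two strongly separated planted subtypes."""
    spec = CohortSpec(n_control=60, n_clinical=80, n_rois=60,
                      n_subtypes=2, effect_size=1.5, affected_fraction=0.3,
                      seed=11)
    features, records, truth = generate_cohort(spec)
    return spec, features, records, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted subtype structure (effect_size = 0)."""
    spec = CohortSpec(n_control=40, n_clinical=50, n_rois=40,
                      n_subtypes=2, effect_size=0.0, seed=23)
    features, records, truth = generate_cohort(spec)
    return spec, features, records, truth


def true_labels(truth, clinical_ids):
    return [truth.subtype_label[s] for s in clinical_ids]


def random_partition_pair(rng, n_max=30, k_max=4):
    n = int(rng.integers(2, n_max + 1))
    ka = int(rng.integers(1, k_max + 1))
    kb = int(rng.integers(1, k_max + 1))
    return rng.integers(1, ka + 1, size=n), rng.integers(1, kb + 1, size=n)
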