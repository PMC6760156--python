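import numpy as np
import pytest

from toothrqa import CohortConfig, EmbeddingParams, SignalParams
from toothrqa.synthetic import Diagnosis, scaled_group_sizes


@pytest.fixture
def default_params():
    return EmbeddingParams()


@pytest.fixture
def small_cohort_config():
    """Six pairs + two singletons (14 subjects), all four diagnoses."""
    return CohortConfig(
        n_pairs=6,
        triplet_count=0,
        singleton_count=2,
        group_sizes={
            Diagnosis.TD: 7,
            Diagnosis.ADHD: 3,
            Diagnosis.ASD: 2,
            Diagnosis.COMORBID: 2,
        },
        seed=11,
    )


def make_paired_cohort(n_pairs, seed, effects=None, elements=None):
    """Cohort of complete pairs with diagnosis counts scaled from the
    default design; used by recovery and null simulations."""
    total = 2 * n_pairs
    return CohortConfig(
        n_pairs=n_pairs,
        triplet_count=0,
        singleton_count=0,
        group_sizes=scaled_group_sizes(total),
        pathway_effects=effects or {},
        elements=tuple(elements) if elements else CohortConfig().elements,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
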