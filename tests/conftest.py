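import numpy as np
import pytest

from connstrat import synthio


@pytest.fixture(scope="session")
def planted_cohort():
    """156-subject cohort with a strong (d=3) subgroup effect on 8 of 13
    behavioural features."""
    effects = np.concatenate([np.full(8, 3.0), np.zeros(5)])
    spec = synthio.CohortSpec(feature_effects=effects, seed=11)
    metadata, features, subgroup = synthio.gen_cohort(spec)
    return metadata, features, subgroup


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted subgroup structure."""
    spec = synthio.CohortSpec(seed=23)
    return synthio.gen_cohort(spec)


@pytest.fixture(scope="session")
def small_stack():
    """20-subject, 10-node connectome stack with its metadata."""
    metadata, _, _ = synthio.gen_cohort(synthio.CohortSpec(n_subjects=20, seed=7))
    spec = synthio.PlantedComponentSpec(n_nodes=10, n_edges_planted=6,
                                        delta=0.5, seed=7)
    stack, true_edges = synthio.gen_connectome_stack(metadata, spec)
    return stack, metadata, true_edges
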