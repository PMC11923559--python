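import numpy as np
import pytest

from cpmnet.parcellation import default_parcellation
from cpmnet.pipeline import cohort_edge_matrix
from cpmnet.synthetic import CohortSpec, generate_cohort, random_edge_sets


@pytest.fixture(scope="session")
def small_parcellation():
    return default_parcellation(20)


@pytest.fixture(scope="session")
def coupled_cohort(small_parcellation):
    """A small cohort with planted positive/negative couplings."""
    pos, neg = random_edge_sets(20, 5, 5, seed=7, parcellation=small_parcellation)
    spec = CohortSpec(n_subjects=24, n_nodes=20, frames_per_run=104,
                      positive_edges=pos, negative_edges=neg,
                      effect_size=0.3, fd_spike_rate=0.05, seed=11)
    return generate_cohort(spec, small_parcellation)


@pytest.fixture(scope="session")
def coupled_edges(coupled_cohort):
    """Subjects×edges FC matrix plus the phenotype vector."""
    edges = cohort_edge_matrix(coupled_cohort.subjects)
    return edges, coupled_cohort.phenotype_vector()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
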