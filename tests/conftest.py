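"""Shared fixtures: state spaces and a simulated hexaploid full-sib family.

The heavy objects (a 298-individual population on a 3 x 120 cM map with a
2 cM grid, and its resampling-based significance thresholds) are built
once per session and shared by the unit, property and acceptance tests.
"""

import numpy as np
import pytest

import polyqtl as pq

POP_SEED = 11
THRESHOLD_SEED = 2
N_FULLSIBS = 298


@pytest.fixture(scope="session")
def space6():
    return pq.build_state_space(6)


@pytest.fixture(scope="session")
def space4():
    return pq.build_state_space(4)


@pytest.fixture(scope="session")
def pi6(space6):
    return pq.build_pi_matrix(space6)


@pytest.fixture(scope="session")
def sim_map():
    """3 linkage groups x 120 cM, grid every 2 cM."""
    return pq.GeneticMap.regular_grid(3, 120.0, 2.0)


@pytest.fixture(scope="session")
def pop298(sim_map):
    """Hexaploid full-sib family of 298 offspring with one-hot genotypes."""
    return pq.simulate_population(pq.MeiosisConfig(6, sim_map, N_FULLSIBS,
                                                   seed=POP_SEED))


@pytest.fixture(scope="session")
def grid298(pop298):
    return pop298.grid


@pytest.fixture(scope="session")
def search_config():
    return pq.SearchConfig(n_resamples=200)


@pytest.fixture(scope="session")
def remim_thresholds(grid298, search_config):
    """Genome-wide score-resampling P-value thresholds at alpha 0.20/0.05."""
    return pq.resampling_threshold(grid298, grid298.n, search_config,
                                   rng=THRESHOLD_SEED)


@pytest.fixture(scope="session")
def small_pop():
    """A smaller family on a single chromosome for cheap unit tests."""
    gmap = pq.GeneticMap.regular_grid(1, 100.0, 5.0)
    return pq.simulate_population(pq.MeiosisConfig(6, gmap, 80, seed=5))


@pytest.fixture(scope="session")
def study_unlinked_offset(grid298):
    """100-replicate FEIM study, unlinked scenario, error vectors subtracted."""
    from polyqtl.simstudy import run_study
    return run_study(grid298, "unlinked", 100, rng=101, methods=("FEIM",),
                     offset=True, n_perm=200)


@pytest.fixture(scope="session")
def study_random_remim(grid298, remim_thresholds, search_config):
    """100-replicate REMIM study on the random scenario."""
    from polyqtl.simstudy import run_study
    return run_study(grid298, "random", 100, rng=202, methods=("REMIM",),
                     remim_thresholds=remim_thresholds, config=search_config)


@pytest.fixture(scope="session")
def study_linked_both(grid298, remim_thresholds, search_config):
    """40-replicate two-method study on the linked scenario."""
    from polyqtl.simstudy import run_study
    return run_study(grid298, "linked", 40, rng=303,
                     methods=("FEIM", "REMIM"),
                     remim_thresholds=remim_thresholds, config=search_config,
                     feim_alpha=0.05, n_perm=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
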