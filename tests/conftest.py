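import itertools

import numpy as np
import pytest

import neiqtl as nq
from neiqtl.genotypes import CROSS_STATES, MISSING, transition_matrix

MAP_FNS = {"haldane": nq.genotypes.haldane_cm_to_rf, "kosambi": nq.genotypes.kosambi_cm_to_rf}


@pytest.fixture(scope="session")
def small_map():
    return nq.GeneticMap(
        ["1", "2"],
        {"1": ["m1_1", "m1_2", "m1_3"], "2": ["m2_1", "m2_2"]},
        {"1": np.array([0.0, 12.0, 30.0]), "2": np.array([0.0, 20.0])},
    )


@pytest.fixture(scope="session")
def f2_cross(small_map):
    return nq.sim_cross("f2", small_map, 120, seed=11)


@pytest.fixture(scope="session")
def f2_smap():
    return nq.sim_spatial(120, seed=12)


@pytest.fixture(scope="session")
def f2_gp(f2_cross):
    return nq.calc_genoprob(f2_cross, nq.insert_pseudomarkers(f2_cross.map, 5.0))


@pytest.fixture(scope="session")
def f2_sim():
    """A seeded F2 data set with short-range neighbor effects."""
    return nq.simulate_dataset(nq.SimScenario(seed=7, true_percentile=10, n=150))


def enumerate_posterior(cross_type, positions, observed, error_prob, map_function="haldane"):
    """Brute-force hidden-path enumeration oracle for conditional genotype
    probabilities on one chromosome.

    ``observed`` holds a genotype code per position (MISSING for
    pseudomarkers or missing calls).  Sums over all |states|^P paths.
    """
    states = CROSS_STATES[cross_type]
    K = len(states)
    init = {"f2": [0.25, 0.5, 0.25]}.get(cross_type, [0.5, 0.5])
    cm_to_rf = MAP_FNS[map_function]
    gaps = np.diff(positions)
    trans = [transition_matrix(cross_type, float(cm_to_rf(d))) for d in gaps]

    def emission(obs, state):
        if obs == MISSING:
            return 1.0
        if obs == state:
            return 1.0 - error_prob
        return error_prob / (K - 1)

    P = len(positions)
    post = np.zeros((P, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=P):
        w = init[path[0]] * emission(observed[0], states[path[0]])
        for t in range(1, P):
            w *= trans[t - 1][path[t - 1], path[t]] * emission(observed[t], states[path[t]])
        total += w
        for t in range(P):
            post[t, path[t]] += w
    return post / total


def ols_rss(X, y):
    """Independent RSS via the explicit hat matrix (pseudo-inverse)."""
    H = X @ np.linalg.pinv(X)
    r = y - H @ y
    return float(r @ r)
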