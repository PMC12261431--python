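import math

import numpy as np
import pytest

from branchfit.rates import FitnessMatrix, ModelParams
from branchfit.trees import MutationTree


def chain_params(lams, mu=1e-3, C0=1e4, C_sampling=1e10, t_max=60.0, beta=1.0):
    """ModelParams whose chain genotypes {1}, {1,2}, ... have the given lambdas."""
    n = len(lams)
    phis = [math.log1p(l / beta) for l in lams]
    F = np.zeros((n, n))
    F[0, 0] = phis[0]
    for v in range(1, n):
        F[v, v] = min(0.0, phis[v]) - 1.0  # dominated base effect
        F[v - 1, v] = phis[v] - phis[v - 1]
    mu_vec = np.full(n, mu) if np.isscalar(mu) else np.asarray(mu)
    return ModelParams(C0=C0, C_sampling=C_sampling, C_seq=100, t_max=t_max,
                       mu=mu_vec, beta=beta, F=FitnessMatrix(F))


def chain_tree(n, counts=None):
    edges = [(None, "root", [])]
    for v in range(1, n + 1):
        edges.append(("root" if v == 1 else f"v{v - 1}", f"v{v}", [v]))
    return MutationTree.from_edges(edges, counts or {})


@pytest.fixture(scope="session")
def small_benchmark():
    """A tiny observable synthetic cohort with known ground truth."""
    from branchfit.simulate import benchmark_scenario

    return benchmark_scenario(3, 25, seed=42, dt=0.1)
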