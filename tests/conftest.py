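import numpy as np
import pytest

from osteoimmune import (
    reference_initial_conditions,
    reference_steady_states,
)
from osteoimmune.parameter_fit import fit_cluster_parameters
from osteoimmune.simulate import integrate_to_convergence

CLUSTERS = (1, 2, 3)


@pytest.fixture(scope="session")
def steady_states():
    return reference_steady_states()


@pytest.fixture(scope="session")
def initial_conditions():
    return reference_initial_conditions()


@pytest.fixture(scope="session")
def fits(steady_states):
    """Cluster-wise parameter fits from the built-in steady states."""
    return {k: fit_cluster_parameters(steady_states[k], seed=1, cluster=k)
            for k in CLUSTERS}


@pytest.fixture(scope="session")
def trajectories(fits, steady_states, initial_conditions):
    """Dimensionless trajectories from the reference initial conditions."""
    return {
        k: integrate_to_convergence(
            fits[k].params, initial_conditions[k].values,
            steady_states[k].values, rtol=1e-8, cluster=k)
        for k in CLUSTERS
    }


def random_positive_params(rng):
    """A fully random positive parameter set (for oracle comparisons)."""
    from osteoimmune.model_core import PARAMETER_NAMES, ParameterSet
    d = {n: float(rng.lognormal(-2.0, 1.0)) for n in PARAMETER_NAMES}
    d["C0"] = float(rng.lognormal(10.0, 1.0))
    d["alpha_NC"] = float(rng.uniform(0.05, 1.0))
    return ParameterSet.from_dict(d)
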