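import numpy as np
import pytest

from dagiv.simulate import (
    SEMParameters,
    default_sigma2,
    intervention_W,
    random_graph_U,
    sample_dataset,
)


@pytest.fixture(scope="session")
def setup_a_small():
    """Setup-A instance (p=10, q=30, n=500) with known truth."""
    p, q = 10, 30
    U = random_graph_U(p, seed=5)
    params = SEMParameters(U, intervention_W("A", p, q), default_sigma2(p))
    data, e = sample_dataset(params, 500, seed=42)
    return params, data, e


@pytest.fixture(scope="session")
def chain_params():
    """Chain Y1 -> Y2 -> ... -> Y6 with per-node instruments (Setup A)."""
    p, q = 6, 12
    U = np.zeros((p, p))
    for j in range(p - 1):
        U[j, j + 1] = 0.8
    return SEMParameters(U, intervention_W("A", p, q), default_sigma2(p))


def random_dag_params(p: int, q: int, seed: int) -> SEMParameters:
    """Random DAG with Setup-A interventions (everyone instrumented)."""
    U = random_graph_U(p, seed)
    return SEMParameters(U, intervention_W("A", p, q), default_sigma2(p))
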