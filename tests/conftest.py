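import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ordbs.dag_model import (
    CausalDAG,
    ExperimentSet,
    assign_systematic_interventions,
    generate_random_dag,
    simulate_experiments,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_ensemble_data(p, q, N, r, seed, *, sigma_lo=0.01, sigma_hi=0.1, **kw):
    """One draw from the standard random-DAG ensemble with systematic knock-outs."""
    rng = np.random.default_rng(seed)
    dag = generate_random_dag(p, q, sigma_lo=sigma_lo, sigma_hi=sigma_hi, rng=rng, **kw)
    interventions = assign_systematic_interventions(p, N, r)
    return dag, simulate_experiments(dag, N, interventions, rng)


def make_chain_data(p=5, N=60, r=30, w=1.0, sigma=0.01, seed=7):
    """A strongly coupled causal chain 0 -> 1 -> ... -> p-1 with knock-outs."""
    W = np.zeros((p, p))
    for i in range(p - 1):
        W[i, i + 1] = w
    dag = CausalDAG(W=W, m=np.full(p, 0.5), sigma=np.full(p, sigma), gen_order=np.arange(p))
    rng = np.random.default_rng(seed)
    interventions = assign_systematic_interventions(p, N, r)
    return dag, simulate_experiments(dag, N, interventions, rng)


def make_iid_data(p, N, seed, scale=1.0):
    """Independent Gaussian columns: no causal structure at all."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, scale, size=(N, p))
    return ExperimentSet(X=X, interventions=tuple({} for _ in range(N)))


@pytest.fixture(scope="session")
def chain5():
    return make_chain_data(p=5)


@pytest.fixture(scope="session")
def chain3():
    return make_chain_data(p=3, N=60, r=30)
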