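import numpy as np
import pytest

from evidenceflow import fixture, hat_matrix
from evidenceflow.synthetic import SyntheticSpec, generate_synthetic


@pytest.fixture(scope="session")
def fig2():
    """Five-treatment worked example with weights 1,3,4,6,5,2,7."""
    return fixture("fig2")


@pytest.fixture(scope="session")
def fig2_hat(fig2):
    return hat_matrix(fig2)


@pytest.fixture(scope="session")
def macfadyen():
    """Four-treatment flow network for the 1-2 comparison (topical antibiotics)."""
    return fixture("macfadyen_flow")


@pytest.fixture(scope="session")
def synthetic_trials():
    """A default-sized synthetic data set (11 treatments, 26 trials, multi-arm)."""
    trials, truth = generate_synthetic(SyntheticSpec(seed=42))
    return trials, truth


def small_synthetic_network(seed: int, n_treatments: int = 6, n_trials: int = 10):
    """Helper: a small pooled network for property checks."""
    from evidenceflow.nma_core import pool_direct

    spec = SyntheticSpec(n_treatments=n_treatments, n_trials=n_trials, seed=seed)
    trials, _ = generate_synthetic(spec)
    return pool_direct(trials)
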