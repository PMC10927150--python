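"""Shared fixtures: small simulated experiments reused across test modules."""

import numpy as np
import pytest

from top2itox import simulate


@pytest.fixture(scope="session")
def small_experiment():
    """A small default-design experiment (300 genes) plus its planted truth."""
    design = simulate.SimDesign(n_genes=300, seed=7)
    experiment, truth = simulate.simulate_counts(design)
    return experiment, truth


@pytest.fixture(scope="session")
def inflated_experiment():
    """A mid-size experiment with the anthracycline 24 h variance inflation."""
    design = simulate.SimDesign(
        n_genes=1500,
        seed=19,
        variance_inflation=simulate.ac_variance_inflation(1.5),
    )
    experiment, truth = simulate.simulate_counts(design)
    return experiment, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
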