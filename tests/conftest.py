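import numpy as np
import pandas as pd
import pytest

import metaregulon as mr
from metaregulon import synthetic


@pytest.fixture(scope="session")
def small_truth():
    """Compact planted scenario shared by read-only tests."""
    master, truth = synthetic.make_master_interactome(
        n_regulators=60, n_genes=1500, targets_per_regulon=40, mode_mix=0.3, seed=11
    )
    return truth


@pytest.fixture(scope="session")
def small_master(small_truth):
    return small_truth.master


@pytest.fixture()
def small_signature(small_truth):
    return synthetic.simulate_signatures(
        small_truth,
        n_samples=12,
        n_active_per_sample=4,
        effect_theta=0.5,
        noise_sd=1.0,
        seed=13,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


@pytest.fixture()
def toy_interactome():
    """Two tiny hand-built regulons with mixed modes."""
    return mr.Interactome(
        name="toy",
        regulons={
            "R1": mr.Regulon(
                "R1",
                np.array(["g1", "g2", "g3"], dtype=object),
                np.array([1.0, -1.0, 0.5]),
                np.array([1.0, 0.8, 0.6]),
            ),
            "R2": mr.Regulon(
                "R2",
                np.array(["g2", "g4"], dtype=object),
                np.array([-1.0, 1.0]),
                np.array([0.9, 1.0]),
            ),
        },
    )
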