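import os

# pin BLAS threading before numpy initializes so results are bit-identical
# across machines with different core counts
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import warnings

import numpy as np
import pytest

from icarh import (
    ModelSpec,
    SamplerSettings,
    SimulationSpec,
    build_design_matrices,
    fit,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with known truth (M=8, P=3, N=12, T=6)."""
    spec = SimulationSpec(
        N=12, T=6, M=8, K=1, P=3, seed=7,
        membership_probs={1: 0.7, 2: 0.3},
    )
    dataset, truth = simulate_dataset(spec, np.random.default_rng(7))
    return spec, dataset, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A two-chain fit of the small dataset, shared across tests."""
    _, dataset, truth = small_sim
    pm = build_design_matrices(truth.Z)
    spec = ModelSpec(
        tau=1.2,
        sampler=SamplerSettings(iterations=700, warmup=350, chains=2, seed=42),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = fit(dataset, pm, spec, standardize=False)
    return dataset, truth, pm, samples
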