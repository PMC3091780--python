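"""Shared fixtures: canonical designs and cached default simulations."""

import pytest

from spikeqc import (
    ArraySimParams,
    QpcrSimParams,
    condition_panel_pair,
    dilution_pool_design,
    simulate_microarray,
    simulate_qpcr,
)


@pytest.fixture(scope="session")
def pools():
    return dilution_pool_design()


@pytest.fixture(scope="session")
def panel_pair():
    return condition_panel_pair()


@pytest.fixture(scope="session")
def default_array_dataset(pools):
    """Default-parameter 3-run microarray simulation of the dilution pools."""
    return simulate_microarray(pools, ArraySimParams(seed=1), n_runs=3)


@pytest.fixture(scope="session")
def default_qpcr_dataset(pools):
    """Default-parameter 3-run triplicate qPCR simulation of the pools."""
    return simulate_qpcr(pools, QpcrSimParams(seed=1), n_runs=3)


def noise_free_array_params(seed: int = 0, **overrides) -> ArraySimParams:
    """Array parameters with every noise source off and saturation disabled."""
    base = dict(
        sigma_tech=0.0,
        sigma_low=0.0,
        run_sd=0.0,
        labelling_sd=0.0,
        saturation_K=float("inf"),
        seed=seed,
    )
    base.update(overrides)
    return ArraySimParams(**base)
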