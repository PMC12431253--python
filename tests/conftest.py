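"""Shared fixtures: everything is generated programmatically at test time."""

import pytest

from enzdesign import synthetic_data as syn
from enzdesign.ensemble_gen import BoundConfig, derive_bounds


@pytest.fixture(scope="session")
def toy():
    """20-residue toy enzyme with triad + ester substrate (seed 1)."""
    return syn.make_toy_enzyme(20, rng_seed=1)


@pytest.fixture(scope="session")
def apo(toy):
    return syn.strip_substrate(toy)


@pytest.fixture(scope="session")
def substrate_template(toy):
    return syn.toy_substrate_template(toy)


@pytest.fixture(scope="session")
def bound_config(toy):
    return BoundConfig(anchor_res_ids=tuple(sorted(toy.meta["triad"].values())))


@pytest.fixture(scope="session")
def bound_set(apo, bound_config):
    return derive_bounds(apo, bound_config)
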