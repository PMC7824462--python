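import dataclasses

import numpy as np
import pytest

import lamap
from lamap.phantom import PhantomSpec, noiseless


def small_spec(**overrides) -> PhantomSpec:
    """A 40-slice phantom: same in-plane geometry, desk-scale runtime."""
    spec = PhantomSpec(shape_zyx=(40, 120, 120))
    return dataclasses.replace(spec, **overrides) if overrides else spec


@pytest.fixture(scope="session")
def default_prior() -> lamap.PriorTable:
    return lamap.default_priors()


@pytest.fixture(scope="session")
def small_noiseless_phantom():
    """(volume, truth) for a noiseless small phantom, shared across tests."""
    return lamap.generate_phantom(noiseless(small_spec()), seed=11)


@pytest.fixture(scope="session")
def small_noisy_phantom():
    """(volume, truth) for a noisy small phantom, shared across tests."""
    return lamap.generate_phantom(small_spec(), seed=11)
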