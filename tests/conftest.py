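"""Shared fixtures: small synthetic bundles and helpers used across the suite."""

import numpy as np
import pytest

from navpd.synthetic import SyntheticSpec, gen_bundle


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def bundle(default_spec):
    """The default closed tetramer (gate diameter target 3.5 Å), seed 1."""
    return gen_bundle(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
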