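"""Shared fixtures: the expensive phantoms are generated once per session."""

import numpy as np
import pytest

from chromovol import segmentation
from chromovol.phantom import generate_phantom, metaphase_spec, prophase_spec


@pytest.fixture(scope="session")
def metaphase_phantom():
    """(grid, truth) for the canonical metaphase conditions, seed 0."""
    return generate_phantom(metaphase_spec(seed=0))


@pytest.fixture(scope="session")
def metaphase_segmented(metaphase_phantom):
    """Default-parameter segmentation of the metaphase phantom."""
    grid, _ = metaphase_phantom
    labels, threshold = segmentation.segment(grid)
    return labels, threshold


@pytest.fixture(scope="session")
def prophase_phantom():
    """(grid, truth) for the canonical prophase conditions, seed 0."""
    return generate_phantom(prophase_spec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
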