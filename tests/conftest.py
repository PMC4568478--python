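"""Shared fixtures: a noise-free phantom session pushed through each stage.

Session-scoped because the phantom render and voxelwise deconvolution are
the expensive steps; all consumers treat the results as read-only.
"""

import numpy as np
import pytest

from dscpipe import (
    PhantomSpec,
    build_phantom_atlas,
    compute_maps,
    default_territory_truths,
    estimate_baseline,
    select_aif_voxels,
    signal_to_concentration,
    simulate_phantom_session,
)


@pytest.fixture(scope="session")
def phantom():
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture(scope="session")
def atlas(phantom):
    return build_phantom_atlas(phantom.grid_shape)


@pytest.fixture(scope="session")
def truths(atlas):
    return default_territory_truths(atlas)


@pytest.fixture(scope="session")
def session(phantom, atlas, truths):
    """(series, sidecar) for the noise-free symmetric phantom."""
    return simulate_phantom_session(phantom, atlas, truths)


@pytest.fixture(scope="session")
def concentration(phantom, session):
    series, _ = session
    s0, mask = estimate_baseline(series)
    return signal_to_concentration(series, s0, mask, k=phantom.k)


@pytest.fixture(scope="session")
def aif(concentration):
    return select_aif_voxels(concentration)


@pytest.fixture(scope="session")
def maps(concentration, aif):
    return compute_maps(concentration, aif)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
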