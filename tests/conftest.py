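"""Shared fixtures: reduced-size scenes keep unit tests fast.

The invariance battery in the acceptance tests runs at the full default
scene size; unit tests exercise the same code paths on a smaller cell.
"""

import numpy as np
import pytest

from mitoquant import synthgen
from mitoquant.optics import PSFModel, gaussian_psf, theoretical_psf


@pytest.fixture(scope="session")
def small_spec() -> synthgen.SceneSpec:
    return synthgen.SceneSpec(
        cell_semi_axes=(2.4, 2.0, 1.2),
        n_mitochondria=6,
        mito_length_range=(0.5, 1.0),
        chromatin_radius=0.5,
        fov_shape=(22, 104, 128),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec) -> synthgen.Scene:
    return synthgen.generate_scene(small_spec, np.random.default_rng(7))


@pytest.fixture(scope="session")
def acq_psf(small_spec) -> np.ndarray:
    return gaussian_psf(voxel_size=small_spec.voxel_size, shape=(7, 13, 13))


@pytest.fixture(scope="session")
def deconv_psf(small_spec) -> np.ndarray:
    model = PSFModel(emission_wavelength=510.0, voxel_size=small_spec.voxel_size)
    return theoretical_psf(model, (9, 21, 21))
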