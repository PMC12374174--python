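"""Shared fixtures: small synthetic cases reused across test modules."""

import numpy as np
import pytest

from coroclust.phantom import PhantomSpec, LesionSpec, generate_phantom
from coroclust.pipeline import PipelineConfig, run_pipeline
from coroclust.volume_io import VesselMask


def small_spec(seed=1, lesions=()):
    """Desk-scale phantom on a reduced grid (fast unit-test version)."""
    return PhantomSpec(grid_shape=(64, 64, 96), seed=seed,
                       lesions=list(lesions))


@pytest.fixture(scope="session")
def healthy_case_small():
    return generate_phantom(small_spec(seed=1))


@pytest.fixture(scope="session")
def diseased_case_small():
    lesions = [
        LesionSpec("calcified", center_fraction=0.20, length_mm=6.0,
                   diameter_stenosis_fraction=0.45),
        LesionSpec("soft", center_fraction=0.60, length_mm=6.0,
                   diameter_stenosis_fraction=0.60),
    ]
    return generate_phantom(small_spec(seed=1, lesions=lesions))


@pytest.fixture(scope="session")
def diseased_result_small(diseased_case_small):
    case = diseased_case_small
    return run_pipeline(case.ct, case.mask, PipelineConfig(seed=1))


def cylinder_mask(radius_vox=3, length=40, pad=4, spacing=(1.0, 1.0, 1.0),
                  axis=2):
    """Axis-aligned solid cylinder; returns (mask, axis voxel coords)."""
    r = radius_vox
    side = 2 * r + 2 * pad + 1
    if axis == 2:
        shape = (side, side, length)
    else:
        raise NotImplementedError
    c = side // 2
    x, y = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    disc = (x - c) ** 2 + (y - c) ** 2 <= r ** 2
    data = np.zeros(shape, dtype=np.uint8)
    data[disc, :] = 1
    return VesselMask(data=data, spacing=spacing), c
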