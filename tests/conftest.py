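"""Shared fixtures: small phantoms and field sets reused across test modules."""

import numpy as np
import pytest

from sarmorph.coilfields import CoilModel, simulate_channel_fields
from sarmorph.core import TissueTable, VoxelModel, default_tissue_table
from sarmorph.phantoms import make_phantom, reference_spec, subject_spec, synthesize_t1


@pytest.fixture(scope="session")
def table() -> TissueTable:
    return default_tissue_table()


@pytest.fixture(scope="session")
def coil() -> CoilModel:
    return CoilModel()


@pytest.fixture(scope="session")
def ref_model_5mm(table) -> VoxelModel:
    return make_phantom(reference_spec(), table, voxel_size_mm=5.0)


@pytest.fixture(scope="session")
def ref_fields_5mm(coil, ref_model_5mm):
    return simulate_channel_fields(coil, ref_model_5mm)


@pytest.fixture(scope="session")
def ref_model_4mm(table) -> VoxelModel:
    return make_phantom(reference_spec(), table, voxel_size_mm=4.0)


@pytest.fixture(scope="session")
def ref_image_4mm(ref_model_4mm):
    return synthesize_t1(ref_model_4mm, noise_sd=5.0, seed=11)


@pytest.fixture(scope="session")
def subject_a_model_5mm(table) -> VoxelModel:
    return make_phantom(subject_spec("subject_a"), table, voxel_size_mm=5.0)


def uniform_block_model(table, shape=(14, 14, 14), voxel_mm=2.0, label=7) -> VoxelModel:
    """Homogeneous single-tissue block, world origin at the grid centre."""
    labels = np.full(shape, label, dtype=np.int16)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    return VoxelModel(labels, affine, table)


@pytest.fixture()
def block_model(table) -> VoxelModel:
    return uniform_block_model(table)
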