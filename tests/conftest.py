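"""Shared fixtures: fast coarse phantoms for study-level tests, and the
default-resolution study/recovery runs (session-scoped; these are the two
expensive computations in the suite)."""

from __future__ import annotations

import numpy as np
import pytest

from osteoct import PhantomSpec, ScannerModel, TumorEffect
from osteoct.study import StudyConfig, run_study


def small_spec(**overrides) -> PhantomSpec:
    """Coarse, fast femur phantom (30 um voxels, 120/660 um lattice)."""
    # rod_radius_factor scaled down so rods stay a ~2% volume fraction, as at
    # the default lattice scale
    kwargs = dict(trabecular_thickness=120.0, trabecular_spacing=660.0,
                  base_voxel=30.0, rod_radius_factor=0.25, seed=0)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def small_scanners() -> dict[str, ScannerModel]:
    return {
        "invivo91": ScannerModel(voxel_size=90.0, hu_gain=1.0, noise_sd=40.0, name="invivo91"),
        "exvivo31": ScannerModel(voxel_size=30.0, hu_gain=2.2, noise_sd=80.0, name="exvivo31"),
    }


def small_config(**overrides) -> StudyConfig:
    kwargs = dict(
        n_animals=4,
        spec=small_spec(),
        scanners=small_scanners(),
        grids={"invivo91": [200.0, 400.0, 600.0], "exvivo31": [1000.0, 1500.0, 2000.0]},
        master_seed=0,
    )
    kwargs.update(overrides)
    return StudyConfig(**kwargs)


def null_effect() -> TumorEffect:
    """A tumor transform that does nothing (both femora healthy)."""
    return TumorEffect(cortical_thickening_factor=1.0, trabecular_removal_fraction=0.0,
                       thickness_jitter_sd=0.0, marrow_density_shift=0.0,
                       mineralization_factor=1.0)


@pytest.fixture(scope="session")
def default_study():
    """The full 11-animal paired study at default conditions (the main run)."""
    return run_study(StudyConfig(), master_seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
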