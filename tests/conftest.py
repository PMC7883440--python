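"""Shared fixtures: small simulated scenes, acquisitions and calibrations."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from nanosip import (  # noqa: E402
    AcquisitionSpec,
    HotspotSpec,
    R_AIR_N,
    R_VPDB_C,
    SceneSpec,
    SessionCalibration,
    build_scene,
    session_cf,
    simulate_acquisition,
)

# Enriched atom fractions used in labelled fixture scenes.
F_CHOANO = (0.020, 0.025)
F_MICROBE = (0.012, 0.015)


def unbiased_calibrations() -> tuple[SessionCalibration, SessionCalibration]:
    """Calibrations for an unbiased instrument measured on the same standard.

    The standard's C2- count ratio is 2*R (the diatomic factor, absorbed into
    cf = 0.5); its CN- count ratio equals R exactly (cf = 1).
    """
    cal_c = session_cf(R_VPDB_C, [2 * R_VPDB_C], isotope="13C", session_id="s1")
    cal_n = session_cf(R_AIR_N, [R_AIR_N], isotope="15N", session_id="s1")
    return cal_c, cal_n


def small_scene_spec(seed: int = 7, enriched: bool = True, **overrides) -> SceneSpec:
    """A ~25 um field at coarse pixels, small enough for fast tests."""
    fractions = (
        {"choanocyte": F_CHOANO, "microbe": F_MICROBE} if enriched else {}
    )
    kwargs = dict(
        image_size_px=(128, 128),
        pixel_size_um=0.2,
        n_choanocyte_chambers=1,
        choanocytes_per_chamber=8,
        n_mesohyl_cells=3,
        microbe_density_per_um2=0.03,
        hotspot_spec=HotspotSpec(count_per_cell=1, multiplier=3.0),
        category_atom_fractions=fractions,
        seed=seed,
    )
    kwargs.update(overrides)
    return SceneSpec(**kwargs)


@pytest.fixture(scope="session")
def enriched_scene():
    return build_scene(small_scene_spec(seed=7, enriched=True))


@pytest.fixture(scope="session")
def control_scene():
    return build_scene(small_scene_spec(seed=7, enriched=False))


@pytest.fixture(scope="session")
def enriched_stack(enriched_scene):
    acq = AcquisitionSpec(
        n_planes=4,
        drift_per_plane_px=[(0, 0), (2, -1), (-1, 3), (1, 1)],
        seed=11,
    )
    return simulate_acquisition(enriched_scene, acq)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
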