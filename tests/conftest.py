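import numpy as np
import pytest

from ctqa.config import StudyConfig
from ctqa.nps import RoiSpec
from ctqa.phantom import AcquisitionPlan, Insert, NoiseSpectrum, PhantomGeometry, ReconPreset
from ctqa.study import default_study_config, run_study


@pytest.fixture(scope="session")
def study_report():
    """Full synthetic study (5 doses x 3 presets), shared across tests."""
    return run_study(default_study_config(seed=1))


@pytest.fixture(scope="session")
def study_config():
    return default_study_config(seed=1)


def tiny_config(seed: int = 0) -> StudyConfig:
    """A miniature study (small grid, few slices) for fast interface tests."""
    geometry = PhantomGeometry(
        body_diameter=100.0,
        inserts=(
            Insert("polyethylene", (-25.0, 0.0), 12.0, -95.0),
            Insert("air", (25.0, 0.0), 12.0, -1000.0),
        ),
    )
    presets = (
        ReconPreset("soft", psf_sigma=1.0, noise_scale=0.6, nps_shape=NoiseSpectrum(0.1)),
        ReconPreset("ref", psf_sigma=0.8, noise_scale=1.0, nps_shape=NoiseSpectrum(0.2)),
    )
    plan = AcquisitionPlan(
        ctdivol_levels=(9.5, 2.5, 0.4),
        reference_dose=9.5,
        reference_noise_sd=8.0,
        n_slices_per_acquisition=5,
        n_acquisitions=2,
        seed=seed,
        n_pixels=128,
        pixel_mm=1.0,
    )
    centers = tuple((64 + sy * 15, 64 + sx * 15) for sy, sx in
                    ((-1, -1), (-1, 1), (1, -1), (1, 1)))
    return StudyConfig(
        geometry=geometry,
        presets=presets,
        reference_preset="ref",
        plan=plan,
        roi=RoiSpec(centers=centers, size=24),
        ttf_slices_per_acquisition=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
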