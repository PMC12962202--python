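import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from famfat.acquisition_sim import EchoSeries, simulate_echoes
from famfat.phantom import make_pdff_t1_phantom, vial_rois
from famfat.sequence_design import AcquisitionParams, get_preset
from famfat.signal_model import FatSpectrum, TissueVoxel, cse_signal


@pytest.fixture(scope="session")
def spectrum():
    """Default six-peak fat spectrum, in vivo (no temperature shift)."""
    return FatSpectrum()


@pytest.fixture(scope="session")
def phantom_spectrum():
    """Six-peak spectrum with the phantom temperature correction."""
    return FatSpectrum().with_temperature_correction()


@pytest.fixture(scope="session")
def small_params():
    """3T protocol on a coarse 48x48 grid for fast simulations."""
    return get_preset("3T", matrix=(48, 48))


@pytest.fixture(scope="session")
def small_phantom(small_params):
    """16-vial phantom rendered on the coarse grid (larger vials)."""
    return make_pdff_t1_phantom(
        matrix=small_params.matrix, fov_cm=small_params.fov_cm,
        vial_radius_cm=3.8, spacing_cm=9.0,
    )


@pytest.fixture(scope="session")
def small_rois(small_phantom):
    return vial_rois(small_phantom, diameter_cm=3.0)


@pytest.fixture(scope="session")
def roi_mask(small_params, small_rois):
    mask = np.zeros(small_params.matrix, dtype=bool)
    for roi in small_rois:
        mask |= roi.mask
    return mask


def single_voxel_series(voxel: TissueVoxel, spectrum: FatSpectrum,
                        params: AcquisitionParams, noise=None) -> EchoSeries:
    """Echo series holding one voxel's noiseless (or perturbed) signal."""
    s = cse_signal(voxel, spectrum, params.tes_ms, params.b0_t)
    if noise is not None:
        s = s + noise
    return EchoSeries(images=s.reshape(-1, 1, 1), tes_ms=params.tes_ms, params=params)
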