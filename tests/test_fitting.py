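"""Magnitude, field-map, complex, and hybrid fitting."""

import numpy as np
import pytest

from conftest import single_voxel_series
from famfat.acquisition_sim import EchoSeries, simulate_echoes
from famfat.fitting import (
    complex_fit,
    estimate_field_map,
    field_map_cost,
    hybrid_fit,
    magnitude_fit,
)
from famfat.phantom import make_pdff_t1_phantom, vial_rois
from famfat.sequence_design import get_preset
from famfat.signal_model import FatSpectrum, TissueVoxel, cse_signal, spgr_steady_state


@pytest.fixture(scope="module")
def tiny_params():
    return get_preset("3T", matrix=(16, 16))


def series_from_voxels(voxels, spectrum, params):
    """Assemble an EchoSeries whose (0, i) voxels hold the given signals."""
    images = np.zeros((params.n_echoes, 1, len(voxels)), dtype=complex)
    for i, vox in enumerate(voxels):
        images[:, 0, i] = cse_signal(vox, spectrum, params.tes_ms, params.b0_t)
    return EchoSeries(images=images, tes_ms=params.tes_ms, params=params)


class TestMagnitudeFit:
    def test_noiseless_voxel_recovery(self, spectrum, tiny_params):
        vox = TissueVoxel(pdff=0.20, r2star_s=40.0, psi_hz=17.0)
        series = single_voxel_series(vox, spectrum, tiny_params)
        fit = magnitude_fit(series, spectrum)
        assert fit.pdff_raw_pct[0, 0] == pytest.approx(20.0, abs=0.1)
        assert fit.r2star_map[0, 0] == pytest.approx(40.0, abs=0.5)

    def test_water_only_voxel(self, spectrum, tiny_params):
        vox = TissueVoxel(pdff=0.0, r2star_s=30.0)
        series = single_voxel_series(vox, spectrum, tiny_params)
        fit = magnitude_fit(series, spectrum)
        assert fit.pdff_raw_pct[0, 0] == pytest.approx(0.0, abs=0.05)
        assert fit.residual_map[0, 0] < 1e-12

    def test_dominance_ambiguity_at_fifty_percent(self, tiny_params):
        # single-peak spectrum: swapping W and F leaves the magnitude model
        # invariant, so both initializations reach equal residuals
        spec = FatSpectrum(offsets_ppm=(-3.4,), amplitudes=(1.0,))
        vox = TissueVoxel(pdff=0.5, r2star_s=30.0)
        series = single_voxel_series(vox, spec, tiny_params)
        fit_w = magnitude_fit(series, spec, inits=("water",))
        fit_f = magnitude_fit(series, spec, inits=("fat",))
        assert fit_w.residual_map[0, 0] == pytest.approx(fit_f.residual_map[0, 0], abs=1e-9)
        assert fit_w.pdff_raw_pct[0, 0] + fit_f.pdff_raw_pct[0, 0] == pytest.approx(100.0, abs=0.5)

    def test_phase_invariance(self, spectrum, tiny_params):
        voxels = [TissueVoxel(pdff=p, r2star_s=45.0, psi_hz=20.0) for p in (0.05, 0.2, 0.35)]
        series = series_from_voxels(voxels, spectrum, tiny_params)
        rng = np.random.default_rng(5)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, series.images.shape[1:]))
        twisted = EchoSeries(images=series.images * phases, tes_ms=series.tes_ms,
                             params=tiny_params)
        a = magnitude_fit(series, spectrum)
        b = magnitude_fit(twisted, spectrum)
        assert np.allclose(a.pdff_raw_pct[0, :3], b.pdff_raw_pct[0, :3], atol=1e-6)

    def test_zero_voxel_flagged_invalid(self, spectrum, tiny_params):
        vox = TissueVoxel(pdff=0.2)
        series = series_from_voxels([vox], spectrum, tiny_params)
        series.images[:, 0, 0] = 0.0  # kill the only voxel... add a live one
        images = np.concatenate([series.images,
                                 series_from_voxels([vox], spectrum, tiny_params).images], axis=2)
        series2 = EchoSeries(images=images, tes_ms=series.tes_ms, params=tiny_params)
        fit = magnitude_fit(series2, spectrum)
        assert not fit.valid[0, 0]
        assert np.isnan(fit.pdff_raw_pct[0, 0])
        assert fit.valid[0, 1]

    def test_matched_steady_state_scaling_removes_t1_bias(self, phantom_spectrum):
        params = get_preset("3T", matrix=(48, 48))
        phantom = make_pdff_t1_phantom(matrix=params.matrix, fov_cm=params.fov_cm,
                                       vial_radius_cm=3.8, spacing_cm=9.0)
        rois = vial_rois(phantom, diameter_cm=3.0)
        mask = np.zeros(params.matrix, bool)
        for roi in rois:
            mask |= roi.mask
        alpha = 3.0
        series = simulate_echoes(phantom, params, alpha, phantom_spectrum)
        # per-vial scaling is exact because T1 is constant inside each ROI;
        # here all fat shares T1=300 and we fit each vial with its own g_w
        for roi in rois[:4]:  # one PDFF group is enough and fast
            g_w = spgr_steady_state(alpha, params.tr_ms, roi.t1w_nominal_ms)
            g_f = spgr_steady_state(alpha, params.tr_ms, 300.0)
            fit = magnitude_fit(series, phantom_spectrum, mask=roi.mask,
                                species_scaling=(g_w, g_f))
            got = np.nanmean(fit.pdff_raw_pct[roi.mask])
            assert got == pytest.approx(100 * roi.pdff_nominal, abs=0.1)


class TestFieldMap:
    def test_uniform_zero_field(self, spectrum, tiny_params):
        voxels = [TissueVoxel(pdff=0.2, r2star_s=40.0, psi_hz=0.0)] * 4
        series = series_from_voxels(voxels, spectrum, tiny_params)
        psi = estimate_field_map(series, spectrum, lambda_smooth=0.01)
        assert np.all(np.abs(psi[0, :4]) <= 2.0)  # within one grid step

    def test_uniform_offset_recovered(self, phantom_spectrum):
        params = get_preset("3T", matrix=(16, 16))
        voxels = [TissueVoxel(pdff=p, r2star_s=40.0, psi_hz=25.0) for p in (0.0, 0.1, 0.2, 0.3)]
        series = series_from_voxels(voxels, phantom_spectrum, params)
        psi = estimate_field_map(series, phantom_spectrum, lambda_smooth=0.01)
        assert np.all(np.abs(psi[0, :4] - 25.0) <= 2.0)

    def test_single_voxel_cost_minimum_at_truth(self, spectrum, tiny_params):
        vox = TissueVoxel(pdff=0.3, r2star_s=40.0, psi_hz=30.0)
        series = single_voxel_series(vox, spectrum, tiny_params)
        grid = np.arange(-200.0, 201.0, 1.0)
        cost, valid = field_map_cost(series, spectrum, grid)
        assert valid[0, 0]
        best = grid[np.argmin(cost[0, 0])]
        assert best == pytest.approx(30.0, abs=1.0)

    def test_smoothing_drives_total_variation_down(self, spectrum):
        params = get_preset("3T", matrix=(8, 8))
        rng = np.random.default_rng(11)
        images = np.zeros((params.n_echoes, 8, 8), dtype=complex)
        for i in range(8):
            for j in range(8):
                vox = TissueVoxel(pdff=0.15, r2star_s=40.0,
                                  psi_hz=float(rng.uniform(-60, 60)))
                images[:, i, j] = cse_signal(vox, spectrum, params.tes_ms, params.b0_t)
        noisy = images + 0.02 * (rng.standard_normal(images.shape)
                                 + 1j * rng.standard_normal(images.shape))
        series = EchoSeries(images=noisy, tes_ms=params.tes_ms, params=params)

        def tv(psi):
            return np.abs(np.diff(psi, axis=0)).sum() + np.abs(np.diff(psi, axis=1)).sum()

        tvs = [tv(estimate_field_map(series, spectrum, lambda_smooth=lam))
               for lam in (0.0, 0.01, 1.0, 1e4)]
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))
        assert tvs[-1] == pytest.approx(0.0, abs=1e-9)  # huge lambda -> constant map

    def test_coarse_grid_rejected(self, spectrum, tiny_params):
        vox = TissueVoxel(pdff=0.2)
        series = single_voxel_series(vox, spectrum, tiny_params)
        with pytest.raises(ValueError):
            estimate_field_map(series, spectrum, psi_step_hz=500.0)


class TestComplexFit:
    def test_exact_recovery_with_true_field(self, spectrum, tiny_params):
        voxels = [TissueVoxel(pdff=p, r2star_s=55.0, psi_hz=12.0) for p in (0.1, 0.3, 0.45)]
        series = series_from_voxels(voxels, spectrum, tiny_params)
        psi = np.full((1, len(voxels)), 12.0)
        fit = complex_fit(series, np.broadcast_to(psi, series.shape).copy(), spectrum)
        for i, vox in enumerate(voxels):
            assert fit.pdff_raw_pct[0, i] == pytest.approx(100 * vox.pdff, abs=1e-6)
            assert fit.r2star_map[0, i] == pytest.approx(55.0, abs=1e-3)
            assert fit.residual_map[0, i] < 1e-14

    def test_field_error_by_ambiguity_frequency_swaps_species(self, tiny_params):
        # off-resonance equal to the dominant fat-water shift aliases fat
        # into water: the classic swap failure
        spec = FatSpectrum(offsets_ppm=(-3.4,), amplitudes=(1.0,))
        f_fat = 42.5775 * 3.0 * (-3.4)
        vox = TissueVoxel(pdff=0.3, r2star_s=0.0, psi_hz=0.0)
        series = single_voxel_series(vox, spec, tiny_params)
        psi_wrong = np.full(series.shape, f_fat)
        fit = complex_fit(series, psi_wrong, spec)
        assert fit.pdff_raw_pct[0, 0] == pytest.approx(70.0, abs=1.0)

    def test_zero_voxel_invalid(self, spectrum, tiny_params):
        images = np.zeros((tiny_params.n_echoes, 1, 2), dtype=complex)
        images[:, 0, 1] = cse_signal(TissueVoxel(pdff=0.2), spectrum,
                                     tiny_params.tes_ms, tiny_params.b0_t)
        series = EchoSeries(images=images, tes_ms=tiny_params.tes_ms, params=tiny_params)
        fit = complex_fit(series, np.zeros((1, 2)), spectrum)
        assert not fit.valid[0, 0]
        assert fit.valid[0, 1]


@pytest.fixture(scope="module")
def voxel_series(spectrum, tiny_params):
    voxels = [TissueVoxel(pdff=p, r2star_s=50.0, psi_hz=8.0) for p in (0.05, 0.25, 0.40)]
    return series_from_voxels(voxels, spectrum, tiny_params)


class TestHybridFit:
    def test_weight_zero_equals_magnitude(self, voxel_series, spectrum):
        h = hybrid_fit(voxel_series, spectrum, weight_w=0.0)
        m = magnitude_fit(voxel_series, spectrum)
        assert np.allclose(h.pdff_raw_pct[0, :3], m.pdff_raw_pct[0, :3], atol=1e-9)

    def test_weight_one_equals_complex(self, voxel_series, spectrum):
        h = hybrid_fit(voxel_series, spectrum, weight_w=1.0)
        psi = estimate_field_map(voxel_series, spectrum, lambda_smooth=0.05)
        c = complex_fit(voxel_series, psi, spectrum)
        assert np.allclose(h.pdff_raw_pct[0, :3], c.pdff_raw_pct[0, :3], atol=1e-9)

    def test_half_weight_noiseless_recovery(self, voxel_series, spectrum):
        h = hybrid_fit(voxel_series, spectrum, weight_w=0.5)
        assert np.allclose(h.pdff_raw_pct[0, :3], [5.0, 25.0, 40.0], atol=0.1)

    def test_invalid_weight_rejected(self, voxel_series, spectrum):
        with pytest.raises(ValueError):
            hybrid_fit(voxel_series, spectrum, weight_w=1.5)
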