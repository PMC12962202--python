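"""Centric ordering, transient recursion, schedule solving, CRLB, timing."""

import numpy as np
import pytest

from famfat.sequence_design import (
    AcquisitionParams,
    FlipSchedule,
    KspaceWeighting,
    centric_order,
    crlb_pdff_variance,
    get_preset,
    kspace_weighting,
    psf_metrics,
    sequence_timing,
    solve_fam_schedule,
    spgr_steady_state,
    target_profile,
    transient_signal,
    weighting_discrepancy,
)
from famfat.signal_model import FatSpectrum, TissueVoxel


class TestCentricOrder:
    def test_single_line(self):
        assert centric_order(1).tolist() == [0]

    def test_six_lines_alternation(self):
        # DC line 3 first, then +1, -1, +2, -2, ... clipped at bounds
        assert centric_order(6).tolist() == [3, 4, 2, 5, 1, 0]

    @pytest.mark.parametrize("ny", [2, 7, 144])
    def test_bijective_and_outward(self, ny):
        order = centric_order(ny)
        assert sorted(order.tolist()) == list(range(ny))
        dist = np.abs(order - ny // 2)
        assert np.all(np.diff(dist) >= 0)

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            centric_order(0)


class TestTransientSignal:
    def test_first_excitation_t1_independent(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ny = 24
            alphas = rng.uniform(1.0, 60.0, ny)
            sched = FlipSchedule(alphas, centric_order(ny))
            first = [
                transient_signal(sched, 10.0, t1, m0=1.3)[0]
                for t1 in (100.0, 300.0, 700.0, 1100.0, 1500.0)
            ]
            expected = 1.3 * np.sin(np.deg2rad(alphas[0]))
            assert np.all(np.abs(np.asarray(first) - expected) < 1e-14)

    def test_two_ninety_degree_pulses(self):
        sched = FlipSchedule(np.array([90.0, 90.0]), np.array([0, 1]))
        s = transient_signal(sched, tr_ms=100.0, t1_ms=100.0, m0=2.0)
        assert s[0] == pytest.approx(2.0, abs=1e-14)
        assert s[1] == pytest.approx(2.0 * (1 - np.exp(-1)), abs=1e-12)

    def test_constant_flip_converges_to_steady_state(self):
        sched = FlipSchedule(np.full(5000, 7.0), np.arange(5000))
        s = transient_signal(sched, 12.6, 1000.0)
        assert s[-1] == pytest.approx(spgr_steady_state(7.0, 12.6, 1000.0), abs=1e-10)
        # convergence is monotone for a constant flip from equilibrium
        assert np.all(np.diff(s) <= 1e-15)


class TestKspaceWeighting:
    def test_dc_weight_is_sin_alpha1_for_all_t1(self, small_params):
        sched = solve_fam_schedule(small_params)
        dc = small_params.ny // 2
        expected = np.sin(np.deg2rad(sched.alphas_deg[0]))
        for t1 in (200.0, 300.0, 600.0, 1000.0, 1400.0):
            w = kspace_weighting(sched, small_params, t1)
            assert w.weights[dc] == pytest.approx(expected, abs=1e-14)

    def test_agrees_with_transient_signal_reordered(self, small_params):
        ny = small_params.ny
        alphas = np.linspace(4.0, 20.0, ny)  # ramped schedule
        sched = FlipSchedule(alphas, centric_order(ny))
        s = transient_signal(sched, small_params.tr_ms, 800.0)
        w = kspace_weighting(sched, small_params, 800.0)
        assert np.allclose(w.weights[sched.pe_order], s, atol=1e-14)


class TestPsfMetrics:
    def test_uniform_weights_unit_broadening(self):
        m = psf_metrics(KspaceWeighting(np.ones(64), 1000.0))
        assert m["fwhm_broadening"] == pytest.approx(1.0, abs=1e-6)
        # box-window sinc first sidelobe
        assert m["max_sidelobe"] == pytest.approx(0.217, abs=0.01)

    def test_hann_weights_match_dense_dft_oracle(self):
        n = 64
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / (n - 1))
        w = np.clip(w, 1e-6, None)

        # independent oracle: explicit zero-padded DFT summation, FWHM by
        # linear interpolation of the amplitude profile
        def oracle_fwhm(weights, pad=256):
            npad = weights.size * pad
            x = np.arange(npad)
            shifted = np.zeros(npad)
            start = (npad - weights.size) // 2
            shifted[start : start + weights.size] = weights
            psf = np.abs(
                np.array([np.sum(shifted * np.exp(2j * np.pi * x * k / npad)) for k in range(npad)])
            )
            psf = np.roll(psf, npad // 2)
            peak = psf.argmax()
            half = psf[peak] / 2
            above = np.nonzero(psf >= half)[0]
            lo, hi = above.min(), above.max()
            lo_f = lo - (psf[lo] - half) / (psf[lo] - psf[lo - 1])
            hi_f = hi + (psf[hi] - half) / (psf[hi] - psf[hi + 1])
            return hi_f - lo_f

        expected = oracle_fwhm(w) / oracle_fwhm(np.ones(n))
        m = psf_metrics(KspaceWeighting(w, 1000.0), pad_factor=256)
        assert m["fwhm_broadening"] == pytest.approx(expected, rel=0.02)
        assert m["fwhm_broadening"] > 1.5  # Hann clearly broadens the PSF

    def test_delta_weighting_rejected(self):
        w = np.full(16, 1e-30)
        with pytest.raises(ValueError):
            psf_metrics(KspaceWeighting(np.where(np.arange(16) == 8, 1.0, 1e-300), 1000.0))


class TestSolveFamSchedule:
    def test_constant_target_recovers_fixed_point(self):
        # a target equal to the steady-state signal of alpha* is tracked by
        # a schedule converging to alpha* (geometric rate ~ E1, so a long
        # schedule is needed to see the limit)
        alpha_star = 5.0
        t1 = 1000.0
        params = get_preset("3T", matrix=(8, 1024))
        target = np.full(params.ny, spgr_steady_state(alpha_star, params.tr_ms, t1))
        sched = solve_fam_schedule(params, {"t1_short": 300.0, "t1_long": t1}, target)
        err = np.abs(sched.alphas_deg - alpha_star)
        assert err[-1] < 1e-2
        assert np.all(np.diff(err) <= 1e-12)  # monotone approach to alpha*

    def test_flat_target_requires_increasing_flips(self):
        params = get_preset("1.5T", matrix=(16, 16))
        s0 = np.sin(np.deg2rad(10.0))
        target = np.full(16, s0)
        sched = solve_fam_schedule(params, {"t1_short": 300.0, "t1_long": 1000.0}, target)
        assert np.all(np.diff(sched.alphas_deg[:10]) > 0)

    @pytest.mark.parametrize("preset", ["0.55T", "1.5T", "3T"])
    def test_round_trip_reproduces_target(self, preset):
        params = get_preset(preset)
        sched = solve_fam_schedule(params)
        target = target_profile(params.ny, 12.0, params.tr_ms, 1000.0, 4.0, 0.10)
        realized = transient_signal(sched, params.tr_ms, 1000.0)
        uncapped = sched.alphas_deg < 90.0 - 1e-9
        assert np.all(np.abs(realized[uncapped] - target[uncapped]) < 1e-8)
        assert np.all(uncapped)  # default designs never hit the cap

    def test_default_design_is_nearly_t1_insensitive(self, small_params):
        sched = solve_fam_schedule(small_params)
        disc = weighting_discrepancy(sched, small_params, 300.0, 1400.0)
        assert disc < 0.15  # normalized outer-k-space discrepancy stays small

    def test_infeasible_target_rejected(self, small_params):
        target = np.full(small_params.ny, 0.9)
        with pytest.raises(ValueError):
            solve_fam_schedule(small_params, target=target, flip_cap_deg=60.0)


class TestCrlb:
    def test_quadratic_noise_scaling(self, spectrum):
        params = get_preset("3T")
        voxel = TissueVoxel(pdff=0.2, r2star_s=50.0)
        v1 = crlb_pdff_variance(params, voxel, spectrum, 0.01)
        v2 = crlb_pdff_variance(params, voxel, spectrum, 0.02)
        assert v2 == pytest.approx(4.0 * v1, rel=1e-12)

    def test_in_phase_echoes_singular(self):
        # all echoes at full-cycle multiples of a single fat peak: no
        # fat-water contrast, the information matrix degenerates
        spec = FatSpectrum(offsets_ppm=(-3.4,), amplitudes=(1.0,))
        period_ms = 1000.0 / abs(42.5775 * 3.0 * 3.4)
        params = AcquisitionParams(b0_t=3.0, tr_ms=50.0, te1_ms=period_ms,
                                   dte_ms=period_ms, n_echoes=6)
        with pytest.raises(ValueError):
            crlb_pdff_variance(params, TissueVoxel(pdff=0.2), spec, 0.01)


class TestSequenceTiming:
    @pytest.mark.parametrize(
        "preset,per_slice,total",
        [("0.55T", 1.7, 54.4), ("1.5T", 1.8, 57.6), ("3T", 1.3, 41.6)],
    )
    def test_protocol_footprints(self, preset, per_slice, total):
        t = sequence_timing(get_preset(preset))
        assert t["per_slice_s"] == pytest.approx(per_slice, abs=1e-12)
        assert t["total_s"] == pytest.approx(total, abs=1e-9)


class TestScheduleCsv:
    def test_round_trip(self, tmp_path, small_params):
        sched = solve_fam_schedule(small_params)
        path = tmp_path / "schedule.csv"
        sched.to_csv(path)
        back = FlipSchedule.from_csv(path)
        assert np.allclose(back.alphas_deg, sched.alphas_deg)
        assert np.array_equal(back.pe_order, sched.pe_order)
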