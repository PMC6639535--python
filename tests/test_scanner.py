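"""Virtual scanner: phantom, acquisition, ghosts, navigator, stability, SNR."""

import math

import numpy as np
import pytest

from ffcmri.dispersion import GAMMA_HZ_PER_T
from ffcmri.fieldcycle import MagnetSpec
from ffcmri.pipeline import noise_sigma_for_snr, phantom_protocol
from ffcmri.scanner import (
    RICIAN_FACTOR,
    FluctuationModel,
    KSpaceSeries,
    _correct_single,
    acquire,
    correct_ghosts,
    drift_correction_loop,
    field_stability_ppm,
    make_bottle_phantom,
    navigator_field_estimate,
    reconstruct,
    rician_snr,
    synthetic_fid,
)

DAC_STEP = MagnetSpec().dac_step


@pytest.fixture(scope="module")
def small_protocol():
    return phantom_protocol(matrix=32, n_evolution_times=2, evolution_fields=(0.02, 0.065, 0.2))


@pytest.fixture(scope="module")
def small_phantom():
    return make_bottle_phantom(grid_size=32, seed=1)


class TestBottlePhantom:
    def test_seven_labels_on_empty_background(self):
        ph = make_bottle_phantom(grid_size=128, seed=0)
        labels = set(np.unique(ph.labels))
        assert labels == set(range(8))
        assert ph.density_image()[ph.labels == 0].max() == 0.0
        assert ph.empty_mask.mean() >= 0.25

    def test_disc_diameter_matches_35mm_bottles(self):
        # 35 mm bottle in a 40 cm FOV at 128 px is ~11 px across
        ph = make_bottle_phantom(grid_size=128, seed=0)
        ys, xs = np.nonzero(ph.labels == 1)
        assert (ys.max() - ys.min() + 1) == pytest.approx(11, abs=1)

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError):
            make_bottle_phantom(grid_size=12, seed=0)


class TestAcquireReconstruct:
    def test_noiseless_round_trip(self, small_phantom, small_protocol):
        fluct = FluctuationModel()
        ks = acquire(small_phantom, small_protocol, fluct, seed=0)
        cplx, mag = reconstruct(ks)
        # re-acquire ideal image directly from the DFT inverse
        from ffcmri.scanner import _ideal_image

        ideal = _ideal_image(small_phantom, small_protocol, 0, small_protocol.evolution_times[0][0])
        assert np.max(np.abs(cplx[0, 0] - ideal)) < 1e-9

    def test_parseval_and_delta(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((16, 16))
        k = np.fft.fft2(img)
        assert np.sum(np.abs(img) ** 2) == pytest.approx(np.sum(np.abs(k) ** 2) / img.size)
        delta = np.zeros((16, 16), dtype=complex)
        delta[0, 0] = 1.0
        rec = np.fft.ifft2(delta)
        assert np.allclose(rec, rec.flat[0])  # constant image

    def test_line_phase_errors_put_energy_in_empty_region(self, small_phantom, small_protocol):
        clean = acquire(small_phantom, small_protocol, FluctuationModel(), seed=3)
        dirty = acquire(small_phantom, small_protocol, FluctuationModel(phase_sd=0.1), seed=3)
        _, mag_c = reconstruct(clean)
        _, mag_d = reconstruct(dirty)
        empty = small_phantom.empty_mask
        assert np.sum(mag_d[0, 0][empty] ** 2) > np.sum(mag_c[0, 0][empty] ** 2)

    def test_missing_lines_rejected(self):
        data = np.full((1, 1, 8, 8), np.nan, dtype=complex)
        ks = KSpaceSeries(data=data, evolution_fields=(0.02, 0.1, 0.2), evolution_times=((0.1,),) * 3)
        with pytest.raises(ValueError):
            reconstruct(ks)


def _textured_instance(n=32, phase_sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros((n, n))
    img[6 : n - 6, 6 : n - 6] = 1.0 + 0.3 * rng.random((n - 12, n - 12))
    mask = np.ones((n, n), bool)
    mask[4 : n - 4, 4 : n - 4] = False
    k = np.fft.fft2(img)
    phi = phase_sd * rng.standard_normal(n)
    return k * np.exp(1j * phi)[:, None], mask, phi, k


class TestGhostCorrection:
    def test_recovers_injected_phases(self):
        kbad, mask, phi, _ = _textured_instance()
        _, est = _correct_single(kbad, mask, 1e-10, 50)
        err = np.abs(np.angle(np.exp(1j * (est + (phi - phi[0])))))
        assert err.max() < 1e-3  # up to a global phase

    def test_matches_per_line_grid_search_oracle(self):
        kbad, mask, _, _ = _textured_instance(seed=5)
        corrected, est = _correct_single(kbad, mask, 1e-10, 50)

        def masked_energy(k):
            return float(np.sum(np.abs(np.fft.ifft2(k))[mask] ** 2))

        # with all other lines fixed at the solution, each line's phase must
        # sit at the grid-search minimum of the masked energy
        thetas = np.linspace(-np.pi, np.pi, 2001)
        for line in (0, 7, 16, 25):
            energies = []
            for th in thetas:
                trial = corrected.copy()
                trial[line] = trial[line] * np.exp(1j * th)
                energies.append(masked_energy(trial))
            th_best = thetas[int(np.argmin(energies))]
            assert abs(np.angle(np.exp(1j * th_best))) < 1e-3 + (thetas[1] - thetas[0])

    def test_zero_injected_phase_gives_identity(self):
        _, mask, _, k = _textured_instance(phase_sd=0.0)
        corrected, est = _correct_single(k, mask, 1e-10, 50)
        assert np.max(np.abs(est)) < 1e-9
        assert np.allclose(corrected, k)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_empty_region_energy_never_increases(self, seed):
        kbad, mask, _, _ = _textured_instance(seed=seed)
        ks = KSpaceSeries(
            data=kbad[None, None], evolution_fields=(0.02, 0.1, 0.2), evolution_times=((0.1,),) * 3
        )
        out, _ = correct_ghosts(ks, mask)
        e_before = np.sum(np.abs(np.fft.ifft2(kbad))[mask] ** 2)
        e_after = np.sum(np.abs(np.fft.ifft2(out.data[0, 0]))[mask] ** 2)
        assert e_after <= e_before + 1e-12

    def test_small_mask_warns_and_returns_identity(self):
        kbad, _, _, _ = _textured_instance()
        tiny = np.zeros((32, 32), bool)
        tiny[0, :5] = True
        ks = KSpaceSeries(
            data=kbad[None, None], evolution_fields=(0.02, 0.1, 0.2), evolution_times=((0.1,),) * 3
        )
        with pytest.warns(UserWarning):
            out, phases = correct_ghosts(ks, tiny)
        assert np.allclose(out.data, kbad)
        assert np.all(phases == 0)


class TestNavigator:
    def _fid(self, offset_hz, n=256, dwell=5e-5, snr=None, seed=0):
        t = np.arange(n) * dwell
        fid = np.exp(2j * np.pi * offset_hz * t) * np.exp(-t / 0.05)
        if snr:
            rng = np.random.default_rng(seed)
            fid = fid + (1.0 / snr) * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        return fid

    def test_500hz_offset_recovered(self):
        est = navigator_field_estimate(self._fid(500.0), 5e-5, 0.2)
        bin_hz = 1.0 / (256 * 8 * 5e-5)
        assert est * GAMMA_HZ_PER_T == pytest.approx(500.0, abs=bin_hz)

    def test_zero_offset(self):
        est = navigator_field_estimate(self._fid(0.0), 5e-5, 0.2)
        bin_hz = 1.0 / (256 * 8 * 5e-5)
        assert abs(est * GAMMA_HZ_PER_T) <= bin_hz

    def test_dac_step_offset_detected_near_130hz(self):
        est = navigator_field_estimate(self._fid(GAMMA_HZ_PER_T * DAC_STEP), 5e-5, 0.2)
        assert est == pytest.approx(DAC_STEP, rel=0.05)
        assert GAMMA_HZ_PER_T * DAC_STEP == pytest.approx(130.0, abs=1.0)

    def test_unbiased_at_snr_50(self):
        bin_hz = 1.0 / (256 * 8 * 5e-5)
        errs = [
            navigator_field_estimate(self._fid(237.0, snr=50, seed=s), 5e-5, 0.2) * GAMMA_HZ_PER_T
            - 237.0
            for s in range(100)
        ]
        assert abs(np.mean(errs)) < bin_hz / 10

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        fid = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        with pytest.raises(ValueError):
            navigator_field_estimate(fid, 5e-5, 0.2)


class TestDriftLoop:
    @pytest.mark.parametrize("seed", range(10))
    def test_slow_drift_residual_within_dac_step(self, seed):
        # 500 ppm over 45 min at 0.2 T is ~0.037 uT/s: far below one DAC
        # step per TR, so the loop must hold the residual within one step
        fluct = FluctuationModel(drift_ppm_per_min=500.0 / 45.0, drift_total_ppm=500.0)
        res = drift_correction_loop(fluct, n_repetitions=60, tr=2.0, seed=seed, noise_sigma=0.01)
        steady = np.abs(res[5:])
        assert steady.max() <= DAC_STEP * (1 + 1e-6)

    def test_zero_drift_gives_zero_corrections(self):
        fluct = FluctuationModel()
        res = drift_correction_loop(fluct, n_repetitions=20, tr=2.0)
        assert np.allclose(res, 0.0)

    def test_uncorrected_drift_reaches_500ppm(self):
        fluct = FluctuationModel(drift_ppm_per_min=500.0 / 45.0, drift_total_ppm=500.0)
        t_end = 45 * 60.0
        assert fluct.drift_field(t_end, 0.2) == pytest.approx(500e-6 * 0.2, rel=1e-9)
        assert fluct.drift_field(2 * t_end, 0.2) == fluct.drift_field(t_end, 0.2)  # monotone, saturated


class TestStabilityMetric:
    def test_pure_tone_is_stable(self):
        t = (np.arange(1024) + 1) * 2e-5
        fid = np.exp(2j * np.pi * 150.0 * t) * np.exp(-t / 0.05)
        assert field_stability_ppm(fid, 2e-5, 0.2) < 1e-6

    def test_monotone_in_mains_amplitude(self):
        dwell = 2e-5
        t = (np.arange(1024) + 1) * dwell
        metrics = []
        for amp_T in (0.15e-6, 0.3e-6, 0.6e-6):
            eps = (amp_T / 0.2) * np.sin(2 * np.pi * 300.0 * t)
            fid = synthetic_fid(eps, dwell)
            metrics.append(field_stability_ppm(fid, dwell, 0.2))
        assert metrics[0] < metrics[1] < metrics[2]

    def test_white_noise_calibration_at_1_5_ppm(self):
        rng = np.random.default_rng(42)
        eps = (1.5 / 3.0) * 1e-6 * rng.standard_normal(2048)
        fid = synthetic_fid(eps, 2e-5)
        metric = field_stability_ppm(fid, 2e-5, 0.2)
        assert metric == pytest.approx(1.5, rel=0.3)

    def test_too_short_fid_raises(self):
        with pytest.raises(ValueError):
            field_stability_ppm(np.ones(8, complex), 2e-5, 0.2)


class TestRicianSNR:
    def test_factor_value(self):
        assert RICIAN_FACTOR == pytest.approx(0.655, abs=5e-4)
        assert RICIAN_FACTOR == math.sqrt(2 - math.pi / 2)

    def test_monte_carlo_recovers_true_snr(self):
        rng = np.random.default_rng(0)
        n = 300_000
        a, sigma = 50.0, 1.0
        noise = sigma * (rng.standard_normal(2 * n) + 1j * rng.standard_normal(2 * n))
        mag = np.abs(np.concatenate([np.full(n, a + 0j), np.zeros(n)]) + noise)
        smask = np.zeros(2 * n, bool)
        smask[:n] = True
        snr = rician_snr(mag, smask, ~smask)
        assert snr == pytest.approx(a / sigma, rel=0.01)

    def test_zero_signal_region(self):
        mag = np.zeros((8, 8))
        mag[4:, :] = np.arange(32).reshape(4, 8)  # background with variance
        smask = np.zeros((8, 8), bool)
        smask[:4] = True
        assert rician_snr(mag, smask, ~smask) == 0.0

    def test_mask_validation(self):
        mag = np.random.default_rng(0).random((8, 8))
        full = np.ones((8, 8), bool)
        with pytest.raises(ValueError):
            rician_snr(mag, full, full)  # overlap
        with pytest.raises(ValueError):
            rician_snr(mag, np.zeros((8, 8), bool), full)  # empty signal mask
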