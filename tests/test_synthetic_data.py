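"""The two synthetic-data routes and their cross-validation."""

import numpy as np
import pytest
from scipy import signal

from seizdcm.model_space import ModelSpec
from seizdcm.spectral_forward import FrequencyGrid, predicted_spectrum, \
    endogenous_input_spectrum
from seizdcm.spectral_features import build_spectral_data
from seizdcm.synthetic_data import (SyntheticScenario, patient1_like,
                                    patient2_like, stationary_scenario,
                                    one_over_f_noise, simulate_spectra,
                                    simulate_timeseries, _integrate_cmc,
                                    _per_sample_parameters)

GRID = FrequencyGrid()


class TestOneOverFNoise:
    def _slope(self, x, fs):
        f, pxx = signal.periodogram(x, fs)
        band = (f >= 1.0) & (f <= 40.0)
        return np.polyfit(np.log(f[band]), np.log(pxx[band]), 1)[0]

    def test_zero_exponent_gives_flat_spectrum(self):
        x = one_over_f_noise(2**18, 256.0, 0.0, seed=0)
        assert abs(self._slope(x, 256.0)) < 0.1

    def test_unit_exponent_gives_unit_log_log_slope(self):
        x = one_over_f_noise(2**18, 256.0, 1.0, seed=1)
        assert self._slope(x, 256.0) == pytest.approx(-1.0, abs=0.1)

    def test_unit_variance_and_seed_determinism(self):
        x1 = one_over_f_noise(4096, 256.0, 1.0, seed=2)
        x2 = one_over_f_noise(4096, 256.0, 1.0, seed=2)
        assert np.array_equal(x1, x2)
        assert x1.std() == pytest.approx(1.0)
        assert not np.array_equal(x1, one_over_f_noise(4096, 256.0, 1.0, seed=3))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            one_over_f_noise(4096, 256.0, -0.5, seed=0)
        with pytest.raises(ValueError):
            one_over_f_noise(100, 256.0, 1.0, seed=0)


class TestScenario:
    def test_durations_outside_10_to_60_seconds_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(duration_s=5.0)
        with pytest.raises(ValueError):
            SyntheticScenario(duration_s=90.0)
        with pytest.raises(ValueError):
            SyntheticScenario(snr=0.0)

    def test_presets_mirror_the_two_patients(self):
        p1 = patient1_like()
        p2 = patient2_like()
        assert p1.n_windows == 10 and p1.n_seizures == 55
        assert p2.n_windows == 30 and p2.n_seizures == 2
        assert p1.input_chirp[0] > p1.input_chirp[1]  # falling frequency

    def test_ground_truth_beta_reproduces_lambda(self):
        from seizdcm.temporal_basis import dct_basis, TIME_VARYING
        truth = patient1_like(seed=0).ground_truth()
        basis = dct_basis(10, 8)
        for row, name in enumerate(TIME_VARYING):
            assert np.allclose(truth["lambda"][name],
                               basis @ truth["beta"][row], atol=1e-12)


class TestSimulateSpectra:
    def test_infinite_snr_equals_noiseless_prediction(self):
        scenario = patient1_like(seed=0, snr=np.inf)
        data, truth = simulate_spectra(scenario)
        ref = np.array([predicted_spectrum(p, GRID)
                        for p in truth["window_parameters"]])
        assert np.array_equal(data.S, ref)

    def test_seed_determinism(self):
        d1, _ = simulate_spectra(patient1_like(seed=5))
        d2, _ = simulate_spectra(patient1_like(seed=5))
        assert np.array_equal(d1.S, d2.S)

    def test_residual_rms_scales_as_inverse_sqrt_seizures(self):
        ref, _ = simulate_spectra(patient1_like(seed=9, snr=np.inf))
        rms = {}
        for n in (4, 16, 64):
            data, _ = simulate_spectra(patient1_like(seed=9, n_seizures=n))
            rms[n] = np.sqrt(np.mean((data.S / ref.S - 1.0) ** 2))
        assert rms[4] / rms[16] == pytest.approx(2.0, rel=0.25)
        assert rms[16] / rms[64] == pytest.approx(2.0, rel=0.25)

    def test_chirp_scenario_peak_frequency_nonincreasing(self):
        truth = patient1_like(seed=0).ground_truth()
        band = GRID.f >= 4.0
        peaks = []
        for p in truth["window_parameters"]:
            gu = endogenous_input_spectrum(p, GRID)
            base = endogenous_input_spectrum(p.copy(d_spec=np.zeros(8)), GRID)
            peaks.append(GRID.f[band][np.argmax((gu / base)[band])])
        assert np.all(np.diff(peaks) <= 0)


class TestSimulateTimeseries:
    def test_no_input_no_noise_gives_silence(self):
        from seizdcm.cmc_model import CMCParameters
        silent_base = CMCParameters(b1=0.0)
        scenario = stationary_scenario(seed=0, duration_s=10.0, n_seizures=1,
                                       base=silent_base, input_scale=0.0)
        seizures, _ = simulate_timeseries(scenario)
        assert np.allclose(seizures[0], 0.0)

    def test_seed_determinism(self):
        kw = dict(duration_s=10.0, n_seizures=1)
        s1, _ = simulate_timeseries(stationary_scenario(seed=4, **kw))
        s2, _ = simulate_timeseries(stationary_scenario(seed=4, **kw))
        assert np.array_equal(s1[0], s2[0])

    def test_stationary_output_spectrum_matches_forward_model(self):
        """Welch spectrum of 200 s of simulated output vs the predicted
        density at the same parameters (within 15% RMS, 1-40 Hz)."""
        scenario = stationary_scenario(seed=3, duration_s=50.0, n_seizures=4)
        seizures, truth = simulate_timeseries(scenario)
        ref = predicted_spectrum(truth["window_parameters"][0], GRID)
        est = np.zeros(len(GRID))
        for y in seizures:
            f, pxx = signal.welch(y, scenario.fs, nperseg=512, noverlap=256)
            est += np.interp(GRID.f, f, pxx) / len(seizures)
        rms = np.sqrt(np.mean(((est - ref) / ref) ** 2))
        assert rms < 0.15

    def test_halving_integration_step_changes_spectrum_below_2_percent(self):
        """Deterministic impulse response at dt and dt/2."""
        p = patient1_like().base
        spectra = {}
        for fs_int in (2048.0, 4096.0):
            n = int(4 * fs_int)
            u = np.zeros(n)
            u[0] = fs_int  # unit-area impulse
            ps = _per_sample_parameters([p], n, 0)
            states = _integrate_cmc(ps, u, 1.0 / fs_int)
            y = states[:, 1] + p.c_dp * states[:, 3]
            freqs = np.fft.rfftfreq(n, 1.0 / fs_int)
            mag = np.abs(np.fft.rfft(y) / fs_int) ** 2
            spectra[fs_int] = np.interp(GRID.f, freqs, mag)
        rel = spectra[2048.0] / spectra[4096.0] - 1.0
        assert np.sqrt(np.mean(rel**2)) < 0.02

    def test_blow_up_reported_with_location(self):
        ps = _per_sample_parameters([patient1_like().base], 2048, 0)
        huge = np.full(2048, 1e9)
        with pytest.raises(FloatingPointError, match="sample"):
            _integrate_cmc(ps, huge, 1.0 / 2048.0)


class TestRouteCrossValidation:
    def test_time_domain_and_spectral_routes_agree(self):
        """The slow ODE route, passed through the feature pipeline,
        matches the fast spectral route within 20% RMS per window at
        the preset's own scale."""
        scenario = patient1_like(seed=5)
        seizures, _ = simulate_timeseries(scenario)
        data_td = build_spectral_data(seizures, scenario.fs)
        data_fast, _ = simulate_spectra(patient1_like(seed=5))
        assert data_td.n_windows == data_fast.n_windows
        for w in range(data_td.n_windows):
            rel = (data_td.S[w] - data_fast.S[w]) / data_fast.S[w]
            assert np.sqrt(np.mean(rel**2)) < 0.20, f"window {w}"
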