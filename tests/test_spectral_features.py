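"""EEG preprocessing, window-length selection, AR spectra, averaging."""

import numpy as np
import pytest
from scipy import signal

from seizdcm.spectral_forward import FrequencyGrid
from seizdcm.spectral_features import (SpectralData, preprocess,
                                       select_window_length, ar_spectrum,
                                       build_spectral_data, read_timeseries,
                                       read_annotations, extract_seizures,
                                       select_channel)

FS = 256.0
GRID = FrequencyGrid()


def _sine(freq, duration=8.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_line_noise_attenuated_at_least_30_db(self):
        x = _sine(50.0, duration=24.0)
        y = preprocess(x, FS)
        core = slice(int(4 * FS), -int(4 * FS))  # outside the notch ring-down
        atten = 20 * np.log10(np.std(y[core]) / np.std(x[core]))
        assert atten <= -30.0

    def test_10_hz_passband_nearly_unchanged(self):
        x = _sine(10.0)
        y = preprocess(x, FS)
        core = slice(int(FS), -int(FS))
        assert abs(np.std(y[core]) / np.std(x[core]) - 1.0) < 0.05

    def test_band_edges_sit_at_minus_3_db(self):
        sos = signal.butter(5, [0.5, 70.0], btype="bandpass", fs=FS, output="sos")
        w, h = signal.sosfreqz(sos, worN=[0.5, 70.0], fs=FS)
        assert np.allclose(20 * np.log10(np.abs(h)), -3.01, atol=0.05)

    def test_common_average_removes_shared_component(self):
        rng = np.random.default_rng(0)
        shared = _sine(7.0)
        x = rng.standard_normal((shared.size, 4)) * 0.01 + shared[:, None]
        y = preprocess(x, FS)
        assert np.std(y) < 0.1 * np.std(shared)

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros(1000), 128.0)


class TestSelectWindowLength:
    def test_stationary_noise_keeps_longest_window(self):
        rng = np.random.default_rng(2)
        x = signal.lfilter([1.0], [1.0, -0.6], rng.standard_normal(int(16 * FS)))
        assert select_window_length(x, FS) == 4.0

    def test_fast_chirp_forces_shorter_window(self):
        t = np.arange(int(16 * FS)) / FS
        freq = 20.0 - 15.0 * ((t % 4.0) / 4.0)  # 20 -> 5 Hz sweep every 4 s
        phase = 2 * np.pi * np.cumsum(freq) / FS
        rng = np.random.default_rng(3)
        x = np.sin(phase) + 0.05 * rng.standard_normal(t.size)
        assert select_window_length(x, FS) < 4.0

    def test_default_candidates_include_2_seconds(self):
        import inspect
        defaults = inspect.signature(select_window_length).parameters["candidates"].default
        assert 2.0 in defaults


class TestArSpectrum:
    def test_white_noise_spectrum_flat_within_20_percent(self):
        # averaged over independent 2 s segments so estimation noise
        # does not mask the flatness property
        rng = np.random.default_rng(4)
        S = np.mean([ar_spectrum(rng.standard_normal(int(2 * FS)), FS,
                                 order=8, grid=GRID) for _ in range(8)], axis=0)
        assert np.all(np.abs(S / S.mean() - 1.0) < 0.20)

    def test_ar2_resonance_recovered_within_1_hz(self):
        f0, r = 10.0, 0.95
        a = [1.0, -2 * r * np.cos(2 * np.pi * f0 / FS), r**2]
        rng = np.random.default_rng(5)
        x = signal.lfilter([1.0], a, rng.standard_normal(int(8 * FS)))[-int(2 * FS):]
        S = ar_spectrum(x, FS, order=8, grid=GRID)
        assert abs(GRID.f[np.argmax(S)] - f0) <= 1.0

    def test_density_integrates_to_segment_variance(self):
        rng = np.random.default_rng(6)
        x = signal.lfilter([1.0], [1.0, -0.5], rng.standard_normal(int(2 * FS)))
        dense = FrequencyGrid(np.linspace(0.25, FS / 2, 512))
        S = ar_spectrum(x, FS, order=8, grid=dense)
        integral = np.trapezoid(S, dense.f)
        assert abs(integral / x.var() - 1.0) < 0.10

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            ar_spectrum(np.zeros(20), FS, order=8)


class TestBuildSpectralData:
    def _noise(self, duration, seed):
        rng = np.random.default_rng(seed)
        return signal.lfilter([1.0], [1.0, -0.5], rng.standard_normal(int(duration * FS)))

    def test_window_counts_for_20_and_60_second_seizures(self):
        d20 = build_spectral_data([self._noise(20.0, 0)], FS)
        d60 = build_spectral_data([self._noise(60.0, 1)], FS)
        assert d20.n_windows == 10
        assert d60.n_windows == 30

    def test_trailing_partial_window_discarded(self):
        d = build_spectral_data([self._noise(9.3, 2)], FS)
        assert d.n_windows == 4

    def test_identical_seizures_average_to_themselves(self):
        x = self._noise(12.0, 3)
        d1 = build_spectral_data([x], FS)
        d2 = build_spectral_data([x, x.copy()], FS)
        assert np.allclose(d1.S, d2.S)

    def test_unequal_lengths_averaged_over_available_seizures(self):
        d = build_spectral_data([self._noise(8.0, 4), self._noise(4.0, 5)], FS)
        assert d.n_windows == 4
        assert list(d.counts) == [2, 2, 1, 1]

    def test_deterministic_given_identical_inputs(self):
        x = self._noise(10.0, 6)
        d1 = build_spectral_data([x], FS)
        d2 = build_spectral_data([x.copy()], FS)
        assert np.array_equal(d1.S, d2.S)

    def test_averaging_variance_scales_inversely_with_n(self):
        """Var of the n-seizure average falls like 1/n (within 25%)."""
        rng = np.random.default_rng(7)
        spectra = np.array([
            ar_spectrum(rng.standard_normal(int(2 * FS)), FS, order=8, grid=GRID)
            for _ in range(256)
        ])
        log_s = np.log(spectra)
        var1 = log_s.var(axis=0, ddof=1).mean()
        var4 = log_s.reshape(64, 4, -1).mean(axis=1).var(axis=0, ddof=1).mean()
        assert var1 / var4 == pytest.approx(4.0, rel=0.25)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_spectral_data([], FS)


class TestIO:
    def test_spectral_data_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        d = SpectralData(S=rng.random((5, 40)) + 0.1, grid=GRID,
                         n_seizures_averaged=3)
        d.to_csv(tmp_path / "spec.csv")
        d2 = SpectralData.from_csv(tmp_path / "spec.csv")
        assert np.allclose(d.S, d2.S)
        assert d2.n_seizures_averaged == 3

    def test_text_recording_with_fs_header(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("# fs=256\nch1,ch2\n" +
                        "\n".join("0.1,0.2" for _ in range(10)) + "\n")
        x, fs, names = read_timeseries(path)
        assert fs == 256.0 and x.shape == (10, 2) and names == ["ch1", "ch2"]

    def test_annotations_and_seizure_extraction(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("onset_s,offset_s,label\n1.0,3.0,sz1\n5.0,6.0,sz2\n")
        ann = read_annotations(path)
        x = np.arange(int(10 * FS), dtype=float)
        seizures = extract_seizures(x, FS, ann)
        assert len(seizures) == 2
        assert seizures[0].size == int(2 * FS)

    def test_channel_selection_picks_band_power_maximum(self):
        rng = np.random.default_rng(9)
        quiet = 0.01 * rng.standard_normal(int(4 * FS))
        loud = _sine(12.0, 4.0) + 0.01 * rng.standard_normal(int(4 * FS))
        x = np.column_stack([quiet, loud, quiet])
        assert select_channel(x, FS) == 1
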