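"""Seizure-like synthetic recordings with known ground truth.

Two routes generate data from the same generative model:

* :func:`simulate_spectra` — the fast route — evaluates the spectral
  forward model at ground-truth per-window parameters and applies
  multiplicative estimation noise (gamma-distributed, mean one), with
  dispersion shrinking with the signal-to-noise ratio and the number
  of seizures averaged, mimicking the sampling noise of averaged
  spectral estimates.
* :func:`simulate_timeseries` — the slow route — integrates the delay
  differential equations (fixed 1/2048 s step) driven by 1/f-type
  coloured noise whose spectrum follows the ground-truth input
  spectrum per window, and adds power-law measurement noise.  The two
  routes cross-validate each other.

Ground-truth parameter drift mimics the canonical seizure pattern: a
transient rise in inhibitory connectivity, a later rise in excitatory
connectivity, a ramping input gain, and an input spectral bump whose
centre frequency falls over the seizure (the spectral "chirp", e.g.
20 Hz down to 10 Hz).  Scenario presets mirror two archetypal
patients: short clustered seizures with a 20->10 Hz chirp averaged
over many events, and long seizures with a 12->5 Hz chirp averaged
over two events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .cmc_model import CMCParameters, jacobian, input_vector
from .model_space import ModelSpec
from .spectral_forward import (FrequencyGrid, frequency_basis, observation_gain,
                               predicted_spectrum, noise_spectrum)
from . import temporal_basis as tb
from .spectral_features import SpectralData

__all__ = [
    "SyntheticScenario",
    "patient1_like",
    "patient2_like",
    "stationary_scenario",
    "one_over_f_noise",
    "simulate_spectra",
    "simulate_timeseries",
    "simulate_linearized",
]

# Internal integration rate: high enough that the 1 ms conduction delay
# spans >= 2 steps, so every RK4 stage can interpolate the delayed state
# from stored history.
_FS_INT = 2048.0


def _delayed(hist: np.ndarray, tau: float) -> np.ndarray:
    """Linear interpolation of the state history at fractional index tau."""
    if tau <= 0:
        return hist[0]
    lo = int(tau)
    w = tau - lo
    return (1.0 - w) * hist[lo] + w * hist[lo + 1] if w else hist[lo]


@dataclass
class SyntheticScenario:
    """Everything that determines one synthetic dataset.

    Bumps are ``(centre_window, width_windows, log_amplitude)``; the
    input chirp is ``(f_start_hz, f_end_hz, log_amplitude, width_hz)``
    describing a Gaussian bump on the log input spectrum whose centre
    moves linearly over windows.  ``snr`` governs the dispersion of
    spectral-estimation noise (the fast route's multiplicative noise
    has relative spread ``1/(snr*sqrt(n_seizures))``); the
    measurement-noise floor itself is part of the generative model via
    ``base.b1`` and sits about 10:1 below the neuronal band power at
    the prior mean.
    """

    model: ModelSpec = field(default_factory=ModelSpec.full)
    base: CMCParameters = field(default_factory=CMCParameters.prior_means)
    duration_s: float = 20.0
    n_seizures: int = 55
    fs: float = 256.0
    snr: float = 10.0
    seed: int = 0
    window_s: float = 2.0
    inhibitory_bump: tuple | None = (2.5, 1.8, 0.5)
    excitatory_bump: tuple | None = (5.5, 1.5, 0.5)
    input_gain_ramp: float = 0.8
    input_tilt_ramp: float = 0.25
    input_chirp: tuple | None = (20.0, 10.0, 0.3, 6.0)
    input_scale: float = 1.0
    label: str = "custom"

    def __post_init__(self) -> None:
        if not (10.0 <= self.duration_s <= 60.0):
            raise ValueError("seizure duration must lie in 10-60 s")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_seizures < 1:
            raise ValueError("need at least one seizure")

    @property
    def n_windows(self) -> int:
        return int(self.duration_s // self.window_s)

    # -- ground truth ------------------------------------------------------

    def band_snr(self, grid: FrequencyGrid | None = None) -> float:
        """Band-power ratio of the neuronal signal to the noise floor.

        Determined by ``base.b1`` (the floor is part of the generative
        model); at the prior mean ``b1 = 1`` the ratio is about 10:1.
        """
        grid = grid or FrequencyGrid()
        neuronal = predicted_spectrum(self.base, grid) - noise_spectrum(self.base, grid)
        floor = noise_spectrum(self.base, grid)
        return float(np.trapezoid(neuronal, grid.f) / np.trapezoid(floor, grid.f))

    def ground_truth(self, grid: FrequencyGrid | None = None) -> dict:
        """Per-window log-scalings, their cosine projection, and parameters."""
        grid = grid or FrequencyGrid()
        W = self.n_windows
        t = np.arange(W, dtype=float)
        lam_raw = {name: np.zeros(W) for name in tb.TIME_VARYING}

        def bump(spec_):
            c, w, a = spec_
            return a * np.exp(-((t - c) ** 2) / (2 * w**2))

        if self.model.inhibitory_varying and self.inhibitory_bump:
            for name in tb.INHIBITORY:
                lam_raw[name] = bump(self.inhibitory_bump)
        if self.model.excitatory_varying and self.excitatory_bump:
            for name in tb.EXCITATORY:
                lam_raw[name] = bump(self.excitatory_bump)
        if self.model.endogenous_varying:
            if self.input_gain_ramp:
                lam_raw["a1"] = self.input_gain_ramp * t / max(W - 1, 1)
            if self.input_tilt_ramp:
                lam_raw["a2"] = self.input_tilt_ramp * t / max(W - 1, 1)
            if self.input_chirp:
                f0, f1, amp, width = self.input_chirp
                centres = np.linspace(f0, f1, W)
                psi = frequency_basis(grid, 8)
                for w_i in range(W):
                    target = amp * np.exp(-((grid.f - centres[w_i]) ** 2)
                                          / (2 * width**2))
                    coeff = psi.T @ target  # least squares on orthonormal basis
                    for k in range(8):
                        lam_raw[f"d{k + 1}"][w_i] = coeff[k]

        beta = np.zeros((len(tb.TIME_VARYING), tb.N_COMPONENTS))
        lam = {}
        for row, name in enumerate(tb.TIME_VARYING):
            beta[row] = tb.project(lam_raw[name], tb.N_COMPONENTS)
            basis = tb.dct_basis(W, tb.N_COMPONENTS)
            lam[name] = basis @ beta[row, : basis.shape[1]]

        traj = tb.ParameterTrajectory(beta, W, self.model)
        params = tb.expand(traj, self.base, self.model)
        return {"lambda_raw": lam_raw, "lambda": lam, "beta": beta,
                "trajectory": traj, "window_parameters": params,
                "n_windows": W}


def patient1_like(seed: int = 0, **overrides) -> SyntheticScenario:
    """Short clustered seizures: 20 s, 20->10 Hz chirp, 55 events."""
    kw = dict(duration_s=20.0, n_seizures=55, snr=10.0,
              inhibitory_bump=(2.5, 1.8, 0.5), excitatory_bump=(5.5, 1.5, 0.5),
              input_gain_ramp=0.8, input_tilt_ramp=0.25,
              input_chirp=(20.0, 10.0, 0.3, 6.0),
              label="patient1-like", seed=seed)
    kw.update(overrides)
    return SyntheticScenario(**kw)


def patient2_like(seed: int = 0, **overrides) -> SyntheticScenario:
    """Long seizures: 60 s, 12->5 Hz chirp, 2 events."""
    kw = dict(duration_s=60.0, n_seizures=2, snr=10.0,
              inhibitory_bump=(8.0, 5.0, 0.5), excitatory_bump=(17.0, 4.5, 0.5),
              input_gain_ramp=0.8, input_tilt_ramp=0.25,
              input_chirp=(12.0, 5.0, 0.3, 4.0),
              label="patient2-like", seed=seed)
    kw.update(overrides)
    return SyntheticScenario(**kw)


def stationary_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """No parameter drift: the pre/post-ictal control condition."""
    kw = dict(model=ModelSpec.null(), duration_s=20.0, n_seizures=55, snr=10.0,
              inhibitory_bump=None, excitatory_bump=None,
              input_gain_ramp=0.0, input_tilt_ramp=0.0, input_chirp=None,
              label="stationary", seed=seed)
    kw.update(overrides)
    return SyntheticScenario(**kw)


# ---------------------------------------------------------------------------
# Noise synthesis


def one_over_f_noise(n: int, fs: float, exponent: float, seed: int) -> np.ndarray:
    """Unit-variance noise with spectral density proportional to f**-exponent.

    Spectral-domain synthesis: Gaussian Fourier coefficients with
    amplitude ``f**(-exponent/2)`` (flat below the lowest resolvable
    octave to avoid the divergence at 0), inverse transformed and
    normalised to unit variance.
    """
    if exponent < 0:
        raise ValueError("power-law exponent must be non-negative")
    if n < 256:
        raise ValueError("need at least 256 samples")
    rng = np.random.default_rng(seed)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    f_floor = max(f[1], 1.0 / min(n / fs, 10.0))
    with np.errstate(divide="ignore"):
        amp[1:] = np.maximum(f[1:], f_floor) ** (-exponent / 2.0)
    coeff = amp * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
    x = np.fft.irfft(coeff, n)
    x -= x.mean()
    return x / x.std()


def _noise_from_psd(psd: np.ndarray, f: np.ndarray, n: int, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise whose one-sided PSD matches ``psd`` at frequencies ``f``."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    target = np.interp(freqs, f, psd, left=psd[0], right=0.0)
    # one-sided PSD -> rFFT coefficient variance
    amp = np.sqrt(target * fs * n / 2.0)
    coeff = amp * (rng.standard_normal(freqs.size)
                   + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real * np.sqrt(2.0)
    return np.fft.irfft(coeff, n)


def _continuous_input_psd(p: CMCParameters, f: np.ndarray,
                          grid: FrequencyGrid) -> np.ndarray:
    """Input PSD evaluated off-grid (shaping interpolated, edges clamped)."""
    psi = frequency_basis(grid, 8)
    shaping_grid = psi @ p.d_spec
    shaping = np.interp(f, grid.f, shaping_grid,
                        left=shaping_grid[0], right=shaping_grid[-1])
    f_eff = np.maximum(f, grid.f[0])
    return p.a1 * f_eff ** (-p.a2) * np.exp(shaping)


# ---------------------------------------------------------------------------
# Time-domain integration


def _integrate_cmc(params_per_sample: dict, u: np.ndarray, dt: float) -> np.ndarray:
    """RK4 integration of the delayed CMC equations.

    ``params_per_sample['g']`` is (N, 10); T, gamma are constants.  The
    delayed state at each RK4 stage time is linearly interpolated from
    the stored history.  Returns states (N, 8).
    """
    g_t = params_per_sample["g"]
    T = params_per_sample["T"]
    gamma = params_per_sample["gamma"]
    d_samples = params_per_sample["d_ms"] * 1e-3 / dt
    n = u.size
    hist = np.zeros((n, 8))
    x = np.zeros(8)
    T2 = T**2
    twoT = 2.0 * T

    for i in range(1, n):
        g = g_t[i - 1]
        ui = u[i - 1]
        # delayed firing rate per RK4 stage (stage times t + c*dt)
        sd_stage = []
        for c in (0.0, 0.5, 1.0):
            xd = _delayed(hist, i - 1 + c - d_samples)
            sd_stage.append(np.tanh(0.5 * gamma * xd[:4]) * 0.5)

        def f(xx, sd):
            v, cur = xx[:4], xx[4:]
            s = np.tanh(0.5 * gamma * v) * 0.5
            drive = np.array([
                -g[0] * s[0] - g[1] * sd[1] - g[2] * sd[2] + ui,
                g[7] * sd[0] - g[6] * s[1],
                g[4] * sd[0] + g[5] * sd[3] - g[3] * s[2],
                -g[8] * sd[2] - g[9] * s[3],
            ])
            return np.concatenate([cur, T * drive - twoT * cur - T2 * v])

        k1 = f(x, sd_stage[0])
        k2 = f(x + 0.5 * dt * k1, sd_stage[1])
        k3 = f(x + 0.5 * dt * k2, sd_stage[1])
        k4 = f(x + dt * k3, sd_stage[2])
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if np.abs(x[:4]).max() > 1e6:
            raise FloatingPointError(
                f"numerical blow-up at sample {i} (t={i * dt:.3f} s)")
        hist[i] = x
    return hist


def _per_sample_parameters(params: list[CMCParameters], n_per_window: int,
                           ramp_samples: int) -> dict:
    """Piecewise-constant per-window values with linear boundary ramps."""
    W = len(params)
    n = W * n_per_window
    g = np.empty((n, 10))
    for w, p in enumerate(params):
        g[w * n_per_window:(w + 1) * n_per_window] = p.g
    for w in range(1, W):
        j0 = w * n_per_window
        r = min(ramp_samples, n_per_window)
        frac = np.linspace(0.0, 1.0, r)[:, None]
        g[j0:j0 + r] = (1 - frac) * params[w - 1].g + frac * params[w].g
    p0 = params[0]
    return {"g": g, "T": p0.T, "gamma": p0.gamma, "d_ms": p0.d}


def simulate_timeseries(scenario: SyntheticScenario,
                        grid: FrequencyGrid | None = None):
    """Integrate the nonlinear delay model per seizure.

    Returns ``(seizures, truth)`` where ``seizures`` is a list of
    source time series at ``scenario.fs`` and ``truth`` the
    ground-truth dictionary (with the effective parameters used).
    Observation: superficial plus ``c_dp`` x deep depolarisation in the
    model's spectral units, plus power-law measurement noise.
    """
    grid = grid or FrequencyGrid()
    truth = scenario.ground_truth(grid)
    params = truth["window_parameters"]
    W = scenario.n_windows
    dt = 1.0 / _FS_INT
    n_per_window = int(round(scenario.window_s * _FS_INT))
    n = W * n_per_window
    ramp = int(0.1 * _FS_INT)  # 100 ms parameter ramps
    ps = _per_sample_parameters(params, n_per_window, ramp)
    gain = np.sqrt(observation_gain())

    frac = Fraction(scenario.fs / _FS_INT).limit_denominator(1000)
    rng_master = np.random.default_rng(scenario.seed)
    seizures = []
    f_syn = np.linspace(grid.f[0] / 4, _FS_INT / 2, 2048)
    for _s in range(scenario.n_seizures):
        rng = np.random.default_rng(rng_master.integers(2**31))
        # per-window coloured input, 100 ms crossfade at boundaries
        u = np.zeros(n)
        prev_tail = None
        for w, p in enumerate(params):
            psd = _continuous_input_psd(p, f_syn, grid) * scenario.input_scale**2
            seg = _noise_from_psd(psd, f_syn, n_per_window + ramp, _FS_INT, rng)
            j0 = w * n_per_window
            u[j0:j0 + n_per_window] = seg[:n_per_window]
            if prev_tail is not None:
                fade = np.linspace(0.0, 1.0, ramp)
                u[j0:j0 + ramp] = (1 - fade) * prev_tail + fade * u[j0:j0 + ramp]
            prev_tail = seg[n_per_window:]
        if scenario.input_scale == 0.0:
            u[:] = 0.0
        states = _integrate_cmc(ps, u, dt)
        y = gain * (states[:, 1] + params[0].c_dp * states[:, 3])
        p0 = params[0]
        if p0.b1 > 0:
            noise_psd = p0.b1 * np.maximum(f_syn, grid.f[0]) ** (-p0.b2)
            y = y + _noise_from_psd(noise_psd, f_syn, n, _FS_INT, rng)
        y_out = signal.resample_poly(y, frac.numerator, frac.denominator)
        seizures.append(y_out)
    return seizures, truth


def simulate_linearized(p: CMCParameters, duration_s: float, seed: int = 0,
                        fs_out: float | None = None) -> tuple[np.ndarray, float]:
    """Linearised delay system driven by unit-PSD white noise.

    Returns ``(y, fs)`` where the one-sided PSD of ``y`` should match
    ``|H_obs(f)|**2`` from :func:`~seizdcm.spectral_forward.transfer_function`.
    """
    dt = 1.0 / _FS_INT
    n = int(duration_s * _FS_INT)
    J0, Jd = jacobian(p)
    B = input_vector(p)
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n) * np.sqrt(_FS_INT / 2.0)  # one-sided PSD 1
    d_samples = p.d * 1e-3 / dt
    hist = np.zeros((n, 8))
    x = np.zeros(8)
    for i in range(1, n):
        c0 = Jd @ _delayed(hist, i - 1 - d_samples) + B * u[i - 1]
        ch = Jd @ _delayed(hist, i - 0.5 - d_samples) + B * u[i - 1]
        c1 = Jd @ _delayed(hist, i - d_samples) + B * u[i - 1]

        k1 = J0 @ x + c0
        k2 = J0 @ (x + 0.5 * dt * k1) + ch
        k3 = J0 @ (x + 0.5 * dt * k2) + ch
        k4 = J0 @ (x + dt * k3) + c1
        x = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        hist[i] = x
    y = hist[:, 1] + p.c_dp * hist[:, 3]
    if fs_out and fs_out != _FS_INT:
        frac = Fraction(fs_out / _FS_INT).limit_denominator(1000)
        y = signal.resample_poly(y, frac.numerator, frac.denominator)
        return y, fs_out
    return y, _FS_INT


# ---------------------------------------------------------------------------
# Fast spectral route


def simulate_spectra(scenario: SyntheticScenario,
                     grid: FrequencyGrid | None = None):
    """Noiseless predicted spectra times multiplicative estimation noise.

    The per-frequency noise is gamma-distributed with mean one and
    shape ``snr**2 * n_seizures``, so the relative dispersion scales as
    ``1/(snr * sqrt(n_seizures))`` — the behaviour of averaged spectral
    estimates.  Returns ``(SpectralData, truth)``.
    """
    grid = grid or FrequencyGrid()
    truth = scenario.ground_truth(grid)
    S = np.array([predicted_spectrum(p, grid) for p in truth["window_parameters"]])
    if not np.isinf(scenario.snr):
        rng = np.random.default_rng(scenario.seed)
        shape = scenario.snr**2 * scenario.n_seizures
        S = S * rng.gamma(shape, 1.0 / shape, size=S.shape)
    data = SpectralData(S=S, grid=grid, window_s=scenario.window_s,
                        n_seizures_averaged=scenario.n_seizures, onset_index=0)
    return data, truth
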