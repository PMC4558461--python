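"""Frequency-domain forward model: parameters -> predicted spectral density.

The CMC is linearised at its resting equilibrium and the observed
spectrum follows from its transfer function.  With ``J0``/``Jd`` the
instantaneous and delayed Jacobians, ``B`` the input vector and ``C``
an observation row, the transfer function at angular frequency
``w = 2*pi*f`` is

    H(w) = C (i*w*I - J0 - Jd*exp(-i*w*d))^(-1) B,

with the conduction delay entering exactly through the phase factor.
The endogenous (afferent) input is coloured noise with one-sided
spectral density

    g_u(f) = a1 * f**(-a2) * exp(sum_k d_k psi_k(f)),

a power law shaped by eight discrete-cosine "spectral innovation"
functions ``psi_k`` over the frequency grid.  The observed density adds
power-law measurement noise:

    S_y(f) = |H_obs(f)|**2 * g_u(f) + b1 * f**(-b2).

All densities are one-sided (integrate to variance over 0..Nyquist).
A fixed observation gain — computed once at prior-mean parameters so
the band-averaged neuronal density equals one — sets the (arbitrary)
amplitude units of the source signal; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .cmc_model import CMCParameters, jacobian, input_vector, observation_vector

__all__ = [
    "FrequencyGrid",
    "frequency_basis",
    "transfer_function",
    "endogenous_input_spectrum",
    "noise_spectrum",
    "predicted_spectrum",
    "population_spectra",
    "observation_gain",
    "max_real_eigenvalue",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing, strictly positive frequencies in Hz."""

    f: np.ndarray = field(default_factory=lambda: np.arange(1.0, 41.0))

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "f", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be positive (power laws diverge at 0)")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.f.size


def frequency_basis(grid: FrequencyGrid, n_components: int = 8) -> np.ndarray:
    """Orthonormal type-II DCT functions over the grid points, (F, K)."""
    n = len(grid)
    k = np.arange(n_components)
    j = np.arange(n)
    basis = np.cos(np.pi * np.outer(2 * j + 1, k) / (2 * n))
    basis *= np.where(k == 0, np.sqrt(1.0 / n), np.sqrt(2.0 / n))
    return basis


def _batch_jacobians(T, g, gamma):
    """Vectorised (J0, Jd) at the origin for parameter arrays.

    ``T``: (..., 4), ``g``: (..., 10), ``gamma``: (...,).  Returns
    arrays of shape (..., 8, 8).
    """
    T = np.asarray(T, float)
    g = np.asarray(g, float)
    gamma = np.asarray(gamma, float)
    shape = np.broadcast_shapes(T.shape[:-1], g.shape[:-1], gamma.shape)
    T = np.broadcast_to(T, shape + (4,))
    g = np.broadcast_to(g, shape + (10,))
    slope = np.broadcast_to(gamma, shape)[..., None] / 4.0  # sigmoid slope at rest

    J0 = np.zeros(shape + (8, 8))
    Jd = np.zeros(shape + (8, 8))
    J0[..., :4, 4:] = np.eye(4)
    for k in range(4):
        J0[..., 4 + k, k] = -T[..., k] ** 2
        J0[..., 4 + k, 4 + k] = -2.0 * T[..., k]
    sl = slope[..., 0]
    # (g index, source, target, sign, delayed)
    wiring = [
        (0, 0, 0, -1.0, False), (1, 1, 0, -1.0, True), (2, 2, 0, -1.0, True),
        (3, 2, 2, -1.0, False), (4, 0, 2, +1.0, True), (5, 3, 2, +1.0, True),
        (6, 1, 1, -1.0, False), (7, 0, 1, +1.0, True), (8, 2, 3, -1.0, True),
        (9, 3, 3, -1.0, False),
    ]
    for gi, src, tgt, sign, delayed in wiring:
        target = Jd if delayed else J0
        target[..., 4 + tgt, src] += sign * T[..., tgt] * g[..., gi] * sl
    return J0, Jd


def batch_transfer(T, g, gamma, d_ms, c_dp, grid: FrequencyGrid):
    """Transfer functions for batched parameters.

    Returns ``(H_obs, H_pop)`` with shapes (..., F) and (..., 4, F):
    complex gains from the afferent input to the observed mixture and
    to each population's depolarisation.
    """
    J0, Jd = _batch_jacobians(T, g, gamma)
    shape = J0.shape[:-2]
    f = grid.f
    w = 2.0 * np.pi * f
    d_s = np.broadcast_to(np.asarray(d_ms, float), shape)[..., None] * 1e-3
    phase = np.exp(-1j * w * d_s)  # (..., F)

    A = (1j * w)[..., :, None, None] * np.eye(8) \
        - J0[..., None, :, :] \
        - Jd[..., None, :, :] * phase[..., None, None]
    B = np.zeros(shape + (8,))
    B[..., 4] = np.broadcast_to(np.asarray(T, float), shape + (4,))[..., 0]
    rhs = np.broadcast_to(B[..., None, :, None], A.shape[:-1] + (1,))
    try:
        x = np.linalg.solve(A, rhs)[..., 0]  # (..., F, 8)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular resolvent on frequency grid {f.min():g}-{f.max():g} Hz"
        ) from err
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))
        raise FloatingPointError(f"non-finite resolvent at frequency {f[bad[0][-2]]} Hz")
    H_pop = np.moveaxis(x[..., :4], -1, -2)  # (..., 4, F)
    c = np.broadcast_to(np.asarray(c_dp, float), shape)[..., None]
    H_obs = H_pop[..., 1, :] + c * H_pop[..., 3, :]
    return H_obs, H_pop


def transfer_function(p: CMCParameters, grid: FrequencyGrid | None = None):
    """Complex transfer gains of one parameter set, ``(H_obs, H_pop)``."""
    grid = grid or FrequencyGrid()
    return batch_transfer(p.T, p.g, p.gamma, p.d, p.c_dp, grid)


def batch_input_spectrum(a1, a2, d_spec, grid: FrequencyGrid):
    """Endogenous input density for batched (a1, a2, d_spec)."""
    f = grid.f
    a1 = np.asarray(a1, float)[..., None]
    a2 = np.asarray(a2, float)[..., None]
    d_spec = np.asarray(d_spec, float)
    psi = frequency_basis(grid, d_spec.shape[-1])
    shaping = np.einsum("...k,fk->...f", d_spec, psi)
    return a1 * f ** (-a2) * np.exp(shaping)


def endogenous_input_spectrum(p: CMCParameters, grid: FrequencyGrid | None = None) -> np.ndarray:
    """One-sided spectral density of the afferent input on the grid."""
    grid = grid or FrequencyGrid()
    if p.a1 <= 0:
        raise ValueError("input amplitude a1 must be positive")
    return batch_input_spectrum(p.a1, p.a2, p.d_spec, grid)


def noise_spectrum(p: CMCParameters, grid: FrequencyGrid | None = None) -> np.ndarray:
    """Power-law measurement-noise density ``b1 * f**(-b2)``."""
    grid = grid or FrequencyGrid()
    return p.b1 * grid.f ** (-p.b2)


@lru_cache(maxsize=1)
def observation_gain() -> float:
    """Fixed gain making the band-mean neuronal density 1 at prior means.

    The source amplitude after source reconstruction is arbitrary, so
    the model adopts units in which the prior-mean neuronal spectrum
    averages to one over the default 1-40 Hz band.  The constant
    depends only on the prior expectations and is applied consistently
    in the forward model and the time-domain simulator.
    """
    p = CMCParameters.prior_means()
    grid = FrequencyGrid()
    H_obs, _ = transfer_function(p, grid)
    gu = endogenous_input_spectrum(p, grid)
    return float(1.0 / np.mean(np.abs(H_obs) ** 2 * gu))


def batch_predicted_spectra(T, g, gamma, d_ms, c_dp, a1, a2, b1, b2, d_spec,
                            grid: FrequencyGrid):
    """Observed spectral density for batched parameter arrays, (..., F)."""
    H_obs, _ = batch_transfer(T, g, gamma, d_ms, c_dp, grid)
    gu = batch_input_spectrum(a1, a2, d_spec, grid)
    neuronal = observation_gain() * np.abs(H_obs) ** 2 * gu
    noise = np.asarray(b1, float)[..., None] * grid.f ** (-np.asarray(b2, float)[..., None])
    return neuronal + noise


def predicted_spectrum(p: CMCParameters, grid: FrequencyGrid | None = None) -> np.ndarray:
    """Predicted observed spectral density ``S_y(f)`` on the grid."""
    grid = grid or FrequencyGrid()
    return batch_predicted_spectra(
        p.T, p.g, p.gamma, p.d, p.c_dp, p.a1, p.a2, p.b1, p.b2, p.d_spec, grid
    )


def population_spectra(p: CMCParameters, grid: FrequencyGrid | None = None) -> np.ndarray:
    """Per-population spectral density (4, F), without measurement noise."""
    grid = grid or FrequencyGrid()
    _, H_pop = transfer_function(p, grid)
    gu = endogenous_input_spectrum(p, grid)
    return observation_gain() * np.abs(H_pop) ** 2 * gu[None, :]


def max_real_eigenvalue(p: CMCParameters) -> float:
    """Largest real part over eigenvalues of ``J0 + Jd``.

    The delay is short (~1 ms) relative to the synaptic kernels, so the
    zero-delay characteristic matrix is used as the stability check for
    the spectral steady state.
    """
    J0, Jd = jacobian(p)
    return float(np.linalg.eigvals(J0 + Jd).real.max())
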