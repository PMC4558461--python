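"""Discrete cosine expansion of slowly varying parameters over windows.

Seizure-window parameter drift is modelled on the log scale: a
parameter with prior mean ``mu`` takes the per-window value
``theta(t) = mu * exp(lambda(t))`` where ``lambda(t)`` is a linear
combination of up to 8 orthonormal discrete cosine functions of the
window index.  The spectral-innovation coefficients ``d1..d8`` are the
one exception: they are additive deviations around zero rather than
log-scalings, since they already live in the exponent of the input
spectrum and must be signable.

Which parameters may vary is set by a :class:`~seizdcm.model_space.ModelSpec`
through three groups:

* inhibitory connections: g3, g4, g9 (all originate from the
  inhibitory interneurons)
* excitatory connections: g5, g6, g8
* endogenous input/noise: a1, a2, b1, b2, d1..d8

Parameters outside the allowed groups carry only the constant cosine
component, i.e. a single window-independent deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cmc_model import CMCParameters
from .model_space import ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TIME_VARYING",
    "INHIBITORY",
    "EXCITATORY",
    "ENDOGENOUS",
    "N_COMPONENTS",
    "ParameterTrajectory",
    "dct_basis",
    "expand",
    "expand_log_scalings",
    "project",
]

INHIBITORY = ("g3", "g4", "g9")
EXCITATORY = ("g5", "g6", "g8")
ENDOGENOUS = ("a1", "a2", "b1", "b2", "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8")
TIME_VARYING = INHIBITORY + EXCITATORY + ENDOGENOUS
N_COMPONENTS = 8

# Index of each connection name in CMCParameters.g
_G_INDEX = {f"g{i}": i - 1 for i in range(1, 11)}

_truncation_warned: set[tuple[int, int]] = set()


def dct_basis(n_windows: int, n_components: int = N_COMPONENTS) -> np.ndarray:
    """Orthonormal type-II DCT basis over window indices, (n_windows, K).

    The first column is constant (``1/sqrt(n)``); columns k = 0..K-1
    have k sign changes.  If fewer windows than components are
    requested the basis is truncated with a warning.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    if n_components > n_windows:
        if (n_windows, n_components) not in _truncation_warned:
            _truncation_warned.add((n_windows, n_components))
            logger.warning(
                "truncating cosine basis from %d to %d components (only %d windows)",
                n_components, n_windows, n_windows,
            )
        n_components = n_windows
    t = np.arange(n_windows)
    k = np.arange(n_components)
    basis = np.cos(np.pi * np.outer(2 * t + 1, k) / (2 * n_windows))
    basis *= np.where(k == 0, np.sqrt(1.0 / n_windows), np.sqrt(2.0 / n_windows))
    return basis


def varying_names(spec: ModelSpec) -> tuple[str, ...]:
    """Parameters allowed a full temporal expansion under ``spec``."""
    names: tuple[str, ...] = ()
    if spec.inhibitory_varying:
        names += INHIBITORY
    if spec.excitatory_varying:
        names += EXCITATORY
    if spec.endogenous_varying:
        names += ENDOGENOUS
    return names


@dataclass
class ParameterTrajectory:
    """Cosine coefficients for every potentially time-varying parameter.

    ``beta`` has one row per name in :data:`TIME_VARYING` and
    :data:`N_COMPONENTS` columns; rows of parameters outside the model's
    varying set must be zero beyond the constant component.
    """

    beta: np.ndarray
    n_windows: int
    spec: ModelSpec

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(TIME_VARYING), N_COMPONENTS):
            raise ValueError(
                f"beta must be {(len(TIME_VARYING), N_COMPONENTS)}, got {self.beta.shape}"
            )
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("trajectory coefficients must be finite")
        varying = set(varying_names(self.spec))
        for row, name in enumerate(TIME_VARYING):
            if name not in varying and np.any(self.beta[row, 1:] != 0.0):
                raise ValueError(
                    f"parameter {name} is constant under model '{self.spec.label}' "
                    "but has non-constant cosine coefficients"
                )

    @classmethod
    def zeros(cls, n_windows: int, spec: ModelSpec) -> "ParameterTrajectory":
        return cls(np.zeros((len(TIME_VARYING), N_COMPONENTS)), n_windows, spec)


def expand_log_scalings(traj: ParameterTrajectory) -> dict[str, np.ndarray]:
    """Per-window deviations ``lambda(t)``, one array of length W per name."""
    basis = dct_basis(traj.n_windows, N_COMPONENTS)
    k = basis.shape[1]
    lam = traj.beta[:, :k] @ basis.T  # (P, W)
    return {name: lam[row] for row, name in enumerate(TIME_VARYING)}


def expand(traj: ParameterTrajectory, base: CMCParameters,
           spec: ModelSpec | None = None) -> list[CMCParameters]:
    """Per-window parameter sets ``theta(t) = mu * exp(lambda(t))``.

    ``base`` supplies the prior-mean (or otherwise scaled) values; the
    spectral innovations ``d1..d8`` are added to ``base.d_spec`` rather
    than log-scaled.
    """
    if spec is not None and spec != traj.spec:
        raise ValueError("trajectory was built for a different model specification")
    lam = expand_log_scalings(traj)
    out = []
    for t in range(traj.n_windows):
        g = base.g.copy()
        for name in INHIBITORY + EXCITATORY:
            g[_G_INDEX[name]] = base.g[_G_INDEX[name]] * np.exp(lam[name][t])
        d_spec = base.d_spec + np.array([lam[f"d{i}"][t] for i in range(1, 9)])
        out.append(base.copy(
            g=g,
            a1=base.a1 * np.exp(lam["a1"][t]),
            a2=base.a2 * np.exp(lam["a2"][t]),
            b1=base.b1 * np.exp(lam["b1"][t]),
            b2=base.b2 * np.exp(lam["b2"][t]),
            d_spec=d_spec,
        ))
    return out


def project(curve: np.ndarray, n_components: int = N_COMPONENTS) -> np.ndarray:
    """Least-squares cosine coefficients of a per-window curve.

    The orthonormal basis makes this a plain projection; the returned
    coefficients reproduce the curve exactly when the basis is complete
    (``n_components >= n_windows``).
    """
    curve = np.asarray(curve, dtype=float)
    basis = dct_basis(curve.size, n_components)
    coeff = basis.T @ curve
    out = np.zeros(n_components)
    out[: coeff.size] = coeff
    return out
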