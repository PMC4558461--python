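"""Canonical microcircuit (CMC) neural mass model of a single cortical source.

The source comprises four interacting neuronal populations — granular
(spiny stellate) cells, superficial pyramidal cells, inhibitory
interneurons and deep pyramidal cells — each described by its mean
depolarisation ``v`` and synaptic current ``i`` (the first derivative of
``v``).  Synapses follow the second-order kernel of the Jansen–Rit
lineage,

    dv/dt = i
    di/dt = T * drive - 2*T*i - T**2 * v,

where ``T`` is the population's synaptic rate constant (Hz) and the
presynaptic *drive* sums firing rates of afferent populations weighted
by the ten intrinsic connections ``g1..g10``.  Firing rate is a centred
sigmoid of depolarisation, so the origin is an exact resting state at
zero input.

Population order everywhere in this package::

    0: granular / spiny stellate   (ss)
    1: superficial pyramidal       (sp)
    2: inhibitory interneurons     (ii)
    3: deep pyramidal              (dp)

Wiring (sign convention: inhibitory-source and recurrent gain-control
connections enter the drive negatively, excitatory ones positively)::

    g1:  ss -> ss  (recurrent, -)     g6:  dp -> ii  (+)
    g2:  sp -> ss  (gain control, -)  g7:  sp -> sp  (recurrent, -)
    g3:  ii -> ss  (-)                g8:  ss -> sp  (+)
    g4:  ii -> ii  (recurrent, -)     g9:  ii -> dp  (-)
    g5:  ss -> ii  (+)                g10: dp -> dp  (recurrent, -)

Exogenous (afferent) input enters the granular population only.
Between-population connections are conducted with a single intrinsic
delay ``d``; recurrent (within-population) terms are instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "CMCParameters",
    "PopulationState",
    "POPULATIONS",
    "sigmoid",
    "sigmoid_slope",
    "state_derivative",
    "equilibrium",
    "jacobian",
    "jacobian_fd",
]

POPULATIONS = ("ss", "sp", "ii", "dp")

# (source population, target index, sign, delayed?) for g1..g10.
_CONNECTIONS = {
    "g1": ("ss", 0, -1.0, False),
    "g2": ("sp", 0, -1.0, True),
    "g3": ("ii", 0, -1.0, True),
    "g4": ("ii", 2, -1.0, False),
    "g5": ("ss", 2, +1.0, True),
    "g6": ("dp", 2, +1.0, True),
    "g7": ("sp", 1, -1.0, False),
    "g8": ("ss", 1, +1.0, True),
    "g9": ("ii", 3, -1.0, True),
    "g10": ("dp", 3, -1.0, False),
}
_POP_INDEX = {name: k for k, name in enumerate(POPULATIONS)}


@dataclass
class CMCParameters:
    """Generative-model parameters of the single-source CMC.

    Defaults are the prior expectations used throughout: synaptic rate
    constants ``T = [250, 170, 80, 70]`` Hz for (ss, sp, ii, dp),
    connection strengths in Hz, sigmoid slope ``gamma = 0.67``,
    conduction delay ``d = 1`` ms, deep-pyramidal observation weight
    ``c_dp = 0.2``, and unit power-law spectra for the endogenous input
    (``a1 * f**-a2``) and measurement noise (``b1 * f**-b2``).  The
    eight ``d_spec`` coefficients shape the input spectrum over
    frequency through a discrete cosine basis and default to zero
    (pure power law).
    """

    T: np.ndarray = field(default_factory=lambda: np.array([250.0, 170.0, 80.0, 70.0]))
    g: np.ndarray = field(
        default_factory=lambda: np.array(
            # g1    g2     g3      g4     g5     g6     g7     g8     g9    g10
            [800.0, 600.0, 1600.0, 800.0, 800.0, 400.0, 400.0, 800.0, 400.0, 200.0]
        )
    )
    gamma: float = 0.67
    d: float = 1.0  # ms
    c_dp: float = 0.2
    a1: float = 1.0
    a2: float = 1.0
    b1: float = 1.0
    b2: float = 1.0
    d_spec: np.ndarray = field(default_factory=lambda: np.zeros(8))

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.d_spec = np.asarray(self.d_spec, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.T.shape != (4,) or np.any(self.T <= 0):
            raise ValueError("T must be 4 strictly positive rate constants")
        if self.g.shape != (10,) or np.any(self.g < 0):
            raise ValueError("g must be 10 non-negative connection strengths")
        if not (self.gamma > 0):
            raise ValueError("gamma must be positive")
        if not (self.d > 0):
            raise ValueError("delay d must be positive")
        if self.a1 <= 0 or self.b1 < 0:
            raise ValueError("spectral amplitudes a1 > 0, b1 >= 0 required")
        if self.a2 < 0 or self.b2 < 0:
            raise ValueError("power-law exponents must be non-negative")
        if self.d_spec.shape != (8,):
            raise ValueError("d_spec must have 8 coefficients")

    @classmethod
    def prior_means(cls) -> "CMCParameters":
        """Parameters at their prior expectations."""
        return cls()

    def copy(self, **changes) -> "CMCParameters":
        out = replace(self)
        for k, v in changes.items():
            setattr(out, k, v)
        out.validate()
        return out


@dataclass
class PopulationState:
    """Mean depolarisations ``v`` and synaptic currents ``i`` (4 each)."""

    v: np.ndarray
    i: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.v.shape != (4,) or self.i.shape != (4,):
            raise ValueError("state must hold 4 depolarisations and 4 currents")

    @classmethod
    def zeros(cls) -> "PopulationState":
        return cls(np.zeros(4), np.zeros(4))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.v, self.i])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "PopulationState":
        x = np.asarray(x, dtype=float)
        if x.shape != (8,):
            raise ValueError("state vector must have 8 components")
        return cls(x[:4], x[4:])


def sigmoid(v, gamma: float):
    """Centred sigmoid firing-rate function, bounded by +/- 1/2.

    ``sigmoid(v, gamma) = 1/(1 + exp(-gamma*v)) - 1/2``; odd, monotone,
    with slope ``gamma/4`` at the origin.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite depolarisation passed to sigmoid")
    # Written via tanh for symmetric floating-point behaviour around 0.
    return 0.5 * np.tanh(0.5 * gamma * v)


def sigmoid_slope(v, gamma: float):
    """Derivative of :func:`sigmoid` with respect to ``v``."""
    s = np.cosh(0.5 * gamma * np.asarray(v, dtype=float))
    return 0.25 * gamma / s**2


def _drives(sig_now: np.ndarray, sig_del: np.ndarray, u: float, g: np.ndarray) -> np.ndarray:
    """Presynaptic drive per population from instantaneous/delayed firing."""
    drive = np.zeros(4)
    for idx, (src, tgt, sign, delayed) in enumerate(_CONNECTIONS.values()):
        s = sig_del if delayed else sig_now
        drive[tgt] += sign * g[idx] * s[_POP_INDEX[src]]
    drive[0] += u
    return drive


def state_derivative(
    x: PopulationState | np.ndarray,
    x_delayed: PopulationState | np.ndarray,
    u: float,
    p: CMCParameters,
) -> np.ndarray:
    """Time derivative of the 8 CMC states.

    ``x_delayed`` is the state a conduction delay ``p.d`` in the past;
    it feeds every between-population connection, while recurrent terms
    and the synaptic decay use the instantaneous state.  Returns the
    derivative as an 8-vector ``[dv/dt, di/dt]`` in units of 1/s.
    """
    if isinstance(x, PopulationState):
        x = x.as_vector()
    if isinstance(x_delayed, PopulationState):
        x_delayed = x_delayed.as_vector()
    x = np.asarray(x, dtype=float)
    x_delayed = np.asarray(x_delayed, dtype=float)
    if x.shape != (8,) or x_delayed.shape != (8,):
        raise ValueError("state vectors must have 8 components")
    if not np.isfinite(u):
        raise ValueError("input u must be finite")

    v, i = x[:4], x[4:]
    sig_now = sigmoid(v, p.gamma)
    sig_del = sigmoid(x_delayed[:4], p.gamma)
    drive = _drives(sig_now, sig_del, u, p.g)
    dv = i
    di = p.T * drive - 2.0 * p.T * i - p.T**2 * v
    return np.concatenate([dv, di])


def equilibrium(p: CMCParameters, u0: float = 0.0, max_iter: int = 500) -> PopulationState:
    """Fixed point of the delay-free vector field at constant input ``u0``.

    Root-finding starts from the origin (the exact rest point at zero
    input).  Raises if the residual norm does not fall below 1e-9.
    """
    if u0 == 0.0:
        return PopulationState.zeros()

    def fun(x):
        return state_derivative(x, x, u0, p)

    sol = optimize.root(fun, np.zeros(8), method="hybr", options={"maxfev": max_iter * 9})
    res = float(np.linalg.norm(fun(sol.x)))
    if res >= 1e-9:
        raise RuntimeError(f"equilibrium search did not converge: residual {res:.3e}")
    return PopulationState.from_vector(sol.x)


def jacobian(p: CMCParameters, x0: PopulationState | None = None):
    """Analytic linearisation ``(J0, Jd)`` of the CMC at an equilibrium.

    ``J0`` collects instantaneous terms, ``Jd`` the terms that act
    through the delayed state, so the linearised dynamics read
    ``dx/dt = J0 x(t) + Jd x(t - d) + B u(t)``.  Both are 8x8.
    """
    if x0 is None:
        x0 = PopulationState.zeros()
    v0 = x0.v
    slope = sigmoid_slope(v0, p.gamma)

    J0 = np.zeros((8, 8))
    Jd = np.zeros((8, 8))
    J0[:4, 4:] = np.eye(4)  # dv/dt = i
    for k in range(4):
        J0[4 + k, k] += -p.T[k] ** 2
        J0[4 + k, 4 + k] = -2.0 * p.T[k]
    for idx, (src, tgt, sign, delayed) in enumerate(_CONNECTIONS.values()):
        j = _POP_INDEX[src]
        target = Jd if delayed else J0
        target[4 + tgt, j] += sign * p.T[tgt] * p.g[idx] * slope[j]
    return J0, Jd


def jacobian_fd(p: CMCParameters, x0: PopulationState | None = None, step: float = 1e-6):
    """Central finite-difference linearisation, for cross-checking."""
    if x0 is None:
        x0 = PopulationState.zeros()
    x0v = x0.as_vector()
    J0 = np.zeros((8, 8))
    Jd = np.zeros((8, 8))
    for j in range(8):
        e = np.zeros(8)
        e[j] = step
        J0[:, j] = (
            state_derivative(x0v + e, x0v, 0.0, p) - state_derivative(x0v - e, x0v, 0.0, p)
        ) / (2 * step)
        Jd[:, j] = (
            state_derivative(x0v, x0v + e, 0.0, p) - state_derivative(x0v, x0v - e, 0.0, p)
        ) / (2 * step)
    return J0, Jd


def input_vector(p: CMCParameters) -> np.ndarray:
    """Input matrix B: exogenous drive enters the granular current."""
    B = np.zeros(8)
    B[4] = p.T[0]
    return B


def observation_vector(p: CMCParameters) -> np.ndarray:
    """Observation row C: superficial plus ``c_dp`` x deep depolarisation."""
    C = np.zeros(8)
    C[1] = 1.0
    C[3] = p.c_dp
    return C
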