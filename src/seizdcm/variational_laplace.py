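"""Variational Laplace inversion of the windowed spectral model.

The generative model maps a latent vector to log spectral densities
over windows x frequencies.  Latents comprise (i) one log-scaling per
constant parameter (rate constants, the four gain-control connections,
sigmoid slope, delay, deep-pyramidal observation weight) and (ii) the
temporal cosine coefficients of every potentially time-varying
parameter — eight components if its group may vary under the model at
hand, otherwise a single constant component.

Priors and posteriors are Gaussian.  Inversion maximises the
variational free energy

    F = -(pi/2) ||y - g(mu)||^2 - (pi/2) tr(J Sigma J') + (n/2) log pi
        - (n/2) log 2 pi - KL[q(lambda) || p(lambda)] - KL[q(h) || p(h)],

with a single log-precision hyper-latent ``h`` (``pi = exp(h)``) on
the observation error of the log-spectral features, by Gauss-Newton
ascent with Levenberg-Marquardt regularisation: a step is accepted only
if F increases, damping doubles on rejection and halves on acceptance.
Prediction gradients are central finite differences, so runs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .cmc_model import CMCParameters
from .model_space import ModelSpec
from .spectral_forward import FrequencyGrid, batch_predicted_spectra
from . import temporal_basis as tb

logger = logging.getLogger(__name__)

__all__ = [
    "CONSTANT_LATENTS",
    "LatentLayout",
    "PriorSpec",
    "Posterior",
    "build_layout",
    "predict",
    "free_energy",
    "invert",
    "gauss_newton_vl",
]

CONSTANT_LATENTS = ("T1", "T2", "T3", "T4", "g1", "g2", "g7", "g10",
                    "gamma", "d", "c_dp")

# Table of per-parameter log prior variances.
_LOG_PRIOR_VARIANCE = {
    **{f"T{i}": 0.0625 for i in range(1, 5)},
    **{f"g{i}": 0.0625 for i in range(1, 11)},
    "gamma": 0.03125,
    "d": 0.03125,
    "c_dp": 0.0625,
    "a1": 0.0078125,
    "a2": 0.0078125,
    "b1": 0.0078125,
    "b2": 0.0078125,
    **{f"d{i}": 0.0078125 for i in range(1, 9)},
}


@dataclass
class LatentLayout:
    """Mapping from the flat latent vector to named parameters."""

    names: list[str]
    slices: dict[str, slice]
    prior_variances: np.ndarray
    n_windows: int
    spec: ModelSpec

    @property
    def n_latents(self) -> int:
        return self.prior_variances.size


def build_layout(spec: ModelSpec, n_windows: int) -> LatentLayout:
    """Enumerate latents for a model: constants, then cosine blocks."""
    names: list[str] = []
    slices: dict[str, slice] = {}
    variances: list[float] = []
    pos = 0
    for name in CONSTANT_LATENTS:
        slices[name] = slice(pos, pos + 1)
        names.append(name)
        variances.append(_LOG_PRIOR_VARIANCE[name])
        pos += 1
    varying = set(tb.varying_names(spec))
    n_comp = min(tb.N_COMPONENTS, n_windows)
    for name in tb.TIME_VARYING:
        k = n_comp if name in varying else 1
        slices[name] = slice(pos, pos + k)
        v0 = _LOG_PRIOR_VARIANCE[name]
        for c in range(k):
            names.append(f"{name}:c{c}")
            variances.append(v0 if c == 0 else v0 / 2.0)
        pos += k
    return LatentLayout(names, slices, np.array(variances), n_windows, spec)


@dataclass
class PriorSpec:
    """Gaussian priors over latents plus the noise hyperprior.

    Latent prior means are zero (parameters at their prior
    expectations).  ``hyper_mean``/``hyper_variance`` govern the
    log-precision of observation error on log-spectral features; the
    hyperprior is deliberately weak so the precision can adapt to the
    scale of spectral-estimation noise.
    """

    layout: LatentLayout
    mean: np.ndarray = None
    variances: np.ndarray = None
    hyper_mean: float = 0.0
    hyper_variance: float = 16.0

    def __post_init__(self) -> None:
        if self.mean is None:
            self.mean = np.zeros(self.layout.n_latents)
        if self.variances is None:
            self.variances = self.layout.prior_variances.copy()
        self.mean = np.asarray(self.mean, float)
        self.variances = np.asarray(self.variances, float)
        if np.any(self.variances <= 0) or self.hyper_variance <= 0:
            raise ValueError("prior variances must be strictly positive")


def _window_parameter_arrays(L: np.ndarray, layout: LatentLayout,
                             base: CMCParameters):
    """Expand a batch of latent vectors (m, p) to per-window arrays.

    Returns a dict of arrays with leading shape (m, W) suitable for the
    batched forward model.
    """
    m = L.shape[0]
    W = layout.n_windows
    sl = layout.slices
    basis = tb.dct_basis(W, tb.N_COMPONENTS)

    def course(name):
        block = L[:, sl[name]]  # (m, k)
        return block @ basis[:, : block.shape[1]].T  # (m, W)

    T = base.T * np.exp(L[:, sl["T1"].start:sl["T4"].stop])  # (m, 4)
    gamma = base.gamma * np.exp(L[:, sl["gamma"]][:, 0])
    d_ms = base.d * np.exp(L[:, sl["d"]][:, 0])
    c_dp = base.c_dp * np.exp(L[:, sl["c_dp"]][:, 0])

    g = np.broadcast_to(base.g, (m, W, 10)).copy()
    for name in ("g1", "g2", "g7", "g10"):
        gi = int(name[1:]) - 1
        g[:, :, gi] *= np.exp(L[:, sl[name]])  # constant over windows
    for name in tb.INHIBITORY + tb.EXCITATORY:
        gi = int(name[1:]) - 1
        g[:, :, gi] *= np.exp(course(name))

    a1 = base.a1 * np.exp(course("a1"))
    a2 = base.a2 * np.exp(course("a2"))
    b1 = base.b1 * np.exp(course("b1"))
    b2 = base.b2 * np.exp(course("b2"))
    d_spec = np.broadcast_to(base.d_spec, (m, W, 8)).copy()
    for i in range(1, 9):
        d_spec[:, :, i - 1] += course(f"d{i}")

    return {
        "T": T[:, None, :], "g": g, "gamma": gamma[:, None], "d_ms": d_ms[:, None],
        "c_dp": c_dp[:, None], "a1": a1, "a2": a2, "b1": b1, "b2": b2,
        "d_spec": d_spec,
    }


_STABILITY_MARGIN = -1.0  # rad/s; penalise linearisations drifting unstable


def _predict_batch(L: np.ndarray, layout: LatentLayout, base: CMCParameters,
                   grid: FrequencyGrid, chunk: int = 64) -> np.ndarray:
    """Log predicted spectra for latent batch (m, p) -> (m, W*F)."""
    L = np.atleast_2d(np.asarray(L, float))
    m = L.shape[0]
    out = np.empty((m, layout.n_windows * len(grid)))
    for lo in range(0, m, chunk):
        part = L[lo:lo + chunk]
        pa = _window_parameter_arrays(part, layout, base)
        S = batch_predicted_spectra(
            pa["T"], pa["g"], pa["gamma"], pa["d_ms"], pa["c_dp"],
            pa["a1"], pa["a2"], pa["b1"], pa["b2"], pa["d_spec"], grid,
        )  # (mc, W, F)
        feats = np.log(S)
        # soft stability penalty: inflate features of near-unstable windows
        from .spectral_forward import _batch_jacobians
        J0, Jd = _batch_jacobians(pa["T"], pa["g"], pa["gamma"])
        max_re = np.linalg.eigvals(J0 + Jd).real.max(axis=-1)  # (mc, W)
        excess = np.maximum(max_re - _STABILITY_MARGIN, 0.0)
        if np.any(excess > 0):
            logger.warning("unstable linearisation in %d window(s); penalised",
                           int((excess > 0).sum()))
            feats = feats + 0.05 * excess[..., None]
        out[lo:lo + chunk] = feats.reshape(part.shape[0], -1)
    return out


def predict(latents: np.ndarray, spec: ModelSpec, n_windows: int,
            grid: FrequencyGrid | None = None,
            base: CMCParameters | None = None) -> np.ndarray:
    """Predicted feature vector (log densities, windows x frequencies)."""
    grid = grid or FrequencyGrid()
    base = base or CMCParameters.prior_means()
    layout = build_layout(spec, n_windows)
    latents = np.asarray(latents, float)
    if latents.shape != (layout.n_latents,):
        raise ValueError(
            f"model '{spec.label}' with {n_windows} windows expects "
            f"{layout.n_latents} latents, got {latents.shape}"
        )
    return _predict_batch(latents[None], layout, base, grid)[0]


# ---------------------------------------------------------------------------
# Generic variational-Laplace machinery


def _gaussian_kl(mu, Sigma, prior_mean, prior_var, logdet_post=None):
    """KL[q||p] for diagonal Gaussian prior, full Gaussian posterior."""
    p = mu.size
    dm = mu - prior_mean
    if logdet_post is None:
        sign, logdet_post = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise np.linalg.LinAlgError("posterior covariance not positive definite")
    return 0.5 * (
        np.sum(np.diag(Sigma) / prior_var)
        + np.sum(dm**2 / prior_var)
        - p
        + np.sum(np.log(prior_var))
        - logdet_post
    )


class _WhitenedCurvature:
    """Eigen-decomposition of the prior-whitened Gauss-Newton curvature.

    With diagonal prior covariance ``S0`` and ``A = S0^1/2 J'J S0^1/2 =
    V diag(d) V'``, every h-dependent quantity of the Laplace scheme —
    ``tr(Sigma J'J)``, ``tr(S0^-1 Sigma)`` and ``log|Sigma|`` — reduces
    to sums over the eigenvalues ``d``, making the log-precision update
    and free-energy evaluations O(p) per candidate.
    """

    def __init__(self, JJ: np.ndarray, prior_var: np.ndarray):
        s = np.sqrt(prior_var)
        A = JJ * np.outer(s, s)
        self.d = np.maximum(np.linalg.eigvalsh(0.5 * (A + A.T)), 0.0)
        self.prior_var = prior_var

    def tr_sigma_jj(self, pi_: float) -> float:
        return float(np.sum(self.d / (pi_ * self.d + 1.0)))

    def tr_prior_inv_sigma(self, pi_: float) -> float:
        return float(np.sum(1.0 / (pi_ * self.d + 1.0)))

    def logdet_ratio(self, pi_: float) -> float:
        """log|Sigma0| - log|Sigma| = sum log(pi d_i + 1)."""
        return float(np.sum(np.log1p(pi_ * self.d)))


def _hyper_update(curv: _WhitenedCurvature, sse: float, n: int,
                  hE: float, hC: float, h0: float) -> float:
    """Damped Newton ascent for the log-precision hyper-latent."""
    h = h0
    for _ in range(64):
        pi_ = np.exp(h)
        r = sse + curv.tr_sigma_jj(pi_)
        grad = -0.5 * pi_ * r + 0.5 * n - (h - hE) / hC
        hess = -0.5 * pi_ * r - 1.0 / hC
        step = float(np.clip(-grad / hess, -2.0, 2.0))
        h = float(np.clip(h + step, -16.0, 32.0))
        if abs(step) < 1e-8:
            break
    return h


def _free_energy_terms(e, curv: _WhitenedCurvature, mu, prior_mean, prior_var,
                       h, hE, hC, fixed_h: bool) -> float:
    """F at the current point given the whitened curvature."""
    n = e.size
    p = mu.size
    pi_ = np.exp(h)
    tr = curv.tr_sigma_jj(pi_)
    sse = float(e @ e)
    acc = -0.5 * pi_ * (sse + tr) + 0.5 * n * h - 0.5 * n * np.log(2 * np.pi)
    dm = mu - prior_mean
    klq = 0.5 * (curv.tr_prior_inv_sigma(pi_) + np.sum(dm**2 / prior_var)
                 - p + curv.logdet_ratio(pi_))
    if fixed_h:
        klh = 0.0
    else:
        Sh = 1.0 / (0.5 * pi_ * (sse + tr) + 1.0 / hC)
        klh = 0.5 * (Sh / hC + (h - hE) ** 2 / hC - 1.0 + np.log(hC / Sh))
    return float(acc - klq - klh)


def _free_energy_at(e, J, mu, prior_mean, prior_var, h, hE, hC,
                    fixed_h: bool) -> tuple[float, np.ndarray]:
    """F and the Laplace posterior covariance at the current point."""
    JJ = J.T @ J
    curv = _WhitenedCurvature(JJ, prior_var)
    F = _free_energy_terms(e, curv, mu, prior_mean, prior_var, h, hE, hC, fixed_h)
    H = np.exp(h) * JJ + np.diag(1.0 / prior_var)
    c, low = cho_factor(0.5 * (H + H.T), lower=True)
    Sigma = cho_solve((c, low), np.eye(mu.size))
    return F, Sigma


@dataclass
class VLResult:
    mean: np.ndarray
    cov: np.ndarray
    F: float
    F_trace: list
    h: float
    converged: bool
    warning: str | None
    variance_explained: float
    n_iterations: int


def gauss_newton_vl(y, predict_fn, prior_mean, prior_var, *,
                    x0=None, hyper_mean=0.0, hyper_variance=16.0,
                    fix_precision=None, fd_step=1e-3,
                    max_iter=128, tol=0.01, tol_streak=3,
                    damping0=1e-2) -> VLResult:
    """Maximise variational free energy for a generic forward model.

    ``predict_fn`` maps a batch of latent vectors (m, p) to predictions
    (m, n).  Gradients use central finite differences (step
    ``fd_step``); steps are accepted only if F increases, with
    Levenberg-Marquardt damping doubled on rejection and halved on
    acceptance.  Convergence: improvement below ``tol`` on
    ``tol_streak`` consecutive accepted steps, or ``max_iter``
    iterations.
    """
    y = np.asarray(y, float).ravel()
    mu = np.asarray(prior_mean if x0 is None else x0, float).copy()
    prior_var = np.asarray(prior_var, float)
    p = mu.size
    fixed_h = fix_precision is not None
    h = float(np.log(fix_precision)) if fixed_h else float(hyper_mean)

    def fd_jacobian(x):
        deltas = np.vstack([np.eye(p) * fd_step, -np.eye(p) * fd_step])
        preds = predict_fn(x[None, :] + deltas)
        return (preds[:p] - preds[p:]).T / (2 * fd_step)

    prior_mean = np.asarray(prior_mean, float)
    e = y - predict_fn(mu[None])[0]
    J = fd_jacobian(mu)
    JJ = J.T @ J
    curv = _WhitenedCurvature(JJ, prior_var)

    def updated_h(e_, h0):
        if fixed_h:
            return h
        return _hyper_update(curv, float(e_ @ e_), y.size, hyper_mean,
                             hyper_variance, h0)

    h = updated_h(e, h)
    F = _free_energy_terms(e, curv, mu, prior_mean, prior_var, h,
                           hyper_mean, hyper_variance, fixed_h)
    F_trace = [F]
    nu = damping0
    streak = 0
    converged = False
    warning = None
    it = 0
    while it < max_iter:
        it += 1
        pi_ = np.exp(h)
        Hmat = pi_ * JJ + np.diag(1.0 / prior_var)
        grad = pi_ * (J.T @ e) - (mu - prior_mean) / prior_var
        D = np.diag(np.diag(Hmat))
        accepted = False
        for _esc in range(10):
            try:
                step = np.linalg.solve(Hmat + nu * D, grad)
            except np.linalg.LinAlgError:
                nu *= 2.0
                continue
            cand = mu + step
            e_c = y - predict_fn(cand[None])[0]
            h_c = updated_h(e_c, h)
            F_c = _free_energy_terms(e_c, curv, cand, prior_mean, prior_var,
                                     h_c, hyper_mean, hyper_variance, fixed_h)
            if F_c > F:
                dF = F_c - F
                mu, e, h, F = cand, e_c, h_c, F_c
                # trace accumulates accepted improvements, each measured
                # under a single linearisation, so it is monotone
                F_trace.append(F_trace[-1] + dF)
                nu = max(nu / 2.0, 1e-10)
                accepted = True
                streak = streak + 1 if dF < tol else 0
                break
            nu *= 2.0
        if not accepted:
            warning = "all steps rejected after 10 damping escalations"
            logger.debug(warning)
            break
        if streak >= tol_streak:
            converged = True
            break
        # relinearise at the accepted point and rebase F for comparisons
        J = fd_jacobian(mu)
        JJ = J.T @ J
        curv = _WhitenedCurvature(JJ, prior_var)
        h = updated_h(e, h)
        F = _free_energy_terms(e, curv, mu, prior_mean, prior_var, h,
                               hyper_mean, hyper_variance, fixed_h)

    Hmat = np.exp(h) * JJ + np.diag(1.0 / prior_var)
    c, low = cho_factor(0.5 * (Hmat + Hmat.T), lower=True)
    Sigma = cho_solve((c, low), np.eye(mu.size))
    ybar = y.mean()
    denom = float(np.sum((y - ybar) ** 2))
    ve = 1.0 - float(np.sum(e**2)) / denom if denom > 0 else np.nan
    return VLResult(mu, Sigma, F, F_trace, h, converged, warning, ve, it)


# ---------------------------------------------------------------------------
# DCM-specific interface


@dataclass
class Posterior:
    """Gaussian posterior over latents with derived quantities."""

    mean: np.ndarray
    cov: np.ndarray
    F: float
    variance_explained: float
    F_trace: list
    h: float
    layout: LatentLayout
    spec: ModelSpec
    base: CMCParameters
    grid: FrequencyGrid
    n_windows: int
    scale_log_offset: float = 0.0
    converged: bool = True
    warning: str | None = None

    def sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def trajectory(self) -> tb.ParameterTrajectory:
        beta = np.zeros((len(tb.TIME_VARYING), tb.N_COMPONENTS))
        for row, name in enumerate(tb.TIME_VARYING):
            sl = self.layout.slices[name]
            beta[row, : sl.stop - sl.start] = self.mean[sl]
        return tb.ParameterTrajectory(beta, self.n_windows, self.spec)

    def scaled_base(self) -> CMCParameters:
        """Base parameters with the constant latents applied."""
        m = self.mean
        sl = self.layout.slices
        return self.base.copy(
            T=self.base.T * np.exp(m[sl["T1"].start:sl["T4"].stop]),
            g=self.base.g * np.exp(np.array(
                [m[sl[n]][0] if n in ("g1", "g2", "g7", "g10") else 0.0
                 for n in (f"g{i}" for i in range(1, 11))])),
            gamma=self.base.gamma * np.exp(m[sl["gamma"]][0]),
            d=self.base.d * np.exp(m[sl["d"]][0]),
            c_dp=self.base.c_dp * np.exp(m[sl["c_dp"]][0]),
        )

    def window_parameters(self) -> list[CMCParameters]:
        """Posterior-mean parameter set for each window."""
        return tb.expand(self.trajectory(), self.scaled_base(), self.spec)

    def predicted_features(self) -> np.ndarray:
        return _predict_batch(self.mean[None], self.layout, self.base, self.grid)[0]

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label,
            "free_energy": self.F,
            "variance_explained": self.variance_explained,
            "log_precision": self.h,
            "converged": self.converged,
            "warning": self.warning,
            "scale_log_offset": self.scale_log_offset,
            "latent_names": self.layout.names,
            "posterior_mean": self.mean.tolist(),
            "posterior_sd": self.sd().tolist(),
        }


def _data_features(data, grid: FrequencyGrid, base: CMCParameters,
                   layout: LatentLayout, normalize: bool):
    S = np.asarray(data.S, float)
    if S.shape != (layout.n_windows, len(grid)):
        raise ValueError("spectral data shape does not match windows x grid")
    y = np.log(S).ravel()
    offset = 0.0
    if normalize:
        prior_pred = _predict_batch(np.zeros((1, layout.n_latents)), layout,
                                    base, grid)[0]
        offset = float(prior_pred.mean() - y.mean())
        y = y + offset
    return y, offset


def free_energy(latents, data, spec: ModelSpec, priors: PriorSpec | None = None,
                *, base: CMCParameters | None = None,
                grid: FrequencyGrid | None = None, h: float | None = None,
                q_cov: np.ndarray | None = None, normalize: bool = True) -> float:
    """Variational free energy at a given latent vector.

    If ``q_cov`` is omitted the Laplace covariance (from the
    finite-difference prediction Jacobian) is used; if ``h`` is omitted
    the log-precision is optimised at this point.
    """
    grid = grid or FrequencyGrid()
    base = base or CMCParameters.prior_means()
    layout = build_layout(spec, data.S.shape[0])
    priors = priors or PriorSpec(layout)
    latents = np.asarray(latents, float)
    y, _ = _data_features(data, grid, base, layout, normalize)
    e = y - _predict_batch(latents[None], layout, base, grid)[0]
    p = layout.n_latents

    def pf(batch):
        return _predict_batch(batch, layout, base, grid)

    deltas = np.vstack([np.eye(p) * 1e-3, -np.eye(p) * 1e-3])
    preds = pf(latents[None, :] + deltas)
    J = (preds[:p] - preds[p:]).T / 2e-3
    JJ = J.T @ J
    if h is None:
        curv = _WhitenedCurvature(JJ, priors.variances)
        h = _hyper_update(curv, float(e @ e), y.size, priors.hyper_mean,
                          priors.hyper_variance, priors.hyper_mean)
    if q_cov is not None:
        n = y.size
        pi_ = np.exp(h)
        tr = float(np.sum(q_cov * JJ))
        acc = -0.5 * pi_ * (e @ e + tr) + 0.5 * n * h - 0.5 * n * np.log(2 * np.pi)
        klq = _gaussian_kl(latents, q_cov, priors.mean, priors.variances)
        return float(acc - klq)
    F, _ = _free_energy_at(e, J, latents, priors.mean, priors.variances, h,
                           priors.hyper_mean, priors.hyper_variance, False)
    return F


def invert(data, spec: ModelSpec, priors: PriorSpec | None = None,
           seed: int = 0, *, base: CMCParameters | None = None,
           grid: FrequencyGrid | None = None, normalize: bool = True,
           fix_precision: float | None = None, max_iter: int = 128,
           tol: float = 0.01, fd_step: float = 1e-3) -> Posterior:
    """Invert one model against windowed spectral data.

    ``seed`` is recorded for provenance; the scheme itself is
    deterministic (finite differences, fixed initialisation at the
    prior mean).
    """
    del seed  # deterministic; kept for interface symmetry
    grid = grid or FrequencyGrid()
    base = base or CMCParameters.prior_means()
    n_windows = np.asarray(data.S).shape[0]
    layout = build_layout(spec, n_windows)
    priors = priors or PriorSpec(layout)
    if priors.layout.n_latents != layout.n_latents:
        raise ValueError("prior specification does not match the model's latents")
    y, offset = _data_features(data, grid, base, layout, normalize)

    def pf(batch):
        return _predict_batch(np.asarray(batch, float), layout, base, grid)

    res = gauss_newton_vl(
        y, pf, priors.mean, priors.variances,
        hyper_mean=priors.hyper_mean, hyper_variance=priors.hyper_variance,
        fix_precision=fix_precision, fd_step=fd_step, max_iter=max_iter, tol=tol,
    )
    return Posterior(
        mean=res.mean, cov=res.cov, F=res.F,
        variance_explained=res.variance_explained, F_trace=res.F_trace,
        h=res.h, layout=layout, spec=spec, base=base, grid=grid,
        n_windows=n_windows, scale_log_offset=offset,
        converged=res.converged, warning=res.warning,
    )
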