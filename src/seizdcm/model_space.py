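"""The eight-model hypothesis space and Bayesian model comparison.

Each hypothesis states which parameter groups may drift over seizure
windows: the three inhibitory-source connections, the three excitatory
connections, and/or the endogenous input/noise spectrum.  All 2**3
combinations are inverted and compared by variational free energy,
which approximates log model evidence; free energies are reported
relative to the null model (no drift anywhere) and a difference of 3
corresponds to posterior odds of about 20:1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "enumerate_models",
    "compare",
    "balance_timecourse",
    "balance_across_posteriors",
    "reconstruct",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which parameter groups are allowed to vary over windows."""

    inhibitory_varying: bool
    excitatory_varying: bool
    endogenous_varying: bool
    label: str

    @property
    def is_null(self) -> bool:
        return not (self.inhibitory_varying or self.excitatory_varying
                    or self.endogenous_varying)

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls(True, True, True, "Inhibitory + excitatory + endogenous")

    @classmethod
    def null(cls) -> "ModelSpec":
        return cls(False, False, False, "Null")


def enumerate_models() -> list[ModelSpec]:
    """The eight hypotheses in a fixed order, full model first, null last."""
    return [
        ModelSpec(True, True, True, "Inhibitory + excitatory + endogenous"),
        ModelSpec(True, True, False, "Inhibitory + excitatory"),
        ModelSpec(True, False, True, "Inhibitory + endogenous"),
        ModelSpec(False, True, True, "Excitatory + endogenous"),
        ModelSpec(True, False, False, "Inhibitory"),
        ModelSpec(False, True, False, "Excitatory"),
        ModelSpec(False, False, True, "Endogenous"),
        ModelSpec(False, False, False, "Null"),
    ]


def compare(free_energies) -> tuple[np.ndarray, np.ndarray]:
    """Relative free energies and posterior model probabilities.

    Free energies are referenced to the last (null) model; posterior
    probabilities assume uniform model priors.  Non-finite entries are
    excluded with a warning and receive probability 0 and relative free
    energy -inf.
    """
    F = np.asarray(list(free_energies), dtype=float)
    finite = np.isfinite(F)
    if not np.all(finite):
        logger.warning("excluding %d model(s) with non-finite free energy",
                       int((~finite).sum()))
    if not finite[-1]:
        raise ValueError("null (reference) model has non-finite free energy")
    rel = np.where(finite, F - F[-1], -np.inf)
    z = np.where(finite, F - F[finite].max(), -np.inf)
    w = np.exp(z, where=finite, out=np.zeros_like(F))
    prob = w / w.sum()
    return rel, prob


def _group_timecourse(post, names) -> tuple[np.ndarray, np.ndarray]:
    """Mean and pointwise SD of the mean-over-group log-scaling course."""
    from .temporal_basis import dct_basis, N_COMPONENTS, TIME_VARYING

    basis = dct_basis(post.n_windows, N_COMPONENTS)
    k = basis.shape[1]
    mean = np.zeros(post.n_windows)
    var = np.zeros(post.n_windows)
    # linear map from latents to the group-mean course: rows of M
    M = np.zeros((post.n_windows, post.mean.size))
    for name in names:
        sl = post.layout.slices.get(name)
        if sl is None:
            continue
        n = sl.stop - sl.start
        M[:, sl] += basis[:, :n] / len(names)
    mean = M @ post.mean
    var = np.einsum("wi,ij,wj->w", M, post.cov, M)
    return mean, np.sqrt(np.maximum(var, 0.0))


def balance_timecourse(post) -> dict[str, np.ndarray]:
    """Inhibitory, excitatory and balance (difference) courses from a posterior.

    Summaries are the mean per-window log-scaling over the three
    connections of each group; balance is excitatory minus inhibitory.
    ``sd_*`` entries are pointwise posterior standard deviations.  For
    the null model all courses are identically zero and the result is
    flagged.
    """
    from .temporal_basis import INHIBITORY, EXCITATORY

    inh, sd_inh = _group_timecourse(post, INHIBITORY)
    exc, sd_exc = _group_timecourse(post, EXCITATORY)
    return {
        "inhibitory": inh,
        "excitatory": exc,
        "balance": exc - inh,
        "sd_inhibitory": sd_inh,
        "sd_excitatory": sd_exc,
        "sd_balance": np.sqrt(sd_inh**2 + sd_exc**2),
        "null_model": post.spec.is_null,
    }


def balance_across_posteriors(posteriors) -> dict[str, np.ndarray]:
    """Mean and +/-2 SD bands of balance courses over individually
    inverted seizures (the multi-seizure convention)."""
    courses = [balance_timecourse(p) for p in posteriors]
    out = {}
    for key in ("inhibitory", "excitatory", "balance"):
        stack = np.array([c[key] for c in courses])
        out[key] = stack.mean(axis=0)
        out["sd_" + key] = stack.std(axis=0, ddof=1) if len(courses) > 1 else np.zeros(stack.shape[1])
    out["n_seizures"] = len(courses)
    return out


def reconstruct(post, grid=None) -> dict[str, np.ndarray]:
    """Spectral read-outs at the posterior-mean parameters.

    Returns per-window predicted observed spectra (W, F), per-population
    time-frequency surfaces (4, W, F) and the endogenous-input surface
    (W, F), aligned on the same window/frequency axes.
    """
    from .spectral_forward import (FrequencyGrid, predicted_spectrum,
                                   population_spectra, endogenous_input_spectrum)

    grid = grid or FrequencyGrid()
    params = post.window_parameters()
    W, F = len(params), len(grid)
    observed = np.zeros((W, F))
    populations = np.zeros((4, W, F))
    inputs = np.zeros((W, F))
    for t, p in enumerate(params):
        observed[t] = predicted_spectrum(p, grid)
        populations[:, t, :] = population_spectra(p, grid)
        inputs[t] = endogenous_input_spectrum(p, grid)
    return {"observed": observed, "populations": populations, "input": inputs,
            "frequencies": grid.f}
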