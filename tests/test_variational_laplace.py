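"""Free-energy optimisation: layout, predictions, F, and inversion."""

import numpy as np
import pytest

from seizdcm.cmc_model import CMCParameters
from seizdcm.model_space import ModelSpec
from seizdcm.spectral_forward import FrequencyGrid
from seizdcm.synthetic_data import patient1_like, simulate_spectra
from seizdcm.variational_laplace import (build_layout, PriorSpec, predict,
                                         free_energy, invert, gauss_newton_vl)
from seizdcm import temporal_basis as tb


class TestLayout:
    def test_latent_counts_for_full_and_null_models(self):
        full = build_layout(ModelSpec.full(), 10)
        null = build_layout(ModelSpec.null(), 10)
        # 11 constants; 18 drift parameters with 8 or 1 components each
        assert full.n_latents == 11 + 18 * 8
        assert null.n_latents == 11 + 18

    def test_prior_variances_follow_reference_table(self):
        lay = build_layout(ModelSpec.full(), 10)
        v = lay.prior_variances
        names = lay.names
        assert v[names.index("T1")] == 0.0625
        assert v[names.index("gamma")] == 0.03125
        assert v[names.index("d")] == 0.03125
        assert v[names.index("a1:c0")] == 0.0078125
        assert v[names.index("a1:c3")] == 0.0078125 / 2
        assert v[names.index("d5:c0")] == 0.0078125

    def test_prior_spec_validates(self):
        lay = build_layout(ModelSpec.null(), 4)
        with pytest.raises(ValueError):
            PriorSpec(lay, variances=np.zeros(lay.n_latents))


class TestPredict:
    def test_null_model_zero_latents_identical_windows(self):
        lay = build_layout(ModelSpec.null(), 6)
        feats = predict(np.zeros(lay.n_latents), ModelSpec.null(), 6)
        per_window = feats.reshape(6, -1)
        assert np.allclose(per_window, per_window[0])

    def test_feature_length_is_windows_times_frequencies(self):
        lay = build_layout(ModelSpec.full(), 5)
        feats = predict(np.zeros(lay.n_latents), ModelSpec.full(), 5)
        assert feats.shape == (5 * 40,)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict(np.zeros(3), ModelSpec.full(), 5)

    def test_unstable_linearisation_penalised_not_fatal(self):
        """Excursions that destabilise the resting state yield finite,
        inflated features instead of an error."""
        from seizdcm.variational_laplace import _predict_batch
        from seizdcm.spectral_forward import FrequencyGrid, max_real_eigenvalue
        lay = build_layout(ModelSpec.full(), 4)
        L = np.zeros(lay.n_latents)
        L[lay.slices["g5"].start] = 6.0  # x20 excitatory drive to interneurons
        L[lay.slices["g6"].start] = 6.0
        p_unstable = CMCParameters.prior_means()
        p_unstable = p_unstable.copy(
            g=p_unstable.g * np.exp(np.array([0, 0, 0, 0, 3, 3, 0, 0, 0, 0.])))
        assert max_real_eigenvalue(p_unstable) > 0  # genuinely unstable
        base = CMCParameters.prior_means()
        penalised = _predict_batch(L[None], lay, base, FrequencyGrid())
        assert np.all(np.isfinite(penalised))

    def test_self_consistency_with_generator_features(self):
        """Prediction at the generating latents equals the noiseless
        simulated features (two independent code paths)."""
        scenario = patient1_like(seed=0, snr=np.inf)
        data, truth = simulate_spectra(scenario)
        lay = build_layout(scenario.model, scenario.n_windows)
        L = np.zeros(lay.n_latents)
        for row, name in enumerate(tb.TIME_VARYING):
            sl = lay.slices[name]
            L[sl] = truth["beta"][row, : sl.stop - sl.start]
        feats = predict(L, scenario.model, scenario.n_windows)
        assert np.allclose(feats, np.log(data.S).ravel(), atol=1e-6)


class TestFreeEnergy:
    def test_inflating_an_irrelevant_prior_lowers_f(self):
        """With the posterior held fixed, widening the prior of an
        unused latent only adds complexity."""
        scenario = patient1_like(seed=1, snr=np.inf)
        data, _ = simulate_spectra(scenario)
        spec = ModelSpec.null()
        lay = build_layout(spec, scenario.n_windows)
        q_cov = np.diag(lay.prior_variances * 0.5)
        latents = np.zeros(lay.n_latents)
        F1 = free_energy(latents, data, spec, q_cov=q_cov, h=0.0, normalize=False)
        wide = PriorSpec(lay)
        wide.variances = wide.variances.copy()
        wide.variances[lay.names.index("d8:c0")] *= 100.0
        F2 = free_energy(latents, data, spec, wide, q_cov=q_cov, h=0.0,
                         normalize=False)
        assert F2 < F1

    def test_linear_gaussian_posterior_matches_conjugate_form(self):
        from seizdcm.experiments import linear_gaussian_check
        res = linear_gaussian_check(seed=0)
        assert res["max_mean_error"] < 1e-6
        assert res["max_cov_error"] < 1e-6
        assert res["f_trace_monotone"]


@pytest.fixture(scope="module")
def noiseless_inversion():
    scenario = patient1_like(seed=5, snr=np.inf)
    data, truth = simulate_spectra(scenario)
    post = invert(data, ModelSpec.full())
    return scenario, data, truth, post


class TestInvert:

    def test_accepted_f_trace_is_nondecreasing(self, noiseless_inversion):
        *_, post = noiseless_inversion
        assert np.all(np.diff(post.F_trace) >= -1e-9)

    def test_noiseless_self_inversion_explains_all_variance(self, noiseless_inversion):
        *_, post = noiseless_inversion
        assert post.variance_explained > 0.99

    def test_posterior_intervals_calibrated_for_prior_typical_truth(self):
        """Latents drawn from the prior are recovered within 2 posterior
        SD for >= 90% of latents.  (Coverage is a prior-average
        property: strongly prior-atypical generators are shrunk beyond
        their credible intervals, and the gamma-connectivity product
        degeneracy makes per-latent intervals meaningless at unbounded
        precision, so the check uses prior-typical truth at realistic
        estimation noise.)"""
        from seizdcm.spectral_forward import FrequencyGrid
        from seizdcm.spectral_features import SpectralData
        from seizdcm.variational_laplace import _predict_batch
        spec = ModelSpec.full()
        lay = build_layout(spec, 10)
        priors = PriorSpec(lay)
        rng = np.random.default_rng(0)
        L_true = rng.standard_normal(lay.n_latents) * np.sqrt(priors.variances)
        feats = _predict_batch(L_true[None], lay, CMCParameters.prior_means(),
                               FrequencyGrid())[0]
        S = np.exp(feats.reshape(10, -1))
        k = 10.0**2 * 55  # SNR-10, 55-seizure estimation noise
        S = S * rng.gamma(k, 1 / k, size=S.shape)
        data = SpectralData(S=S, grid=FrequencyGrid(), n_seizures_averaged=55)
        post = invert(data, spec)
        within = np.abs(post.mean - L_true) <= 2.0 * post.sd()
        assert within.mean() >= 0.90

    def test_posterior_variance_never_exceeds_prior(self, noiseless_inversion):
        *_, post = noiseless_inversion
        assert np.all(np.diag(post.cov) <= post.layout.prior_variances + 1e-9)

    def test_inversion_is_bitwise_reproducible(self):
        scenario = patient1_like(seed=6)
        data, _ = simulate_spectra(scenario)
        p1 = invert(data, ModelSpec.null(), seed=0)
        p2 = invert(data, ModelSpec.null(), seed=0)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.cov, p2.cov)
        assert p1.F == p2.F

    def test_fixed_precision_disables_hyper_adaptation(self):
        scenario = patient1_like(seed=7)
        data, _ = simulate_spectra(scenario)
        post = invert(data, ModelSpec.null(), fix_precision=100.0)
        assert post.h == pytest.approx(np.log(100.0))


class TestGaussNewton:
    def test_damping_recovers_from_bad_start(self):
        """A strongly nonlinear scalar model still converges, and every
        recorded step increases F."""
        rng = np.random.default_rng(0)
        x_true = np.array([0.8])
        y = np.exp(3 * x_true) + 0.01 * rng.standard_normal(20)

        def pf(batch):
            return np.exp(3 * np.asarray(batch)) * np.ones((1, 20))

        res = gauss_newton_vl(y, lambda b: np.repeat(np.exp(3 * np.asarray(b)), 20, axis=1),
                              np.zeros(1), np.array([4.0]), fix_precision=1e4)
        assert abs(res.mean[0] - 0.8) < 0.05
        assert np.all(np.diff(res.F_trace) >= -1e-9)
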