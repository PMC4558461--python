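# Methods

This note documents the generative model, the inversion scheme, the
synthetic study conditions, and the numerical choices behind
`seizdcm`. It is the place to look when a default needs justifying.

## The generative model

A single cortical source is modelled as a canonical microcircuit of
four neuronal populations — granular (spiny stellate) cells,
superficial pyramidal cells, inhibitory interneurons and deep
pyramidal cells. Each population k has mean depolarisation `v_k` and
synaptic current `i_k` obeying the second-order synaptic kernel

    dv_k/dt = i_k
    di_k/dt = T_k * drive_k - 2 T_k i_k - T_k^2 v_k,

with rate constants `T = (250, 170, 80, 70)` Hz for (granular,
superficial, inhibitory, deep). The presynaptic drive sums firing
rates — a centred sigmoid `sigma(v) = 1/(1+exp(-gamma v)) - 1/2`,
slope `gamma/4` at rest — over ten intrinsic connections `g1..g10`
(wiring table in `cmc_model`). Connections originating from the
inhibitory population (g3: ii→ss, g4: ii→ii, g9: ii→dp) and the
recurrent gain-control connections (g1, g2, g7, g10) enter
negatively; the excitatory connections (g5: ss→ii, g6: dp→ii,
g8: ss→sp) enter positively. Exogenous (afferent) input reaches only
the granular population. Between-population terms are conducted with
a single delay `d = 1` ms; recurrent terms are instantaneous. The
centred sigmoid makes the origin an exact resting state, which is the
operating point of the spectral treatment. The sigmoid's functional
form and the exact wiring follow the standard microcircuit literature
for this model family; they are the only parts of the model not
pinned down numerically by the reference parameter table.

Because every linearised coupling carries the product `gamma * g_i`,
a uniform rescaling of the sigmoid slope against all connection
strengths leaves the spectrum exactly invariant; only the priors
break this degeneracy. This matters when interpreting per-latent
posteriors (see Testing, below).

### Spectral forward model

The model is linearised at rest and predictions live entirely in the
frequency domain. With instantaneous/delayed Jacobians `J0`, `Jd`
(analytic), input vector `B` (granular current, weight `T_1`) and an
observation row selecting depolarisations, the transfer function is

    H(w) = C (i w I - J0 - Jd e^{-i w d})^{-1} B,

the delay entering exactly through its phase factor (no Taylor
approximation — exact and cheap in the frequency domain). The
observed signal mixes superficial and deep pyramidal depolarisation
with weights `(1, c_dp)`; `c_dp` is a free parameter (prior mean 0.2,
reflecting the predominant superficial contribution to EEG).

The endogenous input is "scale-free" coloured noise with one-sided
density

    g_u(f) = a1 f^{-a2} exp( sum_k d_k psi_k(f) ),

where `psi_k` are the first eight orthonormal discrete-cosine
functions over the 1–40 Hz grid ("spectral innovations" shaping the
power law). The observed density adds a power-law measurement-noise
floor:

    S_y(f) = G |H_obs(f)|^2 g_u(f) + b1 f^{-b2}.

`G` is a fixed gain, computed once so the neuronal term averages to 1
over 1–40 Hz at prior-mean parameters. Source amplitudes after source
reconstruction are arbitrary, so this is purely a units convention;
it puts the neuronal term and the `b1 = 1` noise floor at a
physiologically sensible ~10:1 band-power ratio and is applied
consistently in the forward model and the time-domain simulator.
Spectral densities are one-sided throughout (they integrate to signal
variance over 0..Nyquist).

### Slow parameter drift

Seizure evolution is modelled as slow drift of three parameter
groups over 2 s windows: inhibitory connections {g3, g4, g9},
excitatory connections {g5, g6, g8}, and the endogenous input/noise
spectrum {a1, a2, b1, b2, d1..d8}. Each drifting parameter carries
eight orthonormal discrete-cosine coefficients over the window index
(onset-aligned, not clock time, because spectra are averaged over
seizures aligned to onset); parameters outside the allowed groups
keep only the constant component. Values map through
`theta(t) = mu exp(lambda(t))`, except the spectral innovations
`d_k`, which are additive around zero — they live in the exponent of
`g_u` already and must be signable (a log-scaling map with the
table's nominal baseline would make them strictly positive and
unable to represent fitted bump shapes). The constant cosine
component doubles as the baseline deviation, avoiding a
non-identifiable mean/constant pair.

Coefficient priors are zero-mean Gaussians: the constant component
uses the parameter's tabulated log prior variance (0.0625 for rate
and connection constants, 0.03125 for `gamma` and `d`, 0.0078125 for
the input/noise parameters), components 2–8 half that value,
encoding that synaptic drift is at least one timescale slower than
the EEG itself.

## Inversion: variational Laplace

Data features are log spectral densities stacked over windows ×
frequencies (the log stabilises the multiplicative sampling noise of
spectral estimates), with a single scalar precision `pi = exp(h)`
and a Gaussian hyperprior on `h` (mean 0, variance 16 by default —
deliberately weak, so the precision can adapt to the actual
estimation-noise scale; all such constants are exposed on
`PriorSpec`). Free energy is maximised by Gauss–Newton ascent with
Levenberg–Marquardt damping: steps are accepted only if F rises,
damping doubles on rejection and halves on acceptance; prediction
gradients are central finite differences (step 1e-3), so inversions
are bit-for-bit reproducible. Convergence: improvement < 0.01 nats
on three consecutive accepted steps, or 128 iterations.

Numerical details that matter:

* All curvature quantities are computed from the eigenvalues of the
  prior-whitened Gauss–Newton matrix, making the hyper-parameter
  update and each candidate's F evaluation O(p) and keeping
  log-determinants stable when the precision is extreme.
* The log-precision Newton update is damped (steps clipped to ±2,
  iterated to a fixed point): the raw Newton step from `h = 0`
  overshoots by tens of nats.
* The F recorded per accepted step accumulates improvements, each
  measured under a single linearisation, so the trace is monotone by
  construction; the reported final F is evaluated at the final
  linearisation.
* Finite-difference batches are evaluated through a vectorised
  forward model (batched 8x8 complex solves over all windows,
  frequencies and perturbations at once); a full-model inversion of
  10 windows x 40 frequencies (155 latents) takes a few seconds.
* If a parameter excursion destabilises the linearisation
  (max Re eig of `J0+Jd` above -1 /s), the affected window's
  features are smoothly penalised rather than failing, which steers
  the optimiser back without breaking differentiability.
* Data in arbitrary units (external recordings) are rescaled once so
  their mean log density matches the prior prediction; model-scale
  data (the package's own simulators) are not rescaled.

Model comparison is fixed-effects: free energies are reported
relative to the null model and converted to posterior model
probabilities under uniform model priors; a difference of 3 nats
corresponds to posterior odds of about 20:1. The excitation–
inhibition read-out summarises each group by the mean per-window
log-scaling over its three connections (the symmetric choice, since
the group is reported as a single curve), and balance is excitatory
minus inhibitory — the sign convention is documented here and
configurable downstream.

## Spectral features from EEG

Recordings are common-average re-referenced (multichannel), band-pass
filtered 0.5–70 Hz (5th-order Butterworth, zero-phase) and notched at
50 Hz (Q = 30). Each seizure is cut into non-overlapping 2 s windows
from onset; trailing partial windows are discarded (zero-padding
would leak). Per-window densities come from a ridge-regularised
AR fit (shrinkage 1e-3 relative to the mean regressor variance;
unstable fits have roots reflected into the unit circle), rescaled so
the density integrates to the segment variance. The AR order default
is 12: order 8 cannot track the steep 1/f rise plus two resonances
and leaves a structured ~20% bias against the analytic forward
spectrum, while order 12 agrees with it to ~10% at the 55-seizure
scale. Spectra are averaged across seizures per aligned window
index; seizures shorter than the longest contribute to the windows
they have (per-window counts are recorded), which preserves
late-seizure windows instead of truncating everything to the
shortest event.

The 2 s window itself can be re-derived from data: the longest
candidate whose windowed description retains 90% of the spectral
power of a complex-Gaussian-wavelet time–frequency estimate. The
retention statistic is the power-weighted overlap between
instantaneous and window-averaged normalised spectra, after 2 s
smoothing of the wavelet power (unsmoothed wavelet power of
stochastic signals fluctuates enough to mask genuine stationarity).

## Synthetic study conditions

No clinical recordings are distributed, so the generator defines the
study conditions. Two presets mirror the two archetypal cases:
`patient1-like` (20 s seizures, 10 windows, 55 events averaged,
activity drifting 20→10 Hz) and `patient2-like` (60 s, 30 windows,
2 events, 12→5 Hz). Ground-truth drift:

* inhibitory bump: Gaussian in window index, centre 2.5, width 1.8
  windows, log-amplitude 0.5;
* excitatory bump: centre 5.5, width 1.5, log-amplitude 0.5
  (the sequential inhibitory → excitatory → balance peaking);
* input gain ramp: `lambda_a1` rising to 0.8 (the amplitude increase
  toward termination);
* input exponent ramp: `lambda_a2` rising to 0.25 (a global tilt of
  the afferent spectrum);
* input chirp: a Gaussian bump on the log input spectrum, width 6 Hz,
  log-amplitude 0.3, centre falling 20→10 Hz, projected onto the
  eight spectral-innovation functions by least squares.

The bump amplitudes are comparable to the log-scaling excursions the
method is expected to resolve; the innovation excursion is kept
within reach of its tight prior (log variance 1/128) — conditions
requiring many-sigma prior excursions would describe data the model
family itself deems implausible. The exponent ramp gives the
endogenous group a spectrally global signature that intrinsic gain
changes cannot mimic; without it, a gain-only drift of the input is
nearly absorbed by connectivity and the model comparison cannot
separate the full model from the inhibitory+excitatory one.

Per-window curves are projected through the 8-component cosine basis,
so the recorded ground truth is exactly representable by the model
family; recovery tests compare against this projection.

The fast route (`simulate_spectra`) multiplies noiseless predicted
spectra by gamma-distributed estimation noise with shape
`snr^2 * n_seizures` (relative spread `1/(snr sqrt(n))`, matching the
sampling behaviour of averaged spectral estimates better than
additive Gaussian noise). The slow route (`simulate_timeseries`)
integrates the nonlinear delay equations at 2048 Hz (RK4; the
delayed state is interpolated per stage — holding it constant over a
step adds half a step of effective delay and a visible transfer
bias), drives them with per-window coloured noise synthesised from
the ground-truth input spectrum (100 ms crossfades at window
boundaries, matching the 100 ms parameter ramps), adds measurement
noise with the model's power-law floor, and resamples to 256 Hz. At
prior-mean operating points depolarisations stay well inside the
sigmoid's linear range, so the linearised forward model describes
the nonlinear simulation to within Welch-estimation error; the two
routes agree to ~10% RMS per window at the 55-seizure scale, and
this cross-validation is a standing test.

What the generator does **not** emulate: volume conduction and
multichannel scalp mixing (source reconstruction is upstream and out
of scope), artefacts, non-stationarity within windows beyond the
parameter ramps, inter-seizure variability of the drift curves, and
any departure of real neural noise from the Gaussian/power-law
family. Passing the recovery studies therefore demonstrates internal
consistency of model + inversion under the stated conditions — not
performance on clinical EEG.

## Testing and known limitations

Problem sizes in the test-suite and acceptance studies are the preset
conditions themselves: 10-replicate studies of the 10-window,
55-seizure patient1-like preset (all eight models inverted per
replicate), 200 s linear-simulation checks of the transfer function,
and single full-scale slow-route cross-validations.

Known limitations, deliberate:

* Per-latent posterior intervals are not interpretable on noiseless
  data (the gamma–connectivity degeneracy has exactly zero curvature)
  and do not cover strongly prior-atypical generators; interval
  calibration is asserted for prior-typical truth, point recovery for
  the seizure-like truth.
* A single scalar observation precision is shared across windows and
  frequencies; heteroscedastic estimation noise (worse at low
  frequencies for AR estimates) is not modelled.
* Fixed-effects model comparison only — appropriate for within-source
  analyses, not group studies.
* The AR feature extractor is a point estimate with fixed shrinkage;
  full hierarchical autoregressive inference is out of scope.
* Cross-spectra between sources are out of scope (single-source
  model); the pipeline fits real auto-spectral densities.
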