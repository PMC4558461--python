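"""Generate seizure-like data with known ground truth, two ways.

The fast route evaluates the spectral forward model per 2 s window;
the slow route integrates the nonlinear delay equations and runs the
output through the same feature pipeline used for real EEG
(band-pass, notch, windowed autoregressive spectra, averaging over
seizures). The two should agree — a standing cross-check of the
whole generative stack.
"""

import numpy as np

from seizdcm import build_spectral_data, patient1_like, simulate_spectra, \
    simulate_timeseries

scenario = patient1_like(seed=0, n_seizures=8)
print(f"scenario: {scenario.label}, {scenario.duration_s:.0f} s seizures, "
      f"{scenario.n_seizures} events, {scenario.n_windows} windows")

data_fast, truth = simulate_spectra(scenario)
seizures, _ = simulate_timeseries(scenario)          # ~15 s of integration
data_slow = build_spectral_data(seizures, scenario.fs)

print("\nwindow  peak f (fast)  peak f (slow)  route RMS diff")
for w in range(scenario.n_windows):
    rel = (data_slow.S[w] - data_fast.S[w]) / data_fast.S[w]
    print(f"{w:6d} {data_fast.grid.f[np.argmax(data_fast.S[w])]:13.0f} "
          f"{data_slow.grid.f[np.argmax(data_slow.S[w])]:14.0f} "
          f"{100 * np.sqrt(np.mean(rel ** 2)):13.1f}%")

li = np.mean([truth["lambda"][n] for n in ("g3", "g4", "g9")], axis=0)
le = np.mean([truth["lambda"][n] for n in ("g5", "g6", "g8")], axis=0)
print("\nground-truth log scalings (what inversion should recover):")
print("  inhibitory:", np.round(li, 2))
print("  excitatory:", np.round(le, 2))
print("peaks: inhibitory at window %d, excitatory at window %d"
      % (li.argmax(), le.argmax()))
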