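"""Excitation-inhibition balance and spectral read-outs of a seizure.

Inverts the full model on synthetic averaged-seizure spectra and
derives the scientific read-outs: the inhibitory/excitatory
log-scaling time courses and their balance (difference), and the
reconstructed time-frequency surfaces of the observed response and
the afferent input. The canonical pattern is a transient inhibitory
rise, then an excitatory rise, then a final balance peak toward
seizure termination.
"""

import numpy as np

from seizdcm import ModelSpec, balance_timecourse, invert, patient1_like, \
    reconstruct, simulate_spectra

data, truth = simulate_spectra(patient1_like(seed=1))
post = invert(data, ModelSpec.full())
print(f"variance explained: {post.variance_explained:.4f}")

bc = balance_timecourse(post)
print("\nwindow  inhibitory  excitatory   balance   (log scalings +/- 2 SD)")
for w in range(post.n_windows):
    print(f"{w:6d} {bc['inhibitory'][w]:+10.3f} {bc['excitatory'][w]:+11.3f} "
          f"{bc['balance'][w]:+9.3f}   "
          f"(+/- {2 * bc['sd_inhibitory'][w]:.3f}/"
          f"{2 * bc['sd_excitatory'][w]:.3f}/{2 * bc['sd_balance'][w]:.3f})")
print("peak order: inhibitory w%d -> excitatory w%d -> balance w%d"
      % (bc["inhibitory"].argmax(), bc["excitatory"].argmax(),
         bc["balance"].argmax()))

rec = reconstruct(post)
from seizdcm import CMCParameters, FrequencyGrid, predicted_spectrum
baseline = predicted_spectrum(CMCParameters.prior_means(), FrequencyGrid())
change = rec["observed"] / baseline  # response relative to the resting spectrum
print("\nreconstructed response relative to baseline (the time-frequency "
      "read-out):")
for w in range(post.n_windows):
    f_peak = rec["frequencies"][np.argmax(change[w])]
    print(f"  window {w}: strongest change at {f_peak:4.0f} Hz "
          f"(x{change[w].max():.2f} power)")
print("Fast (beta-band) activity dominates while the connectivity bumps "
      "peak, then the emphasis shifts to low frequencies toward "
      "termination — the falling-frequency signature of seizure offset.")
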