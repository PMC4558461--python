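"""The end-to-end pipeline as it would run on clinical exports.

Writes synthetic seizures to delimited-text recordings (the format a
clinical EEG export or source-reconstruction step would produce),
then runs the full analysis from files: feature extraction, a model
subset, comparison, read-outs — everything lands in an output
directory with a manifest.

Runtime: ~1 minute.
"""

import json
from pathlib import Path

from seizdcm import RunConfig, run_analysis, simulate_timeseries, \
    stationary_scenario, build_spectral_data
from seizdcm.spectral_features import SpectralData

workdir = Path("scratch-example-run")
workdir.mkdir(exist_ok=True)

# a short stationary recording standing in for a pre-ictal control export
scenario = stationary_scenario(seed=0, duration_s=20.0, n_seizures=2)
seizures, _ = simulate_timeseries(scenario)
data = build_spectral_data(seizures, scenario.fs)
data.to_csv(workdir / "spectra.csv")

cfg = RunConfig(spectra_csv=str(workdir / "spectra.csv"),
                models=["inhibitory + excitatory + endogenous", "null"],
                seed=0, out_dir=str(workdir / "analysis"), figures=False)
manifest = run_analysis(cfg)

print("stages:", manifest["stages"])
print("winning model:", manifest["winning_model"])
print("free energies:", json.dumps(manifest["free_energies"], indent=2))

import pandas as pd
traj = pd.read_csv(workdir / "analysis" / "trajectories.csv")
drift = traj[["inhibitory", "excitatory"]].abs().max().max()
print(f"\nmax |connectivity log scaling| on this control data: {drift:.3f}")
print("With only two events the spectral estimates are noisy, so the "
      "flexible model may still edge out the null by fitting estimation "
      "structure — but the inferred connectivity drift stays small, the "
      "control-condition signature (compare a seizure run, where it "
      "reaches ~0.4).")
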