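"""Fit the shared-kernel temporal-stretch encoding model and recover its parameters.

Simulates noiseless chirp responses for 60 ROIs in 4 scan fields, where each
ROI's response is a shared temporal kernel stretched by a factor set by its
IPL depth (unimodal speed profile peaked at the IPL centre) plus an additive
per-field shift. Two model variants are then fitted from scratch:

* per-ROI stretch — one shared kernel, one free stretch per ROI;
* depth + batch   — stretch tied to depth bins (xi) plus batch shifts (psi).
"""

import numpy as np
from scipy.stats import pearsonr

from iplscan import encoding, synth
from iplscan.stimulus import generate_chirp

stim = generate_chirp()
cfg = synth.PopulationConfig(noise_sigma=0.0, psi_sd=0.15)
population, truth = synth.sample_population(n_roi=60, n_batch=4, config=cfg, seed=5)
traces = synth.simulate_traces(population, truth, stim, repeats=1, seed=6)
table = synth.population_table(population)
covariates = encoding.StretchCovariates.from_table(table)

model = encoding.fit_model(
    "per_roi_stretch", traces.clean, stim.samples, covariates, seed=0
)
alpha_true = table.stretch.to_numpy()
rel_err = np.abs(model.alpha - alpha_true) / alpha_true
print(f"per-ROI stretch fit: mean E.V. {100 * model.mean_ev:.1f}%")
print(f"  stretch recovery: max relative error {100 * rel_err.max():.3f}% "
      f"(every ROI's speed recovered)")

batch_model = encoding.fit_model(
    "depth_plus_batch", traces.clean, stim.samples, covariates, seed=0
)
r = pearsonr(batch_model.psi, truth.psi).statistic
print(f"\ndepth+batch fit: mean E.V. {100 * batch_model.mean_ev:.1f}%")
print(f"  injected vs fitted batch shifts correlate at r = {r:.3f}")

profile, psi_table = encoding.speed_profile(batch_model)
occupied = profile[profile.n_roi > 0].sort_values(["polarity", "bin"])
print("\nspeed profile across the IPL (stretch per occupied depth bin):")
for row in occupied.itertuples():
    print(f"  {row.polarity:3s} bin {row.bin} (depth {row.depth_mid:+.2f}): "
          f"stretch {row.stretch:.2f}  ({row.n_roi} ROIs)")
print("stretch peaks at the IPL centre and falls toward the borders — the "
      "laminar speed gradient — while psi captures the per-field shifts.")
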