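"""Neuron-dropping curve and its saturating-exponential asymptote fit.

Decoding accuracy is measured on random subsets of units (increments of
10, 5 draws each, 20-fold stratified CV) and the curve
``y(k) = c + (A - c) * (1 - w e^{-k/tau1} - (1-w) e^{-k/tau2})`` with
chance c = 1/12 fixed is fit to estimate the asymptotic accuracy A —
the performance the population would support with unlimited units.
"""

import numpy as np

from livesort import make_probe, make_units, make_trials, simulate_trains
from livesort.evaluate import bin_counts, dropping_curve, fit_asymptote

geom = make_probe(30)
units = make_units(geom, 30, seed=8, kappa=2.5, depth=2.5)
trials = make_trials(80, seed=9)
duration = trials["onset_sample"].max() / 30000.0 + 3.0
truth = simulate_trains(units, duration, trials, seed=10, geometry=geom)

counts, centers = bin_counts(truth.trains(), trials["onset_sample"].to_numpy(), truth.fs)
window = (centers >= 50) & (centers <= 400)  # post-onset response window
features = counts[:, :, window].mean(axis=2)

# step 5 instead of the default 10 so the 30-unit curve has enough points
# for the 4-parameter asymptote fit
curve = dropping_curve(features, trials["direction_deg"].to_numpy(), seed=0, step=5)
fit = fit_asymptote(curve)

print("units  accuracy  sem")
for k, a, s in zip(curve.unit_counts, curve.mean_accuracy, curve.sem):
    print(f"{k:5d}  {a:8.3f}  {s:.3f}")
print(f"\nasymptote A = {fit.A:.3f} (w={fit.w:.2f}, tau1={fit.tau1:.1f}, "
      f"tau2={fit.tau2:.1f}, converged={fit.converged})")
print("A is the decoding accuracy this population saturates to as units grow.")
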