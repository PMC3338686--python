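"""Simulate a year-long monitoring campaign and recover profiles from raw peaks.

Generates 24 samples at 15-day intervals with three dominant T-RFs
(219/354/491 bp) responding unimodally to temperature, plus sub-2% spurious
peaks and sizing jitter, then runs the preprocessing chain (size window,
binning, relative abundance, 2% noise floor) and compares the recovered
profiles with the planted truth.
"""

import numpy as np

import trflpdyn as t

scenario = t.default_scenario(seed=42)
env, true_series, peaks = t.simulate_campaign(scenario)
print(f"rendered {len(peaks)} peaks across {scenario.n_samples} samples "
      f"({scenario.n_noise_peaks} noise peaks/sample)")

series, env_aligned = t.preprocess_peaks(peaks, env)
print(f"recovered bins: {series.bin_labels}")

err = np.abs(series.matrix().to_numpy() - true_series.matrix().to_numpy()).max()
print(f"max |recovered - true| relative abundance: {err:.2e}")
removed = max(p.removed_mass for p in series)
print(f"largest per-sample mass removed by the 2% noise floor: {removed:.3f}")
# The noise floor removes only the planted spurious peaks, so renormalized
# profiles reproduce the true compositions to machine precision.
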