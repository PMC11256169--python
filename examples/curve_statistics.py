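"""Fluorescence-curve kinetics on synthetic plate-reader data.

Generates a reproducible synthetic dataset (GFP signal rising toward a
plateau, production programmed to stop at day 4, background wells, Gaussian
noise), then recovers the stop time via the central-difference rule, the
log-log rate constant, and a culture doubling time from an exponential
growth curve.
"""

import numpy as np

from dermasim.curves import (
    SyntheticCurveParams,
    fit_doubling_time,
    generate_synthetic_curves,
    production_stop_time,
    rate_constant,
    subtract_background,
)

params = SyntheticCurveParams(stop_time_days=4.0, noise_sd=5.0, n_samples=8, seed=7)
raw = generate_synthetic_curves(params)
corrected = subtract_background(raw, "background")

stop = production_stop_time(corrected.timepoints, corrected.values.mean(axis=0))
print(f"programmed production stop: {params.stop_time_days} d, "
      f"detected (first negative derivative): {stop:.2f} d")

stats = rate_constant(corrected)
print(f"log-log rate constant (mean slope over {len(stats.per_sample_slopes)} wells): "
      f"{stats.rate_constant:.3f} (higher = faster GFP accumulation)")

t_min = np.arange(0, 400.0, 10)
od = 0.01 * 2 ** (t_min / 40.0) * np.exp(np.random.default_rng(1).normal(0, 0.02, t_min.size))
td = fit_doubling_time(t_min, od)
print(f"doubling time from mid-exponential fit: {td:.1f} min (true 40.0)")
print("-> the stop-time call is exact to the sampling grid; slope statistics "
      "recover their programmed values within noise.")
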