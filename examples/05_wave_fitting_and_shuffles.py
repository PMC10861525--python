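"""Fit the wave model per neuron, then destroy the structure by shuffling.

Per-trajectory Gaussian fits recover the generative parameters exactly on
noise-free data; a condition-swap shuffle preserves every single trace but
degrades the dataset-level rotation measured by the gyration number.
"""

import numpy as np

from rotwave import (
    ShuffleSpec,
    WaveModelParams,
    fit_dataset,
    generate_dataset,
    gyration_pipeline,
    shuffle,
    summarize_fits,
)

ds = generate_dataset(WaveModelParams(n_neurons=80, n_time=200, n_conditions=4, a=20.0))
table = fit_dataset(ds)
summary = summarize_fits(table)
slope, intercept = np.polyfit(table["neuron_index"], table["peak_time"], 1)
print(f"wave fits: median R^2 = {summary['r2_median']:.6f}, "
      f"{summary['frac_converged']:.0%} converged")
print(f"fitted peak times regress to slope {slope:.4f} (true b=1.0), "
      f"intercept {intercept:.2f} (true a=20.0)")

y0 = gyration_pipeline(ds).y
ys = [gyration_pipeline(shuffle(ds, ShuffleSpec("condition_swap", seed=s))).y
      for s in range(10)]
print(f"gyration rotation coordinate: {y0:.3f} before shuffling, "
      f"{np.mean(ys):.3f} after condition_swap (mean of 10 seeds)")
print("the drop shows the measure reads cross-condition structure, "
      "not single-neuron shapes")
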