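"""Classical single-trial synchrony measures on the square-wave design.

Computes the three comparison measures — windowed mean pairwise Pearson
correlation of smoothed trains, spiking regularity (ISI coefficient of
variation), and average order-3 mark-CIF difference from independence — on a
simulation whose latent 3rd-order coordination alternates every 4000 bins.
None of the three resolves the alternating structure as sharply as the
model-based J statistic; that contrast is the point of the comparison.
"""

import numpy as np

from hocoord import (
    avg_pairwise_correlation,
    estimate_mu,
    mark_cif_difference,
    reliable_marks,
    spiking_regularity,
)
from hocoord.model import ModelParams
from hocoord.simulator import make_example1

sim = make_example1(seed=7, T=8000)

corr = avg_pairwise_correlation(sim.raster, smoothing_sd=5, window=200)
reg = spiking_regularity(sim.raster, window=200)
print("window-of-200 measures (facilitation epoch -> suppression epoch):")
for k in (5, 15, 25, 35):
    print(f"  window {k:2d}: corr = {corr.value[k]: .3f} "
          f"[{corr.ci_low[k]: .3f}, {corr.ci_high[k]: .3f}] | "
          f"CV = {reg.value[k]:.2f} +- {(reg.ci_high[k] - reg.value[k]):.2f}")
print("correlations stay positive throughout (bursts synchronize pairs); the"
      "\nCV stays near 1 (Poisson-like), neither isolates the 3rd-order state.")

# mark-CIF difference needs a fitted model: history-free fit, middle window
space = reliable_marks(sim.marked, 1)
hf = estimate_mu(sim.marked, W=10, beta=0.975, markspace=space)
for k, label in ((300, "facilitation"), (700, "suppression")):
    params = ModelParams(hf.marks, 5, 0, hf.mu[k][:, None])
    diff = mark_cif_difference(params, np.ones((1, 1)), r=3)
    print(f"order-3 mark-CIF difference, {label} window {k}: "
          f"{diff.value[0]:+.2e} +- {(diff.ci_high[0] - diff.value[0]):.1e}")
# positive during facilitation, near zero during suppression, but on the raw
# probability scale with wide bands - harder to threshold than the J trace.
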