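"""Attributing coordination to ensemble history versus exogenous drives.

The square-wave design superimposes two kinds of higher-order coordination:
3rd-order patterns driven exogenously (a square wave alternately facilitates
and suppresses them every 4000 bins) and 4th-order coincidences that emerge
endogenously from a shared self-exciting history kernel (population bursts).
History-independent inference flags both; history-dependent inference keeps
only the exogenous one — the complementary readings that let the method
attribute coordination to network history or to an unobserved process.

Runs in a couple of minutes (the history-dependent pass refits 1600 windows).
"""

import numpy as np

from hocoord import run_inference
from hocoord.simulator import make_example1

sim = make_example1(seed=7)
m = sim.marked

r3_static = run_inference(m, r=3, W=10, beta=0.975, alpha=0.01, history=False)
r4_static = run_inference(m, r=4, W=10, beta=0.975, alpha=0.01, history=False)
r4_hist = run_inference(m, r=4, W=10, beta=0.975, alpha=0.01,
                        p=2, s=10, n_thr=1, history=True, raster=sim.raster)

K = r3_static.n_windows
epoch = (np.arange(K) * 10) // 4000
keep = np.arange(K) >= 40  # discard the filter burn-in
fac = (epoch % 2 == 0) & keep
sup = (epoch % 2 == 1) & keep

print("history-INDEPENDENT inference:")
print(f"  J(3) > 0.5 in {100 * (r3_static.J[fac] > 0.5).mean():.0f}% of "
      f"facilitation-epoch windows")
print(f"  J(3) > 0.5 in {100 * (r3_static.J[sup] > 0.5).mean():.0f}% of "
      f"suppression-epoch windows")
print(f"  J(4) > 0.5 in {100 * (r4_static.J[keep] > 0.5).mean():.0f}% of all "
      f"windows  (burst coincidences exceed static independence)")
print("history-DEPENDENT inference:")
print(f"  |J(4)| <= 0.1 in {100 * (np.abs(r4_hist.J[keep]) <= 0.1).mean():.0f}% "
      f"of windows  (4th-order coordination explained by ensemble history)")
print("\nReading: the 3rd-order drive is exogenous (detected by both models); "
      "the 4th-order structure is endogenous (detected only when history is "
      "ignored).")
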