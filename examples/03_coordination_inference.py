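"""Testing for exogenous higher-order coordination with the deviance test.

Simulates a 5-neuron validation ensemble in which a 3rd-order pattern is
exogenously facilitated during the second half, runs the full
history-dependent inference pipeline (Algorithm: adaptive full fit ->
exogenous factors -> Kalman smoothing -> constrained reduced fit -> de-biased
deviance -> non-centrality smoothing -> signed J), and prints the per-window
test summaries before and after the step.
"""

import numpy as np
from scipy.stats import chi2

from hocoord import run_inference
from hocoord.simulator import make_validation

sim = make_validation(n_realizations=1, T=4000, seed=1)[0]
res = run_inference(sim.marked, r=3, W=10, beta=0.99, alpha=0.01,
                    p=2, s=2, n_thr=1, history=True, raster=sim.raster)

print(f"testing {res.M} third-order patterns; "
      f"rejection threshold chi2({res.M}) at 1% = {chi2.ppf(0.99, res.M):.1f}")
print("\nwindow    D      nu     J    sum(gamma~)")
for k in (150, 199, 215, 250, 320, 390):
    print(f"{k + 1:5d} {res.D[k]:7.1f} {res.nu[k]:7.1f} {res.J[k]: .2f}  "
          f"{res.gamma_smooth[k].sum(): .2f}")

first = res.D[125:200]
print(f"\nnull half: mean D = {first.mean():.1f} (chi2 mean {res.M}), "
      f"no rejections expected at 1%")
print(f"driven half: median smoothed non-centrality = "
      f"{np.median(res.nu[250:]):.0f}")

# The sign of J comes from the NET exogenous factor over all tested marks.
# Only one of the ten 3rd-order patterns is driven here: its gamma is large
# and positive, but the drive also raises the participating neurons' rates,
# pushing the other nine patterns slightly below their (now higher)
# independence prediction - so the net sign can be negative even though the
# rejection is caused by facilitation.  Testing the driven pattern alone
# (the nested test accepts any mark subset) gives the clean reading:
single = run_inference(sim.marked, r=None, tested_marks=np.array([7]),
                       W=10, beta=0.99, alpha=0.01, p=2, s=2, n_thr=1,
                       history=True, raster=sim.raster)
print(f"\nsingle-pattern test of the driven mark 7: late-window J = "
      f"{single.J[380:].mean():+.2f} (facilitation, saturating at "
      f"+{1 - single.alpha:.2f})")
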