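# hocoord — dynamic inference of higher-order spiking coordination

`hocoord` asks a precise question about simultaneously recorded neurons: when
several of them spike in the *same* time bin, is that coordination, or chance?
And if it is coordination, is it explained by the ensemble's own spiking
history, or driven by something unobserved?  The package answers this window
by window on a single continuous recording — no repeated trials — for
coincidences of any order r (pairs, triples, quadruples, …), which is exactly
where classical pairwise synchrony measures stop.

It is a library for neurophysiologists and methods researchers analyzing
binned multi-neuron spike data (multi-electrode recordings, or simulated
ensembles), plus a thin command-line interface.

## The model and the test

Binned spiking of C neurons is mapped to a **discretized marked point
process**: each bin holds either no event or exactly one of the
C\* = 2^C − 1 disjoint simultaneous-spiking patterns ("marks"; neuron c is
the c-th bit of the mark index).  Mark rates follow a multinomial logistic
GLM with the no-event outcome as reference,

    λ*_t(m)Δ = exp(x_t'ω(m)) / (1 + Σ_j exp(x_t'ω(j))),

where x_t is the ensemble spiking history up to lag p (or just a constant,
for the history-independent model) and ω(m) = (μ(m), θ(m)) are a base rate
and history kernel per mark.  Parameters are piecewise constant over windows
of W bins and tracked by maximizing the forgetting-factor likelihood
ℓ_k^β(ω) = (1−β) Σ_{i≤k} β^{k−i} ℓ_i(ω) with **AdOMP** — adaptive orthogonal
matching pursuit: per window, greedy selection of an s-sparse history support
followed by a warm-started concave refit, with all weighted statistics
maintained by exact O(1)-per-window recursions.

To test r-th order coordination, the fitted model's log-odds u_t(m) of each
order-r mark are compared with the conditional-independence prediction
u0_t(m) = Σ_{c∈m} logit(λ_t(c)Δ) built from the same model's per-neuron
rates.  The window-averaged gap γ_k(m) — the **exogenous factor** — is
Kalman-smoothed; a reduced model pins the tested base rates at their
independence-implied values, and the **adaptive de-biased deviance**

    D_k = (1+β)/(1−β) · [ 2(ℓ_k^β(full) − ℓ_k^β(reduced)) − ΔB_k ]

is asymptotically χ²(M) under the null (M = number of tested marks) and
non-central χ²(M, ν_k) under the alternative.  The smoothed non-centrality
ν̂_k gives a signed Youden statistic J_k ∈ [−(1−α), 1−α]: 0 when the null is
retained, near ±(1−α) for strongly facilitated/suppressed coordination.
Running the test with and without history covariates separates *endogenous*
coordination (explained by ensemble history) from *exogenous* coordination
(an unobserved driver).

## A worked example

```python
import numpy as np
from hocoord import run_inference
from hocoord.simulator import make_validation

# five independent neurons; one 3rd-order pattern exogenously facilitated
# during the second half of the recording
sim = make_validation(n_realizations=1, T=4000, seed=1)[0]
res = run_inference(sim.marked, r=3, W=10, beta=0.99, alpha=0.01,
                    p=2, s=2, n_thr=1, history=True, raster=sim.raster)
print(res.M)                            # 10 tested third-order patterns
print(round(res.D[125:200].mean(), 1))  # 6.2   null half: D ~ chi2(10)
print(round(np.median(res.nu[250:])))   # 101   driven half: non-centrality
```

The null-half deviances fluctuate around the central χ²(10) law (no window
rejects at α = 0.01), while the facilitated half carries a smoothed
non-centrality near 100 — decisive rejections, with the J statistic
saturating at ±0.99.  Testing the driven pattern alone
(`tested_marks=np.array([7])`) yields `J = +0.99` in late windows: strong
exogenous *facilitation*.  The same pipeline run on
`hocoord.simulator.make_example1()` (square-wave 3rd-order drive plus
endogenous, history-generated 4th-order bursts) reproduces the attribution
contrast: history-independent inference flags 4th-order coordination in 75%
of windows, history-dependent inference reduces it to |J| ≤ 0.1 in 97% of
windows — see `examples/04_attribution_endogenous_vs_exogenous.py`.

The `examples/` directory holds five short narrative scripts (marked
representation, adaptive filtering, the deviance test, endogenous-vs-
exogenous attribution, and the baseline synchrony measures).  The CLI
mirrors the library:

```bash
hocoord simulate --preset example1 --seed 7 --out sim/
hocoord infer sim/raster.txt -r 3 -r 4 --no-history --out out/
hocoord baselines sim/raster.txt --out out/
```

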