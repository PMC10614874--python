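# Methods

This note documents the statistical model, the estimation and testing
procedures, the synthetic study designs, and the numerical choices made in
`hocoord`, at the level of detail a user needs to judge what a passing test
suite does and does not establish.

## Model

**Representation.** Binned ensemble spiking `n_t ∈ {0,1}^C` is mapped to a
disjoint marked Bernoulli series: bin t holds no event or exactly one mark
`m ∈ {1, …, 2^C−1}`, the binary encoding of the coincidence pattern (neuron
c ↔ bit c).  The ground process (any event) has probability equal to the sum
of mark probabilities, and neuron c's spike train is recovered exactly as
the sum of the marks whose c-th bit is set.  The representation is lossless;
its value is that *simultaneous* spiking becomes an explicit categorical
outcome rather than a violation of point-process regularity.

**Likelihood.** Mark probabilities follow a multinomial logistic GLM with
the no-event outcome as the reference category.  Covariates are
`x_t = [1, n_{t−1}(1)…n_{t−p}(1), …, n_{t−1}(C)…n_{t−p}(C)]` (binary raster
history, zero-padded before lag p; the raster rather than the marked series
keeps the dimension at 1 + C·p).  The history-independent model is the
special case p = 0.  Mark space is pruned to "reliable" marks with more than
`n_thr` events in the recording; pruned marks are dropped from the model —
their rates are treated as exactly zero, and bins containing a pruned-mark
event count as no-event bins (such events are, by construction, rarer than
`n_thr` occurrences).  Whether a mark is reliable is decided on the whole
recording, before any windowing.

**Time variation.** Parameters are piecewise constant over windows of W bins
and estimated per window k by maximizing the forgetting-factor likelihood
`ℓ_k^β = (1−β) Σ_{i≤k} β^{k−i} ℓ_i`, an exponentially weighted sum of window
log-likelihoods with effective memory `N_eff = W/(1−β)` bins.  Defaults
throughout the studies: `W = 10`, `β = 0.99` (N_eff = 1000) or `β = 0.975`
(N_eff = 400) for designs whose shortest latent state lasts ~4000 bins — the
rule of thumb being N_eff of roughly a tenth of the shortest state.

**Exact recursions.** Because the covariates are binary, `ℓ_k^β` depends on
the past only through (a) exponentially weighted covariate sums at event
bins (one vector per mark) and (b) an exponentially weighted histogram of
*distinct covariate patterns*.  Both admit exact O(1)-per-window updates, so
the weighted log-likelihood and its gradient are evaluated at cost
proportional to the number of distinct patterns, not the recording length,
and agree with the direct sums to double precision (this equivalence is a
tested contract).  Patterns whose accumulated weight has decayed below
1e−12 of the maximum are periodically dropped.

## Estimation (AdOMP)

Per window: fold the new data into the recursions; warm-start the support
from the previous window and drop history coefficients that have collapsed
below 1e−8; greedily add, per mark, the inactive coordinate with the largest
absolute weighted-likelihood gradient until each mark holds `s` history
coefficients; refit over the active support.  Base rates are never
sparsified.  The refit maximizes the concave objective with bounded
L-BFGS (a gradient-ascent-with-backtracking variant is available; the
optimizer choice only affects tolerances, not the optimum):

- base rates bounded to [−20, 5] log-odds — a mark with no events in the
  effective window has an unbounded MLE; −20 is the same floor the
  closed-form history-free estimator uses;
- history coefficients bounded to [−10, 10] and, in the inference pipeline,
  ridge-penalized at 0.1 on the accumulated-likelihood scale.  Binary
  covariates plus rare marks make quasi-separation routine, and an
  unpenalized separating coefficient runs to its bound and corrupts the
  fitted log-odds; 0.1 is small enough to leave data-rich kernels
  essentially unshrunk (the null calibration below was verified at this
  value; a ridge of 1.0 visibly biases the strong recurrent kernels of the
  square-wave design);
- convergence is declared on the projected gradient (1e−6 by default;
  1e−4 in the windowed pipeline, far below the deviance resolution), with
  up to two L-BFGS restarts near flat optima.

The sparsity budget `s` applies per mark.  `cross_validate_sparsity` scores
candidates prequentially — window k predicted with the window k−1 estimate,
a temporal split at every boundary, so dependent history never leaks — and
breaks ties toward sparser models.  On pure-noise history it selects the
smallest candidate; on planted sparse kernels it selects a nonzero budget
(both tested).

The history-free model is fitted in closed form (the weighted MLE
moment-matches the exponentially weighted empirical frequencies); a
gradient-based solver is kept as an independent oracle and agrees to 1e−6.

## The coordination test

For tested marks (the order-r set intersected with the reliable set, or any
user-supplied subset), the full model's log-odds `u_t(m) = x_t'ω̂(m)` are
compared with the conditional-independence prediction
`u0_t(m) = Σ_{c∈m} logit(λ̂_t(c)Δ)`, with per-neuron intensities summed from
the same fitted model's mark CIFs.  The exogenous factor
`γ̂_k(m) = mean_t(u_t − u0_t)` over window k is a smooth function of the
fitted parameters, so under the null it fluctuates at estimator scale.

**Reduced model.** The null-rate trace `μ̂_k(m) − γ̂_k(m)` is smoothed by a
fixed-interval random-walk Kalman smoother and the reduced model pins the
tested base rates at the smoothed values (equivalently `μ̂ − γ̃`, but
smoothing the null-rate trace rather than γ alone stays stable when a rare
mark's base-rate estimate jumps between its floor and a post-event value).
The reduced pass re-estimates everything else over the *same* per-window
history support the full pass selected: letting the two passes select
supports independently injects greedy path noise into the likelihood gap
(the reduced fit can even out-score the full one); sharing the support
guarantees ℓ_R ≤ ℓ_F and removes that noise.

**Deviance and bias.** `D_k = (1+β)/(1−β) · [2(ℓ_F − ℓ_R) − (B_F − B_R)]`.
Under the null the likelihood gap itself is of size
`(1−β)/(1+β) · χ²(M)` — the factor is the effective inverse sample size of
the weighted likelihood — so the scale restores a central χ²(M).  The
default bias strategy charges each model its free-parameter count at
`(1−β)/(1+β)` per coefficient, counting the reduced model's M data-estimated
constraints as spent; the bias difference therefore vanishes when the
supports coincide and corrects only support-size mismatch.  (A strategy that
subtracted the full M inside the bracket would shift the null mean to ~0 and
destroy the calibration; strategies are pluggable.)

**Non-centrality and J.** ν̂ is estimated from the moment identity
`E[χ²(M,ν)] = M + ν`: pseudo-observations `max(D_k − M, 0)` enter a
random-walk Kalman smoother with observation variance `2(M + 2ν_obs)` (the
χ² variance) and state variance 10 by default (larger values track faster
transitions at the cost of noisier plateaus).  The signed Youden statistic
is `J_k = h_k · (1 − α − F_{χ²(M,ν̂_k)}(F⁻¹_{χ²(M)}(1−α)))` with
`h_k = sgn(Σ_m γ̃_k(m))` on rejected windows and 0 otherwise.  Note the sign
is the *net* smoothed exogenous factor over the tested set: if only part of
the set is facilitated, the remaining marks sit slightly below the inflated
independence prediction and can dominate the sum; testing the relevant
subset directly gives the sharper reading.  Multiple orders tested in one
run are each tested at level α with no cross-order correction; a
Benjamini–Hochberg helper across windows is available but off by default.

## Synthetic study designs

The simulator draws each bin's outcome from the exact model softmax, with
optional exogenous drives added to target-mark logits and history kernels
`θ_true`.  Independent neurons use the product form
`μ(m) = Σ_{c∈m} logit(q_c)`, which makes the multivariate Bernoulli
components exactly independent.

**Validation design** (`make_validation`): five independent neurons at
0.14/bin (14 Hz at 10 ms bins); a +3.0 step on *one* 3rd-order pattern
during the second half.  Two constraints pin this regime.  The pooled null
deviances can only match χ²(10) if every 3rd-order mark carries likelihood
information — about two events per effective window, requiring rates near
0.14.  But at such rates a drive applied to all ten 3rd-order marks is
absorbed: it inflates every neuron's fitted rate until the independence
prediction explains the boost (the residual exogenous factor behaves like
`a − 18q²(1−q)eᵃ`, negative for every amplitude once q ≈ 0.18).  Driving a
single pattern keeps the null informative, keeps all ten marks reliable at
`n_thr = 1` while 5th-order events stay excluded, and yields second-half
non-centrality in the low hundreds.

**Square-wave design** (`make_example1`): nominal rates 0.05/bin plus a
shared push-pull recurrence — every neuron's log-odds rises 1.8 per
population spike one bin back and falls 1.8 per spike two bins back.  This
is exactly the product form `θ(m) = Σ_{c∈m} θ_c`, so the ensemble stays
*conditionally independent given history*: chance pairs ignite single-bin
population bursts (realized rates ~0.11/bin) whose higher-order
coincidences are far above static independence yet exactly at chance given
history — genuinely endogenous coordination, and structurally incapable of
runaway (sustained activity cancels the kernel).  A ±2.0 square wave with
half-period 4000 bins drives all 3rd-order marks exogenously.  A direct
higher-order history kernel cannot play this role: the independence gap is
convex in the history, so any kernel placed on 4th-order marks alone leaves
a positive exogenous residue and the history-dependent test (correctly)
rejects.  **AR design** (`make_example2`): same recurrence, gated on only
for the first and last 4000-bin periods, with a standardized AR(1)
(coefficient 0.995) driving the 3rd-order logits; facilitation is strongest
during excursions above 2.

What these designs do *not* emulate: refractory structure and realistic ISI
statistics, rate heterogeneity across neurons, slow nonstationarity other
than the scripted drives, and recording artifacts (sorting errors, lost
units).  Passing tests show the estimator and test behave as designed on
data generated by the model class itself — the standard first obligation of
an inference method — not that real recordings satisfy the model.

## Calibration studies and their scope

- **Null calibration**: 10 validation realizations, history-dependent
  pipeline (p = 2, s = 2) at r = 3.  Deviances are serially correlated over
  N_eff (≈100 windows), so the pooled sample takes post-burn-in (125
  windows) first-half values spaced 35 windows apart, from realizations
  with all ten marks reliable; the pool passes a KS test against χ²(10) at
  level 0.01.  Two residual finite-sample effects are visible at tighter
  tolerances: a mean shift of roughly +1 (rare-event discreteness at ~2
  events per mark per effective window) and a slightly light upper tail,
  which makes the r = 3 test conservative.
- **Type-I error**: 20 independent realizations, tested at r = 2 where pair
  events (~12 per effective window) put the test in its asymptotic regime;
  the per-window rejection rate must lie within three Monte-Carlo standard
  errors of α = 0.01, with the SE floored at the binomial SE over the
  approximately independent window count (the across-realization spread of
  so few, serially dependent fractions can otherwise degenerate).
- **Attribution study**: one square-wave realization (T = 16000),
  history-independent tests at r = 3 and r = 4 and the history-dependent
  test at r = 4 (p = 2, s = 10 — the full history dimension, appropriate
  for the dense recurrent kernel), 40 windows of burn-in.  Checked pattern:
  J(3) > 0.5 in ≥80% of facilitation-epoch windows and ≤20% of
  suppression-epoch windows; history-independent J(4) > 0.5 in ≥60% of all
  windows; history-dependent |J(4)| ≤ 0.1 in ≥80%.

Problem sizes (realization counts, T) are chosen so the full suite runs in
about twelve minutes on one CPU.

## Numerical details and edge cases

- All soft-max computations use log-sum-exp; probabilities are clipped to
  [1e−12, 1−1e−12] inside logits/logs.
- Zero-frequency marks floor at −20 log-odds (configurable); deviances can
  be marginally negative from tolerance effects and are floored at zero
  only inside the non-centrality estimator (with a warning).
- Event-list input bins half-open [t, t+Δ); multiple spikes of one neuron
  in a bin clip to 1 with a warning (Bernoulli binning).
- γ-smoother observation variance defaults to `var(diff γ̂)/2`, state
  variance to a tenth of that; both configurable.
- Windows are non-overlapping and any trailing partial window is dropped;
  testing an order with no reliable marks raises rather than returning an
  empty trace.

## Known limitations

- The χ² calibration degrades for tested marks with ≪1 event per effective
  window (the test becomes conservative, never anticollinear); choose
  `n_thr`, β, and the tested order so tested marks carry events.
- The signed J reflects the net exogenous factor of the tested set (see
  above).
- Greedy support selection with warm starts can retain a stale coordinate
  until its coefficient collapses; the cross-validated budget mitigates
  but does not eliminate path dependence (the near-optimality of a single
  greedy pass, within 5% of best-subset on ≥90% of small instances, is the
  tested guarantee).
- Costs scale with the number of distinct history patterns; for large C
  and p, dense recordings can make the pattern histogram — and the
  2^C-sized mark space itself — the bottleneck.  Pruning (`n_thr`) is the
  intended control.
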