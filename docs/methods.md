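# Methods

## Model

Three pools, one label per clone.  `U + C` long-lived HSCs never die or
replicate in the model; each fires asymmetric differentiation events as a
rate-`α` Poisson process, adding one progenitor to its lineage.
Progenitors replicate at the shared Hill-regulated rate
`r(N_p) = pK/(N_p + K)`, die at `μ_p`, and terminally differentiate at
`ω` — symmetrically (progenitor replaced by two differentiated cells) with
probability `η`, asymmetrically (progenitor retained, one differentiated
cell added) otherwise.  Differentiated cells die at `μ_d`.  The combined
progenitor removal rate is `μ = μ_p + ηω`; the peripheral amplification is
`w = (1+η)ω/μ_d`.  A sample sequences `S` marked differentiated cells,
i.e. a fraction `ε = S/N_d`.

All rates are per month.  The CLI accepts `μ_d` with a `/day` suffix
(converted at 30.44 days/month) because peripheral turnover is usually
quoted per day.

### Mean-field clone counts

The expected number `c_k(t)` of clones with `k` progenitors obeys the
birth–death–immigration ladder implemented in `hemaclone.dynamics`; its
total first moment closes exactly onto the scalar equation for `N_p`, a
property the tests assert to 1e-8.  The ladder is truncated at `k_max`
(smallest NB tail below 1e-12, times a safety factor 4 because transients
are broader than the stationary law) with an absorbing tail accumulator,
so clone number is conserved identically; integration uses stiff BDF with
rtol 1e-8.

### Stationary laws

From the one-step balance `(α + rk)P_k = μ(k+1)P_{k+1}` the stationary
per-clone progenitor law is negative binomial, `P_k = NB(k; a, r̄)` with
`a = α/r`, `r̄ = r/μ`.  The steady-state `N_p*` is the positive root of a
quadratic; `δ = 1 - r̄ ≈ α(U+C)/((p-μ)K)` is inversely proportional to the
carrying capacity.  Conditional on `k`, the peripheral count is Poisson
with mean `wk` (constant influx, linear clearance), and for `ε ≪ 1` the
read count collapses to Poisson with mean `εw·k`.  The package keeps the
exact two-stage law (Poisson reads over a Poisson peripheral pool,
binomial or Poisson thinning) behind
`sampled_clone_dist_two_stage` for validation and for simulator
comparisons where `ε` is not small.

### Evaluating the sampled law exactly

`⟨m_q⟩/C = Σ_k P_k · Pois(q; εw·k)` is needed up to `q ~ 10³` while the NB
support extends to `k ~ 10⁷`, so direct summation is impractical during
fitting.  We instead expand the probability generating function
`F(z) = ((1-r̄)/(1-s e^{εw z}))^a`, `s = r̄e^{-εw}`: the Taylor
coefficients of `ln F` reduce to negative-order polylogarithms, evaluated
through the Eulerian-polynomial recurrence in a scaled form whose terms
are all positive, and the pmf follows from the standard exp-of-series
convolution — also all-positive, hence stable to roundoff.  The whole pmf
up to `q_max` costs `O(q_max²)` and agrees with brute-force k-summation to
better than 1e-10 relative (asserted in tests).  Truncation is chosen from
the pgf's singularity at `z* = 1 + ln(1/r̄)/εw` and extended adaptively
until the neglected tail is below tolerance; the default fitting path
never needs the tail because the detected-clone normalization
`1 - m_0` has a closed form.

## Inference

Detected clones are i.i.d. given detection, so the likelihood is the
conditional multinomial over read counts with
`p_q = m_q/(1 - m_0)`.  Once the unknown clone number `C` is profiled out,
this is the full-information likelihood of a histogram.  `εw` is held
fixed (default 5e-5, overridable from estimates of `S` and peripheral
turnover); the data constrain it only weakly — doubling it at fixed
`(a, R)` moves the log-likelihood by millinats on a million-clone sample.

Optimization runs in `(ln a, ln R)`.  The likelihood valley in `R` is
narrow (~10% width) while `a` acts mostly as a scale factor, so a fixed
product grid straddles the valley and drifts toward small `a`; the coarse
stage therefore profiles `R` continuously (bounded 1-D minimization) at
each of 21 log-spaced `a` values before Nelder-Mead refinement (relative
tolerance 1e-6).  A fit within one coarse step of the search box is
flagged as a boundary solution.

Identifiability caveat, quantified: at the macaque operating point
(`a = 0.01`, `R = 70`, `εw = 5e-5`) the expected Fisher information for a
million-clone histogram (~42k detected) gives SE(ln a) ≈ 0.44 and
SE(ln R) ≈ 0.017 with correlation -0.72.  `R` is sharply determined —
essentially by the mean reads per detected clone — while single-sample
estimates of `a` scatter over ±50% even at this size, and a few hundred
detected clones leave `a` flat over a decade.  Recovery experiments and
the acceptance script therefore report medians over 20 seeds, and the
active-HSC estimator `U+C ≈ S/(R* a*)` inherits the `a` uncertainty:
reliable at ~4×10⁴ detected clones, order-of-magnitude only at a few
hundred.

Profile likelihoods use the 1.92-nat drop for 95% intervals, re-optimizing
the other parameter.  Goodness of fit reports the multinomial deviance and
the sup-norm between empirical and model `Q(q)`, with Monte-Carlo p-values
from a parametric bootstrap at the fitted parameters (no refitting — valid
for data at the fitted law, slightly conservative otherwise).  Each
bootstrap replicate is analysed on a category grid truncated at its own
largest read count, exactly as the observed histogram is; reusing the
observed grid biases observed statistics upward because the data choose
their own support.

## Stochastic simulator

The exact-event (Gillespie) kernel is compiled with numba and stores each
pool as a flat array of cell→clone labels, giving O(1) birth, death and
differentiation updates (uniform index draw, swap-remove) without per-event
weighted sampling.  A fixed event cap and pool capacity (a multiple of the
mean-field fixed point) convert runaway growth into errors.  The tau-leap
mode uses a fixed step `Δt = 0.05/max(per-cell rates)` with Poisson event
counts per channel and per clone and counts any negative-count clamps in
the returned state.  One seeded generator drives each replicate; identical
config and seed give identical output.

Read sampling treats one read as one sampled marked cell — binomial
thinning at `ε = S/N_d`, or Poisson thinning matching the analytic
collapse.  PCR/sequencing overdispersion is not modeled; if real data are
overdispersed relative to binomial sampling, fitted `R` absorbs some of
that excess and the clone-number estimate degrades accordingly.

### What the synthetic data do and do not emulate

`sample_steady_state_reads` composes the stationary pipeline exactly
(NB progenitors, Poisson reads), which is the right fixture for inference
tests: passing recovery there shows the estimator works when the model is
true, not that macaque blood obeys the model.  The full simulator adds
finite-population effects the analytic laws ignore: shared fluctuations of
`N_p` (hence of `r`) across clones, temporal correlation between a clone's
progenitor and peripheral sizes, and integer-valued pools.  It does not
emulate HSC aging, quiescence cycling, clonal succession waves, subtype
heterogeneity, or sequence-level artifacts; clone identity is an opaque
label.

### Desk-scale validation conditions

Real marrow has `K ~ 10⁹`, far beyond event-driven simulation, and the
stationary laws depend on mechanistic rates only through `(a, r̄, εw)`.
Validation therefore runs at `K = 5×10³` with
`α = 1.08, p = 2.2, μ_p = 1, η = 0, ω = 4, μ_d = 9` (per month),
`C = 669`, `S = 500` — chosen once so that (i) `C` is large enough for
mean-field regulation (`δ` fluctuates by ~5%), (ii) the clones a sample
detects are large (`k ≈ 30` at one read), and (iii) `μ_d` sits at the fast
end of the physiological per-day range, because the conditional Poisson
peripheral law assumes the progenitor count is quasi-static over the
peripheral relaxation time `1/μ_d`.  `hemaclone.oracle` solves the exact
stationary joint (progenitor, peripheral) law of one lineage from the
master equation on a truncated grid (frozen `r`); under the validation
conditions the mean-field read law agrees with it to <1% in the head and a
few percent in the tail (asserted in tests), and the simulator's read
histograms are compared against the exact law, where the residual
discrepancies are only the shared-`r` fluctuations.  At slow `μ_d` and
small clone sizes the mean-field approximation visibly breaks (~40% at one
read for `μ_d = 2`/month with single-cell clones).  Samples are taken at 70
months, seven relaxation times (`1/(μδ) = 10` months) after transplant.
Note the effective `a = 1.20` here: matching the published
`(a, R) = (0.01, 70)` at reduced `K` is impossible for any `C ≥ 1`
because the mean clone size `a/δ = K(p-μ)/(rC')` cannot reach 10⁴ with
desk-scale `K`.

## Numerical choices

- All distribution arithmetic in log space or in scaled all-positive
  recursions; no `Γ` ratios are formed directly.
- NB truncation at tail mass 1e-12; sampled-law tail 1e-10 by default with
  adaptive extension; normalized laws sum to 1 within 1e-9.
- `steady_state_Np` solves the quadratic in closed form; the subcritical
  `p ≤ μ` case without immigration raises, with immigration it is a valid
  immigration–death balance (the simulator warns rather than refuses,
  since the `K → ∞, p < μ` limit is a useful validation regime).
- Degenerate inputs: empty pools sample to empty tables; all-singleton
  histograms fit to the search-box boundary and are flagged; `εw = 0`
  yields the empty sampled distribution.
- Bootstrap and permutation bands use 400 resamples; GOF uses 200.

## Known limitations

- Transient peripheral/sampled distributions are not computed (the
  quadratic `y_n^{(k)}` grid is deliberately not integrated); stationary
  forms only.
- The conditional-multinomial likelihood discards the absolute detected
  count, which is uninformative once `C` is unknown — but means `a` is
  weakly identified at realistic sample sizes (see above).
- The log-approximation `C_s/C ≈ a ln(εw/δ + 1)` overshoots the exact form
  by ~2% at `εw/δ = 70`; the exact form is used everywhere internally.
- Mean-field laws carry `O(1/C)` and `O((r+μ)/(μ_d k))` corrections that
  the reduced-`K` validation conditions are chosen to suppress, not
  eliminate.
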