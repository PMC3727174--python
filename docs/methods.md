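# Methods

## Model

A GTaS process is the triple (λ, (p_D), (Q_D)): a mother Poisson process of
rate λ on ℝ, a probability distribution p over nonempty markings
D ⊆ {1..N}, and a shift law Q_D on ℝ^N per marking. Each mother event is
marked once, one shift vector is drawn, and train i ∈ D receives a copy at
t + Y_i. Because thinning and IID shifting preserve Poissonity, each train
is Poisson with rate λ·p̄_{i} (p̄_D = Σ_{D′⊇D} p_D′), while joint cumulants
of all orders are set by the markings and shifts:

* count cumulants: κ(X_{i1}(A₁), …, X_{ik}(A_k)) =
  λ Σ_{D′⊇D̄} p_D′ ∫ P(t + Y_{D̄} ∈ A₁×…×A_k) dt,
* cumulant densities: the same sum over markings with the difference-vector
  density q_Z^{D′}(τ₁, …, τ_{k−1}) of (Y_{i2}−Y_{i1}, …) as summand,
* infinite-window cumulants: λ·p̄_{D̄} exactly, independent of the shifts,
  and non-increasing under adding trains to the index set.

Empty markings are disallowed: an event deleted everywhere is equivalent to
a lower mother rate, and the MIP constructor performs that reduction exactly
(returning the folded mass for reconciliation with the ε-thinning picture,
under which p̄ values differ by the factor 1 − (1−ε)^N while every physical
quantity λ·p̄ is identical).

Repeated indices in count cumulants are reduced by intersecting the windows
of the repeated train. This identity holds for marginally-Poisson GTaS
processes (every cumulant of the underlying independent Poisson components
equals its mean); general-process auto-cumulant densities, which carry
additional δ(τ) terms proportional to the rate, are out of scope. The
binned auto-density estimator retains same-bin same-train products, so users
should expect a rate-sized zero-lag atom there.

## Shift families

| kind | parameters | difference law |
|---|---|---|
| `delta` | offsets (default 0) | symbolic atoms (exact synchrony / fixed ladder) |
| `gaussian` | mean, covariance | Gaussian of the differenced mean/covariance |
| `exp_cumsum` | α₁..α_N > 0 | independent hypoexponential gaps between coordinates |
| `gamma_cumsum` | μ_shift, σ_shift per increment | independent gamma gaps (shape m·μ²/σ², scale σ²/μ) |
| `empirical` | sample table | sampling only; analytics refuse with a clear error |

The cumulative-sum families produce ordered shifts Y_N ≥ … ≥ Y₁ ≥ 0 —
synfire-like cascades with random inter-neuron delays. Their joint
marginals factor into independent gap densities, which the analytics exploit
(hypoexponential gaps are evaluated by partial fractions for distinct rates,
the Erlang form for equal rates, and a phase-type matrix exponential for
clustered rates; scipy has no hypoexponential law, so this block is
implemented here). The gamma parameterization uses the stated increment
mean and standard deviation; σ_shift = 0 degenerates to a deterministic
ladder and is represented as a point mass.

Singular (delta) components are carried end-to-end as (atom, mass) pairs and
are never binned onto numeric grids; SIP/MIP cumulant densities are exact
delta functions of mass λ·p_D and appear as such in `CumulantDensity.atoms`.

The pairwise Gaussian jitter scale in the cascade constructors defaults to
one time unit (the pair shifts only need to be some zero-mean smooth law;
they are overridable per call).

## Sampling

The mother process is drawn on a padded interval [t₀ − b, t₁ + b], where b
bounds the shift magnitude to mass 10⁻⁹ under every marking's law
(quantile-based per family); shifted events outside the observation window
are dropped. This gives stationarity on the interior without simulating on
the whole line. Event times are continuous; exact duplicates (from delta
shifts) are kept. One seeded `numpy` Generator drives everything: markings
are assigned in event-time order, then shift vectors are drawn
marking-by-marking in canonical subset order — fixed consumption order makes
runs byte-reproducible and enables matched-pair designs.

`simulate_matched` reuses one mother realization, one marking assignment and
the shift draws of all markings whose laws agree across models, drawing only
the differing markings from per-model child streams. This is the
common-random-numbers design of the network experiment.

## Estimators

Joint cumulants use the partition (moment–cumulant) formula with sample
means plugged in; orders are capped at 6 (Bell-number guard). The plug-in
is biased at O(1/n); all shipped analyses use ≥10⁴ observations, where the
bias is far below the Monte-Carlo error. Cumulant densities are estimated
by binning each train at width Δt (half-open bins, right-edge rule, partial
trailing bin dropped), forming lagged count columns, applying the partition
formula, and dividing by Δt^k. A sensible default bin width is
1/(20·max marginal rate). Standard errors come from a block bootstrap over
bins (default 200 resamples, blocks of 10 bins; tests involving cascade
models use 50-bin blocks so that blocks exceed the shift correlation
length). All quantities estimated in one call share the same resample
weights, so pooled (population) estimates propagate correlations correctly.

The expectation of a binned density estimator is the true density convolved
with a product triangular kernel of half-width Δt;
`analytic.bin_averaged_density` computes exactly that, and estimator
validation compares against it rather than against midpoint values (the
distinction matters near the discontinuous cone boundaries of cascade
densities).

## Numerical choices

* Cumulant-density grids are user-supplied; `CumulantDensity.integral()` is
  a plain grid trapezoid (plus atom masses) intended for sanity checks, with
  O(h) error across the jump discontinuities at cascade cone boundaries.
  `analytic.total_cumulant_mass` integrates each marking's difference
  density by adaptive quadrature instead — factorized over independent gaps
  for the cumulative-sum families — and reproduces λ·p̄ to ≲10⁻⁶.
* Smooth-shift count cumulants are quadrature-based and implemented for
  k ≤ 3 (all delta-shift cases are exact at any order); higher smooth orders
  raise `NotImplementedError` and point to the density route.
* Marking probabilities are silently renormalized only when their sum is
  within 10⁻⁹ of one (config round-off), and left untouched within 10⁻¹⁵ so
  that save → load round-trips are bit-exact; larger deviations are errors.

## LIF ring and the cascade-amplification experiment

The network is N = 6 excitatory leaky integrate-and-fire cells on a ring
with nearest-neighbor weights w_syn, driven by GTaS input spikes as
instantaneous jumps w_in; synapses are delayed unit-area exponentials
(delay τ_d, timescale τ_syn); threshold V_th = 1, reset to 0, no refractory
period; time in membrane time constants. Integration is exponential-Euler
on a fixed grid (default dt = 10⁻³): the per-cell synaptic trace decays with
τ_syn between delayed unit increments, the membrane decays with the unit
membrane constant, and input jumps land in the step containing the spike
time. Halving dt changes trial spike counts by at most ~1 per 100 time
units on fixture input. The inner loop is numba-compiled when available.

The experiment drives the ring with a gamma-cascade input (per-neighbor
shift mean μ_shift = 2, SD σ_shift = 0.3, trial length T = 100) and with a
synchronous input identical in rate, markings and *all* long-timescale
cumulants, per-trial matched by common random numbers. The cascade
amplification factor (CAF) is the ratio of mean output counts.

The network and input-rate parameters are package choices, calibrated once
with `scripts/calibrate_caf.py` around the mechanism the model predicts —
the recurrent synaptic pulse of a cell must arrive when its downstream
neighbor receives its own input copy, i.e. τ_d + τ_syn ≈ μ_shift:

| parameter | value | role |
|---|---|---|
| w_in | 0.85 | subthreshold input jump (per spike) |
| w_syn | 0.6 | neighbor pulse peak ≈ 0.22 V_th, below the reverberation regime |
| τ_syn, τ_d | 1.0, 1.0 | wide aligned pulse, tolerant to the 0.3 shift jitter |
| input model | λ = 0.2, p_pop = 0.5, six ring-adjacent pairs at 0.05, singletons 0.2/6 | prominent population events (0.1/t.u.) over a sparse background (~0.13 spikes/t.u./cell) |

At this point the CAF is ≈1.6–1.7 across seeds (500 trials), decreases
monotonically as σ_shift grows through {0.3, 1, 2, 4} (jitter destroys the
pulse/input alignment), and collapses to ≈1 when w_in ≫ V_th (every input
spike fires its cell regardless of timing). Stronger recurrence
(w_syn ≳ 0.7 at these timescales) tips the ring into self-sustained
reverberation and was excluded.

## Fixtures and what the tests do and do not show

`fixture_models()` ships six deterministic models. The exponential-cascade
fixture (λ = 0.7, p_pop = 0.125, four skip-one pairs at 0.05, singletons
0.1125, α = (1,2,1,2,1,2), pair σ = 1) puts each train near 0.2 events per
time unit — the top of a realistic cortical-surrogate range and high enough
that second- and third-order densities are measurable from 10⁴-time-unit
runs. The gamma/synchronous pair uses the network geometry above.

The generator is the model: passing tests show that the sampler, the
analytics and the estimators agree with each other and with closed forms
under exactly the model's assumptions (stationary mother rate, marginal
Poissonity, IID shifts). They do not show that real spike trains satisfy
those assumptions — real data have refractoriness, rate nonstationarity and
non-Poisson variability (Fano factors away from 1), none of which GTaS can
express. Fitting (p_D, Q_D) to recorded data is likewise out of scope.

## Known limitations

* Marginals are strictly Poisson; variability cannot be tuned per train.
* Time-inhomogeneous mother rates and non-Poisson mothers are unsupported.
* `empirical` shifts are sampling-only; analytic densities refuse them.
* Joint-cumulant estimation is capped at order 6; smooth-shift count
  cumulants at order 3.
* The LIF model is minimal by design: excitatory ring only, no inhibition,
  conductances, heterogeneity or refractoriness.
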