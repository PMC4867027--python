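# Methods

## The generative model

A synaptic connection is modelled as `N` identical, independent release
sites.  Immediately before the k-th presynaptic spike, `S⁻_k` sites are
release-competent (occupied by a docked vesicle); each releases
independently with probability `u_k`, leaving `S⁺_k` competent sites, so
the released count `m_k = S⁻_k − S⁺_k` is binomial.  Between spikes each
empty site re-docks a vesicle with constant rate `1/τ_D`, i.e. with
probability `l(Δ) = 1 − exp(−Δ/τ_D)` over an interval `Δ`, so the refill
is again binomial.  The release probability facilitates: it jumps by
`U·(1−u)` at each spike and decays back to its baseline `U` with time
constant `τ_F`, giving the recursion
`u_{k+1} = U + u_k (1−U) exp(−Δ_k/τ_F)` with `u_1 = U`.  At rest all
sites are competent (`S⁻_1 = N` with probability one).

A single released vesicle produces an amplitude with mean `q` (quantal
size) and SD `σ_q`; to capture the right-skew of unitary responses the
amplitude is inverse-Gaussian.  `m` vesicles sum linearly, yielding an
inverse-Gaussian amplitude with mean `m·q` and variance `m·σ_q²`
(shape parameter `λ_m = m²q³/σ_q²`).  The recorded amplitude additionally
carries additive Gaussian baseline noise of SD `σ_n`; a failure (`m = 0`)
is therefore pure baseline noise.  The deterministic skeleton of the model
gives the mean responses `R̄_k = N·q·u_k·x_k`, where `x_k` (the occupancy
probability) obeys `x_{k+1} = 1 − [1 − (1−u_k)x_k] exp(−Δ_k/τ_D)`,
`x_1 = 1`, and `A = N·q` is the absolute efficacy.

Units are fixed package-wide: milliseconds and millivolts.  `τ_F = 0` and
`τ_D = 0` are accepted as exact limits (`u_k ≡ U`, `x_k ≡ 1`) rather than
errors, because fitted values of zero occur in practice.

## Exact likelihood and EM

The hidden pair chain `S⁻_1, S⁺_1, …, S⁻_M, S⁺_M` makes consecutive
responses correlated; the likelihood of a response train is the sum of the
joint density over all hidden paths.  It is computed exactly by
forward–backward recursions over the `N+1` site-count states, with
per-spike normalization (scaling) constants to prevent underflow — the
log-likelihood accumulates from the scalers, and in scaled units the
forward/backward product sums to one at every spike, which the tests
assert.  The backward recursion terminates with `β⁺ = 1` at the *last*
spike (no future observations).  A brute-force enumeration over all
`(N+1)^(2M−1)` paths serves as an independent oracle for `N ≤ 4`, `M ≤ 4`.

Maximum-likelihood estimation uses EM over the hidden site counts.  The
E-step computes pair posteriors `P(S⁻_k, S⁺_k | R_{1→M})` per trial
(batched across trials sharing a spike-train skeleton) and accumulates
three kinds of sufficient statistics: expected site counts before/after
each spike, expected released counts, and the posterior weights over the
released count `m` per response.  The auxiliary function separates into
three blocks solved independently:

* **Quantal block (q, σ_q).**  Without baseline noise the update is
  closed-form (`q ← ΣR / Σ⟨m⟩`, then `σ_q²` from the weighted quadratic
  term; failures carry no information about the quantal parameters and are
  excluded from the weights — with `σ_n = 0` they appear as exact zeros,
  so the sums are unaffected).  With noise the re-estimation equations are
  implicit: the posterior moments of the latent noiseless amplitude `y`
  are evaluated at the *new* parameters.  The public `m_step` solves the
  two equations simultaneously with a derivative-free root solver in
  log-coordinates.  The EM driver's fast path instead treats `y` as an
  additional latent variable, which gives a closed-form ascent step from
  the posterior moments `E[y]` and `E[1/y]` at the current parameters
  (one quadrature pass instead of one per root-solver evaluation).  The
  two updates share their fixed points — a property the test suite checks
  through the stationarity test — and the fast step, being a proper
  expanded-data M-step, can never decrease the likelihood.
* **Docking block (τ_D).**  A 1-D score equation; the score is scanned on
  a 40-point log grid over [10⁻² ms, 10⁷ ms], roots are bracketed strictly
  (+→− sign products only, because the score is numerically zero over
  whole decades when `τ_D` is far below the probed intervals) and solved
  by Brent's method; if no bracket exists the best grid point is polished
  by bounded maximization of the block's auxiliary function.
* **Release block (U, τ_F).**  The two score equations are coupled
  through the `u_k` recursion and its parameter derivatives and are solved
  simultaneously (hybrid Powell method) in (logit U, log τ_F) coordinates.

Every block is verified (on the safe path) to not decrease its auxiliary
contribution, with direct bounded maximization as a fallback; the driver
runs the fast path and repeats the iteration on the safe path if the
log-likelihood ever dips.  This makes monotone ascent an enforced
invariant rather than a hope.  Because EM crawls along ridge directions
(notably the N–q–U trade-off), the driver attempts a safeguarded
extrapolation along the recent trajectory in log/logit coordinates every
third iteration, keeping the extrapolated point only when it improves the
likelihood — a 2–4× reduction in iterations with monotonicity intact.

Convergence: relative log-likelihood change below 10⁻⁸ (default) or 500
iterations.  Initialization is method-of-moments from the first responses
(binomial mean/variance giving `q` and `U` at the scanned `N`; time
constants at the geometric mean of the interspike intervals), with
restarts spreading the time-constant inits across depression- and
facilitation-dominated regimes before random log-perturbations — the
likelihood genuinely has distinct local maxima in those regimes, and a
single moment start can land in the wrong one.  `σ_q` is floored at
10⁻⁴ mV to avoid point-mass emissions.  `σ_n` is treated as known (from
preprocessing or configuration) and never re-estimated.

`N` is discrete: EM runs per candidate `N` and the likelihood profile over
`N` decides (ties toward smaller `N`; an argmax at the edge of the scanned
range is flagged).  The full scan (default 1–100) warm-starts each `N`
from its predecessor with `q` rescaled to preserve `A = N·q`.  A
hill-climbing strategy (`strategy="climb"`) starts at the centre of the
range and expands outward until the profile declines for `patience`
consecutive values; on the unimodal profiles this model produces it finds
the same argmax at a fraction of the cost, and is the default inside the
bootstrap (half-width ±20 around the generating `N`, full scan by flag).

## Emission quadrature

The noisy emission `P(R|m)` is the convolution of the inverse-Gaussian
vesicular density with the Gaussian baseline density.  The integrand is a
product of two unimodal factors, and the quadrature variable is chosen so
the narrower factor is integrated against directly: when
`√m·σ_q > 2σ_n`, 40 Gauss–Hermite nodes in the noise variable (shared
across all such `m`, so the whole emission table evaluates in one
vectorized pass); otherwise 128 Gauss–Legendre nodes over the overlap of
the two supports (inverse-Gaussian quantiles at 10⁻¹⁴ by `R ± 9σ_n`).
All node positions are smooth in the parameters, so the analytic
derivative tables used by the score recursions agree with finite
differences of the values to ~10⁻⁵ relative or better; normalization is
accurate to ~10⁻⁹.  Density values in extreme tails (responses many
combined SDs from every component) are resolved only in relative terms of
the dominant mixture components; this never affects data generated by the
model.

## Score recursions and Fisher information

The gradient of the log-likelihood in the continuous parameters
`(q, σ_q, U, τ_D, τ_F)` is computed exactly by propagating derivative
vectors alongside the scaled forward recursion: emission derivatives are
analytic inverse-Gaussian scores under the noise convolution, release
derivatives flow through `∂u_k/∂U` and `∂u_k/∂τ_F` recursions, docking
derivatives through `∂l_k/∂τ_D`.  The same scaling constants divide value
and derivative vectors, leaving the score (a degree-0 ratio) unchanged.

The Fisher Information Matrix of a stimulation protocol is the expected
outer product of the whole-experiment score and is estimated by Monte
Carlo over fully simulated experiments (default 1000; protocol-comparison
tests use 200 per connection).  `N` is excluded (discrete).  The
normalized Cramér–Rao bound `ε_j = √([I⁻¹]_jj)/θ_j` lower-bounds the
relative error of any unbiased estimator; parameters with identically
zero FIM rows (the time constants under a single-spike protocol) are
reported as unbounded (infinite ε).  The minimum-repetition calculator
uses the central-limit criterion `z·CV/√n ≤ relative precision` with
`z = 3` standard errors by default (configurable); at CV 0.3 this yields
81 repetitions for 10% precision and 324 for 5%.

## Stimulation protocols

* `regular`: `n` spikes at interval `T`, a recovery spike `T_rec = T + 500
  ms` after the last train spike (the experimental convention), and an
  inter-trial interval (default 4 s).
* `poisson`: the same skeleton with i.i.d. exponential within-train
  intervals of mean `T`; the recovery interval stays fixed at `T + 500 ms`
  (mirroring the regular protocol's recovery logic; experimental
  conventions do not pin this down).
* `single_sweep`: Poisson blocks concatenated into one train, the
  recovery spike of block *i* serving as the first spike of block *i+1*,
  filling a requested recording duration.  Each block hence contributes
  `n` new responses; at 5 Hz and 118 s this yields on the order of 400
  responses versus ~170 for the trial-based protocols.

## Least-squares baseline and conditioning

The conventional approach fits the deterministic means `R̄_k(A, U, τ_D,
τ_F)` to trial-averaged responses by weighted least squares (per-position
variances as weights), which can resolve only the product `A = N·q`.  The
optimizer is Levenberg–Marquardt in log/logit-transformed coordinates with
five deterministic starts.  The conditioning analysis evaluates the
sensitivity matrix `D = ∂θ_LS/∂⟨R⟩` by perturbing each average by 10⁻⁴
relative and re-fitting (warm-started, central differences; step-halving
agreement is tested at 1%), and the condition number
`c = ‖D‖₂·‖R̄‖₂/‖θ_LS‖₂`.  `c` is computed with unit weights so that it is
a function of the parameters and protocol alone, reproducible without
knowing any per-position variances.  The
perturbation experiment (1% relative Gaussian noise on the true averages,
15 repeats, range of relative errors per parameter) demonstrates the
practical consequence: for ill-posed parameter sets the re-fitted
estimates scatter wildly even though the averages are nearly exact.

## Validation tools

* **Parametric bootstrap**: simulate-and-refit replicates around a fitted
  connection quantify bias, relative-error SD, and pairwise Pearson
  correlations of the estimates; correlations aggregate across connections
  via Fisher z-transform.  Replicate refits hill-climb over `N` within ±20
  of the generating value (restarts 2, tolerance 10⁻⁶) — a cost reduction
  relative to the full scan that leaves genuine model-order uncertainty in
  place.
  A caveat on the correlation diagnostics: the canonical sign pattern of
  the estimate correlations (N–q, N–U, U–q negative; N–τ_D positive) is a
  *population-level* statement, aggregated over many connections.  On a
  single connection with many sites the strong negative N–q and N–U
  couplings induce a positive U–q component (the product of two negative
  correlations) that can outweigh the direct U–q compensation; the
  bootstrap on the worked-example connection shows exactly this, with the
  three N-couplings matching and the U–q coefficient small and positive.
* **Leave-one-out z_out**: per held-out trial, the fraction of
  model-simulated trials (2000 by default; the original count is not
  documented) with log-likelihood ≤ the held-out trial's, using the ≤
  convention; uniformity tested by Kolmogorov–Smirnov at p = 0.01.
* **Position-preserving shuffle**: independent permutation of trials at
  each train position destroys within-trial correlations while preserving
  every per-position amplitude multiset.  Depression induces negative
  correlations between consecutive responses, so EM on shuffled data
  systematically underestimates `τ_D` — the tests check the sign of this
  bias at 20 replicates.
* **CV by position**: SD/mean across trials per train position; the final
  position is the recovery response.

## Preprocessing

Raw traces are smoothed with a 2 ms boxcar (shrinking at the edges), the
membrane time constant is fit to falling edges (exponential-plus-offset,
averaged over usable windows), and the trace is deconvolved as
`RI = τ_m dV/dt + V` using central differences.  12 ms crops centred on
the nominal stimulation times are re-convolved through the exact
first-order exponential filter (the discrete inverse of the deconvolution,
integrated exactly for piecewise-constant drive) from a zero baseline, and
the peak of each re-convolved crop is the amplitude (sign configurable for
IPSPs).  Baseline noise variance pools the variance of 1 ms pre-onset
windows over all spikes and trials — one `σ_n²` per connection.
Overlapping crops are an error; traces with drift are the caller's
responsibility to exclude (a linear-drift detector warns but does not
filter).  The deconvolve–reconvolve pair is the identity on smooth traces
to below 1% at 0.05 ms sampling; an instantaneous EPSP rise is a
discontinuity that any difference scheme smears over ~2 samples, which
does not affect the extracted peak.

## Synthetic population and simulated recording conditions

Tests that need a population of connections draw parameters independently
from distributions matched to reported cortical values (ferret medial
prefrontal cortex, layer-5 pyramidal pairs): log-normal with mean/SD
(N: 15/12, q: 0.15/0.06 mV, σ_q: 0.05/0.04 mV, τ_D: 335/306 ms,
τ_F: 321/340 ms), normal for U (0.33/0.13), all clipped to the reported
ranges (N additionally capped at 40 to keep enumeration of states cheap,
and rounded).  The worked-example connection for uncertainty
quantification is N = 17, q = 0.18 mV, σ_q = 0.06 mV, U = 0.27,
τ_D = 202 ms, τ_F = 449 ms, probed with 28 trials of the 8-spike 20 Hz
train plus recovery.  Its baseline noise is not reported; the package
uses σ_n = 0.03 mV — half the connection's quantal SD, a good-quality
whole-cell recording, and consistent with the observation that σ_q is
only well estimated when baseline noise stays below quantal noise.

What the simulator does *not* emulate: receptor desensitization,
calcium-dependent docking, multiple vesicle pools, heterogeneous release
sites, electrode drift, and recording artifacts.  Passing tests therefore
demonstrate correctness of inference *under the model*, plus robustness
diagnostics (shuffle, z_out) that would flag some model violations on real
data — they do not certify the model's adequacy for any particular
synapse.

## Problem sizes used in the checks

The acceptance analyses run at desk scale: 100 bootstrap replicates for
the worked example (the original analysis used 500), 20 synthetic
connections at 200 Monte-Carlo samples for the protocol comparison, and
20 replicates for the shuffle control.  These sizes give comfortable
margins for the qualitative orderings and the <0.3 relative-SD bound
while keeping a full run in the tens of minutes on one core.

## Known limitations

* EM cost grows as `(N+1)²` per spike; scanning to `N = 100` on long
  single sweeps is minutes, not seconds.
* The FIM is Monte-Carlo, so protocol comparisons inherit sampling error;
  medians over connections are robust to it, individual entries at
  `n_mc = 200` carry ~10% noise.
* Near-boundary parameters (`U → 1`, `τ_F → 0`) make the release block's
  score equations stiff; the transforms and fallback maximization handle
  this, but confidence regions there should come from the bootstrap, not
  the FIM.
* The leave-one-out procedure refits per fold and is the most expensive
  diagnostic; for large `N` scans use a restricted `N_range`.
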