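# Methods

This note documents the model, the estimation procedure, the entropy-flow
estimators, the synthetic-data generator, and the numerical and design
choices made where the mathematics leaves freedom.

## Observation and state model

Spike trains are binarized at bin width Δ (default 10 ms, half-open bins
`[t0 + tΔ, t0 + (t+1)Δ)`; a spike on a right edge belongs to the next bin;
a bin is 1 if it contains at least one spike).  Bin 0 holds the initial
state and carries no parameters: the likelihood conditions on `x_0`, and
the product over modelled bins runs over `t = 1..T`.

The observation model is the synchronous-update kinetic Ising chain: given
`x_{t-1}`, neurons are conditionally independent with logistic spike
probability driven by `h_{i,t} = θ_{i,t} + Σ_j θ_{ij,t} x_{j,t-1}`.  The
per-neuron natural-parameter vector `θ_t^i = [field, couplings i←1..N]`
(dimension N+1, self-coupling included) follows a Gaussian random walk:
initial law `N(μ^i, Σ^i)`, transition covariance `Q^i`.  Parameters of
different neurons are a-priori independent, which makes every E- and
M-step computation per-neuron and embarrassingly parallel.

## E-step: Laplace filter and smoother

The one-step prediction carries the mean and inflates the covariance by
`Q^i`.  The filter update maximizes the concave per-bin objective (logistic
log likelihood over trials plus Gaussian prior) by damped Newton–Raphson:

* gradient tolerance 1e-8 (max-abs), at most 100 iterations, step halving
  (up to 30 halvings) whenever a full step would decrease the objective;
* an additional Newton-decrement stop (`g·Δθ/2 < 1e-13·(1+|f|)`) ends the
  iteration when the objective has reached its floating-point plateau,
  where the computed gradient's rounding noise can exceed the tolerance;
* the filter covariance is the inverse Hessian at the mode (observed
  Fisher information plus prediction precision), via Cholesky solves;
  every covariance is symmetrized after each update.

Because the per-bin likelihood depends on trials only through the multiset
of (previous pattern, spike outcome) pairs, trials are collapsed once per
fit onto the unique previous patterns (at most `min(L, 2^N)`); all Newton
arithmetic runs on these sufficient statistics, which is what makes
hundreds of EM iterations cheap at small N and large L.

Smoothing is the standard fixed-interval (RTS) backward recursion with
gain `A_t = W_{t|t} W_{t+1|t}^{-1}`.  The lag-one smoothing covariance is
taken as `Cov(θ_t, θ_{t+1} | all data) = A_t W_{t+1|T}` — the exact lag-one
covariance of the Gaussian approximation (pairing the gain with the
smoothed covariance of the *later* bin); degenerate `Q = 0` reduces it to
`W_{t|T}`, and the brute-force joint-MAP oracle validates the convention.

## M-step and marginal likelihood

`Q^i` is updated by averaging the expected squared state increments over
bins 2..T; `diagonal` and `scalar` structures take the diagonal or
trace/(N+1) of the full update.  Tiny negative eigenvalues introduced by
the Laplace approximation are clipped to keep `Q` PSD.  When
`optimize_initial` is on, `μ^i ← θ_{1|T}^i` (the joint maximizer of the
initial-state objective), which reduces the `Σ^i` update to `W_{1|T}^i`;
the flag exists because an explicit update formula for `μ^i` is a design
choice, not a forced consequence of the model.

The marginal likelihood uses the Laplace identity per neuron and bin:
`½log|W_{t|t}| − ½log|W_{t|t-1}| + q(θ_{t|t})`, where `q(·)` is the
log-likelihood-plus-prior exponent at the MAP (the `(2π)^{d/2}` factors of
the two Gaussians cancel).  `log p(x_0)` is zero under the conditioned-on-
`x_0` convention and is stored separately.  EM stops when the relative
change drops below `em_rel_tol` (default 1e-6, cap 200 iterations).
Laplace-EM is only approximately monotone; the validation suite allows a
1e-6 relative slack and observes no violations.

Initialization: `μ^i = [logit(clamped mean rate), 0, …]`, `Σ^i = I`,
`Q^i = 1e-3·I`.  A stationary fit (`freeze_q` with `init_q_scale = 0`)
freezes `Q = 0`, which provably yields bin-constant smoothed parameters
and is used for the misspecification study.

## Entropy flow

The entropy flow of bin t is the expected log-ratio of the forward
transition probability to the reverse conditional, where the reverse
conditional applies the bin-t kernel backwards
(`p(x_{t-1}|x_t) = Π_i exp[x_{i,t-1} h_{i,t}(x_t) − ψ(h_{i,t}(x_t))]`).
This is the definition consistent with the mean-field backward entropy; a
Bayes-posterior reverse conditional would make entropy production vanish
identically and is therefore not meaningful here.  Production satisfies
`σ_t = (S_t − S_{t-1}) + σ_t^flow ≥ 0`, with equality exactly at detailed
balance — both facts are enforced as tests via the enumeration oracle.

* **Exact**: builds the `2^N × 2^N` transition matrix (capacity capped at
  N = 12), propagates the marginal from an independent Bernoulli(0.5)
  start (matching the simulator), and evaluates flow, production and the
  Shannon entropies with `0·log 0 = 0`.
* **Sampling**: runs `n_s` independent chains (default 10,000) and
  averages the exactly-computable model log-ratio over the sampled
  (x_{t-1}, x_t) pairs; a per-bin Monte-Carlo standard error is returned.
  The estimator is unbiased and its error decays as `n_s^{-1/2}`.
* **Mean-field**: treats the summed input to each neuron as Gaussian with
  mean and variance from independent marginal rates; rates follow the
  forward recursion `m_{i,t} = E_z[r(g + z√Δ)]` starting from `m_{i,0}`
  (by default each neuron's spiking probability averaged over all bins
  and trials when data are available, else 0.5).  Forward and backward
  conditional entropies are one-dimensional Gaussian integrals of the
  Bernoulli entropy χ and of `φ_{i,t}(h) = −[m_{i,t-1}h − ψ(h)]`; the
  decomposition `flow = −forward + backward` is exact by construction and
  per-neuron contributions are returned.
* **Steady state**: iterates the rate recursion to a fixed point (plain
  iteration, tolerance 1e-12, cap 2000; convergence failure raises with
  the residual) and evaluates the stationary integrand
  `(r(g + z√Δ) − m)·z√Δ`, the covariance between rate deviation and input
  fluctuation.

Gaussian integrals use 100-node Gauss–Hermite quadrature after the √2
change of variables; components with variance below 1e-12 are evaluated at
the mean.  All entropies are in nats.  When flow is estimated from a fit,
the smoothed means `θ_{t|T}` are plugged in; posterior uncertainty is not
propagated.

## Synthetic-data generator

Fields and couplings are independent Gaussian-process draws with squared-
exponential kernel `k(t,s) = k0·exp(−(t−s)²/2τ²)` (time in bins).  Default
study conditions: couplings with mean 5/N, variance 10/N, length-scale
30/√N (Sherrington–Kirkpatrick scaling — interactions weaken as the
population grows); fields with mean −3, variance 1, length-scale 50,
keeping populations sparsely active at large N.  GP sampling is by
Cholesky with diagonal jitter starting at `1e-10·k0`, escalating tenfold
to at most `1e-4·k0`.  Spike generation starts each trial from
i.i.d. Bernoulli(0.5) states.

Every stochastic operation derives an independent child stream keyed by
the global seed, an operation tag and the object indices, so the draw for
a population of size N is the leading sub-block of the draw for a larger
population under the same seed (nested system-size comparisons).

Trial shuffling permutes trial identities independently per neuron: the
per-neuron PSTH and within-trial single-neuron structure (hence
self-couplings) are preserved bit-for-bit while same-trial cross-neuron
alignment — the only footprint of cross-couplings — is destroyed.

What the generator does *not* emulate: refractoriness beyond the
self-coupling, higher-order dependencies (covered separately by the HOI
model), asynchronous updates, between-trial nonstationarity, and recording
artifacts.  Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to real-data
violations of them — which is exactly what the misspecification study
probes.

## Higher-order interaction model

The alternating-shrinking HOI model is a homogeneous exponential-family
law over binary patterns whose base measure cancels the binomial
multiplicity, giving the count law `P(n) ∝ exp(−f Q(n))` with
`Q(n) = Σ_j (−1)^{j+1} τ^j (n/N)^j` — sparse (mode at 0) yet widespread
(tail mass orders of magnitude above a rate-matched binomial).  Study
settings N = 30, f = 20, τ = 0.8.  The Gibbs sampler visits units in a
fresh random permutation per sweep, using the simplified conditional
log-odds; burn-in defaults to ~10% of sweeps with no thinning, because
consecutive sweeps deliberately become consecutive bins when the samples
are reorganized into a spike tensor (trial boundaries break the chain).

The misspecification experiment fits the kinetic Ising model with `Q`
frozen at zero to HOI data, resamples sequences from the fit, and compares
spike-count histograms via total variation; a self-consistency control
(kinetic-Ising data through the same loop) sets the baseline.  The two
activation functions are the HOI conditional log-odds, whose curvature is
positive over the upper half of the count range (acceleration toward
population synchrony; at low counts the combinatorial base-measure term
is concave), and the fitted model's affine input
`mean(fields) + mean(off-diagonal couplings)·ñ`.

## Downstream analyses

Sparsity CV and rate-difference skewness use population conventions
(divide by n) by default, with a `sample` flag.  Coupling asymmetry
averages `|θ̄_ij − θ̄_ji|` over unordered pairs (the choice of ordered vs
unordered only rescales comparisons).  Credible-interval screening marks a
coupling significant when its level-z interval excludes zero in at least
one window bin; the ≥1-bin union makes the rule anti-conservative relative
to the per-bin level.  The screen is calibrated (union false-positive rate
≤ 2·(1−level) per pair on uncoupled data) when the initial law is held
fixed during EM; the empirical-Bayes update `μ ← θ_{1|T}, Σ ← W_{1|T}`
re-centers the prior on the data and makes the bands overconfident on
stationary data (per-bin zero-exclusion ≈ 20% instead of 5% in our checks),
so fits feeding the screen should use `optimize_initial=False`.
Flow-per-activity-rate is, by default, the mean over neurons of each
neuron's summed flow contribution divided by its mean rate
(`per_spike_mode="per_neuron"`); a population-level normalization is
exposed as an alternative since either reading of "per activity rate" is
defensible.  d′ clamps rates to `[1/(2n), 1−1/(2n)]` before the probit.

## Validation studies and problem sizes

The validation module (exercised by the test suite and by
`scripts/acceptance.py`) runs at sizes chosen to finish in minutes on one
CPU as a deliberate design point:

* EM convergence: N = 2, T = 100, L = 200, spec-default tolerances.
* Recovery: N = 5, T = 50, L ∈ {50, 200, 800}, 5 ground truths,
  `em_rel_tol = 1e-5` (smoothed means and credible bands are unchanged at
  tighter tolerances; only the likelihood tail creeps) and the initial law
  held fixed (`optimize_initial=False`) for the calibration reasons above.
  Coverage is pooled over all (parameter, bin) pairs at L = 800.  In this
  N = 5 regime the SK-scaled coupling prior (mean 1.0, variance 2.0)
  produces occasional strongly coupled, high-rate draws in which field
  and coupling inputs are nearly collinear; estimates then carry bias
  along the ridge and marginal bands undercover somewhat.  A
  well-specified check (truth drawn from the model's own random-walk
  prior, hyperparameters frozen at truth) yields ≈0.94 coverage,
  confirming the Laplace machinery itself is calibrated.
* Oracles: joint MAP at N = 1, T = 4, L = 10 (BFGS on the exact log
  joint); marginal likelihood at N = 1, T = 2, L = 3 versus 40-node
  tensor Gauss–Hermite quadrature of the exact 4-dimensional integral.
* Entropy: 50 random systems (N ≤ 4) for the identities; N = 6, T = 10
  weak couplings for estimator equivalence with `n_s ∈ {10³, 10⁴, 10⁵}`.
* HOI: sampler check at N = 10 with 200k retained sweeps; misspecification
  at N = 30 with 40k retained sweeps and 30k resampled sequences.
* Perturbation scan: N = 8 with positive-mean couplings (so the system
  orders at large gain and the flow maximum is interior), β ∈ [0, 4].
* Shuffling: N = 4, T = 30, L = 300; six replicates for the independent-
  population null.

## Known limitations

* The Laplace filter is a single-pass Gaussian approximation; its
  marginal-likelihood surface is only approximately monotone under EM.
* Empirical-Bayes hyperparameters are point-optimized, so credible bands
  do not account for hyperparameter uncertainty and can undercover when
  the true parameter paths leave the random-walk prior class.
* The exact estimators scale as `4^N` and are capped at N = 12.
* Entropy flow from fitted models plugs in posterior means; no uncertainty
  propagation.
* The synchronous-update assumption makes all quantities bin-size
  dependent; the HOI study quantifies one direction of the resulting
  misspecification.
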