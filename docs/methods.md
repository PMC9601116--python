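# Methods

This note records the model, the estimators, the population (polity) model,
the synthetic-data generators, and the numerical and design choices behind
`politeia`, in enough detail to re-derive or audit any number the package
produces.

## 1. The coupled-stimulus environment

Two scalar stimuli evolve as

    dX₁/dt = −α₁ (X₁ − X₂) + β₁ η₁ ,
    dX₂/dt = −α₂ (X₂ − X₁) + β₂ η₂ ,

with independent unit white noises ηᵢ, relaxation couplings αᵢ ≥ 0
(units 1/time) and noise amplitudes βᵢ ≥ 0 (units length·time^(−1/2)).
Validation rejects α₁+α₂ = 0, β₁+β₂ = 0, and any single process with
αᵢ = βᵢ = 0 (a frozen stream has no well-defined information flow).

The linear change of variables

    D = X₁ − X₂ ,     C = (α₂ X₁ + α₁ X₂)/(α₁ + α₂)

diagonalises the drift: D is an Ornstein–Uhlenbeck process with rate
λ = α₁+α₂ and noise variance rate s_D = β₁²+β₂², and C is a driftless
diffusion with rate s_C = (α₂²β₁² + α₁²β₂²)/λ².  Because both are driven by
the same two noises they are cross-correlated, with rate
s_CD = (α₂β₁² − α₁β₂²)/λ.  Everything Gaussian about the model follows from
three covariance kernels (t₀ the start, s,t ≥ t₀):

* OU autocovariance: Cov(D(s), D(t)) = (s_D/2λ)(e^(−λ|t−s|) − e^(−λ(s+t−2t₀)));
  in the stationary limit R_D(h) = (s_D/2λ) e^(−λ|h|).
* C-increment overlap: Cov(C(u)−C(v), C(s)−C(r)) = s_C · |[v,u] ∩ [r,s]|.
* Cross term: Cov(C(t₂)−C(t₁), D(s)) = (s_CD/λ)(e^(−λ(s−min(s,t₂))) −
  e^(−λ(s−t₁))) for s ≥ t₁, zero otherwise (D predates the increment).

Dimensionless behaviour depends only on (a, b) = ((α₁−α₂)/λ, (β₁−β₂)/(β₁+β₂))
and Δt/τ, τ = 1/λ.  `params_from_asymmetries(a, b, tau)` constructs the
normalised representative (λ = 1/τ, β₁+β₂ = 1); `QualiaParams.rescaled()`
maps any parameter set to it.  The conventional fluctuation scale is quoted
as ℓ = (β₁+β₂)/λ; note that the stationary standard deviation of the
separation is √(s_D/2λ), which coincides with ℓ-based expressions only in
the λ = 1 normalisation — all validation examples are run there.

### Exact simulation

`simulate_paths` propagates (C, D) with the exact Gaussian one-step
transition kernel, including the C–D cross covariance accumulated over the
step, and maps back through X₁ = C + (α₁/λ)D, X₂ = C − (α₂/λ)D.  There is
no Euler bias at any step size, so simulation output is usable as an oracle
for the closed forms.  Runs of equal grid spacing are vectorised (one block
of Gaussian increments; the OU recursion becomes a linear filter), which is
an algebraically identical reorganisation of the stepping.  Default initial
condition in the generators: the two streams start 10 ℓ apart, and 20 τ of
burn-in precede any stationary sample.

## 2. The agent's view: reduced lag covariance

An agent with memory N and sampling interval Δt holds the present X₁(t) and
the 2N snapshots {X₁(t−kΔt)}, {X₂(t−kΔt)}, k = 1..N.  Because C is a random
walk, the raw covariance of these 2N+1 variables diverges as the process
ages.  All stationary computations therefore use coordinates *relative to
the oldest own-history snapshot* X₁(t−NΔt): each coordinate decomposes as

    [C(tᵢ) − C(t_ref)] + c_p D(tᵢ) − c₁ D(t_ref) ,  c₁ = α₁/λ, c₂ = −α₂/λ,

whose covariances are finite combinations of the three kernels above in the
t→∞ limit.  `stationary_lag_covariance` assembles this matrix exactly; the
reference coordinate itself is identically zero and is dropped wherever a
determinant is taken.

Why this leaves transfer entropy unchanged: conditioning own-past is
equivalent to conditioning the own-past *differences* plus the absolute
level X₁(t−NΔt); in the old-age limit the absolute level's variance
diverges while its covariances with every difference stay finite, so its
regression weight on the reduced coordinates vanishes and conditioning on
it has no effect.  The construction is validated three independent ways in
the test suite: (i) the finite-age unreduced covariance
(`finite_time_lag_covariance`), re-referenced, converges entry-wise to the
reduced matrix; (ii) the transfer entropy computed from it as a difference
of two mutual informations converges to the reduced conditional form;
(iii) Monte-Carlo ensembles of exact paths reproduce every entry within
sampling error.

## 3. Information measures

For Gaussian blocks, M[A:B] = ½ log₂ (|Σ_AA||Σ_BB| / |Σ|); all measures are
reported in bits.  Implementation notes:

* Matrices are normalised to unit diagonal before any determinant
  (per-variable scaling leaves every MI unchanged and improves
  conditioning); log-determinants use `slogdet`.
* A singular joint with regular marginals reports `inf` (perfect
  redundancy), not an exception.
* Transfer entropy is computed directly as the conditional mutual
  information T₂→₁ = I(X₁(t); X₂-past | X₁-past) from the reduced
  covariance — the difference-of-MIs form is algebraically equal but its
  two terms diverge individually in the raw coordinates, so it is kept
  only as a finite-age oracle in tests.  Values in [−10⁻¹², 0) are clamped
  to zero.
* The influence is (T₁→₂ − T₂→₁)/(T₁→₂ + T₂→₁), defined as exactly 0 when
  the total flow is below 10⁻¹² bits.  Positive sign means stream 1's
  history is the more informative.  The measure is invariant under affine
  rescaling of either stream and under the logarithm base.

### Small-asymmetry closed form

Linearising the exact N = 1 influence in the asymmetries gives, with
E = 1 − e^(−Δt) and φ = E/(Δt + E) (Δt in units of τ),

    T₁₂ ≈ (a+b)(2φ − 1) + (b−a)(2φ + 1)
        ≈ 2(b−a) − (a+b)Δt/4           (Δt ≪ 1),

implemented in `influence_small_limit`.  Its sign-change root
Δt\* = 8(b−a)/(a+b) exists in the small-Δt regime when the stochastic
asymmetry slightly exceeds the deterministic one (0 < b−a ≪ a+b); both the
root and the Δt-slope −(a+b)/4 are confirmed against finite differences of
the exact influence, with the residual error shrinking with log–log slope
≥ 3 along the regime path (a+b ∝ ε, b−a ∝ ε², Δt ∝ ε²).  A frequently
quoted alternative coefficient of 3/ln 2 for the slope is *not* reproduced
by the exact solution; the package treats the exact computation (validated
by simulation) as authoritative.

### Crossover structure

`crossover_scan` brackets sign changes of the analytic influence on a log
Δt grid and refines each bracket by geometric bisection to relative width
10⁻³ (exact zeros at grid nodes count as crossings).  At b = 0.03, N = 4
the sign-change band occupies 0 < a ≲ 0.03 — in the linear approximation a
crossing requires the deterministic asymmetry to sit between 0 and roughly
the stochastic one, so the band width scales with b (at b = 0.75 it spans
order-one values of a).  Slices
with a outside the band are single-signed in Δt.  Holding the look-back
window T = NΔt fixed does *not* remove the architecture dependence: at
a = 0.7, b = 0.75 the sign at fixed T differs between N = 1 and N = 8.

The Δt-locus of sign flips moves with N and saturates quickly: at b = 0.03
the maximum relative displacement between successive N drops below 2% at
N = 3 and below 0.1% by N = 5 — old snapshots beyond a few relaxation times
decorrelate and stop informing the estimate.  `scripts/acceptance.py`
recomputes this saturation point from scratch.

### Empirical estimator

`transfer_entropy_empirical` is the Gaussian plug-in: delay-embed both
series at the given stride, take the unbiased sample covariance of the raw
level embedding, and apply the conditional-MI determinant formula.  The
raw-level (rather than reference-subtracted) embedding makes the estimator
*exactly* invariant under separate affine maps of each stream — required
when the two streams carry different physical units — and remains
consistent because the pair is cointegrated (the separation is stationary
even though the common centre of mass walks).  Embedding vectors touching a
missing value are dropped; a rank-deficient embedding (e.g. a constant
stream) raises an error naming the offending block.  An optional shrinkage
flag blends the embedding correlation toward the identity for short series
(off by default).

## 4. Polities and belief distributions

A polity is described by `PolitySpec`: memory geometric on {1, 2, …} with
mean ⟨N⟩ (tail ratio x = 1 − 1/⟨N⟩), sampling interval log-normal with mean
⟨Δt⟩ and standard deviation θ of ln Δt (so the log-location is
ln⟨Δt⟩ − θ²/2), independent of each other.  Both marginals are exposed
through scipy distributions; censored populations redraw memory above the
cutoff.

`belief_distribution` pools per-architecture influence estimates into a
mixture: the ln Δt marginal is integrated by a composite midpoint rule with
exact per-cell normal masses (default 64 cells over ±8θ) and the memory sum
is truncated when the geometric tail falls below 10⁻¹⁰.  Midpoint was
chosen over Gaussian quadrature deliberately: the influence map may be
discontinuous in Δt (the step model below), where high-order rules
oscillate while midpoint degrades gracefully — the worst-case weight error
is the mass of the single cell straddling the jump.

Closed-form special cases:

* **Step model** (`step_model_belief`): if agents sampling faster than a
  critical interval τ\* estimate T₁₂,lo and the rest T₁₂,hi, the belief is
  two point masses with weights F(τ\*) and 1 − F(τ\*), F the log-normal CDF
  — equivalently (1−f)/2 and (1+f)/2 with f = 1 − 2F(τ\*).  f is computed
  from the CDF directly, which guarantees consistency with the mixture
  weights.
* **Censored two-camp model** (`censored_two_camp_belief`): agents with
  n ≤ N₁ hold N(μ₁, σ₁²), those with N₁ < n ≤ N₂ hold N(μ₂, σ₂²), and
  memories above N₂ are censored.  The weights are the geometric-CDF ratios
  (1 − x^N₁)/(1 − x^N₂) and (x^N₁ − x^N₂)/(1 − x^N₂); the boundary n = N₁
  belongs to camp 1.

`summarize_belief` reports the mixture mean, the median by CDF inversion
(atoms handled discretely), and the camp fractions below / at / above zero
influence; `has_consensus_problem` flags beliefs with more than a threshold
(default 10%) of mass on each side of zero.

A caution on spreading: with the mean-⟨Δt⟩ parametrisation, increasing θ
moves the step-model minority camp toward ½ only while θ² < 2|ln(τ\*/⟨Δt⟩)|;
beyond that the log-normal median e^(−θ²/2)⟨Δt⟩ runs away and the trend
reverses.  The monotonicity test covers the valid regime.

## 5. The empirical pipeline

`climate-run` (and the library functions underneath) processes two aligned
monthly series, e.g. a CO₂-concentration record (precision 0.01 ppm) and a
local temperature record (precision 0.1 °C):

1. **Ingestion** (`read_monthly_csv`): the NOAA monthly-mean layout
   (comment lines, year/month/value columns, negative fill codes masked,
   never dropped) or a generic date,value CSV; months are reindexed to a
   contiguous monthly grid, and a file providing fewer than half the months
   in its span is rejected as non-monthly cadence.
2. **Detrending** (`fit_remove_trend`): least squares of c₀ + c₁t (linear)
   or c₀ + c₁e^(c₂t) (exponential; nonlinear LS initialised from
   piecewise-linear slopes, explicit error with a linear fallback
   suggestion on non-convergence).  The exponential form is assigned to the
   CO₂-like series and the linear to the temperature-like series by
   configuration, not hard-coded.  Missing months are excluded from fits
   and preserved in residuals.
3. **Seasonal removal** (`remove_top_harmonics`): the k non-DC periodogram
   bins with the largest power (missing values mean-imputed for
   identification only), amplitudes and phases then fit jointly by least
   squares on the observed months and subtracted.  Because the time
   regressor is not exactly orthogonal to in-phase sinusoids, sequential
   trend→harmonic fitting can leave a small linear remnant; a second trend
   pass removes it (progressive removal).
4. **Bootstrap** (`bootstrap_substreams`): each replicate draws a start
   month uniformly from the configured range, keeps the substream to the
   end of the record, and adds i.i.d. Gaussian noise with standard
   deviation equal to each series' instrument precision ("noise at the
   significant digit").  Everything is reproducible from a single seed.
5. **Influence vs memory** (`influence_vs_memory`): for every replicate and
   every memory size n (Δt fixed at one month; a stride flag sub-samples
   for sensitivity analysis), both plug-in transfer entropies and the
   influence.  Replicates with fewer than 12 + 2·n_max usable months are
   skipped and counted.  Point estimates are replicate means; bands are
   replicate quantiles at 10% steps centred on the median.  The default
   replicate count in the CLI is 1000; the test suite uses 100 (the curve
   statistics are stable well below that).
6. **Polity scan** (`polity_belief_from_curve`): for each population mean
   memory ⟨N⟩, memory sizes are weighted by the geometric law truncated to
   the computed grid and every replicate's influence at that memory enters
   as an equal point mass; the scan reports mean, median and camp fractions
   per ⟨N⟩ and locates the ⟨N⟩ at which the belief median crosses zero —
   the point of maximal polarisation.

## 6. Synthetic data and what it does (not) emulate

`gen_coupled_ou` draws stationary paired samples of the model (exact
kernel, 20 τ burn-in).  `gen_climate_like` composes, per stream: secular
trend (exponential for the CO₂-like stream: 280 + 35·e^(0.0018 t) ppm over
768 months, reaching ≈ 420 ppm; linear for the temperature-like stream:
7 °C + 0.00125 °C/month), seasonal harmonics (annual and semiannual;
amplitudes 3 and 1 ppm, 2.5 and 0.4 °C), one exact draw of the coupled
residual pair scaled per stream (defaults 0.45 ppm and 0.75 °C per model
unit), and rounding to the instrument precision *after* the stochastic part
is added, so that bootstrap noise at the significant digit is meaningful.
Every generator is a pure function of (spec, seed), and the returned ground
truth reconstructs the clean series exactly.

The default residual coupling (a = 0.75, b = 0.7, τ = 1.5 months) has an
analytic influence sign change at memory N\* = 5 at monthly sampling
(`analytic_sign_change_memory`), emulating a record whose inferred flow
direction depends on the observer's look-back window.

Two limitations matter for interpreting tests on these fixtures:

* **Single-realisation noise.**  At the ~768-month length of real monthly
  records, the influence curve of one realisation fluctuates by ±0.1–0.2
  around the analytic curve and its sign-change memory wanders by a few
  units; some realisations never flip within n ≤ 12.  Parameter-recovery
  tests therefore run on a 3072-month variant (`recovery_spec`), where the
  estimator's sampling noise is small compared to the curve's slope through
  zero, and recover the crossover within ±1–2 memory units across fixture
  and bootstrap seeds.  Passing them shows estimator correctness, not that
  768 months of real data pin the crossover that tightly.
* **The centre-of-mass walk vs detrending.**  The model's residuals carry a
  common random-walk component.  A fitted smooth trend (especially the
  three-parameter exponential) partially chases each stream's walk,
  subtracting *different* smooth proxies from the two streams and thereby
  breaking the cointegration the level-embedding estimator relies on; this
  can reshape the influence curve of model-generated fixtures even though
  the same operation is benign on data whose residuals are stationary.
  The recovery fixtures therefore use flat baselines with no harmonics (the
  pipeline's linear detrend is then nearly idempotent and harmless), and
  detrending-robustness is asserted as sign-structure preservation under
  linear detrending, not as invariance under arbitrary trend fitting.

## 7. Problem sizes and tolerances used in the checks

* Lag-covariance vs Monte Carlo: 10⁴ replicates, entries within 4 standard
  errors, three parameter sets spanning a ∈ {−0.5, 0, 0.7}.
* Finite-age oracle: ages 300–3000 τ, relative agreement 10⁻⁴.
* Estimator/oracle grid: 3×3 asymmetry grid (a, b ∈ {−0.5, 0, 0.5}),
  10⁵ points each, agreement within 3 block-resampling standard errors
  (16 blocks).
* Locus saturation: a ∈ {0.004, …, 0.032}, Δt grid 41 points in
  [10⁻³, 10³], N = 1..10 (tests) / a-grid covering [−1, 1] with fine
  resolution in the band and N = 1..16 (acceptance script); stabilisation
  threshold 2% successive displacement.
* Polity closed forms: 10⁶ Monte-Carlo draws, 3 standard errors; censored
  weights exact to 10⁻¹².
* Pipeline recovery: 3072-month fixtures, 100 bootstrap replicates,
  memory grid 1..12, ±2 months around the analytic crossover, median-zero
  ⟨N⟩ stable within one 0.5-wide grid step across bootstrap seeds.

## 8. Known limitations

* Two streams only; no interaction between agents (beliefs are pooled, not
  exchanged); uniform pooling weights.
* Gaussian (linear) transfer entropy only — appropriate to the model, a
  choice for real data; nonlinear estimators (k-NN, symbolic) are out of
  scope.
* The influence of measurement noise is only treated through the bootstrap
  perturbation, not as part of the analytic model.
* No gap imputation: missing months simply remove embedding vectors.
* Nothing here supports causal claims about any real data pair; the
  influence is a statement about predictive correlations as seen by a
  particular cognitive architecture.
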