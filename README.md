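# politeia

Transfer-entropy consensus analysis for populations of agents with
heterogeneous memory and sampling.

Any observer with finite resources estimates the statistics of its
environment from `N` stored snapshots taken every `Δt` time units.  Two
observers watching *identical* data streams but storing them differently can
reach opposite conclusions about which stream carries predictive information
about the other.  `politeia` provides an exactly solvable setting in which
this effect can be computed in closed form, plus the machinery to ask the
population-level question: when does a *polity* — a pool of independent
observers with a distribution of cognitive architectures — fail to reach
consensus on the direction of information flow?

It is aimed at researchers in information dynamics, collective cognition and
sociophysics who want a fully analytic benchmark for transfer-entropy
estimation under sub-sampling, and a reference implementation of the
belief-aggregation pipeline for paired monthly time series.

## The model

Two coupled scalar stimuli relax toward each other under independent white
noises,

    dX₁/dt = −α₁ (X₁ − X₂) + β₁ η₁
    dX₂/dt = −α₂ (X₂ − X₁) + β₂ η₂ ,

with relaxation couplings αᵢ ≥ 0 and noise amplitudes βᵢ ≥ 0.  The pair
diagonalises into a driftless diffusion for the coupling-weighted centre of
mass and an Ornstein–Uhlenbeck process for the separation, so every joint
law is Gaussian and known in closed form.  The behaviour is governed by the
asymmetries

    a = (α₁ − α₂)/(α₁ + α₂),   b = (β₁ − β₂)/(β₁ + β₂) ∈ [−1, 1]

and the natural scales τ = 1/(α₁+α₂), ℓ = (β₁+β₂)/(α₁+α₂).

An observer with architecture (N, Δt) estimates the directed transfer
entropy T₂→₁ = I(X₁(t) ; X₂-past | X₁-past) over its stored snapshots, and
the normalised **influence**

    T₁₂ = (T₁→₂ − T₂→₁) / (T₁→₂ + T₂→₁) ∈ [−1, 1],

whose sign encodes the inferred direction of information flow.  For Gaussian
processes every term is a ratio of covariance determinants, so the influence
is available exactly for any (a, b, N, Δt) — and it can change sign as a
function of N or Δt alone.  Populations whose architecture distribution
straddles such a sign change split into camps: the consensus problem.

## Worked example

```python
import numpy as np
from politeia import (Architecture, params_from_asymmetries,
                      transfer_entropy_pair_analytic, influence,
                      crossover_scan)

params = params_from_asymmetries(a=0.01, b=0.03)   # tau = 1 time units
arch = Architecture(n=4, dt=0.5)

pair = transfer_entropy_pair_analytic(params, arch)
print(f"T[1->2] = {pair.te_1to2:.6f} bits")
print(f"T[2->1] = {pair.te_2to1:.6f} bits")
print(f"influence = {influence(pair).value:+.4f}")

roots = crossover_scan(params, 4, np.logspace(-3, 3, 60))
print("influence sign change at dt =", roots)
```

prints

```
T[1->2] = 0.059732 bits
T[2->1] = 0.052505 bits
influence = +0.0644
influence sign change at dt = [10.2516045]
```

At this parameter point an observer sampling twice per relaxation time
concludes that stream 1 is the (mildly) more informative one (influence
+0.064); the scan shows that an observer sampling more slowly than
Δt ≈ 10.3 τ reaches the *opposite* conclusion.  Pooling a population whose
sampling intervals straddle that crossover,

```python
from politeia import PolitySpec, belief_distribution, summarize_belief, influence_analytic

spec = PolitySpec(mean_n=4.0, mean_dt=8.0, theta=1.2)
belief = belief_distribution(spec, lambda a_: influence_analytic(params, a_),
                             quad_nodes=48)
s = summarize_belief(belief)
print(f"mean {s.mean:+.4f}  median {s.median:+.4f}  "
      f"camps -/+ = {s.frac_negative:.3f}/{s.frac_positive:.3f}")
```

```
mean +0.0208  median +0.0189  camps -/+ = 0.282/0.718
```

— 28% of this polity believes the flow runs the other way even though every
agent saw the same streams without noise or error.

The same analysis runs on real or synthetic paired monthly data from the
command line:

```bash
politeia influence-scan -a 0.01 -b 0.03 -n 4 --out scan.csv
politeia make-fixtures --months 768 --seed 0 --out fixtures/
politeia climate-run --co2 fixtures/co2_like.csv --temp fixtures/temp_like.csv \
    --detrend trend+harmonics:2 --nboot 1000 --out results/
```

`climate-run` detrends the pair, bootstraps substreams with random start
dates and measurement noise at the instrument precision, computes the
transfer entropies for every memory size at monthly sampling, and writes the
influence-vs-memory curve with bootstrap bands plus the polity belief
distributions as a function of the population mean memory.

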