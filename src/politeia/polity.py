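"""Populations of agents and the belief distributions their estimates form.

A *polity* is a population of independent agents whose cognitive
architectures (memory size ``n``, sampling interval ``dt``) are drawn from a
population law: geometric in ``n`` (mean ``<N>``) and log-normal in ``dt``
(mean ``<dt>``, log-standard-deviation ``theta``).  Each agent estimates the
influence between the same pair of data streams according to its own
architecture; pooling those estimates yields a mixture *belief distribution*
over influence values.  When the population law straddles a surface of
vanishing influence the mixture develops camps on both sides of zero and the
population cannot agree on the direction of information flow -- the
consensus problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .model import Architecture

__all__ = [
    "PolitySpec",
    "BeliefDistribution",
    "BeliefSummary",
    "polity_pdf",
    "sample_agents",
    "belief_distribution",
    "step_model_belief",
    "censored_two_camp_belief",
    "summarize_belief",
    "has_consensus_problem",
]

#: geometric tail mass below which the memory sum is truncated
_N_TAIL = 1e-10


@dataclass(frozen=True)
class PolitySpec:
    """Population law over cognitive architectures.

    The memory marginal is geometric on {1, 2, ...} with mean ``mean_n``
    (success probability ``1/mean_n``, so ``x = 1 - 1/mean_n`` is the
    tail ratio); the sampling-interval marginal is log-normal with mean
    ``mean_dt`` and standard deviation ``theta`` of ``ln dt``.  The two are
    independent.
    """

    mean_n: float
    mean_dt: float
    theta: float
    censor_lo: int | None = None  # camp-1 boundary N1 (n <= N1)
    censor_hi: int | None = None  # censoring bound N2 (n > N2 excluded)
    allow_point_n: bool = False   # permit mean_n == 1 (all agents have n = 1)

    def __post_init__(self) -> None:
        if self.allow_point_n:
            if self.mean_n < 1:
                raise ValueError("mean_n must be >= 1")
        elif self.mean_n <= 1:
            raise ValueError(
                "mean_n must exceed 1 (set allow_point_n=True for the "
                "degenerate all-n=1 population)"
            )
        if self.mean_dt <= 0:
            raise ValueError("mean_dt must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if (self.censor_lo is None) != (self.censor_hi is None):
            raise ValueError("censoring requires both bounds")
        if self.censor_lo is not None and not (1 <= self.censor_lo < self.censor_hi):
            raise ValueError("censoring bounds must satisfy 1 <= N1 < N2")

    @property
    def x(self) -> float:
        """Geometric tail ratio x = 1 - 1/<N>."""
        return 1.0 - 1.0 / self.mean_n

    @property
    def _log_mu(self) -> float:
        """Location of ln dt so that E[dt] = mean_dt given Var[ln dt] = theta^2."""
        return math.log(self.mean_dt) - 0.5 * self.theta**2

    def n_pmf(self, n: np.ndarray | int) -> np.ndarray | float:
        """Geometric memory marginal P(N = n) on {1, 2, ...}."""
        n = np.asarray(n)
        out = np.where(n >= 1, (1 - self.x) * self.x ** (n - 1.0), 0.0)
        return out if out.ndim else float(out)

    def dt_marginal(self) -> stats.rv_continuous:
        """Frozen log-normal marginal of the sampling interval."""
        return stats.lognorm(s=self.theta, scale=math.exp(self._log_mu))

    def dt_cdf(self, dt: float) -> float:
        return float(self.dt_marginal().cdf(dt))


def polity_pdf(spec: PolitySpec, n: int, dt: float) -> float:
    """Population density rho_N(dt): geometric pmf times log-normal pdf."""
    if int(n) != n or n < 1:
        raise ValueError("n must be an integer >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(spec.n_pmf(int(n))) * float(spec.dt_marginal().pdf(dt))


def sample_agents(spec: PolitySpec, size: int, seed: int | None = None) -> list[Architecture]:
    """Draw i.i.d. architectures from the population law.

    With censoring bounds set, draws with ``n > N2`` are rejected and
    redrawn, so the returned population is the censored polity.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    p = 1.0 / spec.mean_n
    n = rng.geometric(p, size=size)
    if spec.censor_hi is not None:
        while True:
            bad = n > spec.censor_hi
            if not bad.any():
                break
            n[bad] = rng.geometric(p, size=int(bad.sum()))
    dt = rng.lognormal(mean=spec._log_mu, sigma=spec.theta, size=size)
    return [Architecture(int(k), float(d)) for k, d in zip(n, dt)]


@dataclass
class BeliefDistribution:
    """Mixture of point masses and Gaussians over influence values.

    ``components`` is a list of ``(weight, kind, location, scale)`` tuples
    with ``kind`` in {"point", "gaussian"}; weights are non-negative and sum
    to one, and point components have scale 0.
    """

    components: list[tuple[float, str, float, float]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        if np.any(w < -1e-15):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        for _, kind, _, scale in self.components:
            if kind not in ("point", "gaussian"):
                raise ValueError(f"unknown component kind {kind!r}")
            if kind == "gaussian" and scale <= 0:
                raise ValueError("gaussian components need positive scale")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def locations(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    def _arrays(self):
        w = self.weights
        locs = self.locations
        scales = np.array([c[3] for c in self.components])
        is_pt = np.array([c[1] == "point" for c in self.components])
        return w, locs, scales, is_pt

    def mean(self) -> float:
        return float(sum(w * loc for w, _, loc, _ in self.components))

    def cdf(self, v: float) -> float:
        """Right-continuous mixture CDF P(T <= v)."""
        w, locs, scales, is_pt = self._arrays()
        total = float(np.sum(w[is_pt] * (locs[is_pt] <= v)))
        if (~is_pt).any():
            total += float(
                np.sum(w[~is_pt] * stats.norm.cdf(v, locs[~is_pt], scales[~is_pt]))
            )
        return total

    def mass_below(self, v: float) -> float:
        """Strict mass P(T < v)."""
        w, locs, scales, is_pt = self._arrays()
        total = float(np.sum(w[is_pt] * (locs[is_pt] < v)))
        if (~is_pt).any():
            total += float(
                np.sum(w[~is_pt] * stats.norm.cdf(v, locs[~is_pt], scales[~is_pt]))
            )
        return total

    def median(self) -> float:
        """Median by CDF inversion (smallest v with CDF(v) >= 1/2)."""
        w, locs, scales, is_pt = self._arrays()
        if is_pt.all():
            order = np.argsort(locs, kind="stable")
            cum = np.cumsum(w[order])
            return float(locs[order][np.searchsorted(cum, 0.5 - 1e-12)])
        lo = float((locs - 10 * scales - 1e-12).min())
        hi = float((locs + 10 * scales + 1e-12).max())
        if self.cdf(lo) >= 0.5:
            return lo
        # an atom can carry the CDF past 1/2 discontinuously
        for v in sorted(set(locs[is_pt])):
            if self.mass_below(v) < 0.5 <= self.cdf(v):
                return float(v)
        return float(brentq(lambda v: self.cdf(v) - 0.5, lo, hi, xtol=1e-12))


def belief_distribution(
    spec: PolitySpec,
    influence_given_arch: Callable[[Architecture], float | tuple[float, float]],
    quad_nodes: int = 64,
) -> BeliefDistribution:
    """Pool per-architecture influence estimates into a polity mixture.

    ``influence_given_arch`` maps an :class:`Architecture` to either a
    certain estimate (a float -> point mass) or an uncertain one (a
    ``(mean, sd)`` pair -> Gaussian component).  The dt marginal is handled
    by a composite midpoint rule in ``ln dt`` (``quad_nodes`` cells over
    +/- 8 theta; robust to discontinuous influence maps) and the memory sum
    is truncated once the geometric tail mass drops below 1e-10; weights
    are renormalised to machine precision.
    """
    # midpoint rule in z = (ln dt - mu)/theta against the standard normal pdf
    half = 8.0
    edges = np.linspace(-half, half, quad_nodes + 1)
    z = 0.5 * (edges[:-1] + edges[1:])
    qw = np.diff(stats.norm.cdf(edges))
    qw = qw / qw.sum()

    n_max = max(2, int(math.ceil(math.log(_N_TAIL) / math.log(spec.x))) if spec.x > 0 else 1)
    n_vals = np.arange(1, n_max + 1)
    n_w = np.asarray(spec.n_pmf(n_vals), dtype=float)
    n_w = n_w / n_w.sum()

    comps: list[tuple[float, str, float, float]] = []
    for n, wn in zip(n_vals, n_w):
        for zi, wq in zip(z, qw):
            dt = math.exp(spec._log_mu + spec.theta * zi)
            est = influence_given_arch(Architecture(int(n), dt))
            w = float(wn * wq)
            if w == 0.0:
                continue
            if isinstance(est, tuple):
                mean, sd = est
                comps.append((w, "gaussian", float(mean), float(sd)))
            else:
                comps.append((w, "point", float(est), 0.0))
    total = sum(c[0] for c in comps)
    comps = [(w / total, k, m, s) for w, k, m, s in comps]
    return BeliefDistribution(comps, meta={"spec": spec, "kind": "pooled"})


def step_model_belief(
    spec: PolitySpec, tau_star: float, t_lo: float, t_hi: float
) -> BeliefDistribution:
    """Bimodal belief for a step-shaped influence of the sampling interval.

    Agents sampling faster than the critical interval ``tau_star`` estimate
    ``t_lo``; the rest estimate ``t_hi``.  With ``f = 1 - 2 F(tau_star)``
    (``F`` the log-normal CDF of dt) the two camps carry weights
    ``(1 - f)/2`` and ``(1 + f)/2`` -- the fractions of the population on
    either side of the critical sampling time.
    """
    if tau_star <= 0:
        raise ValueError("tau_star must be positive")
    w_lo = spec.dt_cdf(tau_star)
    comps = []
    if w_lo > 0:
        comps.append((w_lo, "point", float(t_lo), 0.0))
    if 1.0 - w_lo > 0:
        comps.append((1.0 - w_lo, "point", float(t_hi), 0.0))
    return BeliefDistribution(
        comps, meta={"spec": spec, "kind": "step", "tau_star": tau_star,
                     "f": 1.0 - 2.0 * w_lo}
    )


def censored_two_camp_belief(
    spec: PolitySpec,
    n1: int,
    n2: int | None,
    mu1: float,
    sigma1: float,
    mu2: float,
    sigma2: float,
) -> BeliefDistribution:
    """Two Gaussian camps split by memory size, with censoring above ``n2``.

    Agents with memory ``n <= n1`` hold belief ``N(mu1, sigma1^2)``; agents
    with ``n1 < n <= n2`` hold ``N(mu2, sigma2^2)``; agents with ``n > n2``
    are censored (excluded from the polity).  With ``x = 1 - 1/<N>`` the
    camp weights are the geometric-CDF ratios::

        w1 = (1 - x^n1) / (1 - x^n2),   w2 = (x^n1 - x^n2) / (1 - x^n2)

    ``n2=None`` means no upper censoring (weights ``1 - x^n1`` and ``x^n1``).
    """
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    if n2 is not None and n2 <= n1:
        raise ValueError("need n1 < n2")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be positive")
    x = spec.x
    xn2 = 0.0 if n2 is None else x**n2
    denom = 1.0 - xn2
    w1 = (1.0 - x**n1) / denom
    w2 = (x**n1 - xn2) / denom
    return BeliefDistribution(
        [(w1, "gaussian", mu1, sigma1), (w2, "gaussian", mu2, sigma2)],
        meta={"spec": spec, "kind": "censored-two-camp", "n1": n1, "n2": n2},
    )


@dataclass(frozen=True)
class BeliefSummary:
    mean: float
    median: float
    frac_negative: float
    frac_zero: float
    frac_positive: float


def summarize_belief(belief: BeliefDistribution) -> BeliefSummary:
    """Mixture mean, median, and the camp fractions below/at/above zero."""
    neg = belief.mass_below(0.0)
    at = sum(w for w, kind, loc, _ in belief.components if kind == "point" and loc == 0.0)
    return BeliefSummary(
        mean=belief.mean(),
        median=belief.median(),
        frac_negative=neg,
        frac_zero=at,
        frac_positive=1.0 - neg - at,
    )


def has_consensus_problem(belief: BeliefDistribution, threshold: float = 0.10) -> bool:
    """True when camps on both sides of zero each exceed ``threshold``."""
    s = summarize_belief(belief)
    return s.frac_negative > threshold and s.frac_positive > threshold
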