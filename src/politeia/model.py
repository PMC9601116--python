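"""Coupled two-stimulus environment model and its exact Gaussian solution.

The environment consists of two scalar stimuli ``X1`` and ``X2`` that relax
toward each other while being driven by independent white noises::

    dX1/dt = -alpha1 (X1 - X2) + beta1 eta1
    dX2/dt = -alpha2 (X2 - X1) + beta2 eta2

The pair diagonalises into a driftless diffusion for the coupling-weighted
centre of mass ``C = (alpha2 X1 + alpha1 X2) / (alpha1 + alpha2)`` and an
Ornstein--Uhlenbeck process for the separation ``D = X1 - X2``.  Both are
Gaussian, so every joint law the information measures need is a multivariate
normal determined by a handful of closed-form covariance kernels.  This module
provides the parameter container, exact (discretisation-free) path simulation,
and the stationary lag-covariance matrix of an agent's sampled history.

Because the centre of mass is a random walk, raw covariances grow without
bound as the process ages.  All stationary quantities are therefore expressed
relative to the oldest sample of the predicted process' own history, in which
coordinates the old-age limit is finite; conditional mutual informations (and
hence transfer entropies) are unchanged by this reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QualiaParams",
    "Architecture",
    "PathEnsemble",
    "LagCovariance",
    "make_params",
    "params_from_asymmetries",
    "simulate_paths",
    "stationary_lag_covariance",
    "finite_time_lag_covariance",
]


@dataclass(frozen=True)
class QualiaParams:
    """Couplings of the two-stimulus environment.

    Parameters
    ----------
    alpha1, alpha2 : float
        Deterministic (relaxation) couplings, units 1/time.  Non-negative,
        not both zero.
    beta1, beta2 : float
        Stochastic (noise) amplitudes, units length/sqrt(time).  Non-negative,
        not both zero.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "beta1", "beta2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.alpha1 + self.alpha2 <= 0:
            raise ValueError("alpha1 + alpha2 must be positive (degenerate model)")
        if self.beta1 + self.beta2 <= 0:
            raise ValueError("beta1 + beta2 must be positive (degenerate model)")
        if self.alpha1 + self.beta1 <= 0 or self.alpha2 + self.beta2 <= 0:
            raise ValueError(
                "a process with zero coupling and zero noise is frozen "
                "(ill-defined information flow)"
            )

    # -- derived asymmetries and natural scales ------------------------------
    @property
    def a(self) -> float:
        """Deterministic asymmetry (alpha1-alpha2)/(alpha1+alpha2), in [-1, 1]."""
        return (self.alpha1 - self.alpha2) / (self.alpha1 + self.alpha2)

    @property
    def b(self) -> float:
        """Stochastic asymmetry (beta1-beta2)/(beta1+beta2), in [-1, 1]."""
        return (self.beta1 - self.beta2) / (self.beta1 + self.beta2)

    @property
    def tau(self) -> float:
        """Relaxation time 1/(alpha1+alpha2) of the separation process."""
        return 1.0 / (self.alpha1 + self.alpha2)

    @property
    def ell(self) -> float:
        """Natural fluctuation scale (beta1+beta2)/(alpha1+alpha2)."""
        return (self.beta1 + self.beta2) / (self.alpha1 + self.alpha2)

    def swapped(self) -> "QualiaParams":
        """Relabel the two processes (negates both asymmetries)."""
        return QualiaParams(self.alpha2, self.alpha1, self.beta2, self.beta1)

    def rescaled(self) -> "QualiaParams":
        """Equivalent parameters in natural units (tau = 1, beta1+beta2 = 1).

        Time is measured in units of ``tau`` and lengths in units of the
        stationary noise scale; the asymmetries ``a`` and ``b`` -- the only
        quantities the dimensionless influence depends on -- are preserved.
        """
        lam = self.alpha1 + self.alpha2
        bsum = self.beta1 + self.beta2
        return QualiaParams(
            self.alpha1 / lam, self.alpha2 / lam, self.beta1 / bsum, self.beta2 / bsum
        )

    # -- diagonalised noise rates -------------------------------------------
    @property
    def _lam(self) -> float:
        return self.alpha1 + self.alpha2

    @property
    def _s_d(self) -> float:
        """Noise variance rate of the separation D."""
        return self.beta1**2 + self.beta2**2

    @property
    def _s_c(self) -> float:
        """Noise variance rate of the centre of mass C."""
        lam = self._lam
        return (self.alpha2**2 * self.beta1**2 + self.alpha1**2 * self.beta2**2) / lam**2

    @property
    def _s_cd(self) -> float:
        """Cross covariance rate between the C and D noises."""
        return (self.alpha2 * self.beta1**2 - self.alpha1 * self.beta2**2) / self._lam

    def to_dict(self) -> dict:
        return {
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "beta1": self.beta1,
            "beta2": self.beta2,
        }


def make_params(
    alpha1: float, alpha2: float, beta1: float, beta2: float
) -> QualiaParams:
    """Validate couplings and return a :class:`QualiaParams`."""
    return QualiaParams(alpha1, alpha2, beta1, beta2)


def params_from_asymmetries(a: float, b: float, tau: float = 1.0) -> QualiaParams:
    """Build parameters from the asymmetries ``a``, ``b`` at relaxation time tau.

    Uses the convention ``alpha1+alpha2 = 1/tau`` and ``beta1+beta2 = 1``;
    all dimensionless information measures depend on the couplings only
    through ``(a, b)`` and the combination ``dt/tau``.
    """
    if not (-1.0 <= a <= 1.0) or not (-1.0 <= b <= 1.0):
        raise ValueError("asymmetries must lie in [-1, 1]")
    if tau <= 0:
        raise ValueError("tau must be positive")
    lam = 1.0 / tau
    return QualiaParams(lam * (1 + a) / 2, lam * (1 - a) / 2, (1 + b) / 2, (1 - b) / 2)


@dataclass(frozen=True)
class Architecture:
    """An agent's cognitive architecture: memory size and sampling interval.

    ``n`` past snapshots taken every ``dt`` time units give a look-back
    window of ``n * dt``.
    """

    n: int
    dt: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"memory size n must be an integer >= 1, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError(f"sampling interval dt must be positive, got {self.dt!r}")

    @property
    def window(self) -> float:
        """Total look-back window T = n * dt."""
        return self.n * self.dt


@dataclass
class PathEnsemble:
    """Replicated exact sample paths of the two stimuli on a common grid."""

    t: np.ndarray  # shape (n_t,)
    x1: np.ndarray  # shape (n_reps, n_t)
    x2: np.ndarray  # shape (n_reps, n_t)
    params: QualiaParams
    seed: int | None = None

    @property
    def n_reps(self) -> int:
        return self.x1.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (columns: replicate, t, x1, x2)."""
        n_reps, n_t = self.x1.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(n_reps), n_t),
                "t": np.tile(self.t, n_reps),
                "x1": self.x1.ravel(),
                "x2": self.x2.ravel(),
            }
        )

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write trajectories as tidy CSV with a YAML parameter sidecar."""
        path = str(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {"params": self.params.to_dict(), "seed": self.seed,
                    "n_reps": int(self.n_reps)}
            with open(path + ".yaml", "w") as fh:
                yaml.safe_dump(meta, fh)


def _step_cov(params: QualiaParams, h: float) -> np.ndarray:
    """Exact covariance of the (C, D) increments over a step of length h."""
    lam = params._lam
    e = math.exp(-lam * h)
    var_c = params._s_c * h
    var_d = params._s_d / (2 * lam) * (1 - e * e)
    cov_cd = params._s_cd / lam * (1 - e)
    return np.array([[var_c, cov_cd], [cov_cd, var_d]])


def simulate_paths(
    params: QualiaParams,
    x0_pair: tuple[float, float],
    t_grid: np.ndarray,
    n_reps: int = 1,
    seed: int | None = None,
) -> PathEnsemble:
    """Sample exact trajectories of the coupled pair on ``t_grid``.

    The pair is propagated in the diagonal (C, D) coordinates with the exact
    Gaussian transition kernel of each step -- including the C--D cross
    covariance induced by the shared noises -- so there is no time
    discretisation bias and arbitrarily coarse grids are exact.

    Parameters
    ----------
    params : QualiaParams
    x0_pair : (float, float)
        Initial values (X1(t0), X2(t0)) at the first grid time.
    t_grid : array
        Strictly increasing sample times; the first entry is the initial time.
    n_reps : int
        Number of independent replicates.
    seed : int, optional
        Seed for the random generator; identical seeds give identical paths.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2:
        raise ValueError("t_grid must be a 1-d array with at least two times")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    lam = params._lam
    c1 = params.alpha1 / lam
    c2 = -params.alpha2 / lam

    n_t = t_grid.size
    c = np.empty((n_reps, n_t))
    d = np.empty((n_reps, n_t))
    x1_0, x2_0 = x0_pair
    c[:, 0] = (params.alpha2 * x1_0 + params.alpha1 * x2_0) / lam
    d[:, 0] = x1_0 - x2_0
    # process runs of equal spacing together: increments are drawn in one
    # block and the OU recursion becomes a linear filter (exact, just fast)
    from scipy.signal import lfilter

    steps = np.diff(t_grid)
    boundaries = np.nonzero(~np.isclose(steps[1:], steps[:-1], rtol=1e-12,
                                        atol=0.0))[0] + 1
    seg_starts = np.concatenate(([0], boundaries, [steps.size]))
    for s, stop in zip(seg_starts[:-1], seg_starts[1:]):
        h = float(steps[s])
        m = stop - s
        chol = np.linalg.cholesky(_step_cov(params, h) + 1e-300 * np.eye(2))
        z = rng.standard_normal((n_reps, m, 2)) @ chol.T
        e = math.exp(-lam * h)
        c[:, s + 1: stop + 1] = c[:, [s]] + np.cumsum(z[:, :, 0], axis=1)
        decay = e ** np.arange(1, m + 1)
        d[:, s + 1: stop + 1] = (
            lfilter([1.0], [1.0, -e], z[:, :, 1], axis=1) + d[:, [s]] * decay
        )

    return PathEnsemble(
        t=t_grid, x1=c + c1 * d, x2=c + c2 * d, params=params, seed=seed
    )


@dataclass
class LagCovariance:
    """Joint Gaussian covariance of an agent's sampled view of the pair.

    The ``2n+1`` coordinates are, in order, the predicted process' present
    value and the stored snapshots of both processes::

        index 0        : X1(t)          - X1(t - n dt)
        index k (1..n) : X1(t - k dt)   - X1(t - n dt)
        index n + k    : X2(t - k dt)   - X1(t - n dt)   (k = 1..n)

    Every coordinate is taken relative to the reference ``X1(t - n dt)``, the
    oldest own-history snapshot; the coordinate at index ``n`` is therefore
    identically zero.  In these divergence-free coordinates the stationary
    (old-age) covariance is finite even though the raw process has a random
    walk component.
    """

    matrix: np.ndarray
    params: QualiaParams
    arch: Architecture
    labels: list[str] = field(default_factory=list)

    @property
    def future_index(self) -> int:
        return 0

    @property
    def own_past_indices(self) -> list[int]:
        """Non-degenerate own-history coordinates (reference excluded)."""
        return list(range(1, self.arch.n))

    @property
    def other_past_indices(self) -> list[int]:
        return list(range(self.arch.n + 1, 2 * self.arch.n + 1))


def _coordinate_labels(n: int) -> list[str]:
    labels = ["x1[t]"]
    labels += [f"x1[t-{k}dt]" for k in range(1, n + 1)]
    labels += [f"x2[t-{k}dt]" for k in range(1, n + 1)]
    return labels


def stationary_lag_covariance(
    params: QualiaParams, arch: Architecture
) -> LagCovariance:
    """Exact old-age covariance of the reduced history coordinates.

    Each coordinate decomposes as ``[C(t_i) - C(t_n)] + c_p D(t_i) - c_1
    D(t_n)`` with ``c_1 = alpha1/lam`` and ``c_2 = -alpha2/lam``; the entries
    are assembled from the closed-form centre-of-mass increment variance, the
    stationary Ornstein--Uhlenbeck autocovariance of the separation, and
    their cross term.  All entries are finite and the matrix is positive
    semi-definite (with one identically-zero coordinate, the reference).
    """
    n, dt = arch.n, arch.dt
    lam = params._lam
    s_c, s_d, s_cd = params._s_c, params._s_d, params._s_cd
    r0 = s_d / (2 * lam)

    # sample times relative to the present; t_ref is the oldest own snapshot
    times = np.concatenate(([0.0], -dt * np.arange(1, n + 1), -dt * np.arange(1, n + 1)))
    procs = np.concatenate(([1], np.ones(n, dtype=int), np.full(n, 2, dtype=int)))
    t_ref = -n * dt
    c1 = params.alpha1 / lam
    coef = np.where(procs == 1, c1, -params.alpha2 / lam)

    ti = times[:, None]
    tj = times[None, :]
    # centre-of-mass increment overlap, OU autocovariance, and their cross
    # term Cov(C(t_i)-C(t_ref), D(t_j)) (zero when t_j = t_ref)
    cc = s_c * (np.minimum(ti, tj) - t_ref)
    rd = r0 * np.exp(-lam * np.abs(ti - tj))
    cd = (s_cd / lam) * (
        np.exp(-lam * (tj - np.minimum(ti, tj))) - np.exp(-lam * (tj - t_ref))
    )
    rd_ref = r0 * np.exp(-lam * np.abs(times - t_ref))
    cov = (
        cc
        + cd * coef[None, :]
        + cd.T * coef[:, None]
        + np.outer(coef, coef) * rd
        - c1 * np.add.outer(coef * rd_ref, coef * rd_ref)
        + c1 * c1 * r0
    )
    # the reference coordinate is identically zero by construction
    cov[n, :] = 0.0
    cov[:, n] = 0.0
    return LagCovariance(matrix=cov, params=params, arch=arch,
                         labels=_coordinate_labels(n))


def finite_time_lag_covariance(
    params: QualiaParams, arch: Architecture, age: float
) -> LagCovariance:
    """Unreduced covariance of the raw coordinates a finite time after start.

    The process starts from a deterministic initial condition ``age`` time
    units before the present; the returned matrix is the covariance of the
    raw (un-referenced) coordinates ``X1(t), X1(t-k dt), X2(t-k dt)``.  It
    grows without bound as ``age`` increases -- it exists as an independent
    cross-check of :func:`stationary_lag_covariance`: conditional mutual
    informations computed from it converge to the reduced stationary values.
    """
    n, dt = arch.n, arch.dt
    if age <= n * dt:
        raise ValueError("age must exceed the look-back window n*dt")
    lam = params._lam
    s_c, s_d, s_cd = params._s_c, params._s_d, params._s_cd
    t0 = -age

    times = np.concatenate(([0.0], -dt * np.arange(1, n + 1), -dt * np.arange(1, n + 1)))
    procs = np.concatenate(([1], np.ones(n, dtype=int), np.full(n, 2, dtype=int)))
    coef = np.where(procs == 1, params.alpha1 / lam, -params.alpha2 / lam)

    def cov_dd(s: float, t: float) -> float:
        return (s_d / (2 * lam)) * (
            math.exp(-lam * abs(t - s)) - math.exp(-lam * (s + t - 2 * t0))
        )

    def cov_cc(s: float, t: float) -> float:
        return s_c * (min(s, t) - t0)

    def cov_c_d(t: float, s: float) -> float:
        return (s_cd / lam) * (
            math.exp(-lam * (s - min(t, s))) - math.exp(-lam * (s - t0))
        )

    m = 2 * n + 1
    cov = np.empty((m, m))
    for i in range(m):
        ti, ci = times[i], coef[i]
        for j in range(i + 1):
            tj, cj = times[j], coef[j]
            v = (
                cov_cc(ti, tj)
                + cj * cov_c_d(ti, tj)
                + ci * cov_c_d(tj, ti)
                + ci * cj * cov_dd(ti, tj)
            )
            cov[i, j] = cov[j, i] = v
    return LagCovariance(matrix=cov, params=params, arch=arch,
                         labels=_coordinate_labels(n))
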