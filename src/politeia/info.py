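"""Gaussian information measures: mutual information, transfer entropy, influence.

For jointly Gaussian variables every information measure reduces to log
determinants of covariance blocks::

    M[A:B] = 1/2 log2( |S_AA| |S_BB| / |S| )

and the transfer entropy from process 2 into process 1 is the conditional
mutual information between the present of 1 and the stored past of 2 given
the stored past of 1.  The analytic route consumes the exact stationary lag
covariance of the environment model; the empirical route plugs a delay-
embedded sample covariance into the same formula.

The *influence* is the normalised antisymmetric ratio of the two directed
transfer entropies; its sign encodes which process' history is the more
informative about the other's future, and it is invariant under affine
rescaling of either series and under the choice of logarithm base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    Architecture,
    LagCovariance,
    QualiaParams,
    params_from_asymmetries,
    stationary_lag_covariance,
)

__all__ = [
    "TransferEntropyPair",
    "InfluenceValue",
    "gaussian_mutual_information",
    "gaussian_conditional_mutual_information",
    "transfer_entropy_analytic",
    "transfer_entropy_pair_analytic",
    "influence",
    "influence_analytic",
    "influence_small_limit",
    "transfer_entropy_empirical",
    "crossover_scan",
    "sign_flip_locus",
    "locus_stabilization_memory",
]

_LN2 = math.log(2.0)
#: directed flows below this total (bits) are treated as zero
ZERO_FLOW_TOL = 1e-12


@dataclass(frozen=True)
class TransferEntropyPair:
    """Both directed transfer entropies (bits) for one architecture."""

    te_1to2: float
    te_2to1: float
    arch: Architecture | None = None
    source: str = "analytic"  # analytic | simulated | empirical
    se_1to2: float | None = None
    se_2to1: float | None = None

    def __post_init__(self) -> None:
        for name in ("te_1to2", "te_2to1"):
            v = getattr(self, name)
            if math.isnan(v) or v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")


@dataclass(frozen=True)
class InfluenceValue:
    """Normalised directed-flow asymmetry in [-1, 1].

    Positive values mean process 1's history carries the larger directed
    flow (T[1->2] > T[2->1]); the value saturates at +/-1 only when one
    direction vanishes exactly, and is defined as 0 when both do.
    """

    value: float
    arch: Architecture | None = None
    provenance: str = "analytic"

    def __post_init__(self) -> None:
        if abs(self.value) > 1 + 1e-12:
            raise ValueError(f"influence must lie in [-1, 1], got {self.value!r}")


def _logdet_corr(corr: np.ndarray, idx: Sequence[int]) -> float:
    idx = list(idx)
    if not idx:
        return 0.0
    sign, ld = np.linalg.slogdet(corr[np.ix_(idx, idx)])
    if sign <= 0:
        return -math.inf  # numerically singular block
    return ld


def _as_correlation(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale to unit diagonal; zero-variance coordinates stay zero rows."""
    d = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0)
    return cov * inv[:, None] * inv[None, :], d


def gaussian_mutual_information(
    joint_cov: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int]
) -> float:
    """Mutual information (bits) between two index blocks of a Gaussian.

    Returns ``inf`` when the joint covariance is singular while both
    marginal blocks are regular (perfectly redundant variables).
    """
    idx_a, idx_b = list(idx_a), list(idx_b)
    if not idx_a or not idx_b:
        raise ValueError("index sets must be non-empty")
    if set(idx_a) & set(idx_b):
        raise ValueError("index sets must be disjoint")
    cov = np.asarray(joint_cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("joint_cov must be a square matrix")
    corr, _ = _as_correlation(cov)
    ld_a = _logdet_corr(corr, idx_a)
    ld_b = _logdet_corr(corr, idx_b)
    ld_ab = _logdet_corr(corr, idx_a + idx_b)
    if math.isinf(ld_ab) and not (math.isinf(ld_a) or math.isinf(ld_b)):
        return math.inf
    mi = 0.5 * (ld_a + ld_b - ld_ab) / _LN2
    return max(mi, 0.0)


def gaussian_conditional_mutual_information(
    joint_cov: np.ndarray,
    idx_a: Sequence[int],
    idx_b: Sequence[int],
    idx_c: Sequence[int] = (),
) -> float:
    """Conditional mutual information M[A:B | C] in bits.

    Computed as ``1/2 log2( |S_AC| |S_BC| / (|S_C| |S_ABC|) )`` on the
    correlation-normalised matrix (per-variable scaling leaves every mutual
    information unchanged and improves conditioning).
    """
    idx_a, idx_b, idx_c = list(idx_a), list(idx_b), list(idx_c)
    if set(idx_a) & set(idx_b) or set(idx_a) & set(idx_c) or set(idx_b) & set(idx_c):
        raise ValueError("index sets must be pairwise disjoint")
    if not idx_c:
        return gaussian_mutual_information(joint_cov, idx_a, idx_b)
    corr, _ = _as_correlation(np.asarray(joint_cov, dtype=float))
    ld_ac = _logdet_corr(corr, idx_a + idx_c)
    ld_bc = _logdet_corr(corr, idx_b + idx_c)
    ld_c = _logdet_corr(corr, idx_c)
    ld_abc = _logdet_corr(corr, idx_a + idx_b + idx_c)
    if math.isinf(ld_abc) and not math.isinf(ld_ac) and not math.isinf(ld_bc):
        return math.inf
    cmi = 0.5 * (ld_ac + ld_bc - ld_c - ld_abc) / _LN2
    return max(cmi, 0.0)


def _te_from_lagcov(lag: LagCovariance) -> float:
    """T[2->1] from a (reduced, X1-referenced) lag covariance."""
    return gaussian_conditional_mutual_information(
        lag.matrix,
        [lag.future_index],
        lag.other_past_indices,
        lag.own_past_indices,
    )


def transfer_entropy_analytic(
    params: QualiaParams, arch: Architecture, direction: str = "2to1"
) -> float:
    """Exact stationary transfer entropy (bits) in one direction.

    ``direction="2to1"`` is the flow from process 2's stored past into
    process 1's present.  The opposite direction is obtained by relabelling
    the processes, which exchanges the roles of the couplings.
    """
    if direction == "2to1":
        return _te_from_lagcov(stationary_lag_covariance(params, arch))
    if direction == "1to2":
        return _te_from_lagcov(stationary_lag_covariance(params.swapped(), arch))
    raise ValueError("direction must be '2to1' or '1to2'")


def transfer_entropy_pair_analytic(
    params: QualiaParams, arch: Architecture
) -> TransferEntropyPair:
    """Both exact directed transfer entropies for one architecture."""
    return TransferEntropyPair(
        te_1to2=transfer_entropy_analytic(params, arch, "1to2"),
        te_2to1=transfer_entropy_analytic(params, arch, "2to1"),
        arch=arch,
        source="analytic",
    )


def _influence_ratio(te_1to2: float, te_2to1: float, tol: float = ZERO_FLOW_TOL) -> float:
    total = te_1to2 + te_2to1
    if not math.isfinite(total):
        raise ValueError("transfer entropies must be finite")
    if total < tol:
        return 0.0
    return (te_1to2 - te_2to1) / total


def influence(te_pair: TransferEntropyPair, tol: float = ZERO_FLOW_TOL) -> InfluenceValue:
    """Directed-flow asymmetry (T[1->2] - T[2->1]) / (T[1->2] + T[2->1]).

    Defined as exactly 0 when the total flow is below ``tol`` bits.
    """
    return InfluenceValue(
        value=_influence_ratio(te_pair.te_1to2, te_pair.te_2to1, tol),
        arch=te_pair.arch,
        provenance=te_pair.source,
    )


def influence_analytic(params: QualiaParams, arch: Architecture) -> float:
    """Exact stationary influence value for one architecture."""
    return _influence_ratio(
        transfer_entropy_analytic(params, arch, "1to2"),
        transfer_entropy_analytic(params, arch, "2to1"),
    )


def influence_small_limit(a: float, b: float, dt: float) -> float:
    """Two-term small-asymmetry influence expansion at memory n = 1.

    Linear response of the exact influence in the asymmetries, at sampling
    interval ``dt`` in units of the relaxation time, expanded to first order
    in ``dt``::

        T12 ~= 2 (b - a) - (a + b) dt / 4

    valid for ``|a|, |b| << 1`` and ``dt << 1``.  The expansion changes sign
    at ``dt* = 8 (b - a) / (a + b)`` (a crossing exists for ``0 < dt* << 1``,
    i.e. when the stochastic asymmetry slightly exceeds the deterministic
    one); both the root and the slope ``-(a + b)/4`` match finite-difference
    probes of the exact influence as the asymmetries shrink.
    """
    return 2.0 * (b - a) - 0.25 * (a + b) * dt


def transfer_entropy_empirical(
    x1: np.ndarray,
    x2: np.ndarray,
    n: int,
    stride: int = 1,
    shrinkage: float = 0.0,
) -> TransferEntropyPair:
    """Plug-in Gaussian transfer entropy in both directions from data.

    The series are delay-embedded with memory ``n`` at the given ``stride``
    (sub-sampling in units of the native cadence) and the conditional-MI
    determinant formula is applied to the unbiased sample covariance of the
    raw level embedding, so the estimate is exactly invariant under affine
    rescaling of either series (the two streams may be in arbitrary,
    different physical units).  Samples whose embedding window touches a
    NaN are dropped.

    Parameters
    ----------
    x1, x2 : arrays of equal length
    n : int
        Memory size (snapshots of each past).
    stride : int
        Sampling interval in index units (>= 1).
    shrinkage : float in [0, 1)
        Optional Ledoit--Wolf-style shrinkage of the embedding correlation
        matrix toward the identity, for short series.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise ValueError("series must have equal length")
    if int(stride) != stride or stride < 1:
        raise ValueError("stride must be an integer >= 1")
    stride = int(stride)
    if x1.size <= 2 * n + 10:
        raise ValueError(
            f"series of length {x1.size} too short for memory n={n} "
            f"(need > {2 * n + 10})"
        )

    def _one_direction(target: np.ndarray, source: np.ndarray) -> float:
        lag = n * stride
        t_idx = np.arange(lag, target.size)
        cols = [target[t_idx]]
        cols += [target[t_idx - k * stride] for k in range(1, n + 1)]
        cols += [source[t_idx - k * stride] for k in range(1, n + 1)]
        emb = np.column_stack(cols)
        keep = np.isfinite(emb).all(axis=1)
        emb = emb[keep]
        if emb.shape[0] <= emb.shape[1] + 2:
            raise ValueError(
                f"only {emb.shape[0]} complete embedding vectors for n={n}; "
                "series too short or too many missing values"
            )
        cov = np.cov(emb, rowvar=False, ddof=1)
        var = np.diag(cov)
        if np.any(var <= 0):
            names = ["future"] + [f"own-past[{k}]" for k in range(1, n + 1)]
            names += [f"other-past[{k}]" for k in range(1, n + 1)]
            bad = np.nonzero(var <= 0)[0]
            raise ValueError(
                "rank-deficient embedding covariance; degenerate block(s): "
                + ", ".join(names[i] for i in bad)
            )
        if shrinkage:
            corr, d = _as_correlation(cov)
            corr = (1.0 - shrinkage) * corr + shrinkage * np.eye(corr.shape[0])
            cov = corr * d[:, None] * d[None, :]
        a_idx = [0]
        c_idx = list(range(1, n + 1))
        b_idx = list(range(n + 1, 2 * n + 1))
        return gaussian_conditional_mutual_information(cov, a_idx, b_idx, c_idx)

    arch = Architecture(n=n, dt=float(stride))
    return TransferEntropyPair(
        te_1to2=_one_direction(x2, x1),
        te_2to1=_one_direction(x1, x2),
        arch=arch,
        source="empirical",
    )


def crossover_scan(
    params: QualiaParams,
    n: int,
    dt_grid: np.ndarray,
    rel_tol: float = 1e-3,
) -> np.ndarray:
    """Locate every sign change of the analytic influence over a dt grid.

    Each bracketing grid interval is refined by bisection (geometric
    midpoints) until its relative width falls below ``rel_tol``; the
    returned locations are the bracket midpoints.  Exact zeros at grid
    nodes count as crossings.  Returns an empty array when the influence
    is single-signed over the grid.
    """
    dt_grid = np.asarray(dt_grid, dtype=float)
    if dt_grid.ndim != 1 or dt_grid.size < 2:
        raise ValueError("dt_grid must contain at least two points")
    if np.any(np.diff(dt_grid) <= 0):
        raise ValueError("dt_grid must be strictly increasing")
    vals = np.array([influence_analytic(params, Architecture(n, d)) for d in dt_grid])

    roots: list[float] = []
    for i in range(dt_grid.size - 1):
        lo, hi = dt_grid[i], dt_grid[i + 1]
        f_lo, f_hi = vals[i], vals[i + 1]
        if f_lo == 0.0:
            if i == 0 or vals[i - 1] != 0.0:
                roots.append(lo)
            continue
        if f_hi == 0.0 or f_lo * f_hi > 0:
            continue
        while (hi - lo) > rel_tol * 0.5 * (hi + lo):
            mid = math.sqrt(lo * hi)
            f_mid = influence_analytic(params, Architecture(n, mid))
            if f_mid == 0.0:
                lo = hi = mid
                break
            if f_lo * f_mid < 0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
        roots.append(math.sqrt(lo * hi))
    if vals[-1] == 0.0 and vals[-2] != 0.0:
        roots.append(dt_grid[-1])
    return np.array(roots)


def sign_flip_locus(
    b: float,
    a_values,
    n_values,
    dt_grid: np.ndarray,
) -> dict[int, dict[float, float]]:
    """Zero-influence contour dt*(a, n) at fixed stochastic asymmetry ``b``.

    For every memory size in ``n_values`` and deterministic asymmetry in
    ``a_values``, locates sign changes of the analytic influence over
    ``dt_grid``; entries are recorded only where the slice has exactly one
    crossing (the single-valued part of the contour).
    """
    locus: dict[int, dict[float, float]] = {}
    for n in n_values:
        locus[int(n)] = {}
        for a in a_values:
            params = params_from_asymmetries(float(a), b)
            roots = crossover_scan(params, int(n), dt_grid)
            if roots.size == 1:
                locus[int(n)][float(a)] = float(roots[0])
    return locus


def locus_stabilization_memory(
    locus: dict[int, dict[float, float]], rel_tol: float = 0.02
) -> tuple[int | None, dict[int, float]]:
    """Smallest memory size past which the sign-flip contour stops moving.

    Compares the contour's dt locations between successive memory sizes on
    the asymmetry values they share; returns the first ``n`` whose maximum
    relative displacement to ``n+1`` is below ``rel_tol`` (and stays below
    for all larger available pairs), together with the per-``n``
    displacement map.
    """
    ns = sorted(locus)
    shifts: dict[int, float] = {}
    for n, n_next in zip(ns[:-1], ns[1:]):
        shared = set(locus[n]) & set(locus[n_next])
        if not shared:
            continue
        shifts[n] = max(
            abs(locus[n_next][a] / locus[n][a] - 1.0) for a in shared
        )
    stable = None
    for n in sorted(shifts):
        if all(shifts[m] < rel_tol for m in shifts if m >= n):
            stable = n
            break
    return stable, shifts

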