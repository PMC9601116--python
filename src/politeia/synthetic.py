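"""Synthetic data generators with known ground truth.

Two generators make every other module testable without external data:
exact stationary samples of the coupled-stimulus model, and "climate-like"
paired monthly series -- secular trend plus seasonal harmonics plus coupled
stochastic residuals, rounded to instrument precision -- whose construction
parameters (trend coefficients, harmonic frequencies and amplitudes, and the
residual coupling with its analytic influence structure) are returned
alongside the data for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import Architecture, QualiaParams, params_from_asymmetries, simulate_paths
from .pipeline import MonthlySeries

__all__ = [
    "ClimateLikeSpec",
    "ClimateLikePair",
    "gen_coupled_ou",
    "gen_climate_like",
    "default_climate_spec",
]

#: burn-in, in units of the relaxation time, before stationary sampling
BURN_IN_TAU = 20.0


def gen_coupled_ou(
    params: QualiaParams,
    dt: float,
    n_points: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary paired samples of the coupled model at spacing ``dt``.

    Simulates one exact path initialised ``10 ell`` apart, discards a
    burn-in of ``20 tau``, and returns the two series sampled every ``dt``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    burn = BURN_IN_TAU * params.tau
    t_grid = np.concatenate(([0.0], burn + dt * np.arange(n_points)))
    ens = simulate_paths(
        params, x0_pair=(5.0 * params.ell, -5.0 * params.ell),
        t_grid=t_grid, n_reps=1, seed=seed,
    )
    return ens.x1[0, 1:], ens.x2[0, 1:]


@dataclass(frozen=True)
class ClimateLikeSpec:
    """Recipe for a paired monthly fixture with known ground truth.

    Stream A carries an exponential secular trend (CO2-like, ppm scale)
    and stream B a linear one (temperature-like, degC scale); each has
    seasonal harmonics given as ``(frequency cycles/month, amplitude,
    phase)`` triples; the residuals are one exact draw of the coupled
    stochastic pair (``residual_params``, monthly time units) scaled per
    stream, and the finished values are rounded to the instrument
    precision.
    """

    n_months: int = 768
    start: str = "1958-03"
    # exponential trend c0 + c1 exp(c2 t) for stream A (t in months)
    trend_a: tuple[float, float, float] = (280.0, 35.0, 0.0018)
    # linear trend d0 + d1 t for stream B
    trend_b: tuple[float, float] = (7.0, 0.00125)
    harmonics_a: tuple = ((1.0 / 12.0, 3.0, 0.0), (1.0 / 6.0, 1.0, 0.7))
    harmonics_b: tuple = ((1.0 / 12.0, 2.5, 2.2), (1.0 / 6.0, 0.4, 1.1))
    residual_params: QualiaParams = field(
        default_factory=lambda: params_from_asymmetries(a=0.75, b=0.7, tau=1.5)
    )
    residual_scale_a: float = 0.45
    residual_scale_b: float = 0.75
    precision_a: float = 0.01
    precision_b: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_months < 120:
            raise ValueError("n_months must be >= 120")
        for freq, amp, _ in tuple(self.harmonics_a) + tuple(self.harmonics_b):
            if amp < 0 or not (0 < freq <= 0.5):
                raise ValueError("harmonics need amplitude >= 0 and 0 < freq <= 1/2")


@dataclass
class ClimateLikePair:
    """Generated fixture pair plus the ground truth that built it."""

    series_a: MonthlySeries
    series_b: MonthlySeries
    truth: dict

    def write_csvs(self, path_a, path_b, sidecar=None) -> None:
        """Write both streams as generic date,value CSVs (+ YAML truth)."""
        self.series_a.write_csv(path_a)
        self.series_b.write_csv(path_b)
        if sidecar is not None:
            meta = {
                k: v for k, v in self.truth.items()
                if not isinstance(v, np.ndarray)
            }
            meta["residual_params"] = self.truth["spec"].residual_params.to_dict()
            meta["spec"] = {
                f: getattr(self.truth["spec"], f)
                for f in ("n_months", "start", "trend_a", "trend_b",
                          "residual_scale_a", "residual_scale_b",
                          "precision_a", "precision_b", "seed")
            }
            with open(sidecar, "w") as fh:
                yaml.safe_dump(_plain(meta), fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _harmonic_sum(harmonics, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for freq, amp, phase in harmonics:
        out += amp * np.cos(2 * np.pi * freq * t + phase)
    return out


def gen_climate_like(spec: ClimateLikeSpec) -> ClimateLikePair:
    """Generate the paired monthly fixture described by ``spec``.

    Rounding to instrument precision happens after the stochastic residual
    is added, mimicking recorded data, so bootstrap noise at the significant
    digit is meaningful on the fixture.  The returned ``truth`` dictionary
    holds every clean component (trend, seasonal, residual series before
    rounding) and the residual coupling parameters.
    """
    t = np.arange(spec.n_months, dtype=float)
    c0, c1, c2 = spec.trend_a
    trend_a = c0 + c1 * np.exp(c2 * t)
    d0, d1 = spec.trend_b
    trend_b = d0 + d1 * t
    seas_a = _harmonic_sum(spec.harmonics_a, t)
    seas_b = _harmonic_sum(spec.harmonics_b, t)

    r1, r2 = gen_coupled_ou(spec.residual_params, dt=1.0,
                            n_points=spec.n_months, seed=spec.seed)
    r1 = r1 - r1.mean()
    r2 = r2 - r2.mean()
    clean_a = trend_a + seas_a + spec.residual_scale_a * r1
    clean_b = trend_b + seas_b + spec.residual_scale_b * r2
    vals_a = np.round(clean_a / spec.precision_a) * spec.precision_a
    vals_b = np.round(clean_b / spec.precision_b) * spec.precision_b

    months = pd.period_range(spec.start, periods=spec.n_months, freq="M")
    series_a = MonthlySeries(months, vals_a, spec.precision_a, name="co2_like")
    series_b = MonthlySeries(months, vals_b, spec.precision_b, name="temp_like")
    truth = {
        "spec": spec,
        "trend_a": trend_a,
        "trend_b": trend_b,
        "seasonal_a": seas_a,
        "seasonal_b": seas_b,
        "residual_a": spec.residual_scale_a * r1,
        "residual_b": spec.residual_scale_b * r2,
        "clean_a": clean_a,
        "clean_b": clean_b,
    }
    return ClimateLikePair(series_a, series_b, truth)


def default_climate_spec(seed: int = 0, n_months: int = 768) -> ClimateLikeSpec:
    """The standard fixture recipe (Mauna-Loa-like scales, known crossover)."""
    return ClimateLikeSpec(seed=seed, n_months=n_months)


def recovery_spec(seed: int = 0, n_months: int = 3072) -> ClimateLikeSpec:
    """Fixture recipe for estimator-validation runs.

    Flat baselines and no seasonal harmonics, so the coupled residual (and
    its analytic crossover memory) is the only structure in the pair, and a
    record long enough that single-realisation fluctuations of the
    influence curve are small compared to its slope through zero.  Rounding
    to instrument precision and bootstrap noise still apply.
    """
    return ClimateLikeSpec(
        seed=seed,
        n_months=n_months,
        trend_a=(315.0, 0.0, 0.001),
        trend_b=(7.0, 0.0),
        harmonics_a=(),
        harmonics_b=(),
    )


def analytic_sign_change_memory(
    params: QualiaParams, dt: float, n_max: int = 36
) -> int | None:
    """Smallest memory size at which the analytic influence has flipped sign.

    Scans the exact influence at fixed sampling interval ``dt`` over
    ``n = 1..n_max`` and returns the first ``n`` whose sign differs from the
    ``n = 1`` sign (None if the sign never flips) -- the ground-truth
    crossover memory of a fixture built from ``params``.
    """
    from .info import influence_analytic

    s0 = None
    for n in range(1, n_max + 1):
        v = influence_analytic(params, Architecture(n, dt))
        s = math.copysign(1.0, v) if v != 0 else 0.0
        if s == 0.0:
            continue
        if s0 is None:
            s0 = s
        elif s != s0:
            return n
    return None
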