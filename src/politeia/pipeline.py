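"""Bootstrap influence-vs-memory analysis for paired monthly series.

The procedure mirrors how a heterogeneous population of observers would
process two aligned monthly records (e.g. a CO2 concentration series and a
local temperature series): optionally remove secular trends and the
strongest seasonal harmonics, bootstrap a population of observers of
different ages by drawing substreams with random start dates and adding
measurement noise at the instrument precision, estimate the Gaussian
transfer entropy in both directions for every memory size ``n`` (the
sampling interval is fixed at one month), and pool the per-``n`` influence
estimates into polity belief distributions parameterised by the population
mean memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .info import transfer_entropy_empirical, _influence_ratio
from .polity import BeliefDistribution, BeliefSummary, summarize_belief

__all__ = [
    "MonthlySeries",
    "DetrendReport",
    "InfluenceCurve",
    "read_monthly_csv",
    "fit_remove_trend",
    "remove_top_harmonics",
    "bootstrap_substreams",
    "influence_vs_memory",
    "polity_belief_from_curve",
    "PolityBeliefScan",
]


@dataclass
class MonthlySeries:
    """A monthly-cadence series with instrument precision and missing mask.

    ``values`` holds NaN where a month is missing; ``months`` is a
    contiguous monthly :class:`pandas.PeriodIndex`.
    """

    months: pd.PeriodIndex
    values: np.ndarray
    precision: float
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.months) != len(self.values):
            raise ValueError("months and values must have equal length")
        if self.months.freqstr not in ("M", "ME"):
            raise ValueError("index must have monthly frequency")
        steps = np.diff(self.months.asi8)
        if np.any(steps != 1):
            raise ValueError("months must be contiguous and strictly increasing")
        if self.precision <= 0:
            raise ValueError("precision must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mask(self) -> np.ndarray:
        """True where the month is missing."""
        return ~np.isfinite(self.values)

    def replace(self, values: np.ndarray) -> "MonthlySeries":
        return MonthlySeries(self.months, np.asarray(values, float),
                             self.precision, self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.months.astype(str), "value": self.values})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _validate_monthly(period_idx: pd.PeriodIndex, values: np.ndarray,
                      precision: float, name: str) -> MonthlySeries:
    order = np.argsort(period_idx.asi8)
    period_idx = period_idx[order]
    values = values[order]
    if len(np.unique(period_idx.asi8)) != len(period_idx):
        raise ValueError("duplicate months in input")
    full = pd.period_range(period_idx[0], period_idx[-1], freq="M")
    if len(period_idx) < 0.5 * len(full):
        raise ValueError(
            f"non-monthly cadence: file provides {len(period_idx)} rows over a "
            f"{len(full)}-month span"
        )
    out = np.full(len(full), np.nan)
    out[period_idx.asi8 - full.asi8[0]] = values
    return MonthlySeries(full, out, precision, name)


def read_monthly_csv(
    path,
    column_spec: dict | None = None,
    precision: float | None = None,
    sentinel_threshold: float = -90.0,
) -> MonthlySeries:
    """Read a monthly series from CSV.

    Two dialects are recognised:

    * the NOAA monthly-mean layout -- ``#`` comment lines, then columns
      including ``year``, ``month`` and a value column (default
      ``average``), with negative fill codes for missing months;
    * a generic two-column ``date,value`` layout.

    ``column_spec`` may override column names, e.g. ``{"year": "yr",
    "month": "mon", "value": "co2"}`` or ``{"date": "time", "value": "t"}``.
    Values at or below ``sentinel_threshold`` are masked as missing (NOAA
    uses ``-99.99``/``-9.99`` fill codes), never dropped silently.
    """
    spec = dict(column_spec or {})
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]

    year_col = spec.get("year", "year")
    month_col = spec.get("month", "month")
    date_col = spec.get("date", "date")
    if year_col in df.columns and month_col in df.columns:
        value_col = spec.get("value", "average")
        if value_col not in df.columns:
            raise ValueError(
                f"value column {value_col!r} not found in {list(df.columns)}"
            )
        years = pd.to_numeric(df[year_col], errors="coerce")
        months = pd.to_numeric(df[month_col], errors="coerce")
        bad = np.nonzero(years.isna() | months.isna())[0]
        if bad.size:
            raise ValueError(
                f"unparseable year/month on data row(s) {[int(i) + 2 for i in bad]}"
            )
        idx = pd.PeriodIndex(
            [pd.Period(f"{int(y)}-{int(m):02d}", freq="M")
             for y, m in zip(years, months)]
        )
        default_precision = 0.01
    elif date_col in df.columns:
        value_col = spec.get("value", "value")
        if value_col not in df.columns:
            raise ValueError(
                f"value column {value_col!r} not found in {list(df.columns)}"
            )
        try:
            idx = pd.PeriodIndex(pd.to_datetime(df[date_col]), freq="M")
        except (ValueError, TypeError) as err:
            raise ValueError(f"unparseable date column: {err}") from err
        default_precision = 0.01
    else:
        raise ValueError(
            "could not identify layout: need year+month or date columns, "
            f"got {list(df.columns)}"
        )

    raw = pd.to_numeric(df[value_col], errors="coerce")
    bad = np.nonzero(raw.isna() & df[value_col].notna())[0]
    if bad.size:
        raise ValueError(
            f"unparseable value on data row(s) {[int(i) + 2 for i in bad]}"
        )
    vals = raw.to_numpy(dtype=float)
    vals[vals <= sentinel_threshold] = np.nan  # fill codes -> masked
    return _validate_monthly(
        idx, vals, precision if precision is not None else default_precision,
        name=str(value_col),
    )


@dataclass
class DetrendReport:
    """What a detrending step removed."""

    kind: str  # linear | exponential | harmonics
    trend_params: dict = field(default_factory=dict)
    harmonics: list[dict] = field(default_factory=list)  # freq, amplitude, phase, power
    residual: MonthlySeries | None = None


def fit_remove_trend(series: MonthlySeries, kind: str) -> tuple[DetrendReport, MonthlySeries]:
    """Least-squares removal of a linear or exponential secular trend.

    ``linear`` fits ``c0 + c1 t``; ``exponential`` fits ``c0 + c1 exp(c2 t)``
    by nonlinear least squares initialised from piecewise linear slopes
    (``t`` in months from the first sample).  Missing months are ignored in
    the fit and stay missing in the residual.
    """
    if kind not in ("linear", "exponential"):
        raise ValueError("kind must be 'linear' or 'exponential'")
    obs = ~series.mask
    if obs.sum() < 24:
        raise ValueError("need at least 24 observed months to fit a trend")
    t = np.arange(len(series), dtype=float)
    y = series.values
    to, yo = t[obs], y[obs]

    if kind == "linear":
        c1, c0 = np.polyfit(to, yo, 1)
        trend = c0 + c1 * t
        params = {"c0": float(c0), "c1": float(c1)}
    else:
        half = len(to) // 2
        s1 = np.polyfit(to[:half], yo[:half], 1)[0]
        s2 = np.polyfit(to[half:], yo[half:], 1)[0]
        span = to[-1] - to[0]
        if s1 * s2 > 0 and s2 / s1 > 0:
            c2_0 = math.log(s2 / s1) / (span / 2.0)
        else:
            c2_0 = 1.0 / span
        if abs(c2_0) < 1e-12:
            c2_0 = 1.0 / span
        c1_0 = s1 / (c2_0 * math.exp(c2_0 * np.mean(to[:half])))
        c0_0 = float(np.mean(yo) - c1_0 * np.mean(np.exp(c2_0 * to)))

        def f(tt, c0, c1, c2):
            return c0 + c1 * np.exp(c2 * tt)

        try:
            popt, _ = curve_fit(f, to, yo, p0=[c0_0, c1_0, c2_0], maxfev=20000)
        except RuntimeError as err:
            raise RuntimeError(
                "exponential trend fit did not converge; consider kind='linear'"
            ) from err
        trend = f(t, *popt)
        params = {"c0": float(popt[0]), "c1": float(popt[1]), "c2": float(popt[2])}

    residual = series.replace(y - trend)
    report = DetrendReport(kind=kind, trend_params=params, residual=residual)
    return report, residual


def remove_top_harmonics(series: MonthlySeries, k: int) -> tuple[DetrendReport, MonthlySeries]:
    """Remove the ``k`` periodogram-dominant sinusoids from a series.

    Frequencies are the ``k`` non-DC FFT bins with the largest periodogram
    power (missing months are mean-imputed for identification only); each
    selected sinusoid's amplitude and phase are then fit jointly by least
    squares on the observed months and subtracted.  ``k = 0`` is the
    identity.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return DetrendReport(kind="harmonics", residual=series), series
    obs = ~series.mask
    y = series.values.copy()
    n = len(y)
    if k >= n // 2:
        raise ValueError(f"k={k} exceeds the {n // 2 - 1} available frequency bins")
    mean = np.nanmean(y)
    y_filled = np.where(obs, y, mean) - mean
    power = np.abs(np.fft.rfft(y_filled)) ** 2
    power[0] = 0.0
    freqs = np.fft.rfftfreq(n, d=1.0)  # cycles per month
    top = np.argsort(power)[::-1][:k]

    t = np.arange(n, dtype=float)
    cols = []
    for j in top:
        cols.append(np.cos(2 * np.pi * freqs[j] * t))
        cols.append(np.sin(2 * np.pi * freqs[j] * t))
    design = np.column_stack(cols + [np.ones(n)])
    coef, *_ = np.linalg.lstsq(design[obs], y[obs], rcond=None)
    seasonal = design[:, :-1] @ coef[:-1]  # intercept is fit but not removed

    harmonics = []
    for m, j in enumerate(top):
        cc, ss = coef[2 * m], coef[2 * m + 1]
        harmonics.append(
            {
                "frequency": float(freqs[j]),
                "amplitude": float(math.hypot(cc, ss)),
                "phase": float(math.atan2(-ss, cc)),
                "power": float(power[j]),
            }
        )
    residual = series.replace(y - seasonal)
    report = DetrendReport(kind="harmonics", harmonics=harmonics, residual=residual)
    return report, residual


def bootstrap_substreams(
    pair: tuple[MonthlySeries, MonthlySeries],
    n_boot: int,
    start_range: tuple[str, str] | None = None,
    seed: int | None = None,
    noise_sd: tuple[float | None, float | None] = (None, None),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Bootstrap a population of observers of different ages.

    Each replicate draws a start month uniformly from ``start_range``
    (inclusive period strings, default: first month to 2/3 of the record),
    takes the substream from there to the end of the data, and perturbs each
    series with i.i.d. Gaussian noise whose standard deviation is the
    instrument precision (the significant digit), overridable per series
    via ``noise_sd``; ``noise_sd=(0, 0)`` gives exact slices.
    """
    s1, s2 = pair
    if len(s1) != len(s2) or (s1.months[0] != s2.months[0]):
        raise ValueError("series must be aligned on the same months")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(s1)
    if start_range is None:
        lo_i, hi_i = 0, max(0, (2 * n) // 3 - 1)
    else:
        lo = pd.Period(start_range[0], freq="M")
        hi = pd.Period(start_range[1], freq="M")
        lo_i = lo.ordinal - s1.months[0].ordinal
        hi_i = hi.ordinal - s1.months[0].ordinal
        if not (0 <= lo_i <= hi_i < n):
            raise ValueError("start_range outside the data span")
    sd1 = s1.precision if noise_sd[0] is None else noise_sd[0]
    sd2 = s2.precision if noise_sd[1] is None else noise_sd[1]
    rng = np.random.default_rng(seed)
    starts = rng.integers(lo_i, hi_i + 1, size=n_boot)
    out = []
    for st in starts:
        a = s1.values[st:].copy()
        b = s2.values[st:].copy()
        if sd1:
            a = a + rng.normal(0.0, sd1, size=a.size)
        if sd2:
            b = b + rng.normal(0.0, sd2, size=b.size)
        out.append((a, b))
    return out


@dataclass
class InfluenceCurve:
    """Directed flows and influence as a function of memory size.

    ``table`` has one row per memory size with the replicate-mean transfer
    entropies, the mean/median influence, and decile bands;
    ``replicate_influence`` keeps the raw per-replicate influence values
    (NaN where a replicate was skipped or failed).
    """

    n_grid: np.ndarray
    table: pd.DataFrame
    replicate_influence: np.ndarray  # shape (n_boot, len(n_grid))
    n_skipped: int = 0


def influence_vs_memory(
    replicates: list[tuple[np.ndarray, np.ndarray]],
    n_grid,
    shrinkage: float = 0.0,
    stride: int = 1,
) -> InfluenceCurve:
    """Per-memory-size transfer entropies and influence across replicates.

    The sampling interval is fixed at the native (monthly) cadence unless
    ``stride`` sub-samples it.  Replicates shorter than ``12 + 2 n_max``
    usable months are skipped (counted in ``n_skipped``).  The point
    estimate for each memory size is the replicate mean; the bands are
    replicate quantiles at 10% steps centred on the median.
    """
    n_grid = np.asarray(sorted(int(n) for n in n_grid))
    if n_grid.min() < 1:
        raise ValueError("memory sizes must be >= 1")
    min_len = 12 + 2 * int(n_grid.max()) * stride
    q_levels = np.round(np.arange(0.1, 0.91, 0.1), 2)

    infl = np.full((len(replicates), len(n_grid)), np.nan)
    te12 = np.full_like(infl, np.nan)
    te21 = np.full_like(infl, np.nan)
    n_skipped = 0
    for r, (x1, x2) in enumerate(replicates):
        usable = np.isfinite(x1) & np.isfinite(x2)
        if usable.sum() < min_len:
            n_skipped += 1
            continue
        for j, n in enumerate(n_grid):
            try:
                pair = transfer_entropy_empirical(
                    x1, x2, n=int(n), stride=stride, shrinkage=shrinkage
                )
            except ValueError:
                continue
            te12[r, j] = pair.te_1to2
            te21[r, j] = pair.te_2to1
            infl[r, j] = _influence_ratio(pair.te_1to2, pair.te_2to1)

    rows = []
    for j, n in enumerate(n_grid):
        col = infl[:, j]
        ok = np.isfinite(col)
        row = {
            "n": int(n),
            "n_replicates": int(ok.sum()),
            "te_1to2": np.nanmean(te12[:, j]) if ok.any() else np.nan,
            "te_2to1": np.nanmean(te21[:, j]) if ok.any() else np.nan,
            "influence_mean": np.nanmean(col) if ok.any() else np.nan,
            "influence_median": np.nanmedian(col) if ok.any() else np.nan,
        }
        for q in q_levels:
            row[f"influence_q{int(round(q * 100)):02d}"] = (
                np.nanquantile(col, q) if ok.any() else np.nan
            )
        rows.append(row)
    return InfluenceCurve(
        n_grid=n_grid,
        table=pd.DataFrame(rows),
        replicate_influence=infl,
        n_skipped=n_skipped,
    )


@dataclass
class PolityBeliefScan:
    """Belief distributions versus population mean memory size."""

    mean_n: np.ndarray
    beliefs: list[BeliefDistribution]
    summaries: list[BeliefSummary]
    median_zero_mean_n: float | None  # <N> at which the median influence crosses 0


def polity_belief_from_curve(
    curve: InfluenceCurve, mean_n_values
) -> PolityBeliefScan:
    """Pool per-memory influence estimates into beliefs indexed by ``<N>``.

    For each population mean memory, memory sizes are weighted by the
    geometric law truncated to the computed grid, and every replicate's
    influence estimate at that memory size enters as an equally weighted
    point mass.  The scan also locates the ``<N>`` where the belief median
    changes sign (linear interpolation between grid values), the point of
    maximal polarisation.
    """
    mean_n_values = np.asarray(sorted(float(v) for v in mean_n_values))
    beliefs, summaries = [], []
    for mn in mean_n_values:
        if mn <= 1:
            raise ValueError("mean memory sizes must exceed 1")
        x = 1.0 - 1.0 / mn
        w_n = (1 - x) * x ** (curve.n_grid - 1.0)
        comps = []
        for j, wn in enumerate(w_n):
            col = curve.replicate_influence[:, j]
            col = col[np.isfinite(col)]
            if col.size == 0 or wn == 0.0:
                continue
            for v in col:
                comps.append((wn / col.size, "point", float(v), 0.0))
        total = sum(c[0] for c in comps)
        comps = [(w / total, k, loc, s) for w, k, loc, s in comps]
        belief = BeliefDistribution(comps, meta={"mean_n": mn})
        beliefs.append(belief)
        summaries.append(summarize_belief(belief))

    med = np.array([s.median for s in summaries])
    crossing = None
    for i in range(len(med) - 1):
        if med[i] == 0.0:
            crossing = float(mean_n_values[i])
            break
        if med[i] * med[i + 1] < 0:
            f = med[i] / (med[i] - med[i + 1])
            crossing = float(mean_n_values[i] + f * (mean_n_values[i + 1] - mean_n_values[i]))
            break
    return PolityBeliefScan(
        mean_n=mean_n_values, beliefs=beliefs, summaries=summaries,
        median_zero_mean_n=crossing,
    )
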