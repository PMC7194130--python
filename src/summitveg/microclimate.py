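"""Soil-temperature logger processing: daily statistics, growing degree days,
seasonal-analogue gap imputation, and warming-trend summaries.

Loggers record hourly soil temperature at 10 cm depth. Daily means follow the
half-range convention Tavg = (Tmin + Tmax) / 2, which weights the diurnal
extremes rather than the full hourly distribution. Growing degree days (GDD)
accumulate Tavg − threshold over days whose Tavg exceeds a biological
threshold (default 5 °C, appropriate for alpine vegetation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    DomainError,
    EmptyInputError,
    ImputationError,
    ValidationError,
)

__all__ = [
    "TemperatureSeries",
    "GddResult",
    "daily_stats",
    "growing_degree_days",
    "impute_gaps",
    "temperature_trend",
    "read_logger_series",
    "write_logger_series",
]


@dataclass
class TemperatureSeries:
    """Hourly soil temperatures for one logger over one recording window.

    ``series`` is a float Series on a strictly increasing hourly
    DatetimeIndex; missing hours are explicit NaN, never sentinel values.
    """

    logger_id: str
    series: pd.Series

    def __post_init__(self) -> None:
        idx = self.series.index
        if len(idx) == 0:
            raise EmptyInputError(f"logger {self.logger_id}: empty series")
        if not isinstance(idx, pd.DatetimeIndex):
            raise ValidationError(f"logger {self.logger_id}: index must be datetimes")
        deltas = np.diff(idx.asi8)
        if len(deltas) and not (deltas == 3_600_000_000_000).all():
            raise ValidationError(f"logger {self.logger_id}: timestamps must be equally spaced at 1 h")
        self.series = self.series.astype(float)

    @property
    def n_missing(self) -> int:
        return int(self.series.isna().sum())


@dataclass(frozen=True)
class GddResult:
    """Accumulated degree-days above threshold over a date window."""

    logger_id: str
    window: tuple
    gdd: float
    days_counted: int


def daily_stats(ts: TemperatureSeries, min_valid_hours: int = 18) -> pd.DataFrame:
    """Per-day tmin/tmax/tavg with tavg = (tmin + tmax) / 2.

    Days with fewer than ``min_valid_hours`` non-missing hourly values are
    emitted with missing statistics.
    """
    s = ts.series
    if s.isna().all():
        raise EmptyInputError(f"logger {ts.logger_id}: no valid hourly values")
    grouped = s.groupby(s.index.normalize())
    out = grouped.agg(tmin="min", tmax="max", n_valid="count")
    bad = out["n_valid"] < min_valid_hours
    out.loc[bad, ["tmin", "tmax"]] = np.nan
    out["tavg"] = 0.5 * (out["tmin"] + out["tmax"])
    out.index.name = "date"
    return out[["tmin", "tmax", "tavg", "n_valid"]]


def growing_degree_days(
    daily: pd.DataFrame,
    threshold: float = 5.0,
    window: tuple | None = None,
    logger_id: str = "",
    strict: bool = True,
) -> GddResult:
    """Sum of (tavg − threshold) over days with tavg above the threshold.

    ``strict`` reads "above" literally (tavg > threshold); pass False for the
    inclusive variant. Days with missing tavg are skipped; ``days_counted``
    reports the number of non-missing days actually inspected.
    """
    if "tavg" not in daily.columns:
        raise DomainError("daily frame must carry a 'tavg' column")
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        if start > end:
            raise DomainError("empty GDD window")
        daily = daily.loc[(daily.index >= start) & (daily.index <= end)]
    else:
        window = (daily.index.min(), daily.index.max())
    if len(daily) == 0:
        raise DomainError("GDD window contains no days")
    tavg = daily["tavg"].dropna()
    exceed = tavg > threshold if strict else tavg >= threshold
    gdd = float((tavg[exceed] - threshold).sum())
    return GddResult(logger_id or "", (pd.Timestamp(window[0]), pd.Timestamp(window[1])), gdd, int(len(tavg)))


def impute_gaps(
    ts: TemperatureSeries,
    reference: TemperatureSeries,
    n_imputations: int = 30,
    seed: int = 0,
) -> tuple[TemperatureSeries, pd.Series]:
    """Fill missing hours from the same logger's prior-year record.

    Each missing hour is filled with the prior year's value at the same
    (month, day, hour) slot plus the mean of ``n_imputations`` residuals drawn
    from the empirical distribution of (current − prior-year) differences over
    the non-missing hours of the same calendar month. Observed values are
    never altered. Returns the filled series and the per-hour SD of the
    imputation draws (zero at observed hours).
    """
    s = ts.series
    ref = reference.series
    slot = lambda idx: list(zip(idx.month, idx.day, idx.hour))
    ref_map = pd.Series(ref.to_numpy(), index=pd.MultiIndex.from_tuples(slot(ref.index)))
    ref_map = ref_map[~ref_map.index.duplicated()]

    missing = s.index[s.isna()]
    sd = pd.Series(0.0, index=s.index)
    if len(missing) == 0:
        return TemperatureSeries(ts.logger_id, s.copy()), sd

    miss_slots = pd.MultiIndex.from_tuples(slot(missing))
    unserviceable = [missing[i] for i in range(len(missing))
                     if miss_slots[i] not in ref_map.index or pd.isna(ref_map.get(miss_slots[i]))]
    if unserviceable:
        raise ImputationError(f"no prior-year counterpart for slots: {unserviceable[:10]}"
                              + ("..." if len(unserviceable) > 10 else ""))

    # residual pools: current − prior-year differences of observed hours, by month
    obs = s.dropna()
    obs_slots = pd.MultiIndex.from_tuples(slot(obs.index))
    matched = ref_map.reindex(obs_slots)
    diffs = pd.Series(obs.to_numpy() - matched.to_numpy(), index=obs.index).dropna()
    pools = {m: grp.to_numpy() for m, grp in diffs.groupby(diffs.index.month)}
    all_pool = diffs.to_numpy()

    rng = np.random.default_rng(seed)
    filled = s.copy()
    for t in missing:
        pool = pools.get(t.month, all_pool)
        if len(pool) == 0:
            pool = np.zeros(1)
        resid_draws = rng.choice(pool, size=n_imputations)
        filled[t] = float(ref_map[(t.month, t.day, t.hour)] + np.mean(resid_draws))
        sd[t] = float(np.std(resid_draws))
    return TemperatureSeries(ts.logger_id, filled), sd


def temperature_trend(means: Iterable[tuple] | pd.Series) -> dict:
    """OLS slope of aggregated mean temperature on period index with t-test.

    ``means`` is a sequence of (period, mean °C) pairs or a Series indexed by
    period; periods are used in given order and regressed on 0, 1, 2, ...
    """
    if isinstance(means, pd.Series):
        y = means.to_numpy(dtype=float)
        periods = list(means.index)
    else:
        pairs = list(means)
        periods = [p for p, _ in pairs]
        y = np.array([v for _, v in pairs], dtype=float)
    if len(y) < 3:
        raise DegenerateDesignError("trend needs at least 3 periods")
    x = np.arange(len(y), dtype=float)
    if np.allclose(y, y[0]):
        return {"slope": 0.0, "statistic": 0.0, "p_value": 1.0, "n_periods": len(y)}
    res = stats.linregress(x, y)
    # perfect fit: zero residual variance makes the t-test degenerate
    if res.stderr == 0 or not np.isfinite(res.stderr):
        return {"slope": float(res.slope), "statistic": np.inf, "p_value": 0.0, "n_periods": len(y)}
    return {
        "slope": float(res.slope),
        "statistic": float(res.slope / res.stderr),
        "p_value": float(res.pvalue),
        "n_periods": len(y),
    }


def read_logger_series(path) -> list[TemperatureSeries]:
    """Read hourly logger records (logger_id, ISO timestamp, temperature)."""
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"], float_precision="round_trip")
    missing = [c for c in ("logger_id", "timestamp", "temperature") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    out = []
    for logger_id, grp in df.groupby("logger_id", sort=True):
        grp = grp.sort_values("timestamp")
        # a logger may hold several disjoint recording windows; split on jumps
        times = grp["timestamp"]
        breaks = np.flatnonzero(times.diff().dt.total_seconds().to_numpy()[1:] != 3600.0) + 1
        for chunk in np.split(np.arange(len(grp)), breaks):
            sub = grp.iloc[chunk]
            s = pd.Series(sub["temperature"].to_numpy(), index=pd.DatetimeIndex(sub["timestamp"]))
            out.append(TemperatureSeries(str(logger_id), s))
    return out


def write_logger_series(series_list: Iterable[TemperatureSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {"logger_id": ts.logger_id, "timestamp": ts.series.index, "temperature": ts.series.to_numpy()}
        )
        for ts in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
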