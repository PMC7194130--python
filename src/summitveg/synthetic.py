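"""Synthetic two-year summit surveys and hourly soil-logger series.

The generator emulates a four-summit monitoring design: four summits spanning
an elevation gradient, four aspects per summit, four corner 1-m² quadrats per
aspect, surveyed in a baseline and a resurvey year. The imposed structure is

* per-quadrat richness declining with elevation (``richness_lapse`` species
  per 100 m) and higher on the warmer south/east aspects,
* summit species pools nested from below with probability
  ``nestedness_strength``,
* between years: species replacement on south/east aspects, net species loss
  (with limited gain) on north/west aspects, and a compositional tilt that
  displaces each quadrat's cover-weighted mean thermic rank upward by
  ``shift_magnitude`` (thermophilization),
* species covers drawn log-normally, with multiplicative log-normal
  between-year noise on surviving species.

A :class:`SimulationTruth` record carries the generating parameters needed
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .community import (
    ASPECTS,
    GROWTH_FORMS,
    QuadratObservation,
    SpeciesAttribute,
    Summit,
)
from .errors import ConfigurationError
from .microclimate import TemperatureSeries

__all__ = [
    "SurveyDesign",
    "LoggerDesign",
    "SimulationTruth",
    "generate_survey",
    "generate_logger_series",
    "DEFAULT_SUMMITS",
]

DEFAULT_SUMMITS: tuple[tuple[str, float], ...] = (
    ("GUL1", 3530.0),
    ("GUL2", 3600.0),
    ("GUL3", 3670.0),
    ("GUL4", 3740.0),
)

WARM_ASPECTS = ("S", "E")
COLD_ASPECTS = ("N", "W")


@dataclass(frozen=True)
class SurveyDesign:
    """Parameters of the synthetic resurvey; defaults are the study conditions."""

    summits: tuple[tuple[str, float], ...] = DEFAULT_SUMMITS
    aspects: tuple[str, ...] = ASPECTS
    quadrats_per_aspect: int = 4
    years: tuple[int, int] = (2014, 2018)
    pool_size: int = 68
    richness_at_base: float = 16.0
    richness_lapse: float = 3.0  # expected species lost per 100 m of elevation
    aspect_richness_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"S": 2.0, "E": 1.0, "N": -2.0, "W": -1.0}
    )
    nestedness_strength: float = 0.9
    shift_magnitude: float = 0.3  # upward displacement of cover-weighted rank
    shift_aspects: tuple[str, ...] | None = None  # None: shift on all aspects
    turnover_rate_warm_aspects: float = 0.08
    loss_rate_cold_aspects: float = 0.10
    gain_fraction_cold_aspects: float = 0.25
    cover_log_mean: float = 1.3  # log-scale location of per-species cover
    cover_log_sd: float = 1.0
    cover_change_sd: float = 0.25  # between-year log-normal cover noise
    pool_richness_factor: float = 4.0  # summit pool size per unit expected richness
    seed: int = 0

    def validate(self) -> None:
        for name in ("nestedness_strength", "turnover_rate_warm_aspects",
                     "loss_rate_cold_aspects", "gain_fraction_cold_aspects"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]; got {v}")
        if self.richness_at_base <= 0 or self.richness_lapse < 0:
            raise ConfigurationError("richness parameters must be positive")
        if self.quadrats_per_aspect < 1:
            raise ConfigurationError("quadrats_per_aspect must be >= 1")
        if self.cover_change_sd < 0 or self.cover_log_sd < 0:
            raise ConfigurationError("cover spread parameters must be non-negative")
        elevs = [e for _, e in self.summits]
        if sorted(elevs) != elevs or len(set(elevs)) != len(elevs):
            raise ConfigurationError("summit elevations must be strictly increasing")
        for a in self.aspects:
            if a not in self.aspect_richness_offsets:
                raise ConfigurationError(f"missing aspect_richness_offsets entry for {a!r}")
        for k in range(len(self.summits)):
            for a in self.aspects:
                t = self._target(k, a)
                if t < 0.5:
                    raise ConfigurationError(
                        f"expected richness {t:.2f} at summit {self.summits[k][0]}, aspect {a} is too small"
                    )
                if t > self._pool_sizes()[k]:
                    raise ConfigurationError("summit pool too small for the requested richness")
        if self._pool_sizes()[0] > self.pool_size:
            raise ConfigurationError(
                f"pool_size {self.pool_size} too small to satisfy richness_at_base "
                f"(need >= {self._pool_sizes()[0]})"
            )

    def _target(self, summit_index: int, aspect: str) -> float:
        """Expected per-quadrat richness for one summit/aspect cell."""
        base_elev = self.summits[0][1]
        elev = self.summits[summit_index][1]
        return (
            self.richness_at_base
            - self.richness_lapse * (elev - base_elev) / 100.0
            + float(self.aspect_richness_offsets[aspect])
        )

    def _mean_target(self, summit_index: int) -> float:
        return float(np.mean([self._target(summit_index, a) for a in self.aspects]))

    def _pool_sizes(self) -> list[int]:
        sizes = [max(2, round(self.pool_richness_factor * self._mean_target(k)))
                 for k in range(len(self.summits))]
        # pools must be non-increasing so nested subsets are drawable
        for k in range(1, len(sizes)):
            sizes[k] = min(sizes[k], sizes[k - 1])
        return sizes


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one generated survey, for parameter-recovery tests."""

    species_rank: dict[str, int]
    summit_pools: dict[str, tuple[str, ...]]
    expected_richness: dict[tuple[str, str], float]  # (summit, aspect) -> per-quadrat E[richness]
    shift_magnitude: float
    shift_aspects: tuple[str, ...]
    aspect_process: dict[str, str]


def _weighted_mean(ranks: np.ndarray, covers: np.ndarray) -> float:
    return float((ranks * covers).sum() / covers.sum())


def _tilt_covers(covers: np.ndarray, ranks: np.ndarray, shift: float) -> np.ndarray:
    """Multiplicative rank-gradient tilt making the cover-weighted mean rank
    move by exactly ``shift`` (clipped to the attainable rank interval)."""
    rmin, rmax = ranks.min(), ranks.max()
    if rmax - rmin <= 0:
        return covers
    s0 = _weighted_mean(ranks, covers)
    eps = 1e-6 * (rmax - rmin)
    target = float(np.clip(s0 + shift, rmin + eps, rmax - eps))
    if abs(target - s0) < 1e-12:
        return covers
    centred = ranks - ranks.mean()

    def s_of(gamma: float) -> float:
        w = covers * np.exp(gamma * centred)
        return _weighted_mean(ranks, w) - target

    lo, hi = -1.0, 1.0
    with np.errstate(over="ignore"):
        while not (s_of(lo) < 0 < s_of(hi)):
            lo *= 2.0
            hi *= 2.0
            if hi > 512.0:  # target numerically at a rank boundary; leave unchanged
                return covers
        gamma = brentq(s_of, lo, hi, xtol=1e-12)
    return covers * np.exp(gamma * centred)


def generate_survey(design: SurveyDesign | None = None):
    """Generate a two-year survey: (observations, attributes, truth)."""
    design = design or SurveyDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_summits = len(design.summits)
    species_ids = np.array([f"sp{i:03d}" for i in range(design.pool_size)])

    # --- nested summit pools -------------------------------------------------
    sizes = design._pool_sizes()
    pools: list[np.ndarray] = []
    pool0 = rng.choice(design.pool_size, size=sizes[0], replace=False)
    pools.append(np.sort(pool0))
    for k in range(1, n_summits):
        below = pools[k - 1]
        n_nested = min(int(rng.binomial(sizes[k], design.nestedness_strength)), len(below))
        chosen = list(rng.choice(below, size=n_nested, replace=False))
        # non-nested members come from the full regional pool and may still
        # land in the pool below by chance
        while len(chosen) < sizes[k]:
            candidates = np.setdiff1d(np.arange(design.pool_size), np.array(chosen, dtype=int))
            chosen.extend(rng.choice(candidates, size=sizes[k] - len(chosen), replace=False).tolist())
        pools.append(np.sort(np.array(chosen, dtype=int)))

    # --- thermic ranks from simulated elevation optima -----------------------
    # a species' optimum is the mean index of the summit pools containing it,
    # binned to a summit index; warm-demanding (low-optimum) species get the
    # HIGH thermic ranks so that a positive indicator change means
    # thermophilization
    membership: dict[int, list[int]] = {}
    for k, pool in enumerate(pools):
        for sp in pool:
            membership.setdefault(int(sp), []).append(k + 1)
    elevations = np.array([e for _, e in design.summits], dtype=float)
    rank_of: dict[str, int] = {}
    for sp in sorted(membership):
        # optimum: centre of the species' summit occurrences, jittered to stand
        # in for the flora-informed part of the field assignment
        optimum = float(np.mean(elevations[np.array(membership[sp]) - 1]))
        optimum += rng.normal(0.0, 100.0)
        optimum_bin = int(np.argmin(np.abs(elevations - optimum))) + 1
        rank_of[str(species_ids[sp])] = n_summits + 1 - optimum_bin

    growth_forms = rng.choice(GROWTH_FORMS, size=design.pool_size, p=(0.2, 0.3, 0.4, 0.1))
    attributes = [
        SpeciesAttribute(str(species_ids[sp]), rank_of[str(species_ids[sp])], str(growth_forms[sp]))
        for sp in sorted(membership)
    ]

    def draw_cover(size: int) -> np.ndarray:
        c = rng.lognormal(design.cover_log_mean, design.cover_log_sd, size=size)
        return np.clip(c, 0.01, 100.0)

    shift_aspects = tuple(design.shift_aspects) if design.shift_aspects is not None else tuple(design.aspects)
    year1, year2 = design.years
    observations: list[QuadratObservation] = []
    expected_richness: dict[tuple[str, str], float] = {}

    for k, (summit_id, _elev) in enumerate(design.summits):
        pool = pools[k]
        pool_names = species_ids[pool]
        pool_ranks = np.array([rank_of[s] for s in pool_names], dtype=float)
        for aspect in design.aspects:
            target = design._target(k, aspect)
            expected_richness[(summit_id, aspect)] = target
            p_inc = target / len(pool)
            for q in range(1, design.quadrats_per_aspect + 1):
                present = np.flatnonzero(rng.random(len(pool)) < p_inc)
                covers1 = draw_cover(len(present))
                for idx, cov in zip(present, covers1):
                    observations.append(
                        QuadratObservation(summit_id, aspect, q, year1, str(pool_names[idx]), float(cov))
                    )

                # --- year 2: aspect-specific composition change ---------------
                keep = dict(zip(present.tolist(), covers1.tolist()))
                if aspect in WARM_ASPECTS and design.turnover_rate_warm_aspects > 0:
                    replaced = [i for i in list(keep) if rng.random() < design.turnover_rate_warm_aspects]
                    for i in replaced:
                        del keep[i]
                    absent = np.setdiff1d(np.arange(len(pool)), np.array(list(keep) + replaced, dtype=int))
                    n_gain = min(len(replaced), len(absent))
                    for i in rng.choice(absent, size=n_gain, replace=False) if n_gain else []:
                        keep[int(i)] = float(draw_cover(1)[0])
                elif aspect in COLD_ASPECTS and design.loss_rate_cold_aspects > 0:
                    lost = [i for i in list(keep) if rng.random() < design.loss_rate_cold_aspects]
                    for i in lost:
                        del keep[i]
                    absent = np.setdiff1d(np.arange(len(pool)), np.array(list(keep) + lost, dtype=int))
                    n_gain = min(int(rng.binomial(len(lost), design.gain_fraction_cold_aspects)), len(absent))
                    for i in rng.choice(absent, size=n_gain, replace=False) if n_gain else []:
                        keep[int(i)] = float(draw_cover(1)[0])

                if not keep:
                    continue
                idx2 = np.array(sorted(keep), dtype=int)
                covers2 = np.array([keep[i] for i in idx2], dtype=float)
                if design.cover_change_sd > 0:
                    covers2 = covers2 * np.exp(rng.normal(0.0, design.cover_change_sd, size=len(covers2)))
                if design.shift_magnitude != 0 and aspect in shift_aspects:
                    covers2 = _tilt_covers(covers2, pool_ranks[idx2], design.shift_magnitude)
                covers2 = np.clip(covers2, 0.01, 100.0)
                for i, cov in zip(idx2, covers2):
                    observations.append(
                        QuadratObservation(summit_id, aspect, q, year2, str(pool_names[i]), float(cov))
                    )

    truth = SimulationTruth(
        species_rank=dict(rank_of),
        summit_pools={
            sid: tuple(str(s) for s in species_ids[p]) for (sid, _), p in zip(design.summits, pools)
        },
        expected_richness=expected_richness,
        shift_magnitude=design.shift_magnitude,
        shift_aspects=shift_aspects,
        aspect_process={a: ("turnover" if a in WARM_ASPECTS else "loss") for a in design.aspects},
    )
    return observations, attributes, truth


# ---------------------------------------------------------------------------
# soil-temperature loggers


@dataclass(frozen=True)
class LoggerDesign:
    """Parameters of the synthetic hourly soil-temperature series."""

    aspect_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.8, "E": 0.5, "N": -0.8, "W": -0.5}
    )
    lapse_rate: float = 1.2  # °C per 100 m
    base_mean: float = 6.0  # annual mean at the lowest summit, °C
    seasonal_amplitude: float = 8.0
    diurnal_amplitude: float = 2.0
    noise_sd: float = 1.0
    warming_increment: float = 1.5  # °C added uniformly in the second window
    windows: tuple[tuple[str, str], ...] = (
        ("2014-08-01", "2015-07-31"),
        ("2017-08-01", "2018-07-31"),
    )
    gap_spec: tuple[tuple[str, str, int], ...] = ()  # (logger_id, start, n_hours)
    seed: int = 0


def generate_logger_series(
    summits: Sequence[Summit] | Sequence[tuple[str, float]],
    design: LoggerDesign | None = None,
    aspects: Sequence[str] = ASPECTS,
) -> list[TemperatureSeries]:
    """One hourly series per (summit, aspect, window).

    hourly value = base mean − lapse·Δelev/100 + aspect offset
                   + seasonal sinusoid + diurnal sinusoid
                   + warming increment (second window onward) + Gaussian noise

    Logger ids are "SUMMIT-ASPECT"; specified gaps become explicit NaN.
    """
    design = design or LoggerDesign()
    summits = [s if isinstance(s, Summit) else Summit(s[0], float(s[1])) for s in summits]
    if not all(np.isfinite(v) for v in (design.lapse_rate, design.base_mean,
                                        design.seasonal_amplitude, design.diurnal_amplitude,
                                        design.noise_sd, design.warming_increment)):
        raise ConfigurationError("logger parameters must be finite")
    rng = np.random.default_rng(design.seed)
    base_elev = min(s.elevation for s in summits)
    out: list[TemperatureSeries] = []
    for summit in summits:
        for aspect in aspects:
            logger_id = f"{summit.summit_id}-{aspect}"
            for w, (start, end) in enumerate(design.windows):
                idx = pd.date_range(start, pd.Timestamp(end) + pd.Timedelta(hours=23), freq="h")
                doy = idx.dayofyear.to_numpy(dtype=float)
                hod = idx.hour.to_numpy(dtype=float)
                values = (
                    design.base_mean
                    - design.lapse_rate * (summit.elevation - base_elev) / 100.0
                    + float(design.aspect_offsets.get(aspect, 0.0))
                    + design.seasonal_amplitude * np.sin(2 * np.pi * (doy - 196) / 365.25)
                    + design.diurnal_amplitude * np.sin(2 * np.pi * (hod - 9) / 24.0)
                    + (design.warming_increment if w >= 1 else 0.0)
                )
                if design.noise_sd > 0:
                    values = values + rng.normal(0.0, design.noise_sd, size=len(idx))
                out.append(TemperatureSeries(logger_id, pd.Series(values, index=idx)))

    _apply_gaps(out, design.gap_spec)
    return out


def _apply_gaps(series_list: list[TemperatureSeries], gap_spec) -> None:
    claimed: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for logger_id, start, n_hours in gap_spec:
        start = pd.Timestamp(start)
        end = start + pd.Timedelta(hours=int(n_hours) - 1)
        for s0, e0 in claimed.get(logger_id, []):
            if start <= e0 and s0 <= end:
                raise ConfigurationError(f"overlapping gap specs on logger {logger_id}")
        claimed.setdefault(logger_id, []).append((start, end))
        hit = False
        for ts in series_list:
            if ts.logger_id != logger_id:
                continue
            mask = (ts.series.index >= start) & (ts.series.index <= end)
            if mask.any():
                ts.series[mask] = np.nan
                hit = True
        if not hit:
            raise ConfigurationError(
                f"gap ({logger_id}, {start}, {n_hours}h) lies outside the simulated period"
            )
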