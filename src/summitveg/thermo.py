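"""Thermophilization: cover-weighted thermic vegetation indicator and its
change between surveys.

Each species carries a thermic elevational rank (higher = more warm-demanding,
i.e. a lower elevational optimum). The thermic vegetation indicator of a
quadrat is the cover-weighted mean rank

    S = Σ rank_i · cover_i / Σ cover_i

and the thermophilization indicator is its change D = S_resurvey − S_baseline;
a positive D denotes a compositional shift toward warm-demanding species. D is
tested against zero with the Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import QuadratObservation, SpeciesAttribute
from .errors import AttributeLookupError, DegenerateDesignError, DomainError, MatchingError

__all__ = [
    "ThermicIndicator",
    "ThermoChange",
    "thermic_indicator",
    "thermophilization_change",
    "wilcoxon_signed_rank",
    "indicator_table",
    "change_table",
    "summit_summary",
]


@dataclass(frozen=True)
class ThermicIndicator:
    """Cover-weighted mean thermic rank of one quadrat in one year."""

    summit_id: str
    aspect: str
    quadrat_index: int
    year: int
    S: float

    def quadrat_key(self) -> tuple:
        return (self.summit_id, self.aspect, self.quadrat_index)


@dataclass(frozen=True)
class ThermoChange:
    """Between-survey indicator change D = S_resurvey − S_baseline."""

    summit_id: str
    aspect: str
    quadrat_index: int
    D: float


def _rank_map(ranks) -> Mapping[str, float]:
    if isinstance(ranks, Mapping):
        return ranks
    return {a.species_id: float(a.elevational_rank) for a in ranks}


def thermic_indicator(composition: Sequence[tuple], ranks) -> float:
    """S = Σ rank·cover / Σ cover for one quadrat composition.

    ``composition`` is a list of (species_id, cover) pairs; ``ranks`` a
    mapping or a SpeciesAttribute collection.
    """
    rank_of = _rank_map(ranks)
    if not composition:
        raise DomainError("empty composition: indicator undefined")
    missing = sorted({sp for sp, _ in composition if sp not in rank_of})
    if missing:
        raise AttributeLookupError(f"species missing a rank: {missing}")
    covers = np.array([c for _, c in composition], dtype=float)
    if covers.sum() <= 0:
        raise DomainError("total cover must be positive")
    r = np.array([rank_of[sp] for sp, _ in composition], dtype=float)
    return float((r * covers).sum() / covers.sum())


def indicator_table(
    observations: Iterable[QuadratObservation], attributes
) -> pd.DataFrame:
    """Per-quadrat, per-year indicator values as a tidy table."""
    rank_of = _rank_map(attributes)
    df = pd.DataFrame(
        [(o.summit_id, o.aspect, o.quadrat_index, o.year, o.species_id, o.cover) for o in observations],
        columns=["summit_id", "aspect", "quadrat_index", "year", "species_id", "cover"],
    )
    if df.empty:
        raise DomainError("no observations")
    missing = sorted(set(df["species_id"]) - set(rank_of))
    if missing:
        raise AttributeLookupError(f"species missing a rank: {missing}")
    df["rank"] = df["species_id"].map(rank_of)
    df["rc"] = df["rank"] * df["cover"]
    g = df.groupby(["summit_id", "aspect", "quadrat_index", "year"], sort=True)
    out = (g["rc"].sum() / g["cover"].sum()).rename("S").reset_index()
    return out


def thermophilization_change(
    baseline: pd.DataFrame | Sequence[ThermicIndicator],
    resurvey: pd.DataFrame | Sequence[ThermicIndicator],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-quadrat D = S_resurvey − S_baseline on matched quadrats.

    Returns (changes, unmatched): quadrats vegetated in only one year are
    excluded from D and reported in the second table rather than dropped
    silently.
    """
    def as_frame(x):
        if isinstance(x, pd.DataFrame):
            return x
        return pd.DataFrame(
            [(i.summit_id, i.aspect, i.quadrat_index, i.year, i.S) for i in x],
            columns=["summit_id", "aspect", "quadrat_index", "year", "S"],
        )

    key = ["summit_id", "aspect", "quadrat_index"]
    b = as_frame(baseline).set_index(key)["S"]
    r = as_frame(resurvey).set_index(key)["S"]
    common = b.index.intersection(r.index)
    if len(common) == 0:
        raise MatchingError("no quadrats matched between baseline and resurvey")
    orphan_keys = b.index.symmetric_difference(r.index)
    unmatched = pd.DataFrame(
        [(k[0], k[1], k[2], "baseline" if k in b.index else "resurvey") for k in orphan_keys],
        columns=key + ["present_in"],
    )
    changes = (r.loc[common] - b.loc[common]).rename("D").reset_index()
    return changes, unmatched


def change_table(observations: Iterable[QuadratObservation], attributes,
                 baseline_year: int, resurvey_year: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: indicator tables for both years, then D per quadrat."""
    ind = indicator_table(observations, attributes)
    b = ind[ind["year"] == baseline_year]
    r = ind[ind["year"] == resurvey_year]
    return thermophilization_change(b, r)


def wilcoxon_signed_rank(values, exact_max_n: int = 25) -> dict:
    """Two-sided Wilcoxon signed-rank test of D against zero.

    Zero differences are dropped (standard zero-handling); the exact null
    distribution is used for ≤ ``exact_max_n`` untied non-zero values,
    otherwise the normal approximation with tie and continuity correction.
    """
    if isinstance(values, pd.DataFrame):
        d = values["D"].to_numpy(dtype=float)
    else:
        d = np.asarray(values, dtype=float)
    nonzero = d[d != 0]
    n = len(nonzero)
    if n == 0:
        raise DegenerateDesignError("all differences are exactly zero")
    has_ties = len(np.unique(np.abs(nonzero))) < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_nonzero": n,
        "method": method,
    }


def summit_summary(changes: pd.DataFrame) -> pd.DataFrame:
    """Per-summit mean ± SE of D with a signed-rank p-value."""
    rows = []
    for summit, grp in changes.groupby("summit_id", sort=True):
        d = grp["D"].to_numpy(dtype=float)
        se = float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan
        try:
            p = wilcoxon_signed_rank(d)["p_value"]
        except DegenerateDesignError:  # all-zero D in this summit
            p = np.nan
        rows.append({"summit_id": summit, "n": len(d), "mean_D": float(np.mean(d)), "se_D": se, "p_value": p})
    return pd.DataFrame(rows)
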