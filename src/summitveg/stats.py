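"""Descriptive and inferential summaries of richness, cover, and soil
temperature across summits, aspects, and survey years.

Richness and cover respond to summit (elevation), aspect (microclimate), and
survey year. The inferential machinery is fixed-effects ANOVA — aspect nested
within summit for the spatial design, summit × year with interaction for the
temporal design — with Tukey post-hoc comparisons, preceded by Shapiro–Wilk
normality and Brown–Forsythe (median-centred Levene) variance-homogeneity
checks.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .community import QuadratObservation, SpeciesAttribute
from .errors import DegenerateDesignError, DomainError, EmptyInputError

__all__ = [
    "group_summary",
    "richness_per_quadrat",
    "total_cover_per_quadrat",
    "cover_change_table",
    "factor_effects",
    "tukey_posthoc",
    "assumption_checks",
]


def _obs_frame(observations: Iterable[QuadratObservation]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(o.summit_id, o.aspect, o.quadrat_index, o.year, o.species_id, o.cover) for o in observations],
        columns=["summit_id", "aspect", "quadrat_index", "year", "species_id", "cover"],
    )
    if df.empty:
        raise EmptyInputError("no observations")
    return df


def group_summary(values: pd.DataFrame, response: str, by: Sequence[str]) -> pd.DataFrame:
    """n, mean, and standard error of the mean per grouping key."""
    g = values.groupby(list(by), sort=True)[response]
    out = g.agg(n="count", mean="mean", sd="std")
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd").reset_index()


def richness_per_quadrat(observations: Iterable[QuadratObservation]) -> pd.DataFrame:
    """Count of distinct species per (summit, aspect, quadrat, year)."""
    df = _obs_frame(observations)
    out = (
        df.groupby(["summit_id", "aspect", "quadrat_index", "year"], sort=True)["species_id"]
        .nunique()
        .rename("richness")
        .reset_index()
    )
    return out


def total_cover_per_quadrat(observations: Iterable[QuadratObservation]) -> pd.DataFrame:
    """Summed percent cover per (summit, aspect, quadrat, year)."""
    df = _obs_frame(observations)
    return (
        df.groupby(["summit_id", "aspect", "quadrat_index", "year"], sort=True)["cover"]
        .sum()
        .rename("total_cover")
        .reset_index()
    )


def cover_change_table(
    observations: Iterable[QuadratObservation],
    baseline_year: int,
    resurvey_year: int,
    attributes: Sequence[SpeciesAttribute] | None = None,
    growth_form: str | None = None,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-species cover change between surveys over occupied quadrats.

    Δ per quadrat is resurvey − baseline cover, treating absence as 0 within
    quadrats where the species occurs in at least one year; mean, SE, and a
    paired-sample (one-sample t on Δ) p-value are reported per species.
    """
    df = _obs_frame(observations)
    if growth_form is not None:
        if attributes is None:
            raise DomainError("growth-form filtering requires an attribute table")
        keep = {a.species_id for a in attributes if a.growth_form == growth_form}
        df = df[df["species_id"].isin(keep)]
    if species is not None:
        df = df[df["species_id"].isin(set(species))]
    df = df[df["year"].isin((baseline_year, resurvey_year))]
    if df.empty:
        raise EmptyInputError("no observations for the requested species/years")

    key = ["summit_id", "aspect", "quadrat_index"]
    wide = df.pivot_table(index=key + ["species_id"], columns="year", values="cover",
                          aggfunc="sum", fill_value=np.nan)
    for yr in (baseline_year, resurvey_year):
        if yr not in wide.columns:
            wide[yr] = np.nan
    wide = wide.fillna(0.0)
    wide["delta"] = wide[resurvey_year] - wide[baseline_year]
    rows = []
    for sp, grp in wide.groupby("species_id", sort=True):
        d = grp["delta"].to_numpy(dtype=float)
        mean = float(np.mean(d))
        se = float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else 0.0
        if len(d) > 1 and np.std(d, ddof=1) > 0:
            p = float(sps.ttest_1samp(d, 0.0).pvalue)
        else:
            p = np.nan
        rows.append({"species_id": sp, "n_quadrats": len(d), "mean_delta": mean, "se_delta": se, "p_value": p})
    return pd.DataFrame(rows)


def factor_effects(
    data: pd.DataFrame,
    response: str,
    design: Literal["oneway", "oneway_nested", "twoway_interaction"],
    factor: str = "summit_id",
) -> pd.DataFrame:
    """Fixed-effects ANOVA table (sequential sums of squares).

    ``oneway`` fits a single factor (``factor``); ``oneway_nested`` fits
    summit + aspect-within-summit, the nested term encoded as the
    summit:aspect interaction of the two fixed factors;
    ``twoway_interaction`` fits summit + year + summit:year.
    """
    df = data.copy()
    if design == "oneway":
        needed = [factor]
        formula = f"{response} ~ C({factor})"
    elif design == "oneway_nested":
        needed = ["summit_id", "aspect"]
        formula = f"{response} ~ C(summit_id) + C(summit_id):C(aspect)"
    elif design == "twoway_interaction":
        needed = ["summit_id", "year"]
        formula = f"{response} ~ C(summit_id) + C(year) + C(summit_id):C(year)"
    else:
        raise DomainError(f"unknown design {design!r}")
    for col in needed + [response]:
        if col not in df.columns:
            raise DomainError(f"data lacks column {col!r}")
    for col in needed:
        if df[col].nunique() < 2:
            raise DegenerateDesignError(f"factor {col} has fewer than 2 levels")

    cells = df.groupby(needed).size()
    full_grid = np.prod([df[c].nunique() for c in needed])
    if len(cells) < full_grid:
        warnings.warn(f"unbalanced design: {int(full_grid - len(cells))} empty cell(s)", stacklevel=2)
    if design == "twoway_interaction" and (cells <= 1).all():
        raise DegenerateDesignError("single replicate per cell: interaction model has no residual")

    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(columns={"PR(>F)": "p_value"})
    not_resid = table.index != "Residual"
    if np.ptp(df[response].to_numpy(dtype=float)) == 0:
        # all responses equal: every between-group contrast is exactly zero
        table.loc[not_resid, "F"] = 0.0
        table.loc[not_resid, "p_value"] = 1.0
    table.loc[not_resid & (table["sum_sq"] <= 1e-12) & table["F"].isna(), "F"] = 0.0
    table.index.name = "term"
    return table.reset_index()


def tukey_posthoc(data: pd.DataFrame, response: str, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD simultaneous pairwise comparisons for one factor."""
    df = data.dropna(subset=[response, factor])
    levels = df[factor].astype(str)
    counts = levels.value_counts()
    if (counts < 2).any():
        bad = list(counts[counts < 2].index)
        raise DegenerateDesignError(f"level(s) with fewer than 2 observations: {bad}")
    if counts.size < 2:
        raise DegenerateDesignError(f"factor {factor} has fewer than 2 levels")
    res = pairwise_tukeyhsd(df[response].to_numpy(dtype=float), levels.to_numpy(), alpha=alpha)
    pairs = [(res.groupsunique[i], res.groupsunique[j]) for i, j in zip(*np.triu_indices(len(res.groupsunique), 1))]
    return pd.DataFrame({
        "group1": [p[0] for p in pairs],
        "group2": [p[1] for p in pairs],
        "mean_diff": res.meandiffs,
        "p_adj": res.pvalues,
        "reject": res.reject,
    })


def assumption_checks(data: pd.DataFrame, response: str, group: str) -> dict:
    """Shapiro–Wilk normality on group-centred residuals and Brown–Forsythe
    (median-centred Levene) homogeneity of variance."""
    df = data.dropna(subset=[response, group])
    y = df[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDesignError("constant response")
    groups = [g[response].to_numpy(dtype=float) for _, g in df.groupby(group)]
    if any(len(g) < 3 for g in groups):
        raise DegenerateDesignError("each group needs at least 3 observations")
    resid = np.concatenate([g - g.mean() for g in groups])
    sw_stat, sw_p = sps.shapiro(resid)
    lv_stat, lv_p = sps.levene(*groups, center="median")
    return {
        "shapiro_stat": float(sw_stat), "shapiro_p": float(sw_p),
        "levene_stat": float(lv_stat), "levene_p": float(lv_p),
    }
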