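"""End-to-end orchestration: configuration, staged execution, table output.

A run is driven by a :class:`RunConfig` holding either input-file paths or a
simulation section (never both). Stages execute in a fixed order —
simulate/load → validate → microclimate → summaries → β-diversity →
variation partitioning → thermophilization — each writing delimited-text
tables whose header comments record the package version, seed, and a hash of
the configuration, so identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta import (
    average_linkage_cluster,
    component_distance_matrix,
    multisite_partition,
    temporal_partition,
)
from .community import (
    Summit,
    build_matrix,
    read_attributes,
    read_observations,
    read_summits,
    validate_attributes,
    validate_observations,
    write_attributes,
    write_observations,
    write_summits,
)
from .errors import ConfigurationError
from .microclimate import (
    daily_stats,
    growing_degree_days,
    impute_gaps,
    read_logger_series,
    temperature_trend,
    write_logger_series,
)
from .stats import cover_change_table, group_summary, richness_per_quadrat, total_cover_per_quadrat
from .synthetic import LoggerDesign, SurveyDesign, generate_logger_series, generate_survey
from .thermo import change_table, summit_summary, wilcoxon_signed_rank
from .varpart import varpart_table

log = logging.getLogger("summitveg")

__all__ = ["RunConfig", "run_pipeline", "write_table", "simulate_to_dir"]


@dataclass
class RunConfig:
    """Validated run configuration: inputs XOR simulation, plus analysis knobs."""

    seed: int = 0
    output_dir: str = "summitveg_out"
    inputs: Mapping[str, str] | None = None
    simulation: Mapping[str, Any] | None = None
    beta_grouping: str = "summit"
    gdd_threshold: float = 5.0
    n_permutations: int = 199
    min_valid_hours: int = 18

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of 'inputs' and 'simulation' must be provided"
            )
        if self.beta_grouping not in ("aspect", "summit"):
            raise ConfigurationError("beta_grouping must be 'aspect' or 'summit'")
        if self.inputs is not None:
            needed = {"observations", "attributes", "summits"}
            missing = needed - set(self.inputs)
            if missing:
                raise ConfigurationError(f"inputs section missing entries: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ConfigurationError(f"input file for {key!r} not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        analysis = dict(raw.get("analysis", {}))
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "summitveg_out")),
            inputs=raw.get("inputs"),
            simulation=raw.get("simulation"),
            beta_grouping=analysis.get("beta_grouping", "summit"),
            gdd_threshold=float(analysis.get("gdd_threshold", 5.0)),
            n_permutations=int(analysis.get("n_permutations", 199)),
            min_valid_hours=int(analysis.get("min_valid_hours", 18)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed, "inputs": dict(self.inputs or {}),
                "simulation": self.simulation, "beta_grouping": self.beta_grouping,
                "gdd_threshold": self.gdd_threshold, "n_permutations": self.n_permutations,
                "min_valid_hours": self.min_valid_hours,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    """Delimited-text output with commented metadata header lines."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# summitveg {__version__}\n")
        fh.write(f"# seed = {config.seed}\n")
        fh.write(f"# config_hash = {config.config_hash()}\n")
        df.to_csv(fh, index=index, float_format="%.10g")


def simulate_to_dir(config: RunConfig, outdir: Path) -> dict[str, Path]:
    """Run the generators and write observation/attribute/summit/logger/truth files."""
    sim = dict(config.simulation or {})
    survey_kwargs = dict(sim.get("survey", {}))
    logger_kwargs = dict(sim.get("loggers", {}))
    if "summits" in survey_kwargs:
        survey_kwargs["summits"] = tuple((s, float(e)) for s, e in survey_kwargs["summits"])
    design = SurveyDesign(**survey_kwargs, seed=config.seed) if "seed" not in survey_kwargs else SurveyDesign(**survey_kwargs)
    observations, attributes, truth = generate_survey(design)
    summits = [Summit(sid, elev) for sid, elev in design.summits]
    if "gap_spec" in logger_kwargs:
        logger_kwargs["gap_spec"] = tuple(tuple(g) for g in logger_kwargs["gap_spec"])
    ldesign = LoggerDesign(**logger_kwargs, seed=config.seed + 1) if "seed" not in logger_kwargs else LoggerDesign(**logger_kwargs)
    loggers = generate_logger_series(summits, ldesign)

    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": outdir / "observations.csv",
        "attributes": outdir / "attributes.csv",
        "summits": outdir / "summits.csv",
        "loggers": outdir / "loggers.csv",
        "truth": outdir / "truth.json",
    }
    write_observations(observations, paths["observations"])
    write_attributes(attributes, paths["attributes"])
    write_summits(summits, paths["summits"])
    write_logger_series(loggers, paths["loggers"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "species_rank": truth.species_rank,
                "summit_pools": {k: list(v) for k, v in truth.summit_pools.items()},
                "expected_richness": {f"{s}:{a}": v for (s, a), v in truth.expected_richness.items()},
                "shift_magnitude": truth.shift_magnitude,
                "shift_aspects": list(truth.shift_aspects),
                "aspect_process": truth.aspect_process,
            },
            fh, indent=1, sort_keys=True,
        )
    log.info("simulate: %d observations, %d species, %d logger series",
             len(observations), len(attributes), len(loggers))
    return paths


def _microclimate_stage(loggers, config: RunConfig, outdir: Path) -> None:
    gdd_rows, trend_rows = [], []
    by_logger: dict[str, list] = {}
    for ts in loggers:
        by_logger.setdefault(ts.logger_id, []).append(ts)
    for logger_id, series_list in sorted(by_logger.items()):
        series_list = sorted(series_list, key=lambda t: t.series.index[0])
        for w, ts in enumerate(series_list):
            if ts.n_missing and w > 0:
                ts, _sd = impute_gaps(ts, series_list[0], seed=config.seed)
            daily = daily_stats(ts, min_valid_hours=config.min_valid_hours)
            res = growing_degree_days(daily, threshold=config.gdd_threshold, logger_id=logger_id)
            gdd_rows.append({
                "logger_id": logger_id, "window_start": res.window[0].date(),
                "window_end": res.window[1].date(), "gdd": res.gdd,
                "days_counted": res.days_counted,
            })
            monthly = daily["tavg"].groupby(daily.index.to_period("M")).mean().dropna()
            if len(monthly) >= 3:
                tr = temperature_trend(monthly)
                trend_rows.append({"logger_id": logger_id, "window": w,
                                   "level": "monthly", **tr})
    write_table(pd.DataFrame(gdd_rows), outdir / "gdd.csv", config)
    write_table(pd.DataFrame(trend_rows), outdir / "temperature_trend.csv", config)
    log.info("microclimate: %d GDD rows", len(gdd_rows))


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict[str, Path]:
    """Execute all stages; returns a name → path map of the output bundle."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    # --- stage 1: data --------------------------------------------------------
    if config.simulation is not None:
        paths = simulate_to_dir(config, outdir / "data")
    else:
        paths = {k: Path(v) for k, v in (config.inputs or {}).items()}
    observations = read_observations(paths["observations"])
    attributes = read_attributes(paths["attributes"])
    summits = read_summits(paths["summits"])
    loggers = read_logger_series(paths["loggers"]) if "loggers" in paths else []

    # --- stage 2: validate ----------------------------------------------------
    validate_observations(observations)
    validate_attributes(attributes, observations)
    years = sorted({o.year for o in observations})
    if len(years) != 2:
        raise ConfigurationError(f"expected exactly two survey years, found {years}")
    year1, year2 = years
    log.info("validate: %d observations across years %s", len(observations), years)

    # --- stage 3: microclimate -------------------------------------------------
    if loggers:
        _microclimate_stage(loggers, config, outdir)
        bundle["gdd"] = outdir / "gdd.csv"
        bundle["temperature_trend"] = outdir / "temperature_trend.csv"

    # --- stage 4: summaries -----------------------------------------------------
    rich = richness_per_quadrat(observations)
    write_table(rich, outdir / "richness.csv", config)
    summary = group_summary(rich, "richness", ["summit_id", "year"])
    write_table(summary, outdir / "richness_summary.csv", config)
    cover = cover_change_table(observations, year1, year2)
    write_table(cover, outdir / "cover_change.csv", config)
    bundle.update({"richness": outdir / "richness.csv",
                   "richness_summary": outdir / "richness_summary.csv",
                   "cover_change": outdir / "cover_change.csv"})

    # --- stage 5: beta diversity -------------------------------------------------
    beta_rows = []
    for year in (year1, year2):
        m = build_matrix(observations, grouping=config.beta_grouping, year_filter=year,
                         mode="incidence", summits=summits)
        part = multisite_partition(m)
        beta_rows.append({"year": year, "grouping": config.beta_grouping, "n_sites": len(m.values),
                          "bsor": part.bsor, "bsim": part.bsim, "bsne": part.bsne})
    write_table(pd.DataFrame(beta_rows), outdir / "beta_multisite.csv", config)

    m1 = build_matrix(observations, grouping="aspect", year_filter=year1, mode="incidence", summits=summits)
    m2 = build_matrix(observations, grouping="aspect", year_filter=year2, mode="incidence", summits=summits)
    temporal = temporal_partition(m1, m2)
    tdf = pd.DataFrame(
        [{"site": k, "bsor": v.bsor, "bsim": v.bsim, "bsne": v.bsne} for k, v in sorted(temporal.items())]
    )
    write_table(tdf, outdir / "beta_temporal.csv", config)
    for comp in ("bsim", "bsne"):
        dm = component_distance_matrix(m1, comp)
        write_table(dm, outdir / f"beta_{comp}_matrix.csv", config, index=True)
        (outdir / f"dendrogram_{comp}.nwk").write_text(average_linkage_cluster(dm).to_newick() + "\n")
    bundle.update({"beta_multisite": outdir / "beta_multisite.csv",
                   "beta_temporal": outdir / "beta_temporal.csv"})
    log.info("beta: multisite and temporal partitions on %d sites", len(m1.values))

    # --- stage 6: variation partitioning ------------------------------------------
    elev = {s.summit_id: s.elevation for s in summits}
    cover_q = total_cover_per_quadrat(observations)
    merged = rich.merge(cover_q, on=["summit_id", "aspect", "quadrat_index", "year"], how="outer").fillna(0.0)
    vp = varpart_table(
        {"richness": merged["richness"].to_numpy(float),
         "total_cover": merged["total_cover"].to_numpy(float)},
        E=merged["summit_id"].map(elev).to_numpy(float),
        A=merged["aspect"], Y=merged["year"],
        n_perm=config.n_permutations, seed=config.seed,
    )
    write_table(vp, outdir / "varpart.csv", config)
    bundle["varpart"] = outdir / "varpart.csv"
    log.info("varpart: partitioned %d responses over %d quadrat-years", 2, len(merged))

    # --- stage 7: thermophilization -------------------------------------------------
    changes, unmatched = change_table(observations, attributes, year1, year2)
    write_table(changes, outdir / "thermo_changes.csv", config)
    tsum = summit_summary(changes)
    overall = wilcoxon_signed_rank(changes)
    tsum = pd.concat(
        [tsum, pd.DataFrame([{"summit_id": "ALL", "n": len(changes),
                              "mean_D": changes["D"].mean(),
                              "se_D": changes["D"].std(ddof=1) / np.sqrt(len(changes)),
                              "p_value": overall["p_value"]}])],
        ignore_index=True,
    )
    write_table(tsum, outdir / "thermo_summary.csv", config)
    if len(unmatched):
        write_table(unmatched, outdir / "thermo_unmatched.csv", config)
    bundle.update({"thermo_changes": outdir / "thermo_changes.csv",
                   "thermo_summary": outdir / "thermo_summary.csv"})
    log.info("thermophilization: %d matched quadrats, overall p = %.4g",
             len(changes), overall["p_value"])
    return bundle
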