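# summitveg

Analysis toolkit for alpine summit resurvey data in the GLORIA multi-summit
style: permanent 1-m² quadrats on a set of summits spanning an elevation
gradient, recorded in a baseline and a resurvey year, with hourly soil
temperature loggers on every summit aspect. It is written for ecologists who
want to ask, from such data, how alpine vegetation is responding to warming —
and for method development against a built-in synthetic generator that
emulates the whole study design with known ground truth.

## What it computes

**β-diversity partitioning (Sørensen family).** For two sites with `a` shared
species and `b`, `c` species unique to each side,

```
βsor = (b+c) / (2a+b+c)          total dissimilarity
βsim = min(b,c) / (a+min(b,c))   turnover (species replacement)
βsne = βsor − βsim               nestedness-resultant dissimilarity
```

with the multiple-site forms aggregating Σ min(bij, bji) and Σ max(bij, bji)
over all site pairs, the same partition applied to one site's composition in
two survey years (temporal change), per-component distance matrices, and UPGMA
clustering with Newick export.

**Thermophilization.** Each species carries a thermic elevational rank
(higher = more warm-demanding). Per quadrat,
`S = Σ rankᵢ·coverᵢ / Σ coverᵢ` and `D = S_resurvey − S_baseline`;
positive D indicates a shift toward warm-demanding species. D is tested
against zero with the Wilcoxon signed-rank test (exact for small samples).

**Soil microclimate.** Daily `Tavg = (Tmin + Tmax)/2` from hourly loggers,
growing degree days `GDD = Σ (Tavg − 5)` over days with Tavg above 5 °C,
seasonal-analogue multiple imputation of logger gaps from the same logger's
prior-year record (30 draws from the empirical monthly residual
distribution), and linear warming trends.

**Variation partitioning.** Adjusted-R² decomposition of a per-quadrat
response (richness, total cover) into pure and shared fractions of elevation
(E), aspect (A), and survey year (Y) — seven fractions by inclusion–exclusion
over the seven nested OLS models — with Freedman–Lane permutation tests
(partial pseudo-F) for the pure fractions.

**Summit statistics.** Group means ± SE, per-species cover-change tables,
fixed-effects ANOVA (one-way, aspect-nested-in-summit, summit × year), Tukey
HSD, and Shapiro–Wilk / Brown–Forsythe assumption checks.

**Synthetic data.** `generate_survey` builds a two-year, 4-summit ×
4-aspect × 4-quadrat survey with richness declining by a set lapse per 100 m,
warmer/richer south and east aspects, summit pools nested from below with
configurable strength, aspect-specific between-year processes (replacement on
S/E, loss on N/W), and a controllable thermophilization shift — plus a truth
record for parameter-recovery tests. `generate_logger_series` builds matching
hourly soil-temperature series (seasonal + diurnal sinusoids, elevation lapse,
aspect offsets, warming increment, specified gaps).

## Worked example

```python
from summitveg import generate_survey, wilcoxon_signed_rank
from summitveg.beta import multisite_partition
from summitveg.community import build_matrix
from summitveg.synthetic import SurveyDesign
from summitveg.thermo import change_table

observations, attributes, truth = generate_survey(SurveyDesign(seed=3))

m = build_matrix(observations, grouping="summit", year_filter=2014, mode="incidence")
print(multisite_partition(m))

changes, _ = change_table(observations, attributes, 2014, 2018)
print(changes["D"].mean(), wilcoxon_signed_rank(changes)["p_value"])
```

prints (seed 3):

```
BetaPartition(bsor=0.25925925925925924, bsim=0.047619047619047616, bsne=0.21164021164021163)
0.35012385039309113 3.3418714026699116e-11
```

Among the four summits, total dissimilarity (0.259) is carried mostly by
nestedness (0.212) rather than turnover (0.048): higher summits hold largely
subsets of the lower summits' flora. The mean thermophilization indicator
change of +0.35 rank units recovers the imposed 0.3-unit shift, and the
signed-rank test rejects D = 0 decisively.

Short narrative scripts for each capability live in `examples/`
(`beta_partitioning.py`, `thermophilization.py`, `microclimate_gdd.py`,
`variation_partitioning.py`, `run_pipeline.py`). A thin CLI wraps the
pipeline: `summitveg simulate|validate|microclim|summarize|beta|varpart|
thermo|report|run`, e.g.

```
summitveg run --config config.yml --seed 1 --out results/
```

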