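# Methods

## The analysis model

The package analyses a multi-summit alpine monitoring design: a set of
summits ordered along an elevation gradient (default: four summits at 3530,
3600, 3670 and 3740 m), four compass aspects per summit, a fixed number of
permanent 1-m² quadrats per aspect (default 4, i.e. 16 per summit, 64 total),
a baseline survey and one resurvey, and one hourly soil-temperature logger at
10 cm depth per summit aspect. The atomic vegetation record is one species'
percent cover in one quadrat in one year; absence is encoded by record
absence and cover 0 is invalid. Summit-area section records (ordinal
abundance classes 1–5) are supported as a second schema and mapped to
representative covers through a configurable, strictly increasing midpoint
table (default 0.5, 3, 15, 37.5, 87.5 % — a declared convention, since class
bounds are a recording choice, not a measurement).

## β-diversity partitioning

All β computations are incidence-based; cover matrices are thresholded at
> 0 first. For a site pair with `a` shared and `b`, `c` one-sided unique
species,

- βsor = (b+c)/(2a+b+c),
- βsim = min(b,c)/(a+min(b,c)),
- βsne = βsor − βsim,

so βsor = βsim + βsne identically; βsim isolates species replacement and βsne
the richness-difference (nestedness) signal. A pair with one empty side is a
domain error rather than βsor = 1: the Sørensen dissimilarity of an empty
community is undefined. The multiple-site forms use the pairwise one-sided
unique counts bij:

- βSIM = Σ min(bij,bji) / (Σ min(bij,bji) + ΣSi − ST),
- βSOR = (Σ min + Σ max) / (2(ΣSi − ST) + Σ min + Σ max),
- βSNE = βSOR − βSIM,

where Si are site richnesses and ST the pooled richness; for n = 2 this
reduces exactly to the pairwise partition. Correctness is anchored in the
test suite by (i) exhaustive agreement with a set-arithmetic oracle over all
incidence pairs on ≤ 10 species and all ≤ 4-site × 6-species matrices (up to
site order, whose irrelevance is property-tested), and (ii) an independent
cross-check against `vegan::nestedbetasor` via Rscript.

Temporal change is the pairwise partition of one site's composition in the
two survey years, matched on (summit, aspect[, quadrat]); unmatched sites are
an error that lists the orphans. Distance matrices of any single component
feed UPGMA (average-linkage) clustering; ties break deterministically by
pre-sorting site labels lexicographically. Dendrograms export as Newick with
ultrametric branch lengths (a leaf-to-root path equals half the cophenetic
distance); labels containing structural characters are quoted.

## Thermophilization

Species carry an integer thermic elevational rank. The rank convention
follows the thermic-indicator literature: **higher rank = more warm-demanding
(lower elevational optimum)**, so that the cover-weighted mean rank
S = Σ rank·cover / Σ cover rises, and D = S_resurvey − S_baseline is
positive, when composition shifts toward warm-adapted species. Ranks are
consumed as given — rank assignment from floras or occurrence data is an
input convention, not an algorithm of this package. Quadrats vegetated in
only one year are excluded from D and reported in a side table. D is tested
against zero with the two-sided Wilcoxon signed-rank test: zeros dropped,
mid-ranks for ties, the exact null distribution for ≤ 25 untied non-zero
values and the tie- and continuity-corrected normal approximation above.

## Soil microclimate

Daily statistics use the half-range convention Tavg = (Tmin + Tmax)/2 over
each calendar day's available hourly values; days with fewer than 18 valid
hours (configurable) are emitted as missing. Growing degree days accumulate
Tavg − threshold over days with Tavg strictly above the threshold (default
5 °C, the biologically motivated alpine choice); "above" is read strictly,
with an inclusive flag exposed. Timestamps are treated as local standard
time; DST is ignored.

Logger gaps are filled by a seasonal-analogue multiple imputation: each
missing hour takes the same logger's prior-year value at the same
(month, day, hour) slot plus the mean of 30 residuals drawn from the
empirical distribution of current-minus-prior differences over the observed
hours of the same calendar month (falling back to the all-month pool if a
month has no overlap). Observed values are never altered, fills are seeded
and reproducible, and the per-hour SD of the draws is returned as an
uncertainty measure. This scheme is fully specified and testable while
honouring the same principle as EM-based imputation from the prior year's
record: the prior year supplies the seasonal-diurnal shape, the residual pool
the current year's deviation scale. Warming trends are OLS slopes of monthly
or annual means on the period index with the standard slope t-test; a
constant series returns slope 0 with p = 1 rather than a degenerate ratio.

## Variation partitioning

Responses are per-quadrat scalars (richness, summed cover), so the partition
reduces to linear-model adjusted R² — Ezekiel's
1 − (1 − R²)(n − 1)/(n − p − 1) — rather than a multivariate ordination.
Elevation enters as a numeric covariate by default (passing summit identity
as a factor is supported), aspect and year as unordered factors. Seven nested
OLS models {E}, {A}, {Y}, {EA}, {EY}, {AY}, {EAY} yield pure fractions
(pure_E = adjR²(EAY) − adjR²(AY), analogously for A and Y) and shared
fractions by inclusion–exclusion (shared_EA = adjR²(EY) + adjR²(AY) −
adjR²(EAY) − adjR²(Y), etc.); the seven fractions sum to the full-model
adjusted R² by construction, and negative fractions are reported as computed.
The implementation agrees with `vegan::varpart` to 1e-9 on shared test
inputs.

A consequence worth knowing: on an *exactly* orthogonal balanced design with
a noiseless single-variable response, the nuisance models have R² = 0 exactly
— below their expectation under random predictors — so the pure fraction of
the active variable overshoots the total by exactly p/(n − p − 1) of the
nuisance model (0.0325 at n = 128 with four nuisance parameters). This is a
property of adjusted-R² partitioning itself (vegan reproduces it to machine
precision), not an implementation artefact.

Pure fractions are tested by Freedman–Lane permutation: residuals of the
reduced model are permuted and added back to its fit, and the **partial
pseudo-F** of the tested variable is recomputed per permutation, with
p = (1 + #{F* ≥ F})/(n_perm + 1) (p = 1 at n_perm = 0). The pseudo-F, not
the adjusted-R² gain, is the permuted statistic: the reduced-model refit
absorbs part of each permuted residual vector, which makes the raw gain's
permutation distribution conservative, while the pseudo-F is calibrated
(null p-values uniform; verified by KS test in the suite). Shared fractions
are algebraic differences and are not testable.

## Summit statistics

ANOVA designs are fixed-effects with sequential (type-I) sums of squares, as
noted in each output: one-way; summit plus aspect-nested-within-summit
(encoded as the summit:aspect interaction, 16 nested levels); and
summit × year with interaction. Balanced designs make the type-I/III choice
moot; empty cells raise a warning listing them, and an interaction model
without replicates is an error. All-equal responses report F = 0 rather than
0/0. Tukey HSD provides simultaneous pairwise comparisons; assumption checks
are Shapiro–Wilk on group-centred residuals and the Brown–Forsythe
(median-centred Levene) variance test, the robust variant. Per-species cover
changes between surveys are simple differences over the quadrats where the
species occurs in at least one year, with absence contributing cover 0 —
the only convention under which "simple subtraction" is defined — and
unadjusted per-species p-values (a Holm flag is available).

## The synthetic generator

`generate_survey` emulates the study conditions with these defaults, chosen
once to mirror the magnitudes a four-summit alpine resurvey reports:

| parameter | default | meaning |
|---|---|---|
| summits | GUL1–GUL4 at 3530–3740 m | the elevation gradient |
| quadrats_per_aspect | 4 | 64 quadrats total |
| years | 2014, 2018 | baseline and resurvey |
| richness_at_base | 16 species/quadrat | expected at the lowest summit |
| richness_lapse | 3 per 100 m | ≈ 40 % richness loss over the 210-m gradient |
| aspect_richness_offsets | S +2, E +1, N −2, W −1 | warm aspects richer; offsets sum to 0 so the mean elevation slope is unbiased |
| pool_size | 68 | regional species pool |
| pool_richness_factor | 4 | summit pool ≈ 4 × mean quadrat richness |
| nestedness_strength | 0.9 | per-species probability a summit-pool member is drawn from the pool below |
| shift_magnitude | 0.3 rank units | imposed upward displacement of the cover-weighted mean rank |
| turnover_rate_warm_aspects | 0.08 | per-species replacement on S/E between years |
| loss_rate_cold_aspects | 0.10 | per-species deletion on N/W (gains at 25 % of losses) |
| cover_log_mean/sd | 1.3 / 1.0 | log-normal species covers (community-abundance default) |
| cover_change_sd | 0.25 | multiplicative log-normal between-year cover noise |

Summit pools are built bottom-up: each higher-summit member is drawn from the
pool below with probability `nestedness_strength`, otherwise uniformly from
the whole regional pool (and may still land in the pool below by chance); at
strength 1 the pools are strictly nested. The regional pool is deliberately
only modestly larger than the lowest summit's flora — a regionally saturated
alpine flora — which is what places the system in the nestedness-dominated
regime at strength 0.9; real floras with more regional exclusives would show
relatively more turnover. Quadrat composition is an independent Bernoulli
draw from the summit pool with inclusion probability target/|pool|, making
expected per-quadrat richness *exactly* linear in elevation plus the aspect
offset — the property the Monte-Carlo slope-recovery test uses. With a
quadrat sampling fraction of ~1/4, sixteen quadrats detect ≈ 99 % of a
summit's pool, so pooled summit incidence is a near-census.

Thermic ranks derive from a simulated elevation optimum: the mean elevation
of the summits whose pools contain the species, jittered by N(0, 100 m) to
stand in for the flora-informed part of a field rank assignment, binned to
the nearest summit index and reversed so warm-demanding species get high
ranks. The between-year thermophilization shift is applied multiplicatively
on the rank gradient: per quadrat, covers are multiplied by exp(γ·rank) with
γ solved (Brent) so the cover-weighted mean rank moves by exactly
`shift_magnitude` (clipped to the attainable rank interval; quadrats whose
species all share one rank cannot move and are left unchanged). Because the
tilt is applied after the between-year cover noise, the expected D equals the
imposed shift and the shift = 0 case reduces to pure noise, which is what the
power and type-I acceptance checks measure. The spec's year-two null example
(no shift, no turnover, no loss ⇒ year 2 identical to year 1) additionally
requires `cover_change_sd = 0`; the noise knob is explicit so that case is
exactly reproducible.

`generate_logger_series` composes an annual sinusoid (amplitude 8 °C), a
diurnal sinusoid (2 °C), an elevation term (−1.2 °C per 100 m), aspect
offsets (S +0.8, E +0.5, N −0.8, W −0.5 °C), a warming increment (+1.5 °C in
the second 12-month window, matching the magnitude of observed soil warming
over such resurvey intervals), and Gaussian noise (SD 1 °C), over two
Aug–Jul windows (2014/15 and 2017/18). Specified gaps (e.g. the classic
20-day battery failure = 480 hours) become explicit NaN; overlapping gap
specifications are a configuration error.

What the generator does *not* emulate: spatial autocorrelation within quadrat
clusters, species interactions, snow-cover dynamics, abundance-dependent
detection, and regional floras much richer than the summit floras. Passing
tests therefore demonstrate that the estimators recover known structure under
idealised sampling, not that field data of this design would yield the same
power.

## Problem sizes and numerical choices

The shipped test suite runs the exhaustive pairwise oracle on all 1024²
10-species pairs, the multi-site oracle on all ≤ 4 × 6 incidence matrices up
to site permutation (~766 k matrices), 200-replicate recovery experiments for
the thermophilization power/type-I and qualitative-structure checks,
400-replicate ANOVA type-I calibration, and 500-replicate permutation-test
calibration at 199 permutations; the acceptance script uses 100 replicate
surveys for rate estimates and 999 permutations for the variation-partition
test. Additivity (βsor = βsim + βsne) is asserted at 1e-12 and the
fraction-sum identity at 1e-10; the Brent tilt solver uses xtol 1e-12 with a
doubling bracket capped at |γ| = 512, beyond which the target is treated as a
rank-boundary and the covers left untouched. CSV round trips use 17
significant digits on write and pandas' round-trip float parser on read so
that validated records survive write→read bit-exactly.
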