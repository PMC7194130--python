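"""Hourly soil-logger series to daily statistics, growing degree days, and
gap filling from the prior year's record."""

from summitveg import LoggerDesign, Summit, daily_stats, generate_logger_series, growing_degree_days, impute_gaps

summits = [Summit("GUL1", 3530.0), Summit("GUL4", 3740.0)]
design = LoggerDesign(seed=7, gap_spec=(("GUL1-N", "2018-01-05", 480),))
series = generate_logger_series(summits, design, aspects=("N",))

for ts in sorted(series, key=lambda t: (t.logger_id, t.series.index[0])):
    window = f"{ts.series.index[0].date()}..{ts.series.index[-1].date()}"
    filled = ts
    if ts.n_missing:
        reference = next(t for t in series
                         if t.logger_id == ts.logger_id and t.series.index[0].year == 2014)
        filled, sd = impute_gaps(ts, reference, seed=7)
        print(f"{ts.logger_id} {window}: filled {ts.n_missing} missing hours "
              f"(mean imputation SD {sd[sd > 0].mean():.2f} °C)")
    daily = daily_stats(filled)  # Tavg = (Tmin + Tmax) / 2 per day
    gdd = growing_degree_days(daily, threshold=5.0)
    print(f"{ts.logger_id} {window}: annual mean {filled.series.mean():6.2f} °C, "
          f"GDD(5 °C) = {gdd.gdd:7.1f} over {gdd.days_counted} days")
# GDD accumulates Tavg - 5 over days with Tavg above 5 °C: a proxy for the
# thermal growing season. The higher summit is ~2.5 °C colder (1.2 °C/100 m)
# and the 2017/18 window is 1.5 °C warmer than 2014/15 by construction.
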