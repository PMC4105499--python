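"""Test for changes in median migration dates across historical periods.

Simulates three periods over western Europe with a 13.36-day advancement
of the southern belt in the last period, estimates per-cell-period median
dates from cloglog fits, and runs the heteroscedastic mixed model with
likelihood-ratio tests and Tukey-style contrasts.
"""

from migwave.change import PeriodSpec, west_europe_nafrica_belts
from migwave.pipeline import RunConfig, simulate_frames, prepare_frames, \
    analyze_change

cfg = RunConfig(
    region="west_europe_nafrica", season="spring",
    simulate={"onset_day": 120.0, "speed": 2.0, "intensity": 150,
              "lat_range": (30.0, 58.0), "lon_range": (-10.0, 22.0),
              "period_shifts": {("1991-2008", "south"): -13.36}},
    seed=3)
records, truth, _ = simulate_frames(cfg, with_periods=True)
_, _, assigned, table, elig, adjacency, _ = prepare_frames(
    records, cfg.region, cfg.season)
mdt, fit = analyze_change(assigned, table, elig, adjacency,
                          PeriodSpec(cfg.periods),
                          west_europe_nafrica_belts(), mc_seed=cfg.seed)

print(f"median-date table: {len(mdt)} (cell, period) rows, "
      f"{mdt['cell_id'].nunique()} cells")
print("\nlikelihood-ratio tests (ML, nested models):")
for name, t in fit.lrt.items():
    print(f"  {name:<20} chi2({t['df']}) = {t['chi2']:6.2f},  p = {t['p']:.4g}")

print("\nper-period residual SDs (days):",
      [round(v, 2) for v in fit.full["sd_resid_by_period"]])

c = fit.contrasts
south = c[c["belt"] == "south"]
print("\nperiod contrasts in the southern belt (days, later minus earlier"
      " period; adjusted p):")
for _, r in south.iterrows():
    print(f"  {r['period_b']} - {r['period_a']}: {r['estimate']:7.2f} "
          f"+- {r['se']:.2f}   p_adj = {r['p_adj']:.4g}")
print("\nA significant negative contrast in the last period means autumn--")
print("style advancement; note the estimate is attenuated because the")
print("spatial autocovariate, built from neighbouring cells' medians,")
print("absorbs part of a belt-wide shift (see docs/methods.md).")
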