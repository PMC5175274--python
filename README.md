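# coralclim

Statistically downscaled SST projections of the onset of **annual
severe coral bleaching (ASB)**.

Reef managers need to know *when* recurrent severe bleaching arrives at
the scale reefs are managed on (kilometres), but climate models project
SST on ~1° grids. `coralclim` implements the standard statistical
downscaling + thermal-stress pipeline that bridges the two:

1. **Downscale** each coarse model's monthly SST (2006–2099) onto a
   fine observed-climatology grid: fill land-masked cells zonally,
   regrid bilinearly, substitute the model's annual cycle with the
   observed one, and pin the 2006–2011 mean to the observed mean —
   preserving the model's projected anomalies exactly.
2. **Accumulate stress**: degree heating months above the maximum
   monthly mean (MMM), summed over every sliding 3-month window,
   converted to degree heating weeks (DHW = DHM × 4.35), reduced to an
   annual maximum per pixel.
3. **Detect onset**: the first year starting a 10-year run with annual
   stress > 8 DHW every year. One DHW is 1 °C above the bleaching
   threshold for one week; 8 DHW (e.g. +2 °C for four weeks) is
   severe-bleaching stress.
4. **Aggregate**: equal-weight multi-model ensemble mean/SD of onset
   years, relative winner/loser classification (onset after 2053 /
   before 2034), per-region summaries, within-coarse-cell onset
   ranges, and RCP4.5 − RCP8.5 scenario deltas.

Everything runs on synthetic worlds generated by the package itself
(`coralclim.synth`), with model bias, annual-cycle phase distortion,
land masks, scenario warming trends and noise — so the whole pipeline
is testable end to end against brute-force oracles without any data
downloads. Real NetCDF inputs with the same layout work identically.

## Worked example

Run the full pipeline on the default synthetic world (4×4 coarse cells
refined to 24×24 four-km-class pixels, three pseudo-models, RCP8.5- and
RCP4.5-like trends, 0.2 °C noise):

```sh
coralclim --log-level WARNING run-all --seed 42 --out-dir runs/demo
```

```
{
  "out_dir": "runs/demo",
  "config_hash": "adea5a8e9851484638f9c4897a1d9cf3531a4f38cd51d1200fa906ad8b8306a5"
}
```

The run writes the climatology, per-model onset maps, per-scenario
ensembles, region summaries and the scenario delta. The region summary
(`runs/demo/region_summary_rcp85.csv`) contains, per region: reef-pixel
counts, ensemble onset statistics and winner/loser percentages:

```
region,n_pixels,n_censored,mean_onset,sd_onset,min_onset,max_onset,range_years,pct_losers,pct_average,pct_winners
region_A,192,0,2032.76,1.68,2028.0,2039.67,11.67,86.98,13.02,0.0
region_B,192,0,2034.14,1.92,2030.0,2039.33,9.33,51.04,48.96,0.0
region_C,192,0,2037.19,2.13,2031.67,2042.0,10.33,3.65,96.35,0.0
```

(values rounded here; the CSV holds full precision). Region A reaches
annual severe bleaching around 2033 on ensemble average with an
11.7-year spread between its earliest and latest pixels — exactly the
kind of within-jurisdiction contrast the fine-scale projections exist
to reveal. Comparing scenarios:

```sh
coralclim compare --rcp45 runs/demo/ensemble_rcp45.nc \
                  --rcp85 runs/demo/ensemble_rcp85.nc --out runs/demo/delta.nc
# wrote delta map to runs/demo/delta.nc (mean delta over defined pixels: 19.65 years)
```

i.e. under this world's mitigation-like trend reefs gain ~20 years on
average before ASB. Stages can equally be run one at a time
(`synth`, `climatology`, `downscale`, `stress`, `onset`, `ensemble`,
`summarize`, `compare`), or from Python:

```python
import coralclim as cc

params = cc.default_params()
cfg, coarse, fine = cc.default_world(seed=42)
obs = cc.synth_observed_sst(cfg, fine, params.clim_window)
clim = cc.compute_monthly_climatology(obs)
raw = cc.synth_model_sst(cfg, coarse, "rcp85", params.projection_window, "m0")
down = cc.downscale_model(raw, clim)
onset = cc.detect_onset(cc.annual_stress(down, clim["mmm"], params))
```

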