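# Methods

## The problem

Coral reefs bleach when sea surface temperature (SST) stays above the
locally accustomed summer maximum for long enough. Climate-model SST
projections exist only on ~1° grids, far coarser than the scale at which
reefs are managed. `coralclim` implements the standard statistical
recipe for bridging that gap: adjust each coarse model series to a fine
observed climatology, accumulate degree-heating stress above the local
bleaching threshold, and report, per fine pixel, the first year from
which severe stress recurs *every* year — the onset of annual severe
bleaching (ASB).

## Model and procedure

**Climatology.** From a fine-grid monthly SST record over 1982–2008 we
form the twelve per-calendar-month means. Their maximum is the maximum
monthly mean (MMM), the bleaching threshold baseline; their average is
the pixel's overall mean. Pixels missing an entire calendar month are
flagged and excluded rather than gap-filled, since a silently
interpolated warm month would distort the MMM.

**Downscaling.** Each coarse model series (2006–2099 monthly SST) is
adjusted in four steps:

1. *Zonal fill* — land-masked coarse cells are filled along each
   latitude row, linearly between valid neighbours and with the nearest
   valid value beyond the row ends (rows that wrap the globe
   interpolate across the antimeridian instead).
2. *Bilinear regridding* to the fine-grid cell centers; fine points
   outside the coarse hull take the nearest edge value.
3. *Annual-cycle substitution* — the model's own per-calendar-month
   means over a reference window (the 2006–2011 baseline by default)
   are replaced with the observed climatological cycle. Deviations
   from the model's own cycle — its projected anomalies — are
   preserved exactly.
4. *Baseline recentering* — one constant per pixel pins the 2006–2011
   mean to the climatology's overall mean.

Because the cycle reference equals the baseline window, steps 3–4 make
both baseline contracts (mean and monthly cycle equal the observations)
hold to floating-point precision, even for noisy inputs. A consequence
worth stating explicitly: the method removes the per-calendar-month
baseline mean of whatever anomaly the model carries, so a linear trend
`t·(y − 2006)` enters the downscaled series as `t·(y − 2006) − 2.5·t`
(2.5 is the mean of the six baseline year offsets). The brute-force
oracle used for verification reproduces this centering; an uncentered
variant is kept for closed-form arithmetic checks.

**Thermal stress.** Monthly hotspots `max(0, SST − MMM)` are summed
over every sliding window of 3 consecutive months (degree heating
months), converted to degree heating weeks by the weeks-per-month
factor 4.35, assigned to the calendar year of the window's final month
(stress is realized at the end of accumulation), and reduced to an
annual maximum. Only positive anomalies accumulate — cool months do
not offset heat — following the satellite DHW methodology.

**Onset detection.** ASB onset is the first year `y` such that the
annual maximum strictly exceeds 8 DHW in every year of `[y, y+9]` and
the full decade fits inside the projection window (latest admissible
onset 2090). Pixels with no such run are censored. 8 DHW corresponds
to e.g. +2 °C above the threshold sustained for four weeks, a stress
level at which severe bleaching is expected.

**Ensembles and summaries.** Per-model onset maps are averaged with
equal weights (mean, not median); model agreement is the sample
standard deviation (n−1), reported as 0 when a single model
contributes. A pixel is censored in the ensemble when fewer than half
the models project an onset — the literature does not fix this rule,
so it is exposed as `min_fraction`. Summaries follow: winner/loser
classification (onset before 2034 = relative loser, after 2053 =
relative winner, between = average; real-valued ensemble years are
compared directly to the integer cutoffs, so 2033.9 is a loser),
per-region statistics over non-censored reef pixels, the within-coarse
-cell onset range (latest minus earliest fine onset; the local-scale
variation diagnostic), and the scenario delta (mitigation-scenario
onset minus high-emissions onset, defined on the intersection of
non-censored pixels).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `clim_window` | 1982–2008 | years | observed climatology |
| `baseline_window` | 2006–2011 | years | mean pinned to climatology |
| `projection_window` | 2006–2099 | years | projection horizon |
| `dhw_threshold` | 8.0 | DHW | strict exceedance level |
| `dhm_to_dhw_factor` | 4.35 | weeks/month | DHM → DHW |
| `window_months` | 3 | months | sliding accumulation window |
| `run_length` | 10 | years | consecutive years defining ASB |
| `loser_cutoff` / `winner_cutoff` | 2034 / 2053 | year | classification band |

All are overridable through YAML for sensitivity runs; the defaults are
the method's standard values. Whether the paper trail supports "before
2033" or "before 2034" for the loser band is ambiguous in the
literature; we adopt the band consistent with "2043 ± 10 years"
(2034–2053 inclusive) and keep the cutoffs configurable.

## The synthetic world

Real inputs (CMIP5 SST, a Pathfinder-class 4-km climatology, reef
locations) are large downloads; the generator fabricates structurally
equivalent inputs from a known fine-scale truth so every stage is
testable against construction:

- **fine truth**: per-pixel base temperature (~27 °C, varying smoothly
  both across and *within* coarse cells), annual cycle amplitude
  (1–3 °C by default), and peak month (February south of the equator,
  August north);
- **pseudo-models**: the area mean of the fine cycle per coarse cell,
  plus a model mean bias (±1.5 °C range), a whole-month phase shift of
  the cycle, a scenario trend (defaults 0.032 °C/yr RCP8.5-like and
  0.019 °C/yr RCP4.5-like, the tropical-SST warming rates of those
  pathways), i.i.d. Gaussian noise (0.2 °C), and a land mask;
- **trend modes**: `annual-step` (constant within a year; makes
  closed-form onset arithmetic exact and is the default) and
  `monthly-continuous`.

What the generator does *not* emulate: ENSO-like interannual
variability, spatially correlated noise, eddies, upwelling, or shifts
in currents. Passing tests therefore demonstrate the correctness of
the downscaling/stress/onset algebra, not skill against dynamical
downscaling or observed bleaching.

`oracle_onset` is the independent check: plain-loop evaluation of the
stress and run definitions for a noise-free linear-warming world. On
such worlds the full pipeline (including zonal fill, regridding, bias
and phase-shift removal) must agree with it at 100 % of pixels, and
does.

## Numerical choices

- Exceedance is strict (`> 8 DHW`); a year at exactly 8.0 breaks a run.
- Windows are assigned to the year of their final month; a
  Dec–Jan–Feb window counts toward the February year.
- Zonal fill end-handling is nearest-value; interior is linear in the
  longitude coordinate. Grids spanning 360° are treated as periodic
  automatically.
- Bilinear regridding is two sequential 1-D linear interpolations on
  cell-center coordinates (identical to the textbook tensor-product
  formula, verified to 1e-12); degenerate single-row/column coarse
  grids broadcast instead of interpolating.
- Sample standard deviation (n−1) throughout; per-region percentages
  are over non-censored pixels only and sum to 100.
- All randomness flows from one integer seed through independent named
  substreams, so outputs are byte-identical across reruns and
  independent of model execution order.

## Problem sizes

The test-suite and acceptance worlds use coarse grids of 1–4 cells per
side at 1–1.5° refined 2–6×, i.e. up to 24×24 fine pixels over the
full 1128-month horizon — small enough to verify every contract in
seconds while exercising every code path (land mask, phase shifts,
multi-model ensembles, two scenarios). The pipeline is pure
numpy/xarray and scales linearly in pixels; nothing in the
implementation assumes these sizes.

## Known limitations

- Monthly inputs only; no daily DHW, no day-weighting within months.
- No hindcast validation against observed bleaching events is included
  (the synthetic world has no observed bleaching to validate against).
- The 1982–2008 climatology era is cooler than the 2006–2011 baseline
  it anchors, which biases projections slightly late ("optimistic");
  like the underlying method, we do not correct for this.
- Region labels are an input (reef-table column); no polygon/EEZ
  geometry is computed.
- No model weighting, skill selection, or hypothetical coral
  adaptation rates.
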