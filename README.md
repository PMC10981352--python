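# cpforage

Movement analysis for GPS-tracked **central-place foraging birds** in
agricultural landscapes — built for studies of sedentary, nest-attached
species (corvids, gulls, starlings) whose foraging shifts with the crop
calendar and whose crop use matters for wildlife–farmer conflict.

Given 5-minute GPS fixes recorded between sunrise and sunset, a nest table,
a categorical habitat raster (grassland / cereal / maize / other
agricultural / non-agricultural) and a biological-period calendar, the
package quantifies, per *tracking day* (one bird × one date):

1. **Behavioral segmentation** — a 3-state hidden Markov model on smoothed
   speed (gamma emissions) and turning angle (von Mises emissions)
   separates stationary activity, short-distance movement (active walk) and
   long-distance movement (flight); a fix decoded as stationary/walk on
   agricultural land is a *foraging occasion*.
2. **Daily occurrence distributions** — biased-random-bridge (BRB)
   utilization distributions per day, their 95 % isopleths, and four
   descriptors: area (km²), mean within-period overlap (%), nest–centroid
   distance (km), nest–farthest-limit distance (km).
3. **Mixed-model inference** — random-intercept (G)LMMs (gamma-log,
   binomial-logit, gaussian) fitted by maximum likelihood with adaptive
   Gauss–Hermite quadrature, with Wald χ² tests, Tukey-adjusted pairwise
   period contrasts (compact letter displays), and marginal/conditional
   pseudo-R².
4. **Habitat selection functions (HSF)** — weighted used–available logistic
   mixed models per biological period (10 availability points per used fix
   drawn in the day's nest-centered circle, weights 1000:1, fixed-large-
   variance tracking-day intercepts, grassland reference), reported as
   relative selection strengths (RSS), plus day-stratified k-fold
   cross-validation (Spearman rank of bin-wise used frequency).

Because real tracking data of this kind are rarely shareable, the package
ships a first-class **synthetic study generator**: seeded-region (Voronoi)
crop mosaics, central-place movement with state-switching speeds and
habitat-weighted foraging-bout placement, sunrise–sunset fix schedules,
and fix dropout — with every generative parameter recorded, so each
analysis stage is verifiable by parameter recovery.

## Worked example

```python
import cpforage as cf
from cpforage.pipeline import PipelineConfig, run_pipeline

scenario = cf.SyntheticScenario(
    n_birds=3, n_repeat_birds=0, extent_m=4000.0, n_patches=1200,
    days_per_bird_per_period={"incubation": 4.0, "post_fledging": 4.0},
    participation={"incubation": 1.0, "post_fledging": 1.0}, seed=5)
config = PipelineConfig(scenario=scenario, output_dir="demo_run",
                        hmm_n_starts=3, hmm_max_fit_steps=4000,
                        master_seed=7)
result = run_pipeline(config)

print(result.hmm_fit.params.gamma_mean.round(1))
print(result.descriptors[["area_km2", "centroid_nest_km"]].mean().round(2))
for period, fit in result.hsf_fits.items():
    print(period, {h: round(v, 2) for h, v in fit.rss.items()})
```

Output from this exact configuration:

```
[ 2.5  9.4 64.9]
area_km2            1.12
centroid_nest_km    0.42
incubation {'cereal': 0.4, 'maize': 1.23, 'other_agri': 0.1}
post_fledging {'cereal': 3.91, 'maize': 0.49, 'other_agri': 0.38}
```

Reading the numbers: the three fitted state mean speeds (m/min) order as
stationary < walk < flight; daily occurrence areas average ≈1 km² with
centroids ≈0.4 km from the nest — the tight, nest-anchored ranging typical
of a sedentary central-place forager. The RSS values are intensities of
use relative to grassland under equal availability: this small scenario's
generator prefers maize during incubation (true RSS 1.1; estimated 1.23,
on par with grassland) and cereal after fledging (true 1.8; estimated 3.9
at only ~12 tracking days), while the avoided habitats stay well below 1.
The 22-day demo is deliberately tiny; the recovery tests in
`tests/test_acceptance.py` quantify estimation error at full study scale.

The same pipeline runs from the command line:

```bash
cpforage simulate --seed 3 --out study/          # synthetic study files
cpforage run --config config.json                # full analysis
cpforage report --results out_dir/               # rendered summary
```

Per-day outputs land in the run directory as CSV (descriptors, daily use,
durations, RSS tables), JSON (model summaries, manifest with all seeds and
parameters) and a Markdown report with compact letter displays.

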