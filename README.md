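# ethotree

Behavioral classification of **low-frequency (1 Hz) biologger data** —
tri-axial acceleration plus collar temperature — with a calibratable,
hierarchical threshold decision tree.

Small animals cannot carry the batteries that high-rate accelerometry
demands, so multi-month deployments must sample slowly; at 1 Hz the usual
spectral features are gone and classification has to come from windowed
amplitude statistics and from temperature, which rises sharply when the
animal is inside an insulated nest.  `ethotree` is for movement
ecologists and biologgers who want a per-second behavioral record
(ethogram) out of such recordings, with every decision constant
calibratable from their own observation data and every step inspectable —
the opposite of a black box.

## The method

Each second of a deployment descends a fixed tree, each split evaluated
on non-overlapping sample windows matched to the natural duration of the
behavior it separates:

1. **in nest / out of nest** — per noon-to-noon day, an exact 1-D
   2-means on smoothed collar temperature gives a daily threshold
   (midpoint of cluster centers); in-nest bouts dominated by movement
   (moving : not-moving strictly above 1) are flipped back out.
2. **moving / not moving** — ΔDBA over 14-s windows, where
   ΔDBA = Σᵢ (|Δd_xᵢ| + |Δd_yᵢ| + |Δd_zᵢ|) on the dynamic (gravity-
   removed) acceleration; threshold = 99.9% quantile of ΔDBA from
   motionless devices (published field value 1.06 g).
3. **feeding / traveling** — ODBA (Σ |dynamic| across axes) over 10-s
   windows; high ODBA ⇒ traveling (field value 6.2 g).
4. **foraging / running** — maximum dynamic surge over 4-s windows;
   high peaks ⇒ running (field value 1.15 g).

The output nests exactly into 2-, 4-, 5- and 6-behavior ethograms, so the
tree can be clipped at whatever detail a question needs.  Around the
classifier the package ships: threshold calibration from observation logs
(purity-rule window selection + balanced-accuracy scans), a random-forest
window-length benchmark, observation-clock alignment by matching abrupt
activity transitions, accuracy evaluation by repeated stratified
subsampling plus night-nest and low-resolution checks, daily time
budgets, and a synthetic collar-trace simulator with exact ground truth.
See `docs/methods.md` for the full model description.

## Worked example

```python
import dataclasses, warnings
from ethotree import generate_trace, scenario_library, classify_hierarchical
from ethotree.evaluation import daily_time_budget, budgets_to_frame

warnings.simplefilter("ignore")
cfg = dataclasses.replace(scenario_library()["field_like"], duration_days=2.0)
trace, truth, obs = generate_trace(cfg, seed=42)   # 2 days @ 1 Hz, known truth
pred = classify_hierarchical(trace, level=6)        # the full tree

acc = (pred.labels == truth.labels).mean()
print(f"per-second level-6 accuracy vs ground truth: {100*acc:.1f}%")
budget = budgets_to_frame(daily_time_budget(pred, trace.seconds_of_day()))
for c in ("in_nest_not_moving", "feeding", "foraging", "running"):
    print(f"  {c:<20s} {100*budget[c].mean():5.1f}% of the day")
```

prints

```
per-second level-6 accuracy vs ground truth: 81.9%
  in_nest_not_moving    48.7% of the day
  feeding               14.7% of the day
  foraging              15.0% of the day
  running                4.4% of the day
```

The `field_like` preset deliberately overlaps the behavior signatures, so
~82% at the finest (6-behavior) level is the intermediate regime a real
field calibration sees; the `separable` preset, where emissions and bout
durations are well separated, classifies at ≈98% and is the
correctness check.  The time budget is recovered within a couple of
percentage points of the generator's configured schedule.

The same pipeline from a shell:

```bash
ethotree simulate --preset field_like --days 2 --seed 42 --out sim/
ethotree classify --input sim/trace.csv --level 6 --out labels.csv
ethotree align    --obs sim/obs.csv --trace sim/trace.csv --out obs_aligned.csv
ethotree evaluate --pred labels.csv --obs obs_aligned.csv --level 5 --reps 100 --n 50 --seed 7
ethotree budget   --pred labels.csv --out budgets.csv
ethotree calibrate --obs obs_aligned.csv --trace sim/trace.csv --out thresholds.yaml --report calib/
```

For real logger exports, pass a `column_map` (YAML) naming the file's
time/x/y/z/temperature columns, and an `ethogram_map` to collapse raw
scoring codes (caching, clipping cones, digging, slow travel, grooming,
vocalizing, …) onto the classification categories.

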