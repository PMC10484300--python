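# headcast

Harvest-date prediction for field broccoli from drone-style individual-plant
phenotyping — built and validated entirely on a synthetic field with known
ground truth.

On-farm food loss in broccoli is dominated by grade-outs: heads outside the
sellable size window (in the Japanese market, below 11 cm or above 14 cm)
at the single mechanical harvest pass. Because heads grow several
millimetres per day near harvest, missing the optimal date by one or two
days sharply increases the grade-out fraction. `headcast` implements the
full desk-side analysis chain that turns per-plant drone measurements into
an income-optimal harvest date:

1. **Synthetic field generator** — a ridged layout (rows 70 cm apart,
   plants at 35 cm), per-plant growth trajectories with individual
   variation in head-induction timing, drone observations with occlusion
   bias and noise, head-outline polygons, and seedling detections
   duplicated across buffered image sectors. It stands in for the
   photogrammetry + deep-learning front end and provides ground truth for
   every downstream stage.
2. **Field geometry** — sector tiling with right/bottom buffers, greedy
   non-maximum suppression of cross-sector duplicates, pixel↔geographic
   homographies, ridge detection from the east–west position histogram,
   and north-to-south / west-to-east plant-ID assignment.
3. **Head morphometry** — head diameter (HD) as the longer side of the
   minimum-area rotated bounding rectangle of each outline; grid-cell
   dedup filtering (bottom/right-edge rule); Mid IoU; r² / RMSE agreement
   metrics.
4. **Growth model** — the thermal-time curve

   $$\ln \mathrm{HD} = a - b\,e^{-cT}$$

   with HD in mm and $T$ the sum of daily mean temperatures clipped to
   [0, 20] °C. An *initialization* model is fit to manual field
   measurements aligned at the 3–3.5 cm startup size; inverting it at each
   plant's first-flight HD ($T_0 = -\tfrac1c \ln\frac{a - \ln HD}{b}$)
   anchors the drone series, and the pooled re-fit gives the *prediction*
   model for the harvest window. Cross-season swap validation is included.
5. **Harvest economics** — per-date grading (M 11–12, L 12–13, 2L 13+ cm,
   sellable envelope 11–14 cm), income under configurable price cases
   (L fixed at $1.00), optimal-date selection, and the deviation-loss
   curve.

## Worked example

Either run the numbered analysis scripts (bulky run artifacts go to
`scratch/`, summary tables to `results/analysis/`):

```bash
python analysis/01_simulate_field.py --seed 7
python analysis/02_detect_positions.py
python analysis/03_measure_heads.py
python analysis/04_fit_growth_models.py
python analysis/05_optimize_harvest.py
python analysis/06_swap_validation.py
```

or the equivalent CLI: `headcast run-all --seed 7 --out headcast_run`.

With seed 7, the 740-plant season prints:

```
906 raw detections -> 740 merged positions (166 buffer duplicates suppressed)
ridges found: 10; true plant count: 740; match: True
```

so NMS recovers every plant exactly once despite the sector-buffer
duplicates. Morphometry then reports per-flight drone-vs-field agreement
(`r2=0.87 ... 0.77`, RMSE 6.4–8.8 mm — the occlusion factor β = 0.95 plus
5 mm noise), and the model fits recover the generating curve:

```
ground truth        : a=5.530 b=2.050 c=0.00546
initialization model: a=5.529 b=2.051 c=0.00548 (startup HD 3.24 cm)
prediction model    : a=5.477 b=1.974 c=0.00555
```

(The prediction model's slightly lower `a` is the drone occlusion bias —
it is fit to drone-scale diameters, as in operation.) Finally:

```
case1: optimal harvest date 2020-05-22
  2020-05-22  income $  559.60  grade-out  25.7% <-- optimum
  -1 day(s) from optimum: 23.1% income loss
  +1 day(s) from optimum: 8.2% income loss
  +2 day(s) from optimum: 35.4% income loss
```

The income curve is unimodal and both price cases pick the same date: the
optimum is set by the spatial size variation of the cohort, not by the
prices. The swap-validation script simulates a second, warmer season with
split transplanting (8-day stagger), predicts it with the first season's
model, and shows the early-window correlations holding (r² ≈ 0.95) while
the late, past-market-size window degrades (r² ≈ 0.89 and falling).

## Layout

```
src/headcast/        library: synthetic_field, field_geometry,
                     head_morphometry, growth_model, harvest_economics,
                     config, pipeline, cli
analysis/            numbered narrative drivers over the pipeline stages
scripts/acceptance.py
tests/               pytest suite (unit, property, acceptance)
docs/methods.md      model and design notes
```
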