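# Methods

## The growth model

Head diameter (HD, millimetres) of an individual broccoli is modelled as a
Gompertz-type curve in thermal time,

    ln HD = a − b·exp(−c·T),

where T (°C·day) is the accumulated daily mean air temperature with each
day clipped to the effective range [0, 20] °C — below 0 °C growth stalls,
above 20 °C it saturates. The parameters are field- and season-specific:
`exp(a)` is the asymptotic head diameter (mm), `exp(a − b)` the diameter at
T = 0 (chosen to be the ~3–3.5 cm size at which a head first becomes
measurable), and `c` (per °C·day) the thermal growth rate. The model is
deliberately single-phase: juvenile and induction phases are outside its
window, which starts at head appearance. Individual variation is carried
entirely by a per-plant location shift δT₀ on the T axis — plants that
induce heads earlier are simply further along the shared curve.

Two regressions are fit, both by nonlinear least squares on the ln-scale
residual (`scipy.optimize.least_squares`, initial guess
a₀ = max(ln HD) + 0.3, b₀ = a₀ − min(ln HD), c₀ = 0.005, positive-parameter
bounds, tolerances 1e−14; the fit is order-invariant and recovers exact
data to ~1e−8):

1. **Initialization model** — from manual field measurements. Each plant's
   T = 0 origin is the first measurement date on which its HD lies in the
   startup band [30, 35] mm; its subsequent (clipped temperature sum from
   that origin, HD) pairs are pooled across plants. Plants that skip the
   band between two measurement visits are excluded and counted. Pooling
   (rather than per-plant curves) is the default because the startup
   alignment already removes the main between-plant variation.
2. **Prediction model** — from drone measurements. The initialization
   model is inverted in closed form, T = −(1/c)·ln((a − ln HD)/b), at each
   plant's first-flight HD, giving its T₀; later flights add clipped
   temperature-sum increments. The pooled anchored pairs are refit, and
   this second curve makes the forward harvest-window predictions. Plants
   whose first-flight HD is at or beyond `exp(a)` are excluded with a
   logged reason.

Because drone diameters carry the occlusion factor (below), the prediction
model lives on the *drone* HD scale; its forward predictions are graded
directly, as they would be in operation, without occlusion correction
(occlusion restoration is out of scope).

## The synthetic field

The generator emulates the data products of a drone phenotyping campaign
on a commercial-style planting — ridges 0.70 m apart, plants at 0.35 m,
position jitter sd 3 cm — without producing any imagery:

- **Trajectories**: true HD follows the curve above with per-plant
  δT₀ ~ Normal(0, 30 °C·day). The 30 °C·day default (≈ ±1.5 days of May
  growth) produces cohort size spreads of ±1–1.5 cm near harvest,
  comparable to the reported head-size spreads in split-transplant trials;
  the true inter-plant variance is otherwise unconstrained, so this is a
  modelling choice, not an estimate. A two-cohort mode shifts the eastern
  half of the field by a configurable number of days (default campaigns
  use 8) to emulate staggered transplanting.
- **Observations**: drone HD = β·true + Normal(0, 5 mm), truncated at 0,
  with occlusion factor β = 0.95 (leaf occlusion makes aerial measurement
  underestimate, never overestimate); manual field HD = true +
  Normal(0, 2 mm). These magnitudes reproduce drone-vs-field RMSEs of
  ~6–9 mm and r² ≈ 0.8–0.9 at harvest sizes.
- **Temperatures**: daily means = monthly means (Tokyo-like springs;
  e.g. March 10.5, April 12.8, May 19.6 °C for the 2020-style season) plus
  an AR(1) anomaly (ρ = 0.7, stationary sd 2 °C), at daily resolution.
- **Geometry**: each observation yields a regular 64-gon of circumdiameter
  equal to the drone HD with 2% radial vertex noise, centred on the plant,
  in a local planar east/north metric frame (no geodesy); each plant
  yields one seedling detection box (0.20 m footprint) in every sector
  whose buffered window contains it, so buffer-overlap plants are emitted
  two or more times by construction. Per-sector homographies map
  image-frame pixels (0-based, origin top-left, y down) to geographic
  coordinates at a 4 mm ground sampling distance.

What the generator does **not** emulate: photogrammetry error surfaces
(ghosting, seam distortion), detection/segmentation failures (every plant
is detected, every outline is a clean noisy polygon), weeds and soil
background, plant death, and heads whose occlusion pattern is asymmetric
rather than a uniform shrinkage. Passing tests therefore demonstrate that
the *analysis chain* is correct and well-calibrated under its stated noise
model — not that the upstream detection/segmentation models would reach
these accuracies on real imagery.

## Positional pipeline

Sector tiling uses half-open core windows that exactly partition the image
and a buffer (default 200 px) extending each core window on the right and
bottom only — an L-shaped overlap; with the cores partitioning the image
this already guarantees any object smaller than the buffer is whole in
some buffered window. Cross-sector duplicates are removed by greedy
score-descending NMS (IoU threshold 0.5, configurable). Box centres map
through the per-sector homography to geographic positions; ridge centres
are peaks of the 0.1 m-binned east–west position histogram separated by at
least 0.7 × the expected row spacing (peak centres refined as member
means); IDs are assigned 1..n by (ridge west→east, northing descending),
ties broken by easting. The manual position-correction step of an
operational campaign is replaced by an explicit override-file input.

## Morphometry

HD is the longer side of the minimum-area rotated rectangle of the convex
hull of the outline's vertex set (shapely's rotating-calipers
`minimum_rotated_rectangle`; the hull leaves the rectangle unchanged and
makes self-intersecting ragged outlines well-defined). A known degeneracy:
polygons with quadrilateral convex hulls can possess two exactly area-tied
rectangle orientations whose longer sides differ by >10%; for such inputs
"the" HD is whichever orientation the library returns. Real head outlines
(many-vertex, roughly convex) do not exhibit ties — verified against an
exhaustive 0.01° rotation search on 10³ random star-convex outlines.

Grid dedup filtering retains a polygon in a cell iff it overlaps the cell
with positive area and does not touch the cell's bottom (southern) or
right edge. The positive-area-overlap containment rule (rather than a
representative-point rule) is what makes retention exactly-once over a
full tiling: an edge-straddler is dropped where it touches bottom/right
and kept by the neighbour, where it touches only top/left.

Mid IoU clips both region sets to the grid cell before the area IoU
(defined as 1 when both are empty inside the cell); it can be computed
per cell and averaged, or pooled — both aggregations are available since
the reference aggregation is ambiguous.

## Harvest economics

Grades are half-open intervals in cm — M [11, 12), L [12, 13),
2L [13, 15) — behind a sellable envelope of [11, 14] checked first, so
14 cm sells as 2L and anything above 14 cm is a grade-out even though the
2L table bound reads 15; both bounds are configurable because the grade
table and the unsellable rule genuinely disagree at the top end. Prices
default to two cases bracketing large and small between-grade differences
(case 1: M 0.70 / L 1.00 / 2L 1.30; case 2: M 0.95 / L 1.00 / 2L 1.05;
L anchored at $1.00) — labelled stand-ins, fully config-driven, since the
surveyed vectors are not public. Income per date is Σ counts × price with
grade-outs at zero; the optimal date is the income argmax with ties broken
by the earliest date (less senescence risk). The deviation-loss curve
(income at each day offset, relative to the optimum) quantifies the cost
of missing the date.

A systematic note: because predictions are drone-scale (β = 0.95), the
pipeline's optimum can sit one day later than the optimum computed from
the true trajectories (≈ 5% of a 12 cm head ≈ 0.8 day of May growth).
This is the same bias an operational campaign would carry and is reported,
not corrected.

## Reproducibility and problem sizes

All randomness flows from one root seed, split per stage by spawning named
`SeedSequence` children, so identical resolved configs give byte-identical
outputs. The default analysis season uses 740 plants × 6 flights with 120
field-sampled plants (a desk-scale stand-in for a ~0.1–0.2 ha planting);
the end-to-end validation season uses 3 000 plants. Parameter-recovery
studies run 20 seeds at 90 / 360 / 1440 observations. Degenerate inputs
raise typed errors throughout (non-positive spacings, gapped temperature
series, under-determined fits, zero-area polygons, singular homographies,
out-of-domain inversions) rather than propagating NaNs.

## Known limitations

- Single-phase thermal-time model; no solar radiation or water covariates,
  no cross-variety generality — per-field, per-season calibration is the
  intended use.
- The occlusion model is a uniform multiplicative factor; real leaf
  occlusion is directional and size-dependent.
- The startup-band origin rule discards plants that cross the band between
  measurement visits (≈ half at 2-day cadence with May growth rates);
  denser early-season measurement reduces the loss.
- Ridge detection assumes ridges parallel to the north–south axis of the
  local frame; rotate the frame first for oblique plantings.
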