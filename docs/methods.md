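# Methods

## The experimental design

A central composite rotatable design in k = 3 coded factors: 8
factorial points (±1), 6 axial points at ±α with α = (2³)^{1/4} =
1.68179 (the rotatability condition: prediction variance depends only
on distance from the centre), and 6 centre replicates. Runs are split
into two fixed blocks as executed in the source study — factorial + 4
centres in block 1, axial + 2 centres in block 2 — because the two
halves were run in different weeks. Coding follows the standard
`(actual − centre)/half-range` convention; the published factor table's
±1.68179 ↔ actual extremes are consistent only with this convention,
which is how it was identified. Run order is a seeded uniform
permutation *within* each block: blocks are executed sequentially, so
randomization across blocks is not physically meaningful. An
orthogonal-blocking α is available but off by default (the study used
the rotatable value; with this centre allocation the two differ
slightly, so blocking is only near-orthogonal).

## Model fitting and ANOVA

The full quadratic model is fitted by ordinary least squares with the
block as a fixed effect in +1/−1 (sum-to-zero) coding. The reported
coded equation excludes the block column, so `predict` is
block-averaged; fitted values and residuals retain the block offsets
and reproduce the observations exactly. Model hierarchy is enforced
structurally (a square or interaction term requires its parent linear
terms) and non-significant parents are never dropped.

The ANOVA decomposes the corrected total SS as block (sequential,
fitted right after the mean) + model (the further RSS drop from adding
all polynomial terms) + residual, which makes the three-way additivity
exact even under non-orthogonal blocking. Per-term SS are partial
(Type III) — the RSS increase from deleting that one column — the
appropriate choice on a design that is only near-orthogonal. Model and
term F-ratios test against the residual mean square. The residual is
split into pure error (within-group SS over replicated coded settings)
and lack of fit; the default pools replicate groups **within** block,
because the two blocks' centre responses differ systematically in the
study data, and an `across_blocks` policy flag exists for the other
hypothesis. R² is SS_model/(SS_model + SS_resid) with block excluded,
and adequate precision is `(max ŷ − min ŷ over the design) /
sqrt(p·MSE/n)` with p counting all fitted parameters; both follow the
conventions of standard DOE software so results are comparable with
published tables. P-values carry no multiplicity adjustment, matching
standard ANOVA reporting practice.

### Known discrepancies in the published tables

Kept verbatim and documented rather than repaired, since no unique
repair exists:

- The run sheet labels one run "3" twice and none "2"; rows are treated
  positionally.
- The six printed centre responses give a within-block pure-error SS of
  ≈3.09 (4 df), not the 12.31 the published ANOVA lists; refitting the
  printed runs likewise gives a temperature coefficient ≈2.47 rather
  than the published 2.02. Both point to transcription noise in the run
  sheet, so exact-match tests target printed-*arithmetic* identities
  (F ratios and R² recomputed from the printed sums of squares, the
  printed equation's predictions) instead of a re-fit.
- The published model F of 4.74 is inconsistent with its own mean
  squares (33.32/5.81 = 5.74, which matches the printed p = 0.0079); we
  do not chase it.
- One quantity *was* repaired: the HPLC table's first peak height
  (printed 1196) is restored to 11196, because the printed percent
  column and printed total are only consistent with the restored value
  (see `datasets.hplc_peaks`).

## Optimization

Desirability follows Derringer & Suich: one-sided linear ramps with a
weight exponent for maximize/minimize, a tent for target goals. Ramp
limits default to the observed response range; the original analysis
reported a desirability of 0.61 at the optimum, but the limit settings
behind it are unrecoverable (with observed-range limits the optimum
saturates at 1), so limits are fully configurable and no particular
value is asserted. The search region defaults to the factorial cube
[−1, 1]³ — the reported optimum is a cube vertex, implying
factorial-range constraints — with the axial sphere available.

The optimizer runs bound-constrained local refinement (L-BFGS-B on the
cube, SLSQP on the sphere) from 32 seeded interior starts plus every
cube vertex and the centre, and also scores the raw start points, so it
can never return less than plain evaluation. For monotone goals it
optimizes the raw predicted response rather than the ramp — the same
argmax under a non-decreasing transform, without the flat plateau a
saturated ramp creates — and reports the desirability at the optimum.
Ties within 1e-9 break toward lexicographically smallest coded
coordinates. A brute-force grid maximizer (`grid_maximum`) serves as an
independent check.

## Quantification

`content = (signal − intercept)/slope · volume · dilution / mass`, with
mass/volume/dilution explicit per call because published contents mix
bases (mg GAE/g DW vs mg QE/100 g); no unit conversion is guessed.
Negative back-calculated concentrations clamp to zero with a warning.
Marker peaks are matched to a fingerprint by a ±2% relative
retention-time window.

## Bioassay statistics

All tests run from (n, mean, SEM) because animal studies publish only
summaries; SD = SEM·√n. Welch's ANOVA uses the standard n/s² weights
and Welch–Satterthwaite df; Games-Howell uses per-pair
`se² = s₁²/n₁ + s₂²/n₂`, Welch–Satterthwaite df, and
`q = |diff|·√2/se` referred to the studentized-range distribution with
k groups (family-wise by construction; no further correction). Raw-data
entry points exist for synthetic per-animal tables, including Levene's
test, which has no summary-only form.

The 4PL curve is `y = bottom + (top − bottom)/(1 + (dose/EC50)^hill)`,
fitted by seeded multi-start Levenberg–Marquardt with EC50 searched in
log space; any parameter can be pinned, and an under-determined request
(more free parameters than distinct doses) raises an instructive error.
The glucose EC50 pipeline fits percent reduction in fasting plasma
glucose against dose for the extract groups only, pinning bottom = 0
and a unit-slope *rising* curve (hill = −1 in this parameterization,
i.e. the Emax model `y = top·d/(d + EC50)`); a falling unit-slope curve
cannot describe a response that grows with dose. With only two active
doses the fit interpolates exactly and the EC50 (~110 mg/kg here) is
entirely determined by the constraint choice — it is reported as
method-dependent, and no published potency is asserted.

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`:

- **CCRD responses**: quadratic surface + per-block offset + iid
  Gaussian noise. Defaults are the study conditions: the published
  coded equation as truth and noise SD √5.81 (the published residual
  mean square), no block offset — block offsets are exposed so the
  week-effect hypothesis is testable.
- **Single-factor screens**: piecewise concave parabola through the
  peak, floored at 0 — unimodal by construction, anchored at the
  published peaks (17.4 mg GAE/g at 70 °C, 18 at 2 h, 17.7 at 2.5%),
  with fall rates chosen to hit the published range minima (2.1 at
  90 °C, 0.9 at 5 h).
- **Animal trial**: each group × day cell is n iid Normal(mean,
  SEM·√n) draws (n = 6 by default), independent across days; draws
  below 0 truncate with a warning since glucose and weight cannot be
  negative.
- **Calibration standards**: a line plus noise over five standards at
  10–200 µg/mL, a typical Folin-Ciocalteu working range (the study did
  not print its standard levels).

What the generators do **not** emulate: within-animal correlation
across days (cells are independent, so longitudinal structure is
absent), non-Gaussian response noise, drift within a block, and HPLC
chromatogram traces (integrated peak tables are consumed directly).
Passing tests therefore validate the *statistical machinery* under the
study's stated first-order assumptions, not the robustness of the
original data to those assumptions.

## Problem sizes and numerical choices

Monte-Carlo checks use 500 replications for refit-bias and pure-error
calibration, 200 for noise-scaling and EC50 recovery, and 100 for
end-to-end optimum recovery — enough for 2-standard-error assertions on
a 20-run design while keeping the full suite around two minutes.
Grid oracles use 201 points per axis (checks against the optimizer are
at 1e-6, far above the grid's own resolution error only because the
optima at stake sit on vertices or are polished locally). Replicate
groups for pure error match coded settings after rounding to 8
decimals. Degenerate inputs (zero denominator mean squares, zero-slope
calibrations, zero total peak area, under-determined 4PL fits) raise
typed errors or flags rather than returning NaN silently.
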