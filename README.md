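# phytorsm

Response-surface optimization of phytochemical extraction, with
calibration-curve quantification and in-vivo bioassay statistics.

`phytorsm` implements the complete desk analysis behind a common study
design in natural-products research: find the extraction conditions
(time, temperature, solid-to-solvent ratio) that maximize the yield of
total polyphenols from a plant material — here aqueous extraction from
okra (*Abelmoschus esculentus*) fruits — then standardize the extract
and test its glucose-lowering activity in a rodent model. The package
covers:

- **Design of experiments** — blocked central composite rotatable
  designs (CCRD): `2^k` factorial points, `2k` axial points at coded
  distance `α = (2^k)^{1/4}` (1.68179 for k = 3), replicated centre
  points, seeded within-block run randomization, and coded/actual unit
  conversion `x = (actual − centre)/half-range`.
- **Response-surface fitting** — the coded second-order model
  `y = β₀ + Σβⱼxⱼ + Σβⱼⱼxⱼ² + Σβᵢⱼxᵢxⱼ` with a sum-to-zero block
  effect, full ANOVA (block fitted first, partial per-term SS,
  lack-of-fit vs pure error), and adequacy statistics (R², adjusted R²,
  CV%, adequate precision).
- **Optimization** — Derringer–Suich desirability transforms and
  seeded multi-start maximization over the factorial cube or the axial
  sphere.
- **Quantification** — calibration lines for spectrophotometric
  assays (mg gallic-acid equivalents / g dry weight and analogues) and
  HPLC peak-table percent-area/height summaries.
- **Bioassay statistics** — Welch's heteroscedastic ANOVA and
  Games-Howell pairwise comparisons computed directly from published
  (n, mean, SEM) summaries, baseline-change summaries, and constrained
  four-parameter-logistic EC50 fits.
- **Synthetic data** — seeded generators for every measured input
  (CCRD responses, single-factor yield screens, per-animal glucose and
  weight trajectories, calibration standards), so the whole pipeline is
  testable end to end.

The published study tables (factor levels, the 20-run sheet, the
reference ANOVA, HPLC peaks, and group summaries) ship as programmatic
fixtures in `phytorsm.datasets`.

## Worked example

```python
import phytorsm as pr

factors = pr.datasets.extraction_factors()
model = pr.model_from_coefficients(
    pr.datasets.fitted_tpc_coefficients(), 3, tuple(factors))
data = pr.datasets.tpc_response_data()

result = pr.optimize_model(
    model, region="factorial_cube",
    goal=pr.goal_from_observed(data.response), seed=0)
print(result.argmax_coded, result.argmax_actual)
print(round(result.predicted_response, 3))
```

prints

```
(-1.0, 1.0, 1.0) (1.0, 70.0, 5.0)
22.166
```

— the fitted surface is maximized at the cube vertex decoding to an
extraction time of 1 h, temperature 70 °C and a 5% w/v solid-to-solvent
ratio, with a predicted yield of 22.17 mg GAE/g DW. The
`examples/` directory has one short script per capability (design
construction, fitting and ANOVA, optimization, quantification, bioassay
statistics, and simulate-and-recover).

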