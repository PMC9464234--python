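# pollenrecon

Quantitative reconstruction of Holocene seasonal temperatures from
fossil pollen, as a tested, end-to-end Python pipeline.

Fossil pollen assemblages record past vegetation, and vegetation is
constrained by both winter and summer temperature — cold tolerance and
chilling requirements matter as much as growing-season warmth.  This
package implements the workflow used to build continental-scale
seasonal temperature stacks from pollen records: it is aimed at
paleoclimatologists who want a reproducible, fully scriptable version
of that chain, and it ships a synthetic-data generator with recorded
ground truth so every stage can be validated by parameter recovery.

## The method

For each fossil record the pipeline runs:

1. **Chronology** — radiocarbon dates are calibrated against a
   pluggable curve (IntCal-layout CSV): the posterior over calendar age
   θ is p(θ) ∝ N(a₁₄; μ(θ), √(σ² + σ_curve(θ)²)); sample ages come from
   piecewise-linear interpolation of the posterior means.  Records are
   screened (≥4 chronological controls with ≥2 independent dates,
   duration > 5 kyr, a sample younger than 1 ka BP, median resolution
   < 400 yr — 1000 yr in northern Asia) and samples are screened
   (within 1 kyr of a date or bracketed by dates ≤ 6 kyr apart; ≥ 200
   pollen grains).
2. **PFT scores** — taxon proportions p are converted to plant
   functional type affinities by the biomization score
   `score(PFT) = Σ_taxa w · √max(0, p − θ)` with θ = 0.5 %.
3. **MAT reconstruction** — each fossil sample is assigned the
   dissimilarity-weighted climate (ANNT, MTWA, MTCO) of its k = 6
   closest modern surface samples under the squared chord distance
   `SCD(p, q) = Σ (√pᵢ − √qᵢ)²`, with weights 1/SCD and a no-analogue
   threshold SCD > 0.2.  Sample-specific errors combine a 100-draw
   bootstrap of the calibration set with the leave-one-out RMSEP in
   quadrature.  WA-PLS (ter Braak & Juggins formulation, inverse
   deshrinking) is available as a cross-check method, and h-block
   cross-validation (withholding all sites within h km) quantifies the
   effect of spatial autocorrelation, with h chosen by matching the
   median fossil SCD to the changing-h median-SCD curve.
4. **Significance** — a reconstruction is retained only if it explains
   more fossil-assemblage variance (as the sole RDA constraint) than
   84.2 % of 999 reconstructions trained on random environmental
   variables.
5. **Isostatic correction** — post-glacial elevation-anomaly histories
   (ICE-7G-style NetCDF) are interpolated to each site (IDW in space,
   linear in time) and the topographic component `rate · Δelev(t)` is
   subtracted, using present-day local lapse rates regressed from the
   climate grid within 300 km.
6. **Stacking** — corrected series become anomalies relative to their
   last-1000-yr mean, are interpolated to 200-yr bins through a
   1000-member Monte-Carlo ensemble, averaged onto a 2° × 2° grid, and
   composited (hemisphere and eight regions) with a second Monte-Carlo
   pass that yields per-bin medians and 95 % bands.  Trends (°C ka⁻¹),
   the summer-minus-winter seasonality curve, and EOF analyses of the
   11–7 and 7–0 ka BP windows summarize the result.

Redundancy analysis (RDA) with partial variance partitioning and
permutation tests is included for calibration-set diagnostics (how much
PFT-score variance winter vs summer temperature explains, uniquely and
jointly).

## Worked example

The synthetic generator imposes a known truth — winter warming 4.0 °C
and summer warming 1.4 °C over 11–7 ka BP, then cooling of 0.7 / 0.5 °C
to the present — and the pipeline recovers it:

```python
import logging; logging.disable(logging.WARNING)
from pollenrecon import scd, synthetic, cross_validate
from pollenrecon.pipeline import PipelineConfig, run_pipeline

print("scd:", round(scd([0.5, 0.5], [0.25, 0.75]), 4))

bundle = synthetic.holocene_demo(seed=0, n_records=12, n_calib=200)
cv = cross_validate(bundle["calibration"], method="mat", scheme="loo")
print("LOO R2:", {k: round(v, 3) for k, v in cv.r2.items()})

cfg = PipelineConfig(out_dir="demo_out", seed=0)
cfg.mc.n_mc = 200; cfg.mc.n_rand = 99
m = run_pipeline(cfg, bundle=bundle)
print("screening:", m["stages"]["screening"]["n_pass"], "of 12")
for k, v in m["stages"]["trends"].items():
    print(f"trend {k}: {v['rate_c_per_ka']:+.2f} degC/ka")
```

prints

```
scd: 0.0681
LOO R2: {'annt': 0.993, 'mtwa': 0.806, 'mtco': 0.986}
screening: 12 of 12
trend annt_11-7ka: +0.72 degC/ka
trend annt_7-0ka: -0.06 degC/ka
trend mtwa_11-7ka: +0.57 degC/ka
trend mtwa_7-0ka: -0.07 degC/ka
trend mtco_11-7ka: +0.81 degC/ka
trend mtco_7-0ka: -0.08 degC/ka
```

The hand-checkable SCD value is (√.5−√.25)² + (√.5−√.75)² = 0.0681;
leave-one-out skill is high for winter (MTCO) and annual temperature
and lower for summer (MTWA), matching the expected ordering; the fitted
trends recover the imposed early-Holocene warming (positive = warming
toward the present) and late-Holocene cooling in both seasons, with
winter amplitude exceeding summer.  `demo_out/` then holds composite
CSVs (`composite_<var>_<region>.csv`), the NH seasonality curve, EOF
correlation maps and a JSON manifest of every stage.

A CLI mirrors the library (`pollenrecon simulate | run | chronology |
pft | recon | validate | significance | correct | stack | eof`); see
`pollenrecon --help`.

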