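# Methods

This note documents the models, parameter choices and numerical
conventions behind `pollenrecon`, and what the synthetic experiments do
and do not demonstrate.

## Radiocarbon calibration and age models

A date (a₁₄, σ) is calibrated on the curve's calendar grid with
likelihood N(a₁₄; μ(θ), √(σ² + σ_curve(θ)²)); the posterior is
normalized by trapezoidal quadrature and summarized by its mean and SD.
The mean (rather than median or intercept) is the point estimate: it is
stable, and testable to < 0.1 yr against dense quadrature.  Age–depth
models are piecewise-linear through calibrated point ages; samples
outside the dated span are linearly extrapolated and flagged.  Age
reversals between consecutive controls are rejected rather than
resolved — the screening rules below make usable records reversal-free
in practice.  Core-top, lamination and biostratigraphic controls enter
the interpolation but never count as independent dates.

Screening thresholds (all configurable, defaults in
`pollenrecon.chronology`): ≥ 4 chronological controls with ≥ 2
independent dates; record duration > 5000 yr; a sample younger than
1000 cal yr BP (required for anomaly referencing); median Holocene
inter-sample gap < 400 yr, relaxed to 1000 yr in northern Asia (N_AS)
where site density is low; per sample, a date within 1000 yr or
bracketing dates ≤ 6000 yr apart, and a total count ≥ 200 grains.
"Resolution" is the median inter-sample age gap — robust to a single
hiatus.

## PFT scores

Biomization-style affinity: score(sample, PFT) = Σ_taxa
w(taxon, PFT) · √max(0, p − θ), θ = 0.005 by default.  Proportions are
computed on the sum of taxa present in the regional taxa–PFT matrix
(the terrestrial pollen sum); fossil taxa missing from the matrix are
reported, never silently dropped.  The square root stabilizes variance
and weights minor taxa up, exactly as in the chord-distance metric.

## Transfer functions

**MAT.** Assemblage vectors are row-normalized, square-rooted, and
compared by squared chord distance (range 0–2).  The k = 6 nearest
calibration samples (ties broken by stable sample order) contribute
with weight 1/SCD; an exact zero distance short-circuits to the mean of
the zero-distance analogues.  A sample whose nearest analogue exceeds
scd_max = 0.2 is flagged no-analogue and its estimate withheld.  k and
scd_max are per-region configurable; the defaults sit inside the 5–7
analogue convention and the usual "SCD < 0.2 is a good analogue" rule
of thumb.

**Sample-specific errors.** 100 bootstrap resamples of the calibration
rows give a prediction SD per fossil sample, combined in quadrature
with the model's leave-one-out RMSEP.  In the bootstrap inner loop a
zero distance is floored at 1e-12, which reproduces the short-circuit
to machine precision while keeping the loop vectorized.

**WA-PLS.** The iterative species-weighted algorithm: per component,
species scores are the species-total-weighted average of the current
environmental residual, site scores the sample-total-weighted average
of species scores, orthogonalized against earlier components and
standardized under site weights; the weighted regression of the
(weight-centred) variable on the components is the inverse deshrinking.
A classical-deshrinking flag regresses the composite score on the
observed variable and inverts.  One component reproduces plain weighted
averaging with inverse deshrinking exactly (tested against an
independent two-step implementation).

**Cross-validation.** h-block withholds the test sample plus every
site strictly within h km (haversine, 6371-km sphere), so h = 0 is
exactly leave-one-out; co-located duplicate sites remain available at
h = 0, as in LOO.  h is selected by matching the median fossil
nearest-analogue SCD to the median-SCD curve of changing-h experiments
(0–1000 km); if the fossil median exceeds the whole curve the largest h
is used, with a warning.

**Significance.** The observed statistic is the fraction of
fossil-assemblage variance explained by the reconstruction as the sole
RDA constraint (closed form for one constraint:
‖x_c'Y_c‖²/(x_c'x_c · total inertia)).  Null reconstructions train the
same method on variables drawn uniformly over the calibration range;
the reconstruction passes if it beats the 84.2 % empirical quantile of
999 nulls.  For MAT the analogue weights are independent of the trained
variable, so each null is the fixed weight matrix applied to the random
draw — identical to retraining, at a fraction of the cost.

A property worth stating plainly: this test family is anti-conservative
when the observed variable is a real, spatially smooth climate field.
Any variable smooth in assemblage space explains more variance than
uniform-random nulls, even for climatically meaningless fossil data —
in our experiments, noise records "pass" 60–90 % of the time when the
reconstruction is trained on the true calibration climate.  The nominal
1 − 0.842 retention holds only in the exchangeable design (observed
variable drawn from the null distribution itself), which is what the
calibration experiment checks.  Interpreting retention rates on real
data should keep this in mind.

## Ordination

RDA centers (and by default unit-scales) the response, projects it onto
the centered constraints by least squares, and eigen-decomposes fitted
and residual parts via SVD.  Partial RDA residualizes both sides on the
conditioning matrix; variance fractions stay relative to the
unconditioned total inertia so that unique₁ + unique₂ + shared =
combined exactly (shared may be negative in suppressor cases).
Permutation p-values use unrestricted row permutation of the
constraints with the add-one rule.  `rda` rejects rank-deficient
constraints; the variance-partition path deliberately tolerates them (a
duplicated constraint has zero unique share).

EOF analysis is PCA of the time × units anomaly matrix over a window:
covariance (not correlation) eigendecomposition, sign fixed so each
mode's spatial-mean loading is non-negative, spatial structure reported
as per-unit Pearson correlation with PC1.  Units with > 20 % missing
bins in the window are dropped; smaller gaps are linearly interpolated.

## Isostatic correction

Elevation-anomaly histories are interpolated to sites by
inverse-distance weighting (power 2, 4 nearest nodes; exact node hits
return the node series) and linearly in time.  Sign convention:
Δelev(t) > 0 means the past surface stood higher than today; with a
negative lapse rate this is a topographic cooling, removed by
corrected(t) = estimate(t) − rate · Δelev(t).  Correction is linear in
both factors, leaves sample errors unchanged, and is guarded against
double application.

Local lapse rates are per-variable OLS slopes of gridded ANNT/MTWA/MTCO
against elevation within 300 km.  The plain slope is the documented
default; the pipeline enables a lat/lon-detrended variant (covariates
for the horizontal gradient, partial slope on elevation) plus a 50-m
minimum-relief guard, because on fields whose horizontal structure
rivals the local relief the plain slope is badly confounded — on the
synthetic grids the detrended estimator recovers the imposed
−6.5 °C km⁻¹ to a few percent, the plain one can be off by an order of
magnitude.  Sites failing the guard are left uncorrected and logged.

## Stacking

Anomalies are relative to each site's own mean over ages ≤ 1000 cal yr
BP.  Stage one draws 1000 Monte-Carlo realizations of each site series
(Normal perturbation by the sample-specific error, re-referencing per
draw), interpolates each onto 200-yr bins (centers 100, 300, …, 10900,
tiling 0–11 ka) inside the record's span, and stores the ensemble
median and SD.  The ensemble SD is the bin error used downstream;
SD/√n_draws is also emitted.  Stage two averages sites into 2° × 2°
cells ([lower, upper) membership) and runs a second 1000-draw pass
across cells, reporting per-bin medians and 2.5/97.5 percentiles.
Averaging is unweighted by default (an area-weighting flag exists).
Bins with no coverage are missing, never zero.

Trends are OLS slopes of the composite median over an age window, with
positive = warming toward the present; the seasonality curve is the
per-bin difference of summer and winter medians with
quadrature-combined bands (independence assumed — the two composites
share sites, so the combined band is approximate).

## Synthetic data

The generator emulates: Gaussian (unimodal) taxon niches in the
MTCO × MTWA plane with optima tiling the climate range; multinomial
counting noise at a configurable total (default 400 grains); smooth
MTCO/MTWA fields whose cross-cell Pearson correlation is tuned to a
target (default 0.6, range of observed regional values ~0.35–0.76) by
mixing a shared and an orthogonalized independent smooth field, with up
to 50 adjustment attempts; a sinusoidal monthly cycle so ANNT is the
MTCO/MTWA midpoint by construction; textured orography with an imposed
−6.5 °C km⁻¹ lapse; sparse radiocarbon dating (controls every 2 kyr,
σ = 60 yr) against identity/linear/wiggly synthetic curves; and an
ice-margin-style elevation anomaly that decays as 1 − exp(−t ln2/τ),
exactly zero at present.  Fossil sites experience the topographic
cooling lapse · Δelev(t) on top of the climate truth, so the correction
stage has a real signal to remove; the recorded truth is climate-only.

The default truth imposes winter warming of 4.0 °C and summer warming
of 1.4 °C over 11–7 ka BP, then winter/summer cooling of 0.7/0.5 °C to
the present — a mid-Holocene optimum with much stronger winter
amplitude in the early Holocene.

What the generator does not emulate: real geography and coastlines,
precipitation or other non-temperature drivers, taphonomy and pollen
productivity biases, age-model structure beyond linear interpolation,
and spatially heterogeneous truth (all sites share one anomaly
history, so EOF PC1 fractions on synthetic data are higher than on real
data).  Passing recovery tests therefore demonstrates the correctness
of the pipeline's statistics, not the fidelity of any real-world
reconstruction.

## Experiment sizes and recovery metrics

The standard recovery fixture is 60 fossil records (40 samples each)
against a 300-sample calibration set; the statistical calibration
experiments use 200 replicate records (significance retention, at 99
nulls per record) and 200 repetitions of a 20-site stack (band
coverage).  These sizes give stable Monte-Carlo estimates in seconds
while leaving the per-record settings at the standard protocol values
(100 bootstrap draws, 1000 MC draws, 84.2 % quantile).

Recovery of the imposed truth is measured as the pooled correlation and
mean bias over all retained fossil samples across records, in absolute
°C: the pooled metric tests the full temperature field (spatial anchor
plus temporal history).  Per-record temporal correlation is reported by
the recovery scripts too, but for MTWA it is intrinsically noise-limited
under the default conditions — the imposed summer history spans 1.4 °C
while per-sample reconstruction noise is 1–2 °C (the calibration skill
ordering MTWA < MTCO is itself part of the emulated conditions).

The early-Holocene winter/summer amplitude ratio is measured on the
stack built without significance selection.  Selection preferentially
retains weak-variable records whose noise exaggerates their apparent
signal and thereby inflates the MTWA stack amplitude (the same
amplification the selection step produces on real data); the unselected
stack is the clean recovery experiment.  Trend signs are checked on the
full protocol including selection.

## Known limitations

- Thin-plate-spline site climate (with elevation covariate) is not
  implemented; bilinear interpolation plus a lapse adjustment stands
  behind the same contract.
- WA-PLS component selection is by simple k-fold RMSEP; no
  randomization t-test.
- The seasonality band treats summer and winter composites as
  independent.
- No Bayesian age-depth modelling, reservoir corrections, or
  outlier-date handling beyond the screening rules.
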