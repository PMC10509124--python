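# Methods

## Scope and conventions

All geometry is 2-D per short-axis slice or per long-axis view, in mm,
origin at the image top-left with y increasing downward. Polygons are
closed implicitly. Slices are indexed 0 = most basal toward the apex; all
slices share one thickness and gap, and every volume uses the effective
spacing thickness + gap. Volumes are reported in ml, areas mm², EF as a
fraction, mass in grams (myocardial density 1.05 g/ml).

The package takes *delineations* as input (a bespoke contour JSON plus a
cohort CSV), not images: segmentation and point tracking are upstream of
this artifact, and the contours are treated as authoritative — no extra
basal-slice exclusion is applied in volumetry beyond what the contours
themselves encode.

## AVPD

The AV "plane" is fitted per long-axis view as a 2-D line through that
view's end-diastolic points — exactly for two points, by orthogonal
regression (total least squares) for three. Orthogonal rather than
ordinary regression because displacement is *measured* perpendicular to
the line. Displacements are always taken against the ED line (no ES line
is ever fitted) and the sign is oriented by an explicit apex landmark in
each view; an apex-free convention based on image order would be fragile
under the rigid-motion invariance we require (and test at 100 random
rigid transforms). Negative Δ (motion away from the apex) propagates into
the means unclamped. LV-AVPD is the unweighted mean of six labels;
RV-AVPD averages the septal pair before the three-way mean, so the septum
is not double-weighted; TAPSE is the lateral tricuspid point alone.

We do not fit a single 3-D AV plane across views: the per-label averaging
of the displacement formulas is compatible with per-view lines and avoids
an unstated 3-D registration between views.

## Stroke-volume decomposition

* **Longitudinal**: AVPD × the mean ED epicardial cross-section of the two
  largest basal slices of that ventricle. "Two largest" is by area, not by
  slice index, which is immune to over-segmented atrial slices. The RV
  epicardial cross-section is the RV epicardial polygon minus its overlap
  with the LV epicardial polygon (resolved by polygon clipping), so the
  septum is never counted twice.
* **Lateral and septal**: the area between ED and ES epicardial borders is
  the signed area of the closed polygon formed by the ED polyline, the
  reversed ES polyline and the end chords. Both polylines are resampled to
  128 points by arc length, so unequal vertex counts and point orderings
  are irrelevant. The sign convention is anchored to a reference point
  (the cavity centroid for lateral sweeps — inward positive; the LV
  cavity centroid for the septal sweep — toward-LV positive), and the
  orientation factor depends only on the ED polyline, which makes
  mirrored septal displacement flip the sign exactly (to ~1e-13 in
  floating point; tests assert 1e-9).
* Only slices with the septum present at both phases enter the sweeps; a
  slice qualifies when an RV cavity contour and both insertion points
  exist at ED and at ES. The septal sweep uses the same thickness + gap
  spacing as the lateral sweep (we treat the narrower wording for the
  septal rule as an elision; the spacing is a single stack property here).
* The septum on each slice is the epicardial arc between the vertices
  nearest the two RV insertion points, chosen as the arc facing the RV
  cavity centroid; the complementary arcs are the LV and RV free walls.

## Phantom model

Two stacked cylinders: a circular LV (endo radius a = 23 mm, epi radius
b = 28 mm, length L = 100 mm) and a crescent RV between the LV epicardium
and an outer arc on one half-plane (cavity width 16 mm, free-wall
thickness 4 mm). These radii give healthy-scale volumes (LV-EDV ≈ 166 ml,
RV-EDV ≈ 181 ml). End-systole applies (i) apical translation of the basal
boundary by the AVPD, slices whose slab centre is passed by the plane
losing their contours, (ii) inward scaling of the free-wall epicardial
radii, (iii) rigid translation of the septal arc.

Two modelling choices matter:

* **Incompressible myocardium.** ES *endocardial* cross-sections are
  derived from wall-volume conservation given the prescribed epicardial
  motion. This is what makes "basal epicardial area × AVPD" the displaced
  blood volume, so a pure-translation phantom yields SV_long% = 100 and
  the decomposition conserves stroke volume. Under radial-only motion the
  stroke volume is therefore the *epicardial* half-annulus closed form,
  not an endocardial one.
* **Septal points ride the LV excursion.** The ground-truth RV-AVPD is the
  weighted mean (avpd_lv + 2·avpd_rv)/3 of the prescribed motions and
  TAPSE equals the lateral excursion avpd_rv; the RV basal truncation uses
  the weighted mean. Defaults (16 mm LV, 25 mm lateral → 22 mm RV mean,
  radial fractions 0.104/0.031, septal shift 1.42 mm) land the
  longitudinal shares near 57% (LV) and 85% (RV), the healthy pattern.

All ground truth is closed form (cylinder and annulus-sector volumes plus
the translation sweep 2bσ per unit length); nothing is measured back from
the generated contours. A validated constraint: a nonzero septal shift
requires free-wall radial clearance (|shift| + b·(1−f_lv) < b), otherwise
the ES epicardial polygon self-intersects at the insertion junctions —
pure-septal motion is exercised through the unit-level sweep operators
instead. Residual phantom error has three benign sources: inscribed
128-gon area deficit (~0.04%), slab truncation when an excursion is not a
multiple of the slice spacing (bounded by half a slice), and a septal
cross term of relative size ~σ·f·b/SV in the conservation identity (a few
percent at defaults; it is the reason conservation is checked at 10%, and
it does not shrink with slice refinement — only the truncation term
does). The phantom does not emulate trabeculation, through-plane motion
of the imaging planes, wall-thickness gradients, or segmentation noise
beyond optional i.i.d. point jitter, so passing phantom tests validates
the estimators' geometry, not their robustness to real segmentation
variability.

## Cohort simulator

Metrics are drawn independently per metric from group-specific normals
truncated at physiologic bounds (AVPD ≥ 0, volumes ≥ 5 ml, heart rate ≥
30), using the published control/patient summaries as defaults; only the
marginals are published, so no cross-metric covariance is imposed. EDV and
EF are *derived* (EDV = ESV + SV, EF = SV/EDV) so each subject is
internally consistent; their marginals therefore deviate slightly from
the printed EDV/EF SDs. CMR-TAPSE has no published summary; its defaults
(control 25 ± 4, patient 14 ± 5 mm) are synthetic, chosen to keep the
lateral excursion above the RV mean. Patient survival is exponential
proportional hazards with linear predictor Σ log_hr·(mean − x) — lower
AVPD raises the hazard; defaults log-HR 0.15/mm (LV) and 0.10/mm (RV)
with baseline 0.25/y. Administrative censoring is uniform over an 8-year
horizon, giving a median follow-up near 3.5 years and an event fraction
near 60%. The exponential baseline is harmless for hazard-ratio recovery
because the Cox fit is semiparametric. Controls carry no survival data.

## Statistics

Cutoffs are control mean ± 2·SD (sample SD, n−1); equality with the
cutoff is *within limits* (alteration means strictly more than 2 SD) and
cutoffs are carried at full precision, rounded only for display. Group
comparisons gate on Shapiro–Wilk at α = 0.05 in both samples: t-test
(classic equal-variance form) when both pass, Mann–Whitney otherwise;
nominal data use the two-sided chi-square without continuity correction.
Kaplan–Meier and log-rank come from lifelines; Cox fits use the partial
likelihood with Breslow tie handling by default (Efron by flag) via
statsmodels, with Wald 95% CIs and p-values. Imaging covariates are
negated before fitting so hazard ratios read per one-unit decrease. The
regression ladder mirrors the clinical analysis: univariate for every
covariate; age-adjusted bivariate where univariate p < 0.1; multivariate
adding incident/prevalent status; age and incident status also fitted on
their own. Coefficients beyond |β| > 50 are flagged as separation rather
than reported.

Problem sizes in the test suite and acceptance script are the package's
own choices: phantoms at 20 slices × 128 vertices (48 × 128 for the
conservation check, with excursions that are multiples of the slice
spacing so slab truncation vanishes and the residual isolates the model
cross term); hazard-ratio recovery over 50 cohorts of n = 1000; type-I
error over 2000 null cohorts of n = 60. Of the nine published cutoffs
only LVEF < 53, RVEF < 48 and LV-AVPD < 12.0 are arithmetically
consistent with the rounded control summaries; the others require
unrounded control statistics that are not available, so they are not
asserted.

## Known limitations

* Per-view 2-D AV lines, not a 3-D plane; frame-resolved AVPD curves and
  strain/dyssynchrony indices are out of scope (only ED→ES excursion).
* Volumetry applies no partial-volume or basal-slice correction schemes.
* The septum partition assumes insertion points are annotated wherever RV
  contours exist; slices violating this are flagged and excluded.
* The cohort simulator's independence across metrics understates the
  collinearity of real imaging metrics, so multivariable model behaviour
  on real cohorts may differ.
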