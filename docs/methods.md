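# Methods

This note documents the models behind `petiq`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic test bed can
and cannot say about real scanner data.

## Forward model

A simulated "reconstruction" is produced in three steps:

1. **Resolution.** The true activity map is convolved with an isotropic
   Gaussian point spread function.  Default FWHM is 4.2 mm, a typical
   reconstructed resolution for a modern digital PET/MR system; the
   PET/CT-like preset uses 5.9 mm to reflect an older analogue system with
   a coarser grid and post-filter.
2. **Counting.** Expected counts per voxel are
   `activity [kBq/ml] × voxel volume [ml] × sensitivity [cps/kBq] × time [s]`,
   and the realised image is one independent Poisson draw per voxel.
   Sensitivity defaults: 21 cps/kBq (PET/MR-like) and 10 cps/kBq
   (PET/CT-like).  The draw order — blur first, then Poisson — models
   *post-reconstruction voxel noise* with the correct first moment and a
   simple, controllable second moment.  Real reconstructions correlate
   noise over a few voxels; here voxel noise is independent by
   construction.  Consequences: noise magnitudes are not transferable to
   real scanners, but ratios across conditions (time, thinning, β) follow
   the correct Poisson scaling, which is what the study design uses.
3. **Penalization surrogate.** β-penalized reconstruction (BSREM-style) is
   emulated by Gaussian post-smoothing with `σ(β) = σ_ref · √(β/300)`,
   `σ_ref = 3 mm` at the reference β = 300.  The square-root law makes the
   smoothed white-noise variance scale as `β^{-3/2}`, i.e. BV drops by
   41 %/26 %/19 % along 150→300→450→600 — the same qualitative pattern
   (large first step, diminishing returns) that penalized reconstructions
   show, with monotonically decreasing small-sphere contrast as the price.
   This is a surrogate for the *role* β plays, not a model of any vendor
   algorithm; absolute β values carry no meaning outside this package.

**Activity reduction** is emulated by binomial count thinning: every count
is kept with probability `1 − r`.  Thinning a Poisson(λ) field gives exactly
Poisson((1−r)λ), so a thinned acquisition is statistically identical to one
with `(1−r)` times the activity (or time) — the same rationale as list-mode
rebinning with a shortened time window.  The deterministic count scale is
divided by `1 − r` on conversion back to concentration, mirroring a scanner
normalising by its actual acquisition time, so quantitation is unbiased
across reductions.

Decay is handled only through `decay_compensated_time`
(`t_ref · 2^{Δt/T½}`, T½ = 67.71 min for Ga-68); no intra-scan decay is
modelled.  The session schedule (90/180/360 s for the 10:1/4:1/2:1
fillings) corresponds to exact doubling per session; the exact compensation
for a 60-minute delay would be 166.3 s, so the doubled times are the
rounded-up practical values, and the simulator uses the configured times
as-is.

Out of scope by design: sinogram/list-mode event simulation, TOF and PSF
system matrices, attenuation, scatter, randoms, and MR-based attenuation
correction.  These change absolute image quality but not the comparative
logic of a (reduction, β) grid.

## Phantom and patient geometry

The digital NEMA-IQ phantom is an elliptical cylinder (semi-axes
150 × 115 mm, height 180 mm) with six spheres (ø 10, 13, 17, 22, 28,
37 mm) on a 57.2 mm ring in the central plane, a ø 50 mm zero-activity
lung insert, and two 500 ml ø 80 mm bottles resting against the body
laterally to mimic arms-down imaging (bottle activity 0.32 kBq/ml).
Filling presets give sphere:background ratios of 10:1 (38.9:4.0 kBq/ml),
4:1 (22.1:5.2) and 2:1 (12.0:5.4).  The six ø 27 × 70 mm background
cylinders sit on a shrunken ellipse rotated half a step from the sphere
ring; the placement keeps every cylinder ≥ 15 mm from each sphere surface,
the lung insert and the body wall.  The exact background positions are a
package convention — no standard prescribes them — and they are validated
at construction time.

The synthetic patient is an elliptical-cylinder torso (SUV 1) with an
ellipsoidal liver (SUV 6) and ten spherical lesions (ø 6–37 mm, SUVmax
4–40) on a ring through two axial planes chosen to keep each lesion's VOI
search window clear of the liver.  Half of the lesions are no larger than
the 10 mm sphere (0.52 ml), reproducing the subcentimeter-heavy case mix
that makes lesion detectability the binding constraint in dose-reduction
studies.  The default dose follows the 1.5 MBq/kg protocol (81 kg →
121.5 MBq).  Lesion voxel values are boosted so that after PSF blurring
the peak equals the nominal SUVmax (closed-form ball-blur correction,
exact in the continuum; within 5 % for lesions ≳ one FWHM × 4).

## VOIs and metrics

Masks use **voxel-centre containment** — deterministic, grid-shared and
resolution-convergent; no partial-volume weighting.  Statistics use the
sample (n−1) standard deviation.  BV averages per-VOI SD/mean ratios (a
pooled variant is available behind a switch; the choice matters little for
six same-size VOIs).  Contrast recovery interprets "counts" as mean voxel
values — units cancel in the double ratio.  Mean CNR is the unweighted
mean over the six spheres.  Lesion VOIs are 50 %-of-local-max isocontours
seeded at the known lesion position (15 mm search radius), falling back to
a fixed ø 10 mm sphere when the component exceeds 100 ml or merges into
the liver VOI — the regimes where a relative threshold is meaningless.
SUVpeak is deliberately not implemented: with mostly subcentimeter lesions
a 1 ml peak sphere is larger than the lesion.

In the noise-free, PSF-free limit the pipeline is exact: CR = 1 for every
sphere, BV = 0 (CNR reported as undefined), liver noise = 0 and lesion
SBR equals the configured SUV ratio — this is a regression anchor in the
test suite.

## Reader statistics

Mean visual scores come from marginal count tables (score levels 0–3, both
readers pooled).  Cohen's κ is unweighted (no weighting scheme is implied
by a four-point quality scale).  ICC uses the McGraw–Wong ICC(A,1)
convention — two-way model, absolute agreement, single rater — with the
F-based 95 % confidence interval (Satterthwaite df).  Detectability is
reported per reader, pooled (Σdetected/Σreference) and as the mean of
per-reader fractions; the pooled figure is the headline number.

The shipped `table2_scores.csv` / `table3_lesions.csv` fixtures are the
published reader-study tables transcribed as printed.  Joint score tables
(needed for κ) and per-patient lesion counts (needed for ICC) are *not*
recoverable from those marginals, so κ and ICC are exercised on synthetic
reader data only; the `step1_*`/`step2_*` fixtures are labelled synthetic
and encode the reported step-1 eligibility and step-2 significance
outcomes.

## Reference comparisons and β selection

`compare_to_reference` screens each condition with Shapiro–Wilk (α = 0.05);
if all pass, a repeated-measures ANOVA (Greenhouse–Geisser corrected when
Mauchly's test rejects sphericity, via `pingouin`) with Dunnett's test
against the reference; otherwise a Friedman test with Dunn's post hoc
(Bonferroni family of reference comparisons only — no all-pairs testing).
The Friedman statistic is computed directly from within-subject midranks
and cross-checked against `scipy`; `scipy.stats.dunnett` assumes
independent groups, a deliberate approximation for the parametric branch.

Step-1 selection: a β is eligible for a reduction when *every* rating is
≥ 2 ("moderate") and pooled detectability strictly exceeds 90 % (the
per-rating reading of "all scores sufficient" is the strict
interpretation; the threshold is configurable, e.g. 94 % for a stricter
criterion).  Ties among eligible β are broken by the smallest
|mean lesion SUVmax − reference SUVmax|, then by the smaller β.  Step 2
accepts the largest reduction whose selected β is significantly worse than
the 0 %-β300 reference on neither visual score nor detectability, falling
back to the reference protocol otherwise.

## Problem sizes, determinism, numerics

Statistical tests in the suite run on 4 mm (phantom) and 3 mm (patient)
isotropic grids — the phantom fits in ~0.4 M voxels there, so whole grids
run in seconds while Poisson expectations stay at a realistic ~480 counts
per background voxel; the trend acceptance check uses a 200³ grid at the
clinical 2.34 × 2.34 × 2.78 mm³ voxel size.  Smoothing uses wrap-around
boundaries: the volumes are zero (air) near the grid edge, so wrapping
carries no signal while keeping the kernel exactly normalised, which makes
the global mean invariant to machine precision.  Every random stage
(Poisson draw, thinning, per-patient replicates) gets its own deterministic
child seed below 2³¹, so identical configurations are bitwise reproducible.
Degenerate inputs raise typed errors rather than returning NaN: zero BV
makes CNR undefined, single-voxel VOIs have no sample SD, κ is undefined
for degenerate margins, and ICC confidence intervals collapse to the point
estimate when the residual mean square is zero.

## Known limitations

- Voxel noise is independent; real reconstructions are spatially
  correlated, so absolute BV/noise levels are not transferable.
- The β surrogate cannot reproduce published per-step BV/CNR percentages
  from real scanner reconstructions — only their monotone trends.
- One bed position, no attenuation: the arm bottles contribute background
  signal but no attenuation effect.
- Passing tests show the *analysis chain* is correct and the *statistical
  scaling* is right; they do not validate any clinical dose-reduction
  claim, which requires real scanner data and human readers.
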