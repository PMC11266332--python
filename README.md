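# petiq

Simulation and analysis tools for **PET injected-activity reduction
studies** with β-penalized reconstruction, built around the NEMA
image-quality (IQ) phantom and the reader-study statistics used in clinical
dose-optimisation work (e.g. somatostatin-receptor PET of neuroendocrine
tumours with [⁶⁸Ga]Ga-DOTA-TATE).

The question the package addresses: *by how much can the injected activity
be lowered — emulated by binomial count thinning — if the reconstruction's
noise-penalization strength β is raised to absorb the extra noise, without
losing image quality or lesion detectability?*  It is aimed at medical
physicists and method developers who want a reproducible, fully synthetic
test bed for the whole analysis chain.

## What it computes

**Phantom image quality** (six fillable spheres, ø 10–37 mm, on a warm
background with a cold lung insert and two lateral "arm" bottles):

- contrast recovery per sphere, `CR = (C_H/C_B − 1)/(a_H/a_B − 1)`, where
  `C_H`, `C_B` are measured sphere/background VOI means and `a_H`, `a_B`
  the true filled activities;
- background variability, `BV = mean_j(SD_j / mean_j)` over six ø 27 × 70 mm
  background cylinders (relative noise);
- contrast-to-noise ratio, `CNR = CR / BV`.

**Patient image quality** (synthetic torso with a homogeneous liver and
spherical lesions, half of them subcentimeter):

- liver noise `= SD_liver / SUVmean_liver` (ø 3 cm liver VOI),
- lesion `SNR = SUVmax / liver noise`, lesion `SBR = SUVmax / SUVmean_liver`,
  with lesion VOIs from a 50 %-of-max isocontour, frozen across conditions.

**Reader statistics**: mean four-point visual scores from marginal count
tables, unweighted Cohen's κ, two-way mixed absolute-agreement single-rater
ICC(A,1), and lesion detectability relative to a reference condition.

**Study orchestration**: (reduction, β) metric grids, Shapiro–Wilk-gated
RM-ANOVA/Dunnett or Friedman/Dunn comparisons against the reference
condition, the two-step optimal-β selection, and the final recommendation.

The simulator is deliberately simple — Gaussian PSF blur of the true
activity, independent Poisson counts per voxel, binomial thinning for
activity reduction, and a documented Gaussian surrogate (σ ∝ √β) for the
penalized reconstruction.  See `docs/methods.md` for the model, its
assumptions and its limits.

## Worked example

```python
from petiq import AcquisitionConfig, PhantomSpec
from petiq.study import run_phantom_grid

spec = PhantomSpec.for_ratio("4:1")          # 22.1 : 5.2 kBq/ml filling
acq = AcquisitionConfig(voxel_size_mm=(4, 4, 4), time_per_bed_s=180)
df = run_phantom_grid(spec, acq, reductions=(0.0, 0.67),
                      betas=(150, 300, 450, 600), seed=1)
print(df.groupby(["reduction", "beta"])["bv"].first().unstack().round(4))
```

prints

```
beta          150     300     450     600
reduction
0.00       0.0124  0.0061  0.0043  0.0034
0.67       0.0221  0.0109  0.0077  0.0061
```

Reading: background variability (relative noise) falls monotonically as β
rises — roughly −50 % per β doubling, the (β₁/β₂)^¾ law of the smoothing
surrogate — while discarding 67 % of the counts raises it by ~√3 at every
β.  The companion `cnr` column rises with β because the noise drops faster
than sphere contrast.  On the reader-study side:

```python
from petiq import fixtures, mean_visual_score, detectability_fraction
t2 = fixtures.load_table2_scores()
grp = t2[t2.condition == "17pct-b450"]
mean_visual_score(grp[["reader", "score_0", "score_1", "score_2", "score_3"]])
# 2.72  (mean score over 50 ratings, two readers x 25 patients)
detectability_fraction(fixtures.load_table3_lesions(), (17, 450), (0, 300)).pooled
# 96.08  (percent of reference lesions re-detected, pooled over readers)
```

A thin CLI mirrors the library: `petiq simulate-phantom`, `analyze-phantom`,
`simulate-patient`, `analyze-patient`, `select-beta`, `recommend`,
`reproduce-tables` (YAML config via `--config`, all seeds explicit).

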