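"""Study orchestration: metric grids, reference statistics, β selection.

The study design crosses simulated injected-activity reductions
{0, 17, 33, 50, 67}% with noise-suppression strengths β ∈ {150, 300, 450,
600}.  Phantom grids report per-sphere contrast recovery, background
variability and CNR; patient grids report liver noise and per-lesion
SUVmax / SNR / SBR with VOIs frozen across conditions.  The optimal β per
reduction is chosen in two steps: (1) keep β values whose images all score
at least "moderate" and whose lesion detectability exceeds a threshold,
breaking ties by the smallest |Δ SUVmax| against a reference; (2) accept the
largest reduction whose selected β is not significantly worse than the
0%-β300 reference on either visual score or detectability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, FixtureError, InsufficientDataError
from .grids import ActivityVolume
from .metrics import (
    background_variability,
    cnr,
    contrast_recovery,
    lesion_sbr,
    lesion_snr,
    liver_noise,
)
from .phantom import (
    DEFAULT_BETAS,
    DEFAULT_REDUCTIONS,
    AcquisitionConfig,
    PatientSpec,
    PhantomSpec,
    ReconParams,
    beta_smooth,
    build_nema_phantom,
    build_patient_volume,
    simulate_acquisition,
    thin_counts,
)
from .voi import (
    make_sphere_voi,
    place_background_vois,
    threshold_lesion_voi,
    voi_stats,
)

__all__ = [
    "run_phantom_grid",
    "run_patient_grid",
    "SelectionResult",
    "select_optimal_beta",
    "friedman_statistic",
    "ComparisonReport",
    "compare_to_reference",
    "Recommendation",
    "final_recommendation",
]

REFERENCE_CONDITION = (0.0, 300)


def _child_seed(seed: int, *indices: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = np.uint32(seed)
    for i in indices:
        h = np.uint32((int(h) * 1000003 + int(i) + 0x9E3779B1) % 2147483647)
    return int(h)


# ---------------------------------------------------------------------------
# phantom grid
# ---------------------------------------------------------------------------


def analyze_phantom_volume(
    image: ActivityVolume,
    spec: PhantomSpec,
    sphere_vois=None,
    bg_vois=None,
    bv_method: str = "per_voi",
) -> pd.DataFrame:
    """Per-sphere CR/CNR plus BV for one reconstructed (or truth) volume."""
    if sphere_vois is None:
        sphere_vois = [
            make_sphere_voi(c, d, image.grid)
            for c, d in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm)
        ]
    if bg_vois is None:
        bg_vois = place_background_vois(spec, image.grid)
    bg_stats = [voi_stats(image, m) for m in bg_vois]
    bv = background_variability(bg_stats, method=bv_method)
    cb = float(np.mean([s.mean for s in bg_stats]))
    rows = []
    for voi, d in zip(sphere_vois, spec.sphere_diameters_mm):
        ch = voi_stats(image, voi).mean
        cr = contrast_recovery(
            ch, cb, spec.sphere_activity_kBq_ml, spec.background_activity_kBq_ml
        )
        rows.append(
            {
                "sphere_diameter_mm": d,
                "cr": cr,
                "bv": bv,
                "cnr": cnr(cr, bv) if bv > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_phantom_grid(
    spec: PhantomSpec,
    acq: AcquisitionConfig,
    reductions=DEFAULT_REDUCTIONS,
    betas=DEFAULT_BETAS,
    surrogate_sigma_ref_mm: float = 3.0,
    seed: int = 0,
    shape=None,
    bv_method: str = "per_voi",
) -> pd.DataFrame:
    """Simulate one phantom acquisition and sweep (reduction, β).

    One count realisation is drawn per grid; each reduction thins it with its
    own child seed, so conditions share low-level noise structure the way
    list-mode rebinning shares events.  Returns a long frame with one row per
    (reduction, β, sphere).
    """
    truth = build_nema_phantom(spec, acq.voxel_size_mm, shape=shape)
    sphere_vois = [
        make_sphere_voi(c, d, truth.grid)
        for c, d in zip(spec.sphere_centers_mm, spec.sphere_diameters_mm)
    ]
    bg_vois = place_background_vois(spec, truth.grid)
    counts = simulate_acquisition(truth, _dc_replace(acq, seed=_child_seed(seed, 0)))
    frames = []
    for i, r in enumerate(reductions):
        thinned = thin_counts(counts, r, seed=_child_seed(seed, 1, i))
        activity = thinned.to_activity()
        for b in betas:
            img = beta_smooth(activity, ReconParams(b, surrogate_sigma_ref_mm))
            df = analyze_phantom_volume(img, spec, sphere_vois, bg_vois, bv_method)
            df.insert(0, "beta", b)
            df.insert(0, "reduction", r)
            df.insert(0, "ratio", spec.ratio_label)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# patient grid
# ---------------------------------------------------------------------------


def run_patient_grid(
    patient_specs,
    acq: AcquisitionConfig,
    reductions=DEFAULT_REDUCTIONS,
    betas=DEFAULT_BETAS,
    surrogate_sigma_ref_mm: float = 3.0,
    seed: int = 0,
    reference_condition=REFERENCE_CONDITION,
    liver_voi_diameter_mm: float = 30.0,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Per-patient liver noise and lesion SUVmax/SNR/SBR over the grid.

    All VOIs are placed once per patient — the liver sphere on the true liver
    centre and the lesion isocontours on the reference reconstruction — and
    reused unchanged for every (reduction, β), mirroring the frozen-VOI
    reading protocol.
    """
    ref_r, ref_b = reference_condition
    reductions = list(reductions)
    betas = list(betas)
    if ref_r not in reductions or ref_b not in betas:
        raise ConfigError("reference condition must be part of the study grid")
    if isinstance(patient_specs, PatientSpec):
        patient_specs = [patient_specs]

    rows = []
    for p_idx, spec in enumerate(patient_specs):
        truth = build_patient_volume(
            spec, acq.voxel_size_mm, calibrate_psf_fwhm_mm=acq.psf_fwhm_mm
        )
        suv_to_conc = spec.dose_MBq / spec.weight_kg  # kBq/ml per SUV
        conc = truth.with_data(truth.data * suv_to_conc, "kBq/ml")
        counts = simulate_acquisition(
            conc, _dc_replace(acq, seed=_child_seed(seed, 2, p_idx)), noiseless=noiseless
        )
        liver_voi = make_sphere_voi(spec.liver_center_mm, liver_voi_diameter_mm, truth.grid)

        def _suv_image(r: float, b: float, r_idx: int):
            thinned = (
                counts
                if (noiseless or r == 0.0)
                else thin_counts(counts, r, seed=_child_seed(seed, 3, p_idx, r_idx))
            )
            act = thinned.to_activity()  # thinning scale cancels here
            img = beta_smooth(act, ReconParams(b, surrogate_sigma_ref_mm))
            return img.with_data(np.asarray(img.data) / suv_to_conc, "SUV")

        # freeze lesion VOIs on the reference reconstruction
        ref_img = _suv_image(ref_r, ref_b, reductions.index(ref_r))
        lesion_vois = [
            threshold_lesion_voi(ref_img, les.center_mm, liver_mask=liver_voi)
            for les in spec.lesions
        ]

        for r_idx, r in enumerate(reductions):
            for b in betas:
                img = _suv_image(r, b, r_idx)
                lst = voi_stats(img, liver_voi)
                noise = liver_noise(lst.sd, lst.mean) if lst.mean > 0 else np.nan
                for l_idx, (les, lvoi) in enumerate(zip(spec.lesions, lesion_vois)):
                    suvmax = float(img.data[lvoi.mask].max())
                    rows.append(
                        {
                            "patient": p_idx,
                            "reduction": r,
                            "beta": b,
                            "lesion": l_idx,
                            "lesion_diameter_mm": les.diameter_mm,
                            "liver_suvmean": lst.mean,
                            "liver_noise": noise,
                            "lesion_suvmax": suvmax,
                            "lesion_snr": lesion_snr(suvmax, noise) if noise > 0 else np.nan,
                            "lesion_sbr": lesion_sbr(suvmax, lst.mean),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics vs a reference condition
# ---------------------------------------------------------------------------


def friedman_statistic(matrix) -> tuple[float, int]:
    """Friedman chi-square for an n-subjects × k-conditions matrix.

    Implemented directly from within-subject midranks:
    ``χ² = 12n/(k(k+1)) · Σ_j (R̄_j − (k+1)/2)²`` (no tie correction).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InsufficientDataError("need an n>=2 by k>=2 matrix")
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    mean_ranks = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float(np.sum((mean_ranks - (k + 1) / 2.0) ** 2))
    return chi2, k - 1


def _dunn_vs_reference(matrix: np.ndarray, ref_idx: int) -> pd.DataFrame:
    """Dunn's post hoc for Friedman, comparisons against one reference."""
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for j in range(k):
        if j == ref_idx:
            continue
        z = (mean_ranks[j] - mean_ranks[ref_idx]) / se
        p = min(1.0, 2.0 * (1.0 - stats.norm.cdf(abs(z))) * (k - 1))  # Bonferroni family
        rows.append({"col": j, "statistic": z, "p_adj": p})
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    method: str  # "rm_anova" or "friedman"
    statistic: float
    pvalue: float
    normality: dict
    sphericity_corrected: bool
    posthoc: pd.DataFrame  # condition, statistic, p_adj, significant, direction
    alpha: float = 0.05

    def significant_conditions(self) -> list:
        return list(self.posthoc.loc[self.posthoc["significant"], "condition"])


def compare_to_reference(
    df: pd.DataFrame,
    value_col: str,
    subject_col: str,
    condition_col: str,
    reference,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Paired comparison of every condition against a reference condition.

    Each condition group is first screened with Shapiro–Wilk (α = 0.05).  If
    all groups look normal, a repeated-measures ANOVA (Greenhouse–Geisser
    corrected when sphericity is rejected) with Dunnett's test against the
    reference is used; otherwise a Friedman test with Dunn's post hoc.
    """
    wide = df.pivot_table(index=subject_col, columns=condition_col, values=value_col)
    if wide.isna().any().any():
        raise InsufficientDataError("unbalanced design: missing (subject, condition) cells")
    if reference not in wide.columns:
        raise ConfigError(f"reference condition {reference!r} not present")
    if len(wide) < 3:
        raise InsufficientDataError("need at least 3 subjects")
    conditions = list(wide.columns)
    ref_idx = conditions.index(reference)
    x = wide.to_numpy(dtype=float)

    normality = {}
    all_normal = True
    for j, c in enumerate(conditions):
        vals = x[:, j]
        if np.ptp(vals) == 0:
            normality[c] = 1.0  # constant column: treat as non-informative
            continue
        p = float(stats.shapiro(vals).pvalue)
        normality[c] = p
        all_normal &= p >= 0.05

    if np.allclose(x, x[:, [ref_idx]]):
        # identical columns: nothing can differ
        posthoc = pd.DataFrame(
            {
                "condition": [c for c in conditions if c != reference],
                "statistic": 0.0,
                "p_adj": 1.0,
            }
        )
        posthoc["significant"] = False
        posthoc["direction"] = "equal"
        return ComparisonReport("degenerate", 0.0, 1.0, normality, False, posthoc, alpha)

    gg_corrected = False
    if all_normal:
        import pingouin as pg

        long = wide.reset_index().melt(
            id_vars=subject_col, var_name=condition_col, value_name=value_col
        )
        aov = pg.rm_anova(
            data=long,
            dv=value_col,
            within=condition_col,
            subject=subject_col,
            correction=True,
            detailed=False,
        )
        row = aov.iloc[0]
        sph_ok = bool(row.get("sphericity", True))
        gg_corrected = not sph_ok and "p_GG_corr" in row and np.isfinite(row["p_GG_corr"])
        pvalue = float(row["p_GG_corr"]) if gg_corrected else float(row["p_unc"])
        statistic = float(row["F"])
        res = stats.dunnett(
            *[x[:, j] for j in range(len(conditions)) if j != ref_idx],
            control=x[:, ref_idx],
        )
        posthoc = pd.DataFrame(
            {
                "condition": [c for c in conditions if c != reference],
                "statistic": np.atleast_1d(res.statistic),
                "p_adj": np.atleast_1d(res.pvalue),
            }
        )
        method = "rm_anova"
    else:
        statistic, dof = friedman_statistic(x)
        pvalue = float(stats.chi2.sf(statistic, dof))
        dunn = _dunn_vs_reference(x, ref_idx)
        posthoc = pd.DataFrame(
            {
                "condition": [conditions[j] for j in dunn["col"]],
                "statistic": dunn["statistic"].to_numpy(),
                "p_adj": dunn["p_adj"].to_numpy(),
            }
        )
        method = "friedman"

    means = {c: float(np.mean(x[:, j])) for j, c in enumerate(conditions)}
    posthoc["significant"] = posthoc["p_adj"] <= alpha
    posthoc["direction"] = [
        "higher" if means[c] > means[reference] else ("lower" if means[c] < means[reference] else "equal")
        for c in posthoc["condition"]
    ]
    return ComparisonReport(method, float(statistic), float(pvalue), normality, gg_corrected, posthoc, alpha)


# ---------------------------------------------------------------------------
# β selection and final recommendation
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Step-1 outcome: the optimal β per reduction plus diagnostics."""

    per_reduction: dict  # reduction_pct -> beta | None
    eligibility: pd.DataFrame  # reduction_pct, beta, scores_ok, detectability_pct, eligible, suvmax_diff
    reference_suvmax: float
    score_threshold: int = 2
    detectability_threshold_pct: float = 90.0


def select_optimal_beta(
    scores: pd.DataFrame,
    lesions: pd.DataFrame,
    suvmax: pd.DataFrame,
    reference_suvmax: float,
    score_threshold: int = 2,
    detectability_threshold_pct: float = 90.0,
    reference_condition=(0, 300),
) -> SelectionResult:
    """Step 1 of the visual analysis.

    ``scores``: long table (reduction_pct, beta, patient[, reader], score);
    ``lesions``: (reduction_pct, beta[, reader], lesions_detected);
    ``suvmax``: (reduction_pct, beta, suvmax_mean).  A β is *eligible* for a
    reduction when every single score is at least ``score_threshold`` and
    pooled detectability against the reference condition strictly exceeds
    ``detectability_threshold_pct``; among eligible β the one whose mean
    lesion SUVmax is closest to ``reference_suvmax`` wins (ties → smaller β).
    """
    for name, tbl, cols in (
        ("scores", scores, {"reduction_pct", "beta", "score"}),
        ("lesions", lesions, {"reduction_pct", "beta", "lesions_detected"}),
        ("suvmax", suvmax, {"reduction_pct", "beta", "suvmax_mean"}),
    ):
        if not cols.issubset(tbl.columns):
            raise FixtureError(f"{name} table must have columns {sorted(cols)}")

    ref_r, ref_b = reference_condition
    ref_rows = lesions[(lesions["reduction_pct"] == ref_r) & (lesions["beta"] == ref_b)]
    if ref_rows.empty:
        raise FixtureError(f"reference condition {reference_condition} missing from lesion table")
    ref_total = float(ref_rows["lesions_detected"].sum())

    grid = suvmax[["reduction_pct", "beta"]].drop_duplicates()
    records = []
    for _, cond in grid.iterrows():
        r, b = cond["reduction_pct"], cond["beta"]
        cond_scores = scores[(scores["reduction_pct"] == r) & (scores["beta"] == b)]
        if cond_scores.empty:
            raise FixtureError(f"condition ({r}, {b}) missing from score table")
        cond_lesions = lesions[(lesions["reduction_pct"] == r) & (lesions["beta"] == b)]
        if cond_lesions.empty:
            raise FixtureError(f"condition ({r}, {b}) missing from lesion table")
        scores_ok = bool((cond_scores["score"] >= score_threshold).all())
        detect_pct = 100.0 * float(cond_lesions["lesions_detected"].sum()) / ref_total
        sv = float(
            suvmax[(suvmax["reduction_pct"] == r) & (suvmax["beta"] == b)]["suvmax_mean"].iloc[0]
        )
        records.append(
            {
                "reduction_pct": r,
                "beta": b,
                "scores_ok": scores_ok,
                "detectability_pct": detect_pct,
                "eligible": scores_ok and detect_pct > detectability_threshold_pct,
                "suvmax_mean": sv,
                "suvmax_diff": abs(sv - reference_suvmax),
            }
        )
    elig = pd.DataFrame(records).sort_values(["reduction_pct", "beta"]).reset_index(drop=True)

    per_reduction: dict = {}
    for r, grp in elig.groupby("reduction_pct"):
        ok = grp[grp["eligible"]]
        if ok.empty:
            per_reduction[r] = None
        else:
            best = ok.sort_values(["suvmax_diff", "beta"]).iloc[0]
            per_reduction[r] = int(best["beta"])
    return SelectionResult(
        per_reduction, elig, reference_suvmax, score_threshold, detectability_threshold_pct
    )


@dataclass(frozen=True)
class Recommendation:
    reduction_pct: float
    beta: int
    reason: str


def final_recommendation(
    selection: SelectionResult,
    significance: pd.DataFrame,
    reference_condition=(0, 300),
) -> Recommendation:
    """Step 2: the largest reduction whose selected β is not significantly
    worse than the reference on either visual score or lesion detectability.

    ``significance`` has columns ``reduction_pct``,
    ``score_significantly_worse`` and ``detectability_significantly_worse``
    (booleans from the reference-comparison tests).  Falls back to the
    reference condition when nothing qualifies.
    """
    required = {
        "reduction_pct",
        "score_significantly_worse",
        "detectability_significantly_worse",
    }
    if not required.issubset(significance.columns):
        raise FixtureError(f"significance table must have columns {sorted(required)}")
    flags = significance.set_index("reduction_pct")
    candidates = sorted(
        (r for r, b in selection.per_reduction.items() if b is not None and r != reference_condition[0]),
        reverse=True,
    )
    for r in candidates:
        if r not in flags.index:
            continue
        row = flags.loc[r]
        if not bool(row["score_significantly_worse"]) and not bool(
            row["detectability_significantly_worse"]
        ):
            return Recommendation(
                float(r),
                int(selection.per_reduction[r]),
                f"largest reduction with β={selection.per_reduction[r]} not significantly "
                "worse than the reference on visual score or detectability",
            )
    return Recommendation(
        float(reference_condition[0]),
        int(reference_condition[1]),
        "no reduction met both non-inferiority checks; keeping the reference protocol",
    )
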