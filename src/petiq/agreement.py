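"""Reader-study statistics: visual scores, agreement and detectability.

Visual image quality uses a four-point ordinal scale — non-diagnostic (0),
poor (1), moderate (2), good (3).  Marginal tables give, per condition and
reader, the number of patients at each score level.  Agreement statistics
are unweighted Cohen's kappa for the scores and a two-way mixed-effects,
absolute-agreement, single-rater intraclass correlation (McGraw–Wong
ICC(A,1)) for lesion counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FixtureError, InsufficientDataError, UndefinedMetricError

__all__ = [
    "SCORE_LEVELS",
    "mean_visual_score",
    "cohens_kappa",
    "ICCResult",
    "icc_absolute_single",
    "Detectability",
    "detectability_fraction",
]

SCORE_LEVELS = (0, 1, 2, 3)


def _marginals_to_frame(marginals) -> pd.DataFrame:
    """Normalise marginal score counts to a reader × score-level frame."""
    if isinstance(marginals, pd.DataFrame):
        df = marginals.copy()
        if "reader" in df.columns:
            df = df.set_index("reader")
        cols = {}
        for s in SCORE_LEVELS:
            for cand in (f"score_{s}", s, str(s)):
                if cand in df.columns:
                    cols[s] = df[cand]
                    break
            else:
                cols[s] = pd.Series(0, index=df.index)
        return pd.DataFrame(cols).fillna(0).astype(int)
    if isinstance(marginals, Mapping):
        return (
            pd.DataFrame(
                {r: {s: counts.get(s, 0) for s in SCORE_LEVELS} for r, counts in marginals.items()}
            )
            .T.fillna(0)
            .astype(int)
        )
    raise FixtureError("marginals must be a DataFrame or mapping reader -> {score: count}")


def mean_visual_score(marginals) -> float:
    """Mean score over all ratings of one condition, pooled across readers.

    Accepts either ``{reader: {score: count}}`` or a DataFrame with a
    ``reader`` column and ``score_0..score_3`` columns.  Every reader must
    have rated the same number of patients.
    """
    table = _marginals_to_frame(marginals)
    if (table.values < 0).any():
        raise FixtureError("negative score count")
    totals = table.sum(axis=1)
    if totals.nunique() != 1:
        raise FixtureError(
            f"inconsistent per-reader totals: {totals.to_dict()} (each reader must rate every patient)"
        )
    n = int(totals.sum())
    if n == 0:
        raise FixtureError("no ratings")
    weighted = sum(int(s) * table[s].sum() for s in table.columns)
    return float(weighted) / n


def cohens_kappa(joint) -> float:
    """Unweighted Cohen's kappa from a square reader1 × reader2 table."""
    table = np.asarray(joint, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise FixtureError("joint table must be square")
    if (table < 0).any():
        raise FixtureError("joint table counts must be >= 0")
    n = table.sum()
    if n <= 0:
        raise FixtureError("joint table is empty")
    po = np.trace(table) / n
    pe = float(np.sum(table.sum(axis=0) * table.sum(axis=1))) / n**2
    if pe >= 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1 (degenerate margins)")
    return float((po - pe) / (1.0 - pe))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


def icc_absolute_single(ratings, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single rater.

    ``ratings`` is an n-subjects × k-raters matrix with no missing cells.
    The point estimate comes from the two-way ANOVA mean squares

        ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

    and the confidence interval from the McGraw–Wong F-based construction
    with a Satterthwaite-approximated denominator df.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise InsufficientDataError("ratings must be a 2-D subjects × raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise InsufficientDataError("ratings matrix contains missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise UndefinedMetricError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 0 or icc >= 1.0 - 1e-12:
        return ICCResult(float(icc), float(icc), float(icc), confidence)
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
    lower = (
        n * (msr - f_l * mse)
        / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_u * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    )
    return ICCResult(float(icc), float(lower), float(upper), confidence)


@dataclass(frozen=True)
class Detectability:
    """Lesion detectability relative to a reference condition, in percent."""

    per_reader: dict
    pooled: float
    mean_of_readers: float


def detectability_fraction(
    counts: pd.DataFrame,
    condition: tuple[float, float],
    reference_condition: tuple[float, float],
) -> Detectability:
    """Percent of reference lesions re-detected under ``condition``.

    ``counts`` is a long table with columns ``reduction_pct``, ``beta``,
    ``reader`` and ``lesions_detected``; conditions are ``(reduction_pct,
    beta)`` pairs.  Reported per reader, pooled over readers (sum/sum) and
    as the mean of the per-reader fractions.
    """
    required = {"reduction_pct", "beta", "reader", "lesions_detected"}
    if not required.issubset(counts.columns):
        raise FixtureError(f"lesion table must have columns {sorted(required)}")

    def _rows(cond):
        r, b = cond
        sel = counts[(counts["reduction_pct"] == r) & (counts["beta"] == b)]
        if sel.empty:
            raise FixtureError(f"no rows for condition {cond}")
        return sel.set_index("reader")["lesions_detected"]

    det = _rows(condition)
    ref = _rows(reference_condition)
    per_reader = {}
    for reader in det.index:
        if reader not in ref.index:
            raise FixtureError(f"reader {reader!r} missing from the reference condition")
        if ref[reader] <= 0:
            raise UndefinedMetricError(f"zero reference lesion count for reader {reader!r}")
        per_reader[reader] = 100.0 * float(det[reader]) / float(ref[reader])
    pooled = 100.0 * float(det.sum()) / float(ref[det.index].sum())
    return Detectability(per_reader, pooled, float(np.mean(list(per_reader.values()))))
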