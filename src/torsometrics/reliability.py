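"""Measurement reliability: ICC(A,1), classification bands, MAD.

The reliability statistic used to validate the measurement tool is the
two-way random-effects, absolute-agreement, *single-rater* intraclass
correlation, ICC(A,1) in McGraw & Wong's taxonomy (equivalently ICC(2,1)
in Shrout & Fleiss').  With ``n`` subjects rated once by each of ``k``
raters (a two-way layout without replication), the mean squares of the
subject x rater ANOVA give

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

where MSR, MSC, MSE are the rows (subjects), columns (raters) and
residual mean squares.  The 95% confidence interval follows McGraw &
Wong's F-based method with Satterthwaite degrees of freedom.

Interpretation bands (McGraw-Wong style thresholds): below 0.5 poor,
0.5-0.75 moderate, 0.75-0.9 good, above 0.9 excellent.  Values exactly
on 0.5 / 0.75 fall upward into moderate / good; 0.9 itself is good.
Negative ICCs are possible and reported as computed, not truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .exceptions import RatingsError, UndefinedICCError

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "icc_a1",
    "classify_icc",
    "mean_absolute_difference",
    "reliability_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatingsMatrix:
    """n subjects x k ratings, complete (no missing cells).

    Missing data is rejected rather than imputed — imputation would
    silently change the estimand.
    """

    values: np.ndarray
    subject_ids: tuple = ()
    rating_labels: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise RatingsError("ratings must be a 2D subjects x ratings array")
        n, k = v.shape
        if n < 2 or k < 2:
            raise RatingsError(f"need >= 2 subjects and >= 2 ratings (got {n}x{k})")
        if not np.isfinite(v).all():
            raise RatingsError("ratings contain missing/non-finite cells")
        object.__setattr__(self, "values", v)
        subject_ids = tuple(self.subject_ids) or tuple(range(1, n + 1))
        rating_labels = tuple(self.rating_labels) or tuple(
            f"R{j}" for j in range(1, k + 1)
        )
        if len(subject_ids) != n:
            raise RatingsError("subject_ids length mismatch")
        if len(rating_labels) != k:
            raise RatingsError("rating_labels length mismatch")
        if len(set(subject_ids)) != n:
            dupes = sorted({s for s in subject_ids if subject_ids.count(s) > 1})
            raise RatingsError(f"duplicated subject ids: {dupes}")
        object.__setattr__(self, "subject_ids", subject_ids)
        object.__setattr__(self, "rating_labels", rating_labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    """ICC(A,1) point estimate with ANOVA mean squares and 95% CI."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    ci95_low: float
    ci95_high: float
    classification: str


def classify_icc(icc: float) -> str:
    """Reliability band for an ICC value (poor/moderate/good/excellent)."""
    if icc > 1.0 + 1e-12:
        raise ValueError(f"ICC cannot exceed 1 (got {icc})")
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def _anova_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)  # guard tiny negative round-off
    return msr, msc, mse, sst


def icc_a1(ratings: RatingsMatrix, confidence: float = 0.95) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC.

    Raises :class:`UndefinedICCError` when every cell is identical
    (zero total variance leaves the agreement ratio undefined).
    """
    if isinstance(ratings, np.ndarray):
        ratings = RatingsMatrix(ratings)
    x = ratings.values
    n, k = ratings.n, ratings.k
    msr, msc, mse, sst = _anova_mean_squares(x)
    if sst <= 0:
        raise UndefinedICCError("all ratings identical: ICC undefined")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based CI with Satterthwaite df (ICC(A,1) case).
    alpha = 1.0 - confidence
    if mse <= 0 and msc <= 0:
        lo = hi = icc  # degenerate perfect-agreement case
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
        else:
            v = (n - 1) * (k - 1)
        f_lo = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_hi = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
        lo = min(lo, icc)
        hi = max(hi, icc)
    return ICCResult(
        icc=float(icc),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n=n,
        k=k,
        ci95_low=float(lo),
        ci95_high=float(hi),
        classification=classify_icc(icc),
    )


def mean_absolute_difference(a, b):
    """Mean and sample SD (n-1) of ``|a_i - b_i|``, in measurement units."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    d = np.abs(a - b)
    return float(d.mean()), float(d.std(ddof=1))


def reliability_report(measurements: pd.DataFrame) -> pd.DataFrame:
    """Intra- and inter-user ICC(A,1) per metric from a long-format table.

    ``measurements`` must have columns ``subject``, ``metric``, ``user``,
    ``session``, ``value`` — one row per measurement, complete for every
    subject x user x session combination per metric.

    For each metric the report contains one row per user comparing that
    user's sessions (intra-user, k = number of sessions), plus — when at
    least two users are present — one row comparing users on their final
    session (inter-user, k = number of users).  Returns a DataFrame with
    columns metric/comparison/icc/ci95_low/ci95_high/classification/n/k.
    """
    required = {"subject", "metric", "user", "session", "value"}
    missing = required - set(measurements.columns)
    if missing:
        raise RatingsError(f"measurements table missing columns: {sorted(missing)}")

    rows = []
    for metric, sub in measurements.groupby("metric", sort=True):
        users = sorted(sub["user"].unique())
        for user in users:
            wide = (
                sub[sub["user"] == user]
                .pivot(index="subject", columns="session", values="value")
                .sort_index()
            )
            result = icc_a1(
                RatingsMatrix(
                    wide.to_numpy(),
                    subject_ids=tuple(wide.index),
                    rating_labels=tuple(str(c) for c in wide.columns),
                )
            )
            rows.append((metric, f"intra:{user}", result))
        if len(users) >= 2:
            final_session = sub["session"].max()
            wide = (
                sub[sub["session"] == final_session]
                .pivot(index="subject", columns="user", values="value")
                .sort_index()
            )
            result = icc_a1(
                RatingsMatrix(
                    wide.to_numpy(),
                    subject_ids=tuple(wide.index),
                    rating_labels=tuple(str(c) for c in wide.columns),
                )
            )
            rows.append((metric, "inter", result))
        else:
            log.info(
                "metric %s: single user, inter-user comparison omitted", metric
            )

    return pd.DataFrame(
        [
            {
                "metric": metric,
                "comparison": comparison,
                "icc": r.icc,
                "ci95_low": r.ci95_low,
                "ci95_high": r.ci95_high,
                "classification": r.classification,
                "n": r.n,
                "k": r.k,
            }
            for metric, comparison, r in rows
        ]
    )
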