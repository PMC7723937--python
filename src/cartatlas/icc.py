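"""Intrarater reliability: ICC(2,1) with F-based confidence intervals.

Implements the two-way random effects, absolute agreement, single
measurement intraclass correlation

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

from the two-way ANOVA mean squares of an n-subject x k-trial table
(rows random subjects, columns random trials), with the McGraw-Wong
F-based 95% interval. Point estimates are classified with the Koo-Li
cutoffs: below 0.5 poor, 0.5-0.75 moderate, above 0.75 up to 0.9 good,
above 0.9 excellent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = ["RatingsTable", "ICCResult", "icc_2way_random_absolute",
           "classify_icc", "count_reliable", "load_table4_iccs",
           "icc_by_group"]


@dataclass(frozen=True)
class RatingsTable:
    """Complete n_subjects x k_trials measurement matrix (mm)."""

    values: np.ndarray
    subject_ids: tuple = ()
    parameter: str = ""
    rater: str = ""
    modality: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("values must be (n_subjects >= 2, k_trials >= 2)")
        if not np.all(np.isfinite(v)):
            raise ValueError("ratings table must be complete (no missing cells)")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    classification: str


def _mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse


def icc_2way_random_absolute(table: RatingsTable,
                             alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its F-based (1 - alpha) confidence interval."""
    x = table.values
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or np.allclose(x, x.flat[0]):
        warnings.warn("degenerate ratings table (zero total variance); "
                      "ICC defined as 1", stacklevel=2)
        return ICCResult(1.0, 1.0, 1.0, classify_icc(1.0))
    icc = (msr - mse) / denom

    # McGraw & Wong F-based interval for ICC(A,1)
    if mse == 0.0 or icc >= 1.0:
        lo, hi = icc, 1.0
    else:
        a = k * icc / (n * (1.0 - icc))
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr)
        lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(float(icc), float(lo), float(hi), classify_icc(icc))


def classify_icc(icc: float) -> str:
    """Koo-Li reliability category of an ICC point estimate."""
    if icc > 1.0 + 1e-12:
        raise ValueError("icc must be <= 1")
    if icc > 0.9:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def count_reliable(iccs, threshold: float = 0.75) -> int:
    """Number of ICC values strictly greater than ``threshold``."""
    return int(np.sum(np.asarray(list(iccs), dtype=float) > threshold))


def load_table4_iccs() -> pd.DataFrame:
    """Packaged worked-example table of published intrarater ICC point
    estimates (5 length parameters x 4 raters x 2 imaging modalities)."""
    with resources.files("cartatlas.data").joinpath("table4_icc.csv").open() as fh:
        return pd.read_csv(fh)


def icc_by_group(long_df: pd.DataFrame, value_col: str = "value_mm",
                 group_cols=("rater",)) -> pd.DataFrame:
    """Compute ICC(2,1) per group of a long-form ratings table.

    The table needs columns ``subject_id``, ``trial``, ``value_col`` and
    the grouping columns. Returns one row per group with icc, ci_low,
    ci_high and classification.
    """
    rows = []
    for key, g in long_df.groupby(list(group_cols)):
        mat = g.pivot(index="subject_id", columns="trial",
                      values=value_col).to_numpy()
        res = icc_2way_random_absolute(RatingsTable(mat))
        key = key if isinstance(key, tuple) else (key,)
        rows.append({**dict(zip(group_cols, key)), "icc": res.icc,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "classification": res.classification})
    return pd.DataFrame(rows)
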