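"""Reliability and validity statistics for device-vs-reference agreement.

Implements the agreement battery used to validate wearable accelerometry
against a mechanical reference:

* ICC(2,1) — two-way random effects, single measure, absolute agreement —
  with the exact-F 95% confidence interval of McGraw & Wong, for
  inter-device reliability (subjects = seconds, raters = co-mounted
  devices);
* Pearson product-moment correlation;
* Lin's concordance correlation coefficient (population-moment estimator)
  with a Fisher-z confidence interval using the corrected asymptotic
  variance;
* mean absolute error, mean bias with 95% limits of agreement (and an
  SE-based CI of the bias, separately labelled), Bland-Altman points;
* pooled per-brand validity summaries and per-speed error summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCResult",
    "BiasResult",
    "ValiditySummary",
    "icc_2way_random_absolute",
    "interpret_icc",
    "interpret_ccc",
    "pearson_r",
    "lins_ccc",
    "mean_absolute_error",
    "mean_bias_loa",
    "bland_altman_points",
    "summarize_validity",
    "per_speed_error_summary",
    "reliability_matrix",
    "summarize_reliability",
]

Aggregation = Literal["mean", "rms"]

_AGG_COLUMN = {"mean": "enmo_mean_mg", "rms": "enmo_rms_mg"}


def _agg_column(aggregation: str) -> str:
    try:
        return _AGG_COLUMN[aggregation]
    except KeyError:
        raise ValueError(
            f"unknown aggregation {aggregation!r}; expected 'mean' or 'rms'"
        ) from None


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int
    aggregation: str = "mean"
    interpretation: str = ""
    brand: str = ""


def interpret_icc(icc: float) -> str:
    """Reliability category for an ICC: poor / moderate / good / excellent.

    Bins: < 0.50 poor; [0.50, 0.75) moderate; [0.75, 0.90) good;
    >= 0.90 excellent (boundaries assigned to the upper category).
    """
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def interpret_ccc(ccc: float) -> str:
    """Concordance category: < 0.20 poor, >= 0.80 excellent; the
    intermediate range follows the conventional ladder (fair [0.20, 0.40),
    moderate [0.40, 0.60), good [0.60, 0.80))."""
    if not np.isfinite(ccc):
        raise ValueError("CCC must be finite")
    if ccc < 0.20:
        return "poor"
    if ccc < 0.40:
        return "fair"
    if ccc < 0.60:
        return "moderate"
    if ccc < 0.80:
        return "good"
    return "excellent"


def _two_way_mean_squares(m: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects x raters) ANOVA without
    replication: returns (MSR, MSC, MSE, n, k)."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((m - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0), n, k


def icc_2way_random_absolute(
    matrix: np.ndarray | pd.DataFrame,
    alpha: float = 0.05,
    aggregation: str = "mean",
    brand: str = "",
) -> ICCResult:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    ``matrix`` is subjects (seconds) x raters (devices); rows containing
    missing values are dropped (listwise deletion).  The point estimate is

        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    from the two-way ANOVA mean squares, and the confidence interval uses
    the exact-F method of McGraw & Wong for ICC(A,1).  Raises on fewer than
    two complete rows or columns, or on zero total variance.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 device columns")
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 2:
        raise ValueError("need at least 2 complete (no-missing) seconds")
    if np.allclose(m, m.flat[0]):
        raise ValueError("ICC undefined: zero total variance in the matrix")
    msr, msc, mse, n, k = _two_way_mean_squares(m)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    if icc >= 1.0 - 1e-12:
        lo = hi = icc
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        num_v = (a * msc + b * mse) ** 2
        den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else np.inf
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        n_subjects=n,
        k_raters=k,
        aggregation=aggregation,
        interpretation=interpret_icc(float(icc)),
        brand=brand,
    )


# ---------------------------------------------------------------------------
# Correlation / concordance
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample product-moment correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length series of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined for a zero-variance series")
    return float(stats.pearsonr(x, y).statistic)


def lins_ccc(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with 95% CI.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) with population
    (1/n) moments.  The CI applies the Fisher z-transform with the
    corrected asymptotic variance

        var(z) = [ (1-r^2) c^2 / ((1-c^2) r^2)
                   + 4 c^3 (1-c) u^2 / (r (1-c^2)^2)
                   - 2 c^4 u^4 / (r^2 (1-c^2)^2) ] / (n-2)

    where c is the CCC, r the Pearson correlation and
    u = (xbar - ybar) / sqrt(s_x s_y).  Degenerate cases (|c| = 1 or
    r = 0) collapse the interval onto the estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series of length >= 3")
    n = x.size
    sx2 = np.var(x)  # population (1/n) moments
    sy2 = np.var(y)
    if sx2 == 0 and sy2 == 0:
        raise ValueError("CCC undefined when both series are constant")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    ccc = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)

    if sx2 == 0 or sy2 == 0:
        return float(ccc), float(ccc), float(ccc)
    r = sxy / np.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-12 or r == 0 or n < 4:
        return float(ccc), float(ccc), float(ccc)
    u = (x.mean() - y.mean()) / (sx2 * sy2) ** 0.25
    c2 = ccc * ccc
    var_z = (
        (1 - r * r) * c2 / ((1 - c2) * r * r)
        + 4 * ccc**3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
        - 2 * c2 * c2 * u**4 / (r * r * (1 - c2) ** 2)
    ) / (n - 2)
    se_z = np.sqrt(max(var_z, 0.0))
    z = np.arctanh(ccc)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - zcrit * se_z), np.tanh(z + zcrit * se_z)
    return float(ccc), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Discrepancy statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasResult:
    """Mean bias with 95% limits of agreement and an SE-based 95% CI.

    ``loa_low/loa_high`` = bias +/- 1.96 x SD(differences) — the interval
    expected to contain 95% of individual differences.  ``ci_low/ci_high``
    = bias +/- 1.96 x SD/sqrt(n) — the CI of the mean difference itself.
    The two are distinct; tables of this battery conventionally print the
    limits of agreement.
    """

    bias_mg: float
    loa_low_mg: float
    loa_high_mg: float
    ci_low_mg: float
    ci_high_mg: float
    sd_mg: float
    n: int


def mean_absolute_error(x: Sequence[float], ref: Sequence[float]) -> float:
    """Mean of |x_i - ref_i| (mg)."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape or x.size < 1:
        raise ValueError("need equal-length non-empty series")
    return float(np.mean(np.abs(x - ref)))


def mean_bias_loa(x: Sequence[float], ref: Sequence[float]) -> BiasResult:
    """Mean bias (x - ref) with 95% limits of agreement and SE-based CI."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape or x.size < 2:
        raise ValueError("need equal-length series of length >= 2")
    d = x - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half_loa = 1.96 * sd
    half_ci = 1.96 * sd / np.sqrt(d.size)
    return BiasResult(
        bias_mg=bias,
        loa_low_mg=bias - half_loa,
        loa_high_mg=bias + half_loa,
        ci_low_mg=bias - half_ci,
        ci_high_mg=bias + half_ci,
        sd_mg=sd,
        n=int(d.size),
    )


def bland_altman_points(x: Sequence[float], ref: Sequence[float]) -> pd.DataFrame:
    """Per-pair (mean_of_pair_mg, difference_mg) for Bland-Altman plots."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("series lengths differ")
    return pd.DataFrame(
        {"mean_of_pair_mg": (x + ref) / 2.0, "difference_mg": x - ref}
    )


# ---------------------------------------------------------------------------
# Table-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValiditySummary:
    brand: str
    aggregation: str
    n_obs: int
    mean_mg: float
    sd_mg: float
    pearson_r: float
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    ccc_interpretation: str
    mae_mg: float
    bias_mg: float
    loa_low_mg: float
    loa_high_mg: float


def summarize_validity(table, aggregation: str = "mean") -> pd.DataFrame:
    """Per-brand validity summary pooled over devices and frequencies.

    For each brand: number of device-seconds, pooled mean and SD of the
    chosen ENMO aggregate, Pearson r against the reference, Lin's CCC with
    95% CI and interpretation, MAE, and mean bias with limits of agreement.
    """
    col = _agg_column(aggregation)
    df = table.df
    if df.empty:
        raise ValueError("cannot summarize an empty epoch table")
    rows = []
    for brand, grp in df.groupby("brand", sort=True):
        x = grp[col].to_numpy()
        ref = grp["reference_mg"].to_numpy()
        ccc, lo, hi = lins_ccc(x, ref)
        bias = mean_bias_loa(x, ref)
        rows.append(
            ValiditySummary(
                brand=str(brand),
                aggregation=aggregation,
                n_obs=len(grp),
                mean_mg=float(np.mean(x)),
                sd_mg=float(np.std(x, ddof=1)),
                pearson_r=pearson_r(x, ref),
                ccc=ccc,
                ccc_ci_low=lo,
                ccc_ci_high=hi,
                ccc_interpretation=interpret_ccc(ccc),
                mae_mg=mean_absolute_error(x, ref),
                bias_mg=bias.bias_mg,
                loa_low_mg=bias.loa_low_mg,
                loa_high_mg=bias.loa_high_mg,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def per_speed_error_summary(table, aggregation: str = "mean") -> pd.DataFrame:
    """MAE and mean bias per brand and oscillation frequency, with SEs."""
    col = _agg_column(aggregation)
    df = table.df
    if df.empty:
        raise ValueError("cannot summarize an empty epoch table")
    rows = []
    for (brand, f), grp in df.groupby(["brand", "frequency_hz"], sort=True):
        d = grp[col].to_numpy() - grp["reference_mg"].to_numpy()
        n = len(d)
        rows.append(
            {
                "brand": str(brand),
                "aggregation": aggregation,
                "frequency_hz": float(f),
                "n_obs": n,
                "mae_mg": float(np.mean(np.abs(d))),
                "mae_se_mg": float(np.std(np.abs(d), ddof=1) / np.sqrt(n))
                if n > 1
                else np.nan,
                "bias_mg": float(np.mean(d)),
                "bias_se_mg": float(np.std(d, ddof=1) / np.sqrt(n))
                if n > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def reliability_matrix(
    table,
    aggregation: str = "mean",
    device_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Pivot one reliability batch into a seconds x devices matrix.

    Rows are (trial_id, frequency_hz, second_index) epochs, columns the
    co-mounted devices in clamp order (``device_order``, default sorted
    device ids).  Missing device-seconds appear as NaN.
    """
    col = _agg_column(aggregation)
    df = table.df
    if device_order is None:
        device_order = sorted(df["device_id"].unique())
    wide = df.pivot_table(
        index=["trial_id", "frequency_hz", "second_index"],
        columns="device_id",
        values=col,
        aggfunc="first",
    )
    return wide.reindex(columns=list(device_order)).to_numpy()


def summarize_reliability(
    batch_matrices: Sequence[np.ndarray],
    aggregation: str = "mean",
    alpha: float = 0.05,
    brand: str = "",
) -> ICCResult:
    """One ICC(2,1) per brand from one or more reliability batches.

    Each batch is a seconds x 5 (clamp positions) matrix from one group of
    co-mounted devices; batches are stacked as additional subjects with
    columns indexed by clamp position, so ten physical devices tested five
    at a time yield a single brand-level ICC.  Rows with missing values are
    dropped listwise inside :func:`icc_2way_random_absolute`.
    """
    mats = [np.asarray(m, dtype=float) for m in batch_matrices]
    if not mats:
        raise ValueError("need at least one batch matrix")
    k = mats[0].shape[1]
    if any(m.shape[1] != k for m in mats):
        raise ValueError("all batches must have the same number of device columns")
    stacked = np.vstack(mats)
    return icc_2way_random_absolute(
        stacked, alpha=alpha, aggregation=aggregation, brand=brand
    )
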