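"""Reproducibility statistics for patient x reader x method tables.

Implements the analysis stage of a multi-laboratory infarct-size
reproducibility study:

* per-patient averaged absolute between-reader differences, and the
  coefficient of variation CV = 100 * SD(averaged differences) / mean
  method measurement;
* the two-way random-effects, absolute-agreement, single-measurement
  intraclass correlation ICC(2,1) with an F-based 95% CI;
* Bland-Altman bias, SD and 95% limits of agreement per reader pair,
  with a paired t-test for systematic offset;
* one-way variance components: between-patient sigma_T^2 and
  within-patient (method/reader) sigma_e^2, and the within share of
  total variance;
* the two-arm sample size n = 2 sigma^2 (z_{alpha/2} + z_beta)^2 /
  delta^2 for detecting an absolute infarct-size difference delta;
* Pearson correlation between per-patient image quality (SNR/CNR) and
  per-patient measurement variability.

The measurement table is a pandas DataFrame with columns
(patient, reader, method, percent_lv, mass_g, lv_mass_g).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class BlandAltman:
    reader_a: str
    reader_b: str
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    p_value: float


@dataclass
class ReproReport:
    """Per-method reproducibility summary."""

    method: str
    mean_size: float
    sd_size: float
    mean_abs_diff: float
    sd_of_diffs: float
    cv: float
    icc: float
    icc_ci: tuple[float, float]
    bland_altman: list[BlandAltman]
    sigma_T2: float
    sigma_e2: float
    within_share: float
    sample_sizes: dict[float, int] = field(default_factory=dict)


@dataclass
class SampleSizeSpec:
    """Inputs of the two-arm sample-size formula.

    delta is the expected absolute reduction in infarct size (%LV),
    sigma the SD of infarct size (total, or its between-patient and
    method components sigma_T / sigma_e combined in quadrature), alpha
    the two-sided type-I and beta the type-II error rate.
    """

    delta: float
    sigma: float | None = None
    alpha: float = 0.05
    beta: float = 0.2
    sigma_T: float | None = None
    sigma_e: float | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.sigma is None:
            if self.sigma_T is None or self.sigma_e is None:
                raise ValueError("provide sigma, or both sigma_T and sigma_e")
            self.sigma = math.hypot(self.sigma_T, self.sigma_e)


def _method_pivot(table: pd.DataFrame, method: str) -> pd.DataFrame:
    sub = table[table["method"] == method]
    if sub.empty:
        raise ValueError(f"no measurements for method {method!r}")
    piv = sub.pivot(index="patient", columns="reader", values="percent_lv")
    if piv.isna().any().any():
        missing = piv[piv.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete reader crossing for patients {missing}")
    return piv


def per_patient_diffs(table: pd.DataFrame, method: str) -> tuple[np.ndarray, float, float]:
    """Per-patient mean absolute between-reader difference, and its mean/SD.

    For each patient, all reader pairs' absolute differences are
    averaged; the population mean and SD (n-1) of these per-patient
    values are returned alongside the per-patient vector.
    """
    piv = _method_pivot(table, method)
    if piv.shape[1] < 2:
        raise ValueError("need at least 2 readers")
    vals = piv.to_numpy()
    pair_means = np.mean(
        [np.abs(vals[:, i] - vals[:, j]) for i, j in combinations(range(vals.shape[1]), 2)],
        axis=0,
    )
    return pair_means, float(pair_means.mean()), float(pair_means.std(ddof=1))


def cv(table: pd.DataFrame, method: str) -> float:
    """CV (%) = 100 * SD(per-patient averaged differences) / mean size."""
    _, _, sd_diffs = per_patient_diffs(table, method)
    mean_size = float(table.loc[table["method"] == method, "percent_lv"].mean())
    if mean_size <= 0:
        raise ValueError("method mean must be positive for CV")
    return 100.0 * sd_diffs / mean_size


def icc(table: pd.DataFrame, method: str, ci: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from two-way ANOVA mean squares; the CI uses the F-based
    formulas of McGraw & Wong with a Satterthwaite-approximated
    denominator df.
    """
    piv = _method_pivot(table, method)
    x = piv.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 patients and 2 readers")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0, (1.0, 1.0)
    value = (msr - mse) / denom

    alpha = 1 - ci
    a = k * value / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
    if not np.isfinite(a):
        return float(value), (1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
    if not np.isfinite(v) or v <= 0:
        return float(value), (float("nan"), float("nan"))
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return float(value), (float(lower), float(upper))


def bland_altman(
    table: pd.DataFrame, method: str, reader_pair: tuple[str, str]
) -> BlandAltman:
    """Bias, SD and 95% limits of agreement between two readers."""
    piv = _method_pivot(table, method)
    a, b = reader_pair
    d = (piv[a] - piv[b]).to_numpy(dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 patients")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return BlandAltman(
        reader_a=a,
        reader_b=b,
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        p_value=p,
    )


def variance_components(table: pd.DataFrame, method: str) -> tuple[float, float, float]:
    """One-way random-effects variance components (sigma_T^2, sigma_e^2, within share).

    sigma_e^2 is the within-patient mean square; sigma_T^2 the
    moment estimator max(0, (MS_between - MS_within)/k).  The within
    share is sigma_e^2 / (sigma_T^2 + sigma_e^2), guarded to 0 for a
    constant table.
    """
    piv = _method_pivot(table, method)
    x = piv.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 patients")
    row_means = x.mean(axis=1)
    ms_between = k * row_means.var(ddof=1)
    ms_within = float(np.mean(x.var(axis=1, ddof=1)))
    sigma_e2 = ms_within
    sigma_T2 = max(0.0, (ms_between - ms_within) / k)
    total = sigma_T2 + sigma_e2
    share = sigma_e2 / total if total > 0 else 0.0
    return float(sigma_T2), float(sigma_e2), float(share)


def sample_size(spec: SampleSizeSpec) -> int:
    """Two-arm n = ceil(2 sigma^2 (z_{alpha/2} + z_beta)^2 / delta^2)."""
    if spec.sigma == 0:
        warnings.warn("zero variance: sample size is 0", stacklevel=2)
        return 0
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(1 - spec.beta)
    return int(math.ceil(2 * spec.sigma**2 * (z_a + z_b) ** 2 / spec.delta**2))


def sample_size_exact(spec: SampleSizeSpec) -> float:
    """The same formula before rounding (for scaling-law checks)."""
    if spec.sigma == 0:
        return 0.0
    z_a = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(1 - spec.beta)
    return float(2 * spec.sigma**2 * (z_a + z_b) ** 2 / spec.delta**2)


def quality_correlation(
    variability: np.ndarray, quality: np.ndarray
) -> tuple[float, float, float]:
    """Pearson r (and least-squares slope/intercept) of variability vs quality."""
    variability = np.asarray(variability, dtype=float)
    quality = np.asarray(quality, dtype=float)
    if len(variability) != len(quality) or len(variability) < 3:
        raise ValueError("need equal-length lists with n >= 3")
    if variability.std() == 0 or quality.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(stats.pearsonr(quality, variability).statistic)
    slope, intercept = np.polyfit(quality, variability, 1)
    return r, float(slope), float(intercept)


def run_reproducibility(
    table: pd.DataFrame,
    deltas: tuple[float, ...] = (3.0, 5.0, 7.0),
    sigma_mode: str = "total",
) -> dict[str, ReproReport]:
    """Assemble a full per-method reproducibility report.

    ``sigma_mode`` selects the sample-size SD: 'total' uses
    sqrt(sigma_T^2 + sigma_e^2), 'between' uses sigma_T alone.
    """
    if sigma_mode not in ("total", "between"):
        raise ValueError("sigma_mode must be 'total' or 'between'")
    reports: dict[str, ReproReport] = {}
    for method in sorted(table["method"].unique()):
        piv = _method_pivot(table, method)
        readers = sorted(piv.columns)
        _, mean_diff, sd_diffs = per_patient_diffs(table, method)
        method_vals = table.loc[table["method"] == method, "percent_lv"]
        icc_val, icc_ci = icc(table, method)
        sT2, se2, share = variance_components(table, method)
        sigma = math.sqrt(sT2 + se2) if sigma_mode == "total" else math.sqrt(sT2)
        sizes = {
            d: sample_size(SampleSizeSpec(delta=d, sigma=sigma)) for d in deltas
        }
        reports[method] = ReproReport(
            method=method,
            mean_size=float(method_vals.mean()),
            sd_size=float(method_vals.std(ddof=1)),
            mean_abs_diff=mean_diff,
            sd_of_diffs=sd_diffs,
            cv=cv(table, method),
            icc=icc_val,
            icc_ci=icc_ci,
            bland_altman=[
                bland_altman(table, method, (a, b))
                for a, b in combinations(readers, 2)
            ],
            sigma_T2=sT2,
            sigma_e2=se2,
            within_share=share,
            sample_sizes=sizes,
        )
    return reports


def report_frame(reports: dict[str, ReproReport]) -> pd.DataFrame:
    """Flatten reports into a summary DataFrame (one row per method)."""
    rows = []
    for m, r in reports.items():
        row = {
            "method": m,
            "mean_size": r.mean_size,
            "sd_size": r.sd_size,
            "mean_abs_diff": r.mean_abs_diff,
            "sd_of_diffs": r.sd_of_diffs,
            "cv_percent": r.cv,
            "icc": r.icc,
            "icc_ci_low": r.icc_ci[0],
            "icc_ci_high": r.icc_ci[1],
            "sigma_T2": r.sigma_T2,
            "sigma_e2": r.sigma_e2,
            "within_share": r.within_share,
        }
        for d, n in r.sample_sizes.items():
            row[f"n_delta_{d:g}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
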