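"""Stage 1 preprocessing: per-day boxplot outlier masking and predictive
mean matching (PMM) imputation that borrows strength from the whole series.

Outliers are judged per day against Tukey fences computed over all genotypes
and replicates of that day; flagged cells become missing and are later
imputed together with the originally missing cells.  PMM imputes each day
from the remaining days: a day-on-other-days regression with sampled
coefficients produces predictions, and each missing cell receives the
observed value of one of the k donors whose predictions are closest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PhenoMatrix

__all__ = ["OutlierReport", "boxplot_fences", "detect_outliers", "impute_pmm"]

#: maximum per-day missing fraction PMM will accept
MAX_MISSING_FRACTION = 0.75

#: ridge penalty applied to standardized predictors for numerical stability
RIDGE = 1e-5


@dataclass
class OutlierReport:
    per_day_counts: dict  # day -> flagged count
    fences: dict  # day -> (lower, upper)
    total_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "day": d,
                "lower": self.fences[d][0],
                "upper": self.fences[d][1],
                "n_flagged": self.per_day_counts[d],
            }
            for d in self.per_day_counts
        ]
        return pd.DataFrame(rows)


def boxplot_fences(values) -> tuple[float, float]:
    """Tukey fences (QR1 - 1.5*IQR, QR3 + 1.5*IQR) of the non-missing values.

    Quantiles use linear interpolation (the common "type 7" convention).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("boxplot_fences needs at least one non-missing value")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return q1 - 1.5 * iqr, q3 + 1.5 * iqr


def detect_outliers(pheno: PhenoMatrix) -> tuple[PhenoMatrix, OutlierReport]:
    """Mask per-day boxplot outliers (strictly outside the fences) as missing."""
    out = pheno.copy()
    vals = out.values.to_numpy(copy=True)
    counts: dict = {}
    fences: dict = {}
    n_flagged = 0
    for j, day in enumerate(out.days):
        col = vals[:, j]
        obs = ~np.isnan(col)
        if not obs.any():
            warnings.warn(f"day {day} has no observed values; passed through")
            counts[day] = 0
            fences[day] = (np.nan, np.nan)
            continue
        lo, hi = boxplot_fences(col[obs])
        flag = obs & ((col < lo) | (col > hi))
        vals[flag, j] = np.nan
        counts[day] = int(flag.sum())
        fences[day] = (lo, hi)
        n_flagged += int(flag.sum())
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.days)
    report = OutlierReport(counts, fences, n_flagged / vals.size)
    return out, report


def _fit_day_regression(
    y: np.ndarray, preds: np.ndarray, obs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One sampled-coefficient regression of a day on the other days.

    Returns predictions for all rows computed with coefficients drawn from
    the fitted coefficients' sampling distribution (sigma^2 from a scaled
    inverse-chi-square on the residual sum of squares, then a Gaussian
    centered at the estimates), plus the point predictions.  Predictors are
    standardized and carry a tiny ridge penalty so the system is always
    solvable.
    """
    n_fit = int(obs.sum())
    mu = preds[obs].mean(axis=0)
    sd = preds[obs].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z_all = (preds - mu) / sd
    x_fit = np.column_stack([np.ones(n_fit), z_all[obs]])
    p = x_fit.shape[1]
    xtx = x_fit.T @ x_fit
    pen = np.eye(p) * RIDGE
    pen[0, 0] = 0.0  # no penalty on the intercept
    a = xtx + pen
    a_inv = np.linalg.inv(a)
    beta = a_inv @ (x_fit.T @ y[obs])
    resid = y[obs] - x_fit @ beta
    rss = float(resid @ resid)
    df = max(n_fit - p, 1)
    sigma2 = rss / max(rng.chisquare(df), 1e-12)
    cov = sigma2 * a_inv
    # draw coefficients from N(beta, sigma2 * (X'X + ridge)^-1)
    chol = np.linalg.cholesky(cov + np.eye(p) * 1e-12)
    beta_star = beta + chol @ rng.standard_normal(p)
    x_all = np.column_stack([np.ones(len(z_all)), z_all])
    return x_all @ beta_star, x_all @ beta


def impute_pmm(pheno: PhenoMatrix, m: int = 5, k: int = 5, seed: int = 0) -> PhenoMatrix:
    """Predictive-mean-matching imputation of every missing cell.

    For each day with missing cells, the other days form the predictor set.
    A linear regression (fit on rows where the day is observed, with missing
    predictor cells mean-filled in a single pass) yields predictions under
    sampled coefficients; each missing cell then receives the observed value
    of one of the ``k`` donors whose predictions are closest to its own.
    The procedure is repeated ``m`` times and the completed matrices are
    pooled by cell-wise mean.  Observed cells are never modified.
    """
    if m < 1 or k < 1:
        raise ValueError("m and k must be >= 1")
    vals = pheno.values.to_numpy(copy=True)
    n_plots, n_days = vals.shape
    miss = np.isnan(vals)
    if not miss.any():
        return pheno.copy()
    frac = miss.mean(axis=0)
    bad = [pheno.days[j] for j in range(n_days) if frac[j] == 1.0]
    if bad:
        raise ValueError(
            f"day(s) {bad} have no observed values and cannot supply donors; "
            "exclude them before imputation"
        )
    too_missing = [pheno.days[j] for j in range(n_days) if frac[j] > MAX_MISSING_FRACTION]
    if too_missing:
        raise ValueError(
            f"day(s) {too_missing} exceed {MAX_MISSING_FRACTION:.0%} missing values, "
            "beyond what predictive mean matching can reliably handle; "
            "exclude them or impute another way"
        )
    n_obs_per_day = (~miss).sum(axis=0)
    if (n_obs_per_day < k).any():
        raise ValueError(f"every day needs at least k={k} observed values")

    # single-pass mean fill of the predictor copy (original values untouched)
    col_means = np.nanmean(vals, axis=0)
    filled = np.where(miss, col_means[None, :], vals)

    rng = np.random.default_rng(seed)
    stacks = np.zeros((m, n_plots, n_days))
    for imp in range(m):
        completed = vals.copy()
        for j in range(n_days):
            mis_rows = np.nonzero(miss[:, j])[0]
            if len(mis_rows) == 0:
                continue
            obs = ~miss[:, j]
            preds = np.delete(filled, j, axis=1)
            yhat_star, _ = _fit_day_regression(vals[:, j], preds, obs, rng)
            obs_rows = np.nonzero(obs)[0]
            obs_pred = yhat_star[obs_rows]
            # k closest observed predictions per missing row (stable order),
            # then one uniform donor draw per missing row
            d = np.abs(obs_pred[None, :] - yhat_star[mis_rows][:, None])
            donor_sets = np.argsort(d, axis=1, kind="stable")[:, :k]
            picks = rng.integers(k, size=len(mis_rows))
            donors = obs_rows[donor_sets[np.arange(len(mis_rows)), picks]]
            completed[mis_rows, j] = vals[donors, j]
        stacks[imp] = completed
    pooled = stacks.mean(axis=0)
    pooled[~miss] = vals[~miss]  # observed cells pass through bit-exactly
    out = pheno.copy()
    out.values = pd.DataFrame(pooled, index=pheno.values.index, columns=pheno.days)
    return out
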