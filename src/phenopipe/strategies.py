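"""Strategies S1-S9: from raw plot x day data to genotype adjusted-mean series.

Each strategy toggles per-day boxplot outlier masking, PMM imputation and
the spatial surface of the mixed model; S9 is the single-step alternative
that instead cleans each day by iterative Grubbs deletion on the model
residuals and lets the mixed model drop whatever is missing.

    S1  - - -        S5  - - spatial
    S2  O - -        S6  O - spatial
    S3  - I -        S7  - I spatial
    S4  O I -        S8  O I spatial
    S9  single-step mixed model (spatial)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .preprocessing import detect_outliers, impute_pmm
from .spatial import DesignMatrices, ModelSpec, fit_day, grubbs_clean, heritability
from .synthetic import PhenoMatrix, TrialDesign

__all__ = ["Strategy", "GBlueSeries", "LogisticFit", "run_strategy", "fit_logistic"]

_TABLE = {
    "S1": (False, False, False, False),
    "S2": (True, False, False, False),
    "S3": (False, True, False, False),
    "S4": (True, True, False, False),
    "S5": (False, False, True, False),
    "S6": (True, False, True, False),
    "S7": (False, True, True, False),
    "S8": (True, True, True, False),
    "S9": (False, False, True, True),
}


@dataclass(frozen=True)
class Strategy:
    name: str
    outlier_detection: bool
    imputation: bool
    spatial: bool
    single_step: bool = False

    @classmethod
    def from_name(cls, name: str) -> "Strategy":
        key = name.upper()
        if key not in _TABLE:
            raise ValueError(f"unknown strategy {name!r}; expected S1..S9")
        o, i, s, ss = _TABLE[key]
        return cls(key, o, i, s, ss)

    def __post_init__(self):
        if self.single_step and (
            not self.spatial or self.outlier_detection or self.imputation
        ):
            raise ValueError("single-step strategy implies spatial=True and no preprocessing")


@dataclass
class GBlueSeries:
    """Genotype x day adjusted means plus the per-day heritability series."""

    genotypes: list
    days: list
    blues: pd.DataFrame  # genotypes x days
    h2_series: pd.Series  # day -> h2 (NaN where not computed)
    strategy: Strategy

    def to_frame(self) -> pd.DataFrame:
        return self.blues


def run_strategy(
    pheno: PhenoMatrix,
    design: TrialDesign,
    strategy: Strategy | str,
    seed: int = 0,
    days: list | None = None,
    compute_h2: bool = True,
    grubbs_alpha: float = 0.05,
) -> GBlueSeries:
    """Apply one Table-of-strategies pipeline over a time series.

    Order of operations: outlier masking (if flagged) -> PMM imputation (if
    flagged) -> per-day mixed-model fit with genotype fixed for the adjusted
    means, plus a second random-genotype fit per day for the heritability
    series (skipped when ``compute_h2`` is false).  ``days`` restricts the
    fitted days (preprocessing always sees the full series).
    """
    if isinstance(strategy, str):
        strategy = Strategy.from_name(strategy)
    work = pheno
    if strategy.outlier_detection:
        work, _ = detect_outliers(work)
    if strategy.imputation:
        work = impute_pmm(work, seed=seed)

    spec_fixed = ModelSpec(genotype_role="fixed", include_spatial=strategy.spatial)
    spec_random = ModelSpec(genotype_role="random", include_spatial=strategy.spatial)
    dm_fixed = DesignMatrices(design, spec_fixed)
    dm_random = DesignMatrices(design, spec_random) if compute_h2 else None

    fit_days = list(days) if days is not None else list(work.days)
    genotypes = design.genotypes
    blues = pd.DataFrame(np.nan, index=genotypes, columns=fit_days)
    h2 = pd.Series(np.nan, index=fit_days, dtype=float)
    init_f = init_r = None
    for day in fit_days:
        y = work.values[day]
        try:
            if strategy.single_step:
                y = grubbs_clean(y, design, spec_fixed, alpha=grubbs_alpha, dm=dm_fixed)
            fit = fit_day(y, design, spec_fixed, dm=dm_fixed, day_label=day, init=init_f)
            init_f = fit.varcomps
            blues[day] = fit.blues
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"day {day}: adjusted-mean fit failed ({exc}); recorded missing")
            continue
        if compute_h2:
            try:
                rfit = fit_day(
                    y, design, spec_random, dm=dm_random, day_label=day, init=init_r
                )
                init_r = rfit.varcomps
                h2[day] = heritability(rfit, spec_random)
            except (np.linalg.LinAlgError, ValueError) as exc:
                warnings.warn(f"day {day}: heritability fit failed ({exc})")
    return GBlueSeries(genotypes, fit_days, blues, h2, strategy)


@dataclass
class LogisticFit:
    asymptote: float
    rate: float
    midpoint: float
    r2: float
    converged: bool


def _logistic(t, a, k, t0):
    return a / (1.0 + np.exp(-np.clip(k * (t - t0), -500, 500)))


def fit_logistic(series, t=None) -> LogisticFit:
    """Least-squares 3-parameter logistic fit A / (1 + exp(-k (t - t0))).

    ``series`` is a day-ordered vector of one genotype's adjusted means
    (NaN allowed); ``t`` defaults to 0..n-1.  Initialization: the asymptote
    from the series maximum, the midpoint from the half-maximum crossing,
    and the rate from the log-linear slope between 20% and 80% of the
    asymptote.  A failed fit is returned flagged, with NaN parameters.
    """
    y = np.asarray(series, dtype=float)
    if t is None:
        t = np.arange(len(y), dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    keep = ~np.isnan(y)
    y, t = y[keep], t[keep]
    if len(y) == 0:
        raise ValueError("all values missing")
    if len(y) < 4:
        raise ValueError("need at least 4 non-missing points")

    sstot = float(np.sum((y - y.mean()) ** 2))
    a0 = max(float(np.max(y)), 1e-6)
    above = np.nonzero(y >= a0 / 2)[0]
    t00 = t[above[0]] if len(above) else float(np.median(t))
    band = (y > 0.2 * a0) & (y < 0.8 * a0)
    if band.sum() >= 2:
        logit = np.log(y[band] / (a0 - y[band]))
        slope = np.polyfit(t[band], logit, 1)[0]
        k0 = float(slope) if slope > 0 else 0.5
    else:
        k0 = 0.5
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            y,
            p0=[a0, k0, t00],
            bounds=([1e-8, 1e-8, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False)
    ssres = float(np.sum((y - _logistic(t, *popt)) ** 2))
    r2 = 0.0 if sstot < 1e-12 else 1.0 - ssres / sstot
    return LogisticFit(float(popt[0]), float(popt[1]), float(popt[2]), r2, True)
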