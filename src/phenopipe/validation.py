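"""Evaluation machinery: cross validation, between-experiment correlation,
and the missing/noise robustness simulation.

The robustness study mirrors the pipeline's stress test: pick a clean
reference day, compute its spatially adjusted genotype means, contaminate
the whole series with missing values and/or additive noise at increasing
rates, rerun each strategy, and correlate the recomputed means for the
reference day with the clean reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ttest_1samp

from .preprocessing import detect_outliers, impute_pmm
from .spatial import DesignMatrices, ModelSpec, fit_day, grubbs_clean, heritability, predict_validation
from .strategies import Strategy, run_strategy
from .synthetic import PhenoMatrix, TrialDesign, inject_missing, inject_noise

__all__ = [
    "CVReport",
    "SimReport",
    "cross_validate",
    "between_experiment_corr",
    "robustness_simulation",
]


def _child_seed(seed: int, *idx) -> int:
    import hashlib

    digest = hashlib.blake2b(
        "|".join(repr(i) for i in idx).encode(), digest_size=4
    ).digest()
    ss = np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
    return int(ss.generate_state(1)[0] % 2**31)


def _pearson(a: pd.Series, b: pd.Series) -> float:
    j = a.notna() & b.notna()
    if int(j.sum()) < 3:
        return np.nan
    return float(pearsonr(a[j], b[j])[0])


@dataclass
class CVReport:
    records: pd.DataFrame  # strategy, replicate, fold, day, rho, h2
    means: pd.DataFrame  # per strategy: mean rho, mean h2
    treatment_tests: pd.DataFrame  # treatment, mean_on, mean_off, diff, p

    def to_frame(self) -> pd.DataFrame:
        return self.records


@dataclass
class SimReport:
    records: pd.DataFrame  # scenario, x, strategy, rep, corr
    summary: pd.DataFrame  # scenario, x, strategy, mean_corr, sd_corr, n_rep

    def to_frame(self) -> pd.DataFrame:
        return self.summary


def cross_validate(
    pheno: PhenoMatrix,
    design: TrialDesign,
    strategies,
    n_rep: int = 10,
    n_fold: int = 5,
    seed: int = 0,
) -> CVReport:
    """Replicated k-fold cross validation of the per-day mixed model.

    Each replicate randomly selects a day; that day's observed plots are
    partitioned into ``n_fold`` folds reused identically across strategies.
    Per fold, each strategy's preprocessing is applied with the validation
    responses masked, the model is fitted on the estimation portion, the
    fold is predicted from the design and genotype information, and the
    Pearson correlation with the held-out observations plus the training
    heritability are recorded — n_rep x n_fold values per strategy.
    """
    strategies = [Strategy.from_name(s) if isinstance(s, str) else s for s in strategies]
    rng = np.random.default_rng(seed)
    rows = []
    days = list(pheno.days)
    dms: dict = {}
    for rep in range(n_rep):
        day = days[rng.integers(len(days))]
        col = pheno.values[day]
        obs_plots = col.index[col.notna()].to_numpy()
        if len(obs_plots) < n_fold:
            raise ValueError(f"day {day} has fewer than {n_fold} observations")
        perm = rng.permutation(obs_plots)
        folds = np.array_split(perm, n_fold)
        for f, fold_plots in enumerate(folds):
            if len(fold_plots) < 2:
                raise ValueError("fold with fewer than 2 observations")
            for strat in strategies:
                seed_sf = _child_seed(seed, "cv", rep, f, strat.name)
                work = pheno.copy()
                work.values.loc[fold_plots, day] = np.nan
                if strat.outlier_detection:
                    work, _ = detect_outliers(work)
                if strat.imputation:
                    work = impute_pmm(work, seed=seed_sf)
                y_train = work.values[day].copy()
                y_train.loc[fold_plots] = np.nan  # imputation must not leak folds

                spec_f = ModelSpec(genotype_role="fixed", include_spatial=strat.spatial)
                spec_r = ModelSpec(genotype_role="random", include_spatial=strat.spatial)
                for spec in (spec_f, spec_r):
                    dms.setdefault((spec.genotype_role, spec.include_spatial), DesignMatrices(design, spec))
                if strat.single_step:
                    y_train = grubbs_clean(
                        y_train, design, spec_f, dm=dms[("fixed", True)]
                    )
                fit = fit_day(
                    y_train, design, spec_f, dm=dms[(spec_f.genotype_role, spec_f.include_spatial)], day_label=day
                )
                pred = predict_validation(fit, fold_plots)
                rho = _pearson(pred, col.loc[fold_plots])
                rfit = fit_day(
                    y_train, design, spec_r, dm=dms[(spec_r.genotype_role, spec_r.include_spatial)], day_label=day
                )
                h2 = heritability(rfit, spec_r)
                rows.append(
                    {
                        "strategy": strat.name,
                        "replicate": rep,
                        "fold": f,
                        "day": day,
                        "rho": rho,
                        "h2": h2,
                    }
                )
    records = pd.DataFrame(rows)
    means = records.groupby("strategy")[["rho", "h2"]].mean()
    treatment_tests = _treatment_tests(records)
    return CVReport(records, means, treatment_tests)


_TREATMENTS = {
    "outlier_detection": (["S2", "S4", "S6", "S8"], ["S1", "S3", "S5", "S7"]),
    "imputation": (["S3", "S4", "S7", "S8"], ["S1", "S2", "S5", "S6"]),
    "spatial": (["S5", "S6", "S7", "S8"], ["S1", "S2", "S3", "S4"]),
}


def _treatment_tests(records: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of each treatment from per-fold on/off differences."""
    rows = []
    have = set(records["strategy"])
    for treatment, (on, off) in _TREATMENTS.items():
        on = [s for s in on if s in have]
        off = [s for s in off if s in have]
        if not on or not off:
            continue
        piv = records.pivot_table(
            index=["replicate", "fold"], columns="strategy", values="rho"
        )
        diffs = piv[on].mean(axis=1) - piv[off].mean(axis=1)
        diffs = diffs.dropna()
        if len(diffs) < 2:
            continue
        t, p = ttest_1samp(diffs, 0.0)
        rows.append(
            {
                "treatment": treatment,
                "mean_on": float(piv[on].mean(axis=1).mean()),
                "mean_off": float(piv[off].mean(axis=1).mean()),
                "diff": float(diffs.mean()),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def between_experiment_corr(series_a, series_b, day_pairs=None):
    """Per-day Pearson correlation of genotype means across two experiments.

    ``day_pairs`` lists matched (day_a, day_b) labels; by default days are
    matched by position.  Days sharing fewer than 3 genotypes with data in
    both experiments are skipped with a warning.  Returns (per-day Series,
    mean).
    """
    ba, bb = series_a.blues, series_b.blues
    common = ba.index.intersection(bb.index)
    if len(common) == 0:
        raise ValueError("no shared genotypes between the two series")
    if day_pairs is None:
        day_pairs = list(zip(ba.columns, bb.columns))
    out = {}
    for da, db in day_pairs:
        rho = _pearson(ba.loc[common, da], bb.loc[common, db])
        if np.isnan(rho):
            warnings.warn(f"day pair ({da}, {db}) skipped: <3 shared genotypes with data")
            continue
        out[(da, db)] = rho
    per_day = pd.Series(out)
    return per_day, float(per_day.mean()) if len(per_day) else np.nan


def robustness_simulation(
    pheno_clean: PhenoMatrix,
    design: TrialDesign,
    reference_day: int,
    strategies=("S5", "S6", "S7", "S8", "S9"),
    x_levels=(0.1, 0.2, 0.3, 0.4, 0.5),
    scenarios=("missing", "noise", "both"),
    n_rep: int = 10,
    scale_mult: float = 3.0,
    seed: int = 0,
) -> SimReport:
    """Missing/noise robustness study against clean reference genotype means.

    The reference day (an index into the series) must be complete; its
    spatially adjusted genotype means are computed once on the clean data.
    Per repeat, scenario and rate x, the whole series is contaminated
    (missing cells, additive N(0, scale_mult * day variance) noise, or
    both, drawn independently), each strategy is rerun, and the Pearson
    correlation between the recomputed and reference means on that day is
    recorded.
    """
    strategies = [s if isinstance(s, str) else s.name for s in strategies]
    ref_label = pheno_clean.days[reference_day]
    if pheno_clean.values[ref_label].isna().any():
        raise ValueError(f"reference day {ref_label} contains missing values")
    ref_fit = fit_day(
        pheno_clean.values[ref_label],
        design,
        ModelSpec(genotype_role="fixed", include_spatial=True),
        day_label=ref_label,
    )
    reference = ref_fit.blues

    rows = []
    for scenario in scenarios:
        for x in x_levels:
            for rep in range(n_rep):
                s_noise = _child_seed(seed, scenario, x, rep, "noise")
                s_miss = _child_seed(seed, scenario, x, rep, "miss")
                contaminated = pheno_clean
                if scenario in ("noise", "both"):
                    contaminated = inject_noise(contaminated, x, scale_mult, s_noise)
                if scenario in ("missing", "both"):
                    contaminated = inject_missing(contaminated, x, s_miss)
                for strat in strategies:
                    s_run = _child_seed(seed, scenario, x, rep, strat)
                    try:
                        series = run_strategy(
                            contaminated,
                            design,
                            strat,
                            seed=s_run,
                            days=[ref_label],
                            compute_h2=False,
                        )
                        corr = _pearson(series.blues[ref_label], reference)
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        warnings.warn(
                            f"{strat} scenario={scenario} x={x} rep={rep} failed: {exc}"
                        )
                        corr = np.nan
                    rows.append(
                        {
                            "scenario": scenario,
                            "x": x,
                            "strategy": strat,
                            "rep": rep,
                            "corr": corr,
                        }
                    )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["scenario", "x", "strategy"])["corr"]
        .agg(mean_corr="mean", sd_corr="std", n_rep="count")
        .reset_index()
    )
    return SimReport(records, summary)
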