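"""Synthetic trial generator with known ground truth.

Emulates plot-based outdoor laser-scanner phenotyping trials: an alpha
(resolvable incomplete block) layout on a row/column grid, logistic genotype
growth curves, a smooth spatial surface plus row/column effects, and iid
measurement error calibrated to a target single-day heritability.  Every
downstream pipeline stage can therefore be tested against the exact genotype
effects, surface and noise that generated the data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "TrialDesign",
    "TruthRecord",
    "PhenoMatrix",
    "make_design",
    "simulate_trial",
    "inject_missing",
    "inject_noise",
]


@dataclass
class TrialDesign:
    """Plot layout of one experiment.

    ``table`` holds one row per plot with columns
    ``plot_id, genotype, replicate, block, row, col``.  Blocks are nested in
    replicates; ``(row, col)`` pairs are unique grid coordinates (1-based).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["plot_id", "genotype", "replicate", "block", "row", "col"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        coords = list(zip(self.table["row"], self.table["col"]))
        if len(set(coords)) != len(coords):
            dup = pd.Series(coords)[pd.Series(coords).duplicated()].iloc[0]
            ids = self.table.loc[[c == dup for c in coords], "plot_id"].tolist()
            raise ValueError(f"duplicate grid coordinate {dup} for plots {ids}")
        counts = self.table["genotype"].value_counts()
        if counts.nunique() != 1:
            raise ValueError("every genotype must appear the same number of times")
        if self.table["plot_id"].duplicated().any():
            raise ValueError("duplicate plot_id")

    @property
    def plots(self) -> pd.Index:
        return pd.Index(self.table["plot_id"])

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique())

    @property
    def n_rep(self) -> int:
        return int(self.table["replicate"].nunique())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TruthRecord:
    """Ground truth behind one simulated trial."""

    genotype_effects_per_day: pd.DataFrame  # genotypes x days, trait units
    spatial_surface: pd.Series  # per plot, trait units
    variance_components: dict  # sigma_g2/sigma_e2 per day + design-term variances
    growth_params: pd.DataFrame  # per genotype: asymptote, rate, midpoint
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "variance_components": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.variance_components.items()
            },
            "genotype_effects_per_day": self.genotype_effects_per_day.to_dict(),
            "spatial_surface": self.spatial_surface.to_dict(),
            "growth_params": self.growth_params.to_dict(),
        }


@dataclass
class PhenoMatrix:
    """Plots x days trait values; NaN marks missing cells."""

    design: TrialDesign
    days: list[str]  # ISO-8601 date labels, ascending
    values: pd.DataFrame  # index = plot_id, columns = days, float

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.days):
            raise ValueError("values columns must equal day labels")
        if not self.values.index.equals(self.design.plots):
            self.values = self.values.reindex(self.design.plots)
            if self.values.isna().all(axis=1).any():
                raise ValueError("phenotype plots do not match design plots")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_days(self) -> int:
        return len(self.days)

    def copy(self) -> "PhenoMatrix":
        return PhenoMatrix(self.design, list(self.days), self.values.copy())


def make_design(
    n_geno: int,
    n_rep: int,
    n_block: int,
    grid_rows: int,
    grid_cols: int,
    seed: int,
) -> TrialDesign:
    """Randomized resolvable incomplete-block (alpha-style) layout.

    Each replicate is a contiguous band of grid positions; within a replicate
    the genotypes are shuffled into ``n_block`` equal blocks laid on
    contiguous segments.  Statistically valid for testing the pipeline, with
    no claim of agronomic optimality.
    """
    if n_geno % n_block != 0:
        raise ValueError(f"n_geno={n_geno} not divisible by n_block={n_block}")
    if grid_rows * grid_cols < n_geno * n_rep:
        raise ValueError(
            f"grid {grid_rows}x{grid_cols} too small for {n_geno * n_rep} plots"
        )
    block_size = n_geno // n_block
    rng = np.random.default_rng(seed)
    width = len(str(n_geno))
    genos = np.array([f"G{i + 1:0{width}d}" for i in range(n_geno)])
    positions = [(r + 1, c + 1) for r in range(grid_rows) for c in range(grid_cols)]

    rows = []
    plot = 0
    for rep in range(1, n_rep + 1):
        order = rng.permutation(n_geno)
        for blk in range(1, n_block + 1):
            members = genos[order[(blk - 1) * block_size : blk * block_size]]
            for g in members:
                r, c = positions[plot]
                rows.append(
                    {
                        "plot_id": f"P{plot + 1:05d}",
                        "genotype": g,
                        "replicate": rep,
                        "block": blk,
                        "row": r,
                        "col": c,
                    }
                )
                plot += 1
    return TrialDesign(pd.DataFrame(rows))


def _logistic(t: np.ndarray, a: np.ndarray, k: np.ndarray, t0: np.ndarray) -> np.ndarray:
    return a / (1.0 + np.exp(-k * (t - t0)))


def _default_growth_shape(n_days: int) -> dict:
    t_max = n_days - 1
    return {
        "asymptote": (40.0, 80.0),
        "rate": (0.15, 0.35),
        "midpoint": (0.35 * t_max, 0.65 * t_max),
    }


def simulate_trial(
    design: TrialDesign,
    n_days: int,
    h2_target: float,
    spatial_amplitude: float = 2.0,
    growth_shape: dict | None = None,
    seed: int = 0,
    start_date: str = "2015-01-01",
    sd_rep: float = 1.0,
    sd_block: float = 1.0,
    sd_row: float = 0.5,
    sd_col: float = 0.5,
    sigma_e_floor: float = 1.0,
    growth_params: pd.DataFrame | None = None,
) -> tuple[PhenoMatrix, TruthRecord]:
    """Simulate a plots x days trait matrix with known truth.

    value(plot, day) = logistic(day; genotype curve) + replicate + block
    + smooth spatial surface + row/col effects + iid Gaussian error.  The
    error variance is calibrated per day so that the realized plot-level
    heritability Var_g(day) / (Var_g(day) + sigma_e^2(day)) equals
    ``h2_target``.  Days with zero genotype variance fall back to
    ``sigma_e_floor**2`` error variance.
    """
    if not (0.0 < h2_target < 1.0):
        raise ValueError("h2_target must lie strictly between 0 and 1")
    if n_days < 3:
        raise ValueError("need n_days >= 3")

    rng = np.random.default_rng(seed)
    shape = dict(_default_growth_shape(n_days))
    if growth_shape:
        shape.update(growth_shape)

    tab = design.table
    genos = design.genotypes
    n_g = len(genos)
    t = np.arange(n_days, dtype=float)
    days = [str(d.date()) for d in pd.date_range(start_date, periods=n_days)]

    if growth_params is not None:
        # reuse another experiment's genotype curves (shared genetics)
        gp = growth_params.loc[genos]
        a = gp["asymptote"].to_numpy(dtype=float)
        k = gp["rate"].to_numpy(dtype=float)
        t0 = gp["midpoint"].to_numpy(dtype=float)
        rng.uniform(size=3 * n_g)  # keep downstream draws aligned
    else:
        a = rng.uniform(*shape["asymptote"], size=n_g)
        k = rng.uniform(*shape["rate"], size=n_g)
        t0 = rng.uniform(*shape["midpoint"], size=n_g)
    curves = _logistic(t[None, :], a[:, None], k[:, None], t0[:, None])  # n_g x n_days
    mean_curve = curves.mean(axis=0)
    g_eff = curves - mean_curve  # genotype effect per day

    rep_levels = sorted(tab["replicate"].unique())
    blk_levels = sorted(set(zip(tab["replicate"], tab["block"])))
    row_levels = sorted(tab["row"].unique())
    col_levels = sorted(tab["col"].unique())
    rep_eff = dict(zip(rep_levels, rng.normal(0.0, sd_rep, len(rep_levels))))
    blk_eff = dict(zip(blk_levels, rng.normal(0.0, sd_block, len(blk_levels))))
    row_eff = dict(zip(row_levels, rng.normal(0.0, sd_row, len(row_levels))))
    col_eff = dict(zip(col_levels, rng.normal(0.0, sd_col, len(col_levels))))

    surface = _smooth_surface(tab, rng, spatial_amplitude)

    g_idx = {g: i for i, g in enumerate(genos)}
    gi = tab["genotype"].map(g_idx).to_numpy()
    static = (
        tab["replicate"].map(rep_eff).to_numpy()
        + pd.Series(list(zip(tab["replicate"], tab["block"]))).map(blk_eff).to_numpy()
        + tab["row"].map(row_eff).to_numpy()
        + tab["col"].map(col_eff).to_numpy()
        + surface
    )

    var_g = g_eff.var(axis=0, ddof=0)  # realized genotype variance per day
    sigma_e2 = np.where(
        var_g > 0, var_g * (1.0 - h2_target) / h2_target, sigma_e_floor**2
    )
    noise = rng.normal(0.0, 1.0, size=(len(tab), n_days)) * np.sqrt(sigma_e2)[None, :]
    values = mean_curve[None, :] + g_eff[gi, :] + static[:, None] + noise

    pheno = PhenoMatrix(
        design,
        days,
        pd.DataFrame(values, index=design.plots, columns=days),
    )
    truth = TruthRecord(
        genotype_effects_per_day=pd.DataFrame(g_eff, index=genos, columns=days),
        spatial_surface=pd.Series(surface, index=design.plots),
        variance_components={
            "sigma_g2_per_day": var_g,
            "sigma_e2_per_day": sigma_e2,
            "sigma_rep2": sd_rep**2,
            "sigma_block2": sd_block**2,
            "sigma_row2": sd_row**2,
            "sigma_col2": sd_col**2,
        },
        growth_params=pd.DataFrame(
            {"asymptote": a, "rate": k, "midpoint": t0}, index=genos
        ),
        seed=seed,
    )
    return pheno, truth


def _smooth_surface(tab: pd.DataFrame, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Low-order polynomial plus a Gaussian ridge along one wall.

    The ridge mimics heat dissipating from a wall on one side of the
    platform.  The combined surface is centered and scaled to standard
    deviation ``amplitude`` (trait units); amplitude 0 gives a flat surface.
    """
    r = tab["row"].to_numpy(dtype=float)
    c = tab["col"].to_numpy(dtype=float)
    rn = (r - r.mean()) / max(r.max() - r.min(), 1.0)
    cn = (c - c.mean()) / max(c.max() - c.min(), 1.0)
    a1, a2, a3 = rng.normal(0.0, 1.0, 3)
    # heat bump strongest near one corner of the wall, decaying along it:
    # a genuinely 2D feature no additive row+col decomposition can absorb
    wc, wr = 0.15, 0.4
    bump = np.exp(
        -((cn - cn.max()) ** 2) / (2 * wc**2) - ((rn - rn.max()) ** 2) / (2 * wr**2)
    )
    raw = a1 * rn + a2 * cn + 2.0 * a3 * rn * cn + 1.5 * bump
    raw = raw - raw.mean()
    sd = raw.std()
    if sd == 0 or amplitude == 0:
        return np.zeros_like(raw)
    return raw / sd * amplitude


# ---------------------------------------------------------------------------
# Contamination operators
# ---------------------------------------------------------------------------
#
# Cell selection and noise draws are keyed by a counter-based hash of
# (seed, plot_id, day label) instead of a sequential RNG stream, so the
# operators commute exactly with any reordering of the plots: a cell's fate
# depends only on its identity, never on its position in the table.


def _cell_uniform(seed: int, plot_id: str, day: str, tag: str) -> float:
    h = hashlib.blake2b(
        f"{seed}|{tag}|{plot_id}|{day}".encode(), digest_size=8
    ).digest()
    return (int.from_bytes(h, "big") + 0.5) / 2.0**64


def inject_missing(pheno: PhenoMatrix, x: float, seed: int) -> PhenoMatrix:
    """Set exactly round(x * n_cells) uniformly chosen observed cells missing."""
    if not (0.0 <= x < 1.0):
        raise ValueError("missing fraction x must lie in [0, 1)")
    out = pheno.copy()
    vals = out.values.to_numpy(copy=True)
    n_target = int(round(x * vals.size))
    if n_target == 0:
        return out
    plots = out.values.index.to_numpy()
    obs_i, obs_j = np.nonzero(~np.isnan(vals))
    if n_target > len(obs_i):
        raise ValueError("not enough observed cells to reach the requested fraction")
    keys = np.fromiter(
        (
            _cell_uniform(seed, plots[i], out.days[j], "miss")
            for i, j in zip(obs_i, obs_j)
        ),
        dtype=float,
        count=len(obs_i),
    )
    pick = np.argsort(keys)[:n_target]
    vals[obs_i[pick], obs_j[pick]] = np.nan
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.days)
    return out


def inject_noise(
    pheno: PhenoMatrix, x: float, scale_mult: float = 3.0, seed: int = 0
) -> PhenoMatrix:
    """Add N(0, scale_mult * Var(day)) perturbations to x of each day's plots.

    Per day, round(x * n_plots) observed cells receive an additive Gaussian
    draw whose variance is ``scale_mult`` times the day's pre-contamination
    sample variance.
    """
    if not (0.0 <= x < 1.0):
        raise ValueError("noise fraction x must lie in [0, 1)")
    if scale_mult <= 0:
        raise ValueError("scale_mult must be positive")
    out = pheno.copy()
    n_target = int(round(x * len(out.design)))
    if n_target == 0:
        return out
    vals = out.values.to_numpy(copy=True)
    plots = out.values.index.to_numpy()
    for j, d in enumerate(out.days):
        col = vals[:, j]
        obs = np.nonzero(~np.isnan(col))[0]
        if len(obs) < 2:
            raise ValueError(f"day {d} has fewer than 2 observed values")
        sd = float(np.std(col[obs], ddof=1)) * np.sqrt(scale_mult)
        keys = np.fromiter(
            (_cell_uniform(seed, plots[i], d, "noise-sel") for i in obs),
            dtype=float,
            count=len(obs),
        )
        chosen = obs[np.argsort(keys)[: min(n_target, len(obs))]]
        if sd == 0:
            continue  # N(0, 0) draws leave values unchanged
        draws = np.fromiter(
            (ndtri(_cell_uniform(seed, plots[i], d, "noise-val")) for i in chosen),
            dtype=float,
            count=len(chosen),
        )
        vals[chosen, j] = col[chosen] + sd * draws
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.days)
    return out
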