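"""Per-day mixed model with a 2D P-spline (PS-ANOVA) spatial surface.

The model for a plot in replicate j, block k(j), row l, column m of
genotype i is

    y = mu + rep_j + block_k(j) + f(row_l, col_m) + row_l + col_m + geno_i + e

where f(row, col) is a tensor-product penalized spline decomposed PS-ANOVA
style: fixed intercept/linear-row/linear-col/linear-interaction parts plus
five random smooth blocks (smooth row, smooth col, linear-by-smooth both
ways, smooth-by-smooth), each carrying its own variance.  Replicate, block
within replicate, row and column enter as independent random factors.
Genotype is fixed (sum-to-zero contrasts) for adjusted-mean (BLUE)
computation, or random for heritability.

Variance components are estimated by a Schall-type REML iteration with
effective-dimension updates: sigma_c^2 = u_c'u_c / ED_c and
sigma_e^2 = RSS / (n - p - sum ED_c), iterated to convergence.  The
heritability under the spatial model is ED_g / (n_g - l), the effective
dimension of the genotype block over its available degrees of freedom;
without the spatial surface the classical sigma_g^2/(sigma_g^2+sigma_e^2)
is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, lapack
from scipy.stats import t as t_dist

from .synthetic import TrialDesign

__all__ = [
    "ModelSpec",
    "DailyFit",
    "DesignMatrices",
    "build_design_matrices",
    "fit_day",
    "heritability",
    "classical_h2",
    "grubbs_clean",
    "predict_validation",
]

VARIANCE_FLOOR = 1e-10
LAMBDA_CAP = 1e12
# lower bound keeps aliased random blocks (e.g. replicate vs intercept)
# weakly penalized instead of exactly unpenalized, so the system stays
# positive definite
LAMBDA_MIN = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the per-day mixed model."""

    genotype_role: str = "fixed"  # "fixed" (BLUEs) or "random" (h2)
    include_spatial: bool = True
    random_terms: tuple = ("replicate", "block", "row", "col")
    nseg: tuple | None = None  # (nseg_row, nseg_col); None = from grid size
    degree: int = 3
    penalty_order: int = 2
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self):
        if self.genotype_role not in ("fixed", "random"):
            raise ValueError("genotype_role must be 'fixed' or 'random'")
        if self.nseg is not None and min(self.nseg) < 3:
            raise ValueError("basis segment counts must be >= 3")


@dataclass
class DailyFit:
    """Result of one day's mixed-model fit."""

    day: str
    blues: pd.Series | None  # genotype -> adjusted mean (genotype fixed only)
    blues_se: pd.Series | None
    varcomps: dict  # term -> variance
    effective_dims: dict  # random term -> ED
    ED_g: float | None
    n_g: int
    l: int
    h2: float | None
    spatial_trend: pd.Series | None  # fitted surface per plot
    converged: bool
    n_iter: int
    # private machinery for prediction
    _dm: "DesignMatrices" = field(repr=False, default=None)
    _theta: np.ndarray = field(repr=False, default=None)
    _geno_kept: list = field(repr=False, default=None)
    _G_full: np.ndarray = field(repr=False, default=None)


def _bspline_basis(x: np.ndarray, xl: float, xr: float, nseg: int, degree: int) -> np.ndarray:
    dx = (xr - xl) / nseg
    knots = xl + dx * np.arange(-degree, nseg + degree + 1)
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _smooth_block(b: np.ndarray, penalty_order: int) -> np.ndarray:
    """Reparameterize a penalized B-spline basis to iid random effects.

    Eigen-decomposes the difference penalty D'D; the range-space columns,
    scaled by the inverse square-root eigenvalues, give a design whose
    coefficients have an identity covariance up to one variance parameter.
    The null space (polynomials up to penalty_order-1) is carried by the
    fixed linear part of the surface.
    """
    nb = b.shape[1]
    d = np.diff(np.eye(nb), n=penalty_order, axis=0)
    evals, evecs = np.linalg.eigh(d.T @ d)
    pos = evals > 1e-10
    return b @ evecs[:, pos] / np.sqrt(evals[pos])


class DesignMatrices:
    """Model matrices for one (design, spec) pair, reusable across days."""

    def __init__(self, design: TrialDesign, spec: ModelSpec):
        self.design = design
        self.spec = spec
        tab = design.table
        n = len(tab)
        r = tab["row"].to_numpy(dtype=float)
        c = tab["col"].to_numpy(dtype=float)
        self.r_c = (r - r.mean()) / max(r.std(), 1.0)
        self.c_c = (c - c.mean()) / max(c.std(), 1.0)

        self.genotypes = design.genotypes
        self.geno_codes = tab["genotype"].map(
            {g: i for i, g in enumerate(self.genotypes)}
        ).to_numpy()

        # fixed base: intercept (+ linear surface parts when spatial)
        cols = [np.ones(n)]
        self.spatial_fixed_idx: list[int] = []
        if spec.include_spatial:
            for v in (self.r_c, self.c_c, self.r_c * self.c_c):
                self.spatial_fixed_idx.append(len(cols))
                cols.append(v)
        self.X_base = np.column_stack(cols)

        # random factor blocks
        self.random_blocks: list[tuple[str, np.ndarray]] = []
        factors = {
            "replicate": tab["replicate"].astype(str),
            "block": tab["replicate"].astype(str) + ":" + tab["block"].astype(str),
            "row": tab["row"].astype(str),
            "col": tab["col"].astype(str),
        }
        for name in spec.random_terms:
            if name not in factors:
                raise ValueError(f"unknown random term {name!r}")
            z = pd.get_dummies(factors[name]).to_numpy(dtype=float)
            self.random_blocks.append((name, z))

        self.spline_block_names: list[str] = []
        if spec.include_spatial:
            n_rows = int(tab["row"].max())
            n_cols = int(tab["col"].max())
            if spec.nseg is not None:
                nseg_r, nseg_c = spec.nseg
            else:
                nseg_r = int(np.clip(np.ceil(n_rows / 2), 5, 12))
                nseg_c = int(np.clip(np.ceil(n_cols / 2), 5, 12))
            br = _bspline_basis(r, r.min(), r.max(), nseg_r, spec.degree)
            bc = _bspline_basis(c, c.min(), c.max(), nseg_c, spec.degree)
            zr = _smooth_block(br, spec.penalty_order)
            zc = _smooth_block(bc, spec.penalty_order)
            zss = (zr[:, :, None] * zc[:, None, :]).reshape(n, -1)
            for name, z in [
                ("spline_row", zr),
                ("spline_col", zc),
                ("col_by_spline_row", zr * self.c_c[:, None]),
                ("row_by_spline_col", zc * self.r_c[:, None]),
                ("spline_row_col", zss),
            ]:
                self.random_blocks.append((name, z))
                self.spline_block_names.append(name)

        # zero-eigenvalue count of the genotype hat block: rank deficiency
        # induced by the identifiability overlap with the fixed part
        zg = np.zeros((n, len(self.genotypes)))
        zg[np.arange(n), self.geno_codes] = 1.0
        self.Z_geno = zg
        full = np.column_stack([self.X_base, zg])
        self.l_geno = int(
            self.X_base.shape[1] + zg.shape[1] - np.linalg.matrix_rank(full)
        )

    def geno_fixed_columns(self, kept_codes: np.ndarray) -> np.ndarray:
        """Sum-to-zero contrast columns for the kept genotypes."""
        n = len(self.design.table)
        n_kept = len(kept_codes)
        code_pos = {c: i for i, c in enumerate(kept_codes)}
        x = np.zeros((n, n_kept - 1))
        for i, code in enumerate(self.geno_codes):
            pos = code_pos.get(code)
            if pos is None:
                continue
            if pos < n_kept - 1:
                x[i, pos] = 1.0
            else:
                x[i, :] = -1.0
        return x


def build_design_matrices(design: TrialDesign, spec: ModelSpec) -> DesignMatrices:
    return DesignMatrices(design, spec)


def _schall(
    g: np.ndarray,
    y: np.ndarray,
    p_fixed: int,
    block_slices: list[tuple[str, slice]],
    tol: float,
    max_iter: int,
    init: dict | None = None,
) -> dict:
    """Schall/effective-dimension REML iteration on the stacked system."""
    n = len(y)
    gty = g.T @ y
    gtg = g.T @ g
    var_y = float(np.var(y)) if n > 1 else 1.0
    var_y = max(var_y, VARIANCE_FLOOR)

    sigma_e2 = (init or {}).get("error", 0.5 * var_y)
    sigmas = {
        name: (init or {}).get(name, 0.1 * var_y) for name, _ in block_slices
    }
    sigma_e2 = max(sigma_e2, VARIANCE_FLOOR)
    sigmas = {k: max(v, VARIANCE_FLOOR) for k, v in sigmas.items()}

    if not block_slices:  # pure fixed-effects model
        c = cho_factor(gtg + np.eye(gtg.shape[0]) * 1e-10)
        theta = cho_solve(c, gty)
        resid = y - g @ theta
        dof = max(n - p_fixed, 1)
        return {
            "theta": theta,
            "sigma_e2": float(resid @ resid) / dof,
            "sigmas": {},
            "eds": {},
            "converged": True,
            "n_iter": 0,
            "c_inv": np.linalg.inv(gtg + np.eye(gtg.shape[0]) * 1e-10),
        }

    converged = False
    n_iter = 0
    theta = None
    c_inv = None
    eds: dict = {}
    # components falling this far below the response variance are estimated
    # at the zero boundary and frozen there, avoiding a long geometric decay
    zero_thresh = 1e-6 * var_y
    frozen: set = set()
    history: list[dict] = []
    for n_iter in range(1, max_iter + 1):
        lam = np.zeros(g.shape[1])
        for name, sl in block_slices:
            if name in frozen:
                lam[sl] = LAMBDA_CAP
                continue
            lam[sl] = np.clip(
                sigma_e2 / max(sigmas[name], VARIANCE_FLOOR), LAMBDA_MIN, LAMBDA_CAP
            )
        c = gtg + np.diag(lam)
        try:
            cf = cho_factor(c, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular mixed-model system; check for aliased design terms"
            ) from exc
        inv_tri, info = lapack.dpotri(cf[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("inversion of the mixed-model system failed")
        c_inv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
        theta = c_inv @ gty
        resid = y - g @ theta
        rss = float(resid @ resid)

        new_sigmas = {}
        ed_total = 0.0
        for name, sl in block_slices:
            q = sl.stop - sl.start
            ed = q - lam[sl.start] * np.trace(c_inv[sl, sl])
            ed = max(ed, 0.0)
            eds[name] = ed
            ed_total += ed
            u = theta[sl]
            if name in frozen or ed < 1e-8:
                new_sigmas[name] = VARIANCE_FLOOR
                frozen.add(name)
            else:
                val = max(float(u @ u) / ed, VARIANCE_FLOOR)
                if val < zero_thresh:
                    val = VARIANCE_FLOOR
                    frozen.add(name)
                new_sigmas[name] = val
        denom = max(n - p_fixed - ed_total, 1.0)
        new_sigma_e2 = max(rss / denom, VARIANCE_FLOOR)

        rel = abs(new_sigma_e2 - sigma_e2) / (sigma_e2 + 1e-12)
        for name in new_sigmas:
            if name in frozen:
                continue
            rel = max(
                rel, abs(new_sigmas[name] - sigmas[name]) / (sigmas[name] + 1e-12)
            )
        sigmas, sigma_e2 = new_sigmas, new_sigma_e2
        if rel < tol:
            converged = True
            break

        # Aitken extrapolation on log-variances: the update map converges
        # linearly, so periodically jumping to the geometric-series limit
        # cuts the iteration count by an order of magnitude
        history.append(
            {**{k: np.log(v) for k, v in sigmas.items()}, "__e": np.log(sigma_e2)}
        )
        if len(history) > 3:
            history.pop(0)
        if n_iter % 4 == 0 and len(history) == 3:
            accel = {}
            for key in history[-1]:
                x0, x1, x2 = (h[key] for h in history)
                d1, d2 = x1 - x0, x2 - x1
                if abs(d1) > 1e-14 and 0 < d2 / d1 < 0.9999:
                    r = d2 / d1
                    accel[key] = x2 + np.clip(r / (1 - r) * d2, -20, 20)
            for key, lv in accel.items():
                if key == "__e":
                    sigma_e2 = max(float(np.exp(lv)), VARIANCE_FLOOR)
                elif key not in frozen:
                    sigmas[key] = max(float(np.exp(lv)), VARIANCE_FLOOR)
            if accel:
                history.clear()

    # final solve at the converged components so the returned solution is
    # exactly the GLS solution for the reported variances
    lam = np.zeros(g.shape[1])
    for name, sl in block_slices:
        lam[sl] = np.clip(
            sigma_e2 / max(sigmas[name], VARIANCE_FLOOR), LAMBDA_MIN, LAMBDA_CAP
        )
    cf = cho_factor(gtg + np.diag(lam), lower=True, check_finite=False)
    inv_tri, _ = lapack.dpotri(cf[0], lower=True)
    c_inv = np.tril(inv_tri) + np.tril(inv_tri, -1).T
    theta = c_inv @ gty
    for name, sl in block_slices:
        q = sl.stop - sl.start
        eds[name] = max(q - lam[sl.start] * np.trace(c_inv[sl, sl]), 0.0)

    return {
        "theta": theta,
        "sigma_e2": sigma_e2,
        "sigmas": sigmas,
        "eds": eds,
        "converged": converged,
        "n_iter": n_iter,
        "c_inv": c_inv,
    }


def fit_day(
    day_values,
    design: TrialDesign,
    spec: ModelSpec,
    dm: DesignMatrices | None = None,
    day_label: str = "",
    init: dict | None = None,
) -> DailyFit:
    """Fit the per-day mixed model; missing responses are dropped.

    ``day_values`` is a plot-indexed Series (or array aligned to the design
    table) with NaN for missing plots.  Pass a prebuilt ``dm`` to reuse the
    model matrices across days, and ``init`` (a previous fit's varcomps) to
    warm-start the variance-component iteration.
    """
    if dm is None:
        dm = DesignMatrices(design, spec)
    if isinstance(day_values, pd.Series):
        y_all = day_values.reindex(design.plots).to_numpy(dtype=float)
    else:
        y_all = np.asarray(day_values, dtype=float)
    obs = ~np.isnan(y_all)
    n_obs = int(obs.sum())
    if n_obs < 3:
        raise ValueError("need at least 3 observed plots")

    codes_obs = dm.geno_codes[obs]
    kept_codes = np.array(sorted(set(codes_obs)))
    kept_names = [dm.genotypes[c] for c in kept_codes]
    dropped = [g for g in dm.genotypes if g not in set(kept_names)]
    if dropped:
        warnings.warn(
            f"{len(dropped)} genotype(s) unobserved on day {day_label!r}; "
            "no adjusted mean reported for them"
        )

    fixed_parts = [dm.X_base]
    if spec.genotype_role == "fixed":
        if len(kept_codes) < 2:
            raise ValueError("need at least 2 observed genotypes")
        fixed_parts.append(dm.geno_fixed_columns(kept_codes))
    x = np.column_stack(fixed_parts)
    p_fixed = x.shape[1]

    blocks = list(dm.random_blocks)
    if spec.genotype_role == "random":
        blocks = blocks + [("genotype", dm.Z_geno)]

    mats = [x] + [z for _, z in blocks]
    g_full = np.column_stack(mats)
    offset = p_fixed
    block_slices = []
    for name, z in blocks:
        block_slices.append((name, slice(offset, offset + z.shape[1])))
        offset += z.shape[1]

    res = _schall(
        g_full[obs], y_all[obs], p_fixed, block_slices, spec.tol, spec.max_iter, init
    )
    theta = res["theta"]
    sigma_e2 = res["sigma_e2"]
    if not res["converged"]:
        warnings.warn(
            f"variance-component iteration did not converge in {res['n_iter']} "
            f"iterations on day {day_label!r}"
        )

    varcomps = {"error": sigma_e2, **res["sigmas"]}
    eds = dict(res["eds"])

    blues = blues_se = None
    ed_g = None
    h2 = None
    n_g = len(kept_codes)
    l = dm.l_geno
    if spec.genotype_role == "fixed":
        n_eff = len(kept_codes)
        t_mat = np.vstack([np.eye(n_eff - 1), -np.ones((1, n_eff - 1))])
        beta_geno = theta[p_fixed - (n_eff - 1) : p_fixed]
        effects = t_mat @ beta_geno
        intercept = theta[0]
        vals = intercept + effects
        # SE of intercept + effect via the fixed-effect covariance block
        cov = sigma_e2 * res["c_inv"][:p_fixed, :p_fixed]
        lmat = np.zeros((n_eff, p_fixed))
        lmat[:, 0] = 1.0
        lmat[:, p_fixed - (n_eff - 1) : p_fixed] = t_mat
        se = np.sqrt(np.maximum(np.einsum("ip,pq,iq->i", lmat, cov, lmat), 0.0))
        blues = pd.Series(vals, index=kept_names).reindex(dm.genotypes)
        blues_se = pd.Series(se, index=kept_names).reindex(dm.genotypes)
    else:
        ed_g = eds.get("genotype", 0.0)
        if spec.include_spatial:
            h2 = float(np.clip(ed_g / max(n_g - l, 1), 0.0, 1.0))
        else:
            sg = res["sigmas"].get("genotype", 0.0)
            h2 = float(np.clip(sg / max(sg + sigma_e2, VARIANCE_FLOOR), 0.0, 1.0))

    spatial_trend = None
    if spec.include_spatial:
        trend = np.zeros(len(y_all))
        for idx in dm.spatial_fixed_idx:
            trend += g_full[:, idx] * theta[idx]
        for name, sl in block_slices:
            if name in dm.spline_block_names:
                trend += g_full[:, sl] @ theta[sl]
        spatial_trend = pd.Series(trend, index=design.plots)

    return DailyFit(
        day=day_label,
        blues=blues,
        blues_se=blues_se,
        varcomps=varcomps,
        effective_dims=eds,
        ED_g=ed_g,
        n_g=n_g,
        l=l,
        h2=h2,
        spatial_trend=spatial_trend,
        converged=res["converged"],
        n_iter=res["n_iter"],
        _dm=dm,
        _theta=theta,
        _geno_kept=kept_names,
        _G_full=g_full,
    )


def classical_h2(sigma_g2: float, sigma_e2: float) -> float:
    """Broad-sense heritability sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be non-negative")
    tot = sigma_g2 + sigma_e2
    return 0.0 if tot == 0 else sigma_g2 / tot


def heritability(fit: DailyFit, spec: ModelSpec) -> float:
    """Heritability of a random-genotype fit.

    Spatial model: ED_g / (n_g - l); non-spatial: classical variance ratio.
    """
    if spec.genotype_role != "random":
        raise ValueError("heritability requires a random-genotype fit")
    if spec.include_spatial:
        return float(np.clip(fit.ED_g / max(fit.n_g - fit.l, 1), 0.0, 1.0))
    return classical_h2(fit.varcomps.get("genotype", 0.0), fit.varcomps["error"])


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha."""
    tcrit = t_dist.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(tcrit**2 / (n - 2 + tcrit**2))


def grubbs_clean(
    day_values,
    design: TrialDesign,
    spec: ModelSpec,
    alpha: float = 0.05,
    dm: DesignMatrices | None = None,
    max_remove: int | None = None,
) -> pd.Series:
    """Iteratively delete the most extreme residual by the Grubbs test.

    Fits the model, computes residuals over observed plots, applies the
    two-sided Grubbs statistic G = max|r - rbar| / s against its t-based
    critical value at ``alpha``, removes the offending observation and
    refits; stops when no residual is significant, residual variance
    degenerates, or the removal cap (2% of the observations by default) is
    reached.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if dm is None:
        dm = DesignMatrices(design, spec)
    y = (
        day_values.reindex(design.plots).astype(float).copy()
        if isinstance(day_values, pd.Series)
        else pd.Series(np.asarray(day_values, dtype=float), index=design.plots)
    )
    n_obs0 = int(y.notna().sum())
    if max_remove is None:
        max_remove = max(1, int(round(0.02 * n_obs0)))
    init = None
    for _ in range(max_remove + 1):
        obs_idx = y.notna()
        if int(obs_idx.sum()) < 3:
            break
        fit = fit_day(y, design, spec, dm=dm, init=init)
        init = fit.varcomps
        pred = fit._G_full @ fit._theta
        resid = y.to_numpy(dtype=float) - pred
        resid = pd.Series(resid, index=y.index)[obs_idx]
        s = resid.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            break
        n = len(resid)
        g_stat = (resid - resid.mean()).abs().max() / s
        if g_stat <= grubbs_critical(n, alpha):
            break
        worst = (resid - resid.mean()).abs().idxmax()
        y.loc[worst] = np.nan
        if int(y.notna().sum()) <= n_obs0 - max_remove:
            break
    return y


def predict_validation(fit: DailyFit, validation_plots) -> pd.Series:
    """Predict trait values for validation plots of the fitted design.

    Predictions combine the genotype estimate with the estimated replicate,
    block, row and column effects and the spatial surface at the plot's
    coordinates.  Plots of genotypes unseen in training get NaN and a
    warning.
    """
    dm = fit._dm
    plots = pd.Index(validation_plots)
    if len(plots) == 0:
        return pd.Series(dtype=float)
    pos = dm.design.plots.get_indexer(plots)
    if (pos < 0).any():
        raise KeyError(f"unknown plots: {list(plots[pos < 0])}")
    pred = fit._G_full[pos] @ fit._theta
    kept = set(fit._geno_kept)
    genos = dm.design.table["genotype"].to_numpy()[pos]
    unseen = ~np.isin(genos, list(kept))
    if unseen.any():
        warnings.warn(
            f"{int(unseen.sum())} validation plot(s) carry genotypes absent "
            "from training; excluded from predictions"
        )
        pred = pred.astype(float)
        pred[unseen] = np.nan
    return pd.Series(pred, index=plots)
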