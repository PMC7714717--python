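"""Temporal analysis of genotype adjusted-mean series.

Clusters genotypes on their whole growth series (Gaussian kernel k-means,
cluster count from the silhouette), tracks expressed genetic diversity as
the per-day distance between cluster centers (Clust-Dist), locates growth
phases by multivariate e-divisive change-point analysis of the joint
(heritability, Clust-Dist) series, codifies the choice of the optimal time
window (OTW), and validates cluster stability with a genotype-cluster x
time-window two-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "ClusterModel",
    "ChangePointResult",
    "AnovaResult",
    "kernel_kmeans",
    "select_k",
    "clust_dist_series",
    "e_divisive",
    "select_otw",
    "gc_tw_anova",
]


@dataclass
class ClusterModel:
    k: int
    assignment: pd.Series  # genotype -> cluster id (0..k-1)
    kernel_bandwidth: float
    silhouette: float
    centers_per_day: pd.DataFrame  # cluster x day
    objective: float


def _as_matrix(series_matrix) -> pd.DataFrame:
    m = (
        series_matrix.copy()
        if isinstance(series_matrix, pd.DataFrame)
        else pd.DataFrame(np.asarray(series_matrix, dtype=float))
    )
    empty = [c for c in m.columns if m[c].isna().all()]
    if empty:
        warnings.warn(f"dropping day(s) with no adjusted means: {empty}")
        m = m.drop(columns=empty)
    if m.isna().any().any():
        warnings.warn("missing genotype-day cells mean-filled for clustering")
        m = m.apply(lambda col: col.fillna(col.mean()), axis=0)
    return m


def _kernel_objective(kmat: np.ndarray, labels: np.ndarray, k: int) -> float:
    total = 0.0
    for c in range(k):
        idx = np.nonzero(labels == c)[0]
        if len(idx) == 0:
            continue
        sub = kmat[np.ix_(idx, idx)]
        # sum of feature-space squared distances to the cluster mean
        total += float(np.trace(sub)) - float(sub.sum()) / len(idx)
    return total


def _kernel_lloyd(kmat: np.ndarray, labels: np.ndarray, k: int, max_iter: int) -> np.ndarray:
    """Lloyd iterations in kernel feature space; dispersion non-increasing."""
    n = len(kmat)
    reseeds = 0
    for _ in range(max_iter):
        dist = np.empty((n, k))
        for c in range(k):
            idx = np.nonzero(labels == c)[0]
            if len(idx) == 0:
                dist[:, c] = np.inf
                continue
            kc = kmat[:, idx]
            dist[:, c] = 1.0 - 2.0 * kc.mean(axis=1) + kmat[np.ix_(idx, idx)].mean()
        new_labels = dist.argmin(axis=1)
        for c in range(k):
            if not (new_labels == c).any():
                if reseeds >= 10:
                    raise RuntimeError("kernel k-means: too many empty-cluster reseeds")
                reseeds += 1
                warnings.warn(f"kernel k-means: reseeding empty cluster {c}")
                worst = dist[np.arange(n), new_labels].argmax()
                new_labels[worst] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


def _hartigan_polish(kmat: np.ndarray, labels: np.ndarray, k: int, max_sweeps: int = 20) -> np.ndarray:
    """Single-point exchange refinement of a Lloyd solution.

    Lloyd's assignment step ignores the centroid shift caused by moving a
    point, so with small clusters its fixed points can miss partitions that
    a single exchange would improve; sweeping exact-objective moves fixes
    that.
    """
    n = len(kmat)
    labels = labels.copy()
    current = _kernel_objective(kmat, labels, k)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            home = labels[i]
            if (labels == home).sum() == 1:
                continue  # never empty a cluster
            for c in range(k):
                if c == home:
                    continue
                labels[i] = c
                obj = _kernel_objective(kmat, labels, k)
                if obj < current - 1e-12:
                    current = obj
                    home = c
                    improved = True
                else:
                    labels[i] = home
        if not improved:
            break
    return labels


def kernel_kmeans(
    series_matrix,
    k: int,
    bandwidth: float | str = "auto",
    seed: int = 0,
    max_iter: int = 100,
    n_init: int = 10,
) -> ClusterModel:
    """Gaussian-kernel k-means on whole-series genotype vectors.

    The kernel is exp(-||a-b||^2 / (2 sigma^2)); sigma defaults to the
    median pairwise Euclidean distance.  The first initialization is a
    deterministic farthest-first traversal (a pure function of the data, so
    well-separated structure is recovered independent of row order); the
    remaining ``n_init - 1`` restarts are seeded random partitions guarding
    against local optima, and the lowest-dispersion solution wins.
    """
    m = _as_matrix(series_matrix)
    x = m.to_numpy(dtype=float)
    n = len(x)
    if not (2 <= k < n):
        raise ValueError("need 2 <= k < n_genotypes")
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    if bandwidth == "auto":
        off = np.sqrt(d2[np.triu_indices(n, 1)])
        sigma = float(np.median(off))
        if sigma == 0:
            sigma = 1.0
    else:
        sigma = float(bandwidth)
    kmat = np.exp(-d2 / (2 * sigma**2))

    centers = [int(np.argmax(d2.sum(axis=1)))]
    while len(centers) < k:
        min_d = d2[:, centers].min(axis=1)
        centers.append(int(np.argmax(min_d)))
    inits = [np.asarray(d2[:, centers].argmin(axis=1))]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_init - 1, 0)):
        lab = rng.integers(k, size=n)
        lab[rng.choice(n, size=k, replace=False)] = np.arange(k)
        inits.append(lab)

    # polish every restart on small problems (cheap, explores more basins);
    # on large ones polishing the single best restart is enough
    polish_all = n <= 64
    labels, best_obj = None, np.inf
    for init in inits:
        cand = _kernel_lloyd(kmat, init.copy(), k, max_iter)
        if polish_all:
            cand = _hartigan_polish(kmat, cand, k)
        obj = _kernel_objective(kmat, cand, k)
        if obj < best_obj - 1e-12:
            labels, best_obj = cand, obj
    if not polish_all:
        labels = _hartigan_polish(kmat, labels, k)

    sil = float(silhouette_score(x, labels)) if len(set(labels)) > 1 else 0.0
    centers = pd.DataFrame(
        [x[labels == c].mean(axis=0) for c in range(k)], columns=m.columns
    )
    return ClusterModel(
        k=k,
        assignment=pd.Series(labels, index=m.index),
        kernel_bandwidth=sigma,
        silhouette=sil,
        centers_per_day=centers,
        objective=_kernel_objective(kmat, labels, k),
    )


def select_k(series_matrix, k_range, seed: int = 0, bandwidth="auto") -> int:
    """Cluster count maximizing the mean silhouette; ties pick the smallest k."""
    m = _as_matrix(series_matrix)
    scores = {}
    for k in sorted(set(int(k) for k in k_range)):
        if not (2 <= k < len(m)):
            raise ValueError(f"k={k} outside [2, n-1]")
        scores[k] = kernel_kmeans(m, k, bandwidth=bandwidth, seed=seed).silhouette
    best = max(scores, key=lambda k: (scores[k], -k))
    # Kaufman-Rousseeuw reading: mean silhouette < 0.25 = no substantial structure
    if scores[best] < 0.25:
        warnings.warn(
            f"low silhouette ({scores[best]:.2f}) at every k; clustering weakly supported"
        )
    return best


def clust_dist_series(model: ClusterModel, series) -> pd.Series:
    """Per-day mean pairwise Euclidean distance between cluster centers.

    Centers are the per-day means of each cluster's member adjusted means;
    with two clusters this is simply |c1 - c2|.  Fully missing days yield
    NaN.
    """
    blues = series.blues if hasattr(series, "blues") else pd.DataFrame(series)
    labels = model.assignment.reindex(blues.index)
    out = {}
    for day in blues.columns:
        col = blues[day]
        centers = col.groupby(labels).mean()
        centers = centers.dropna()
        if len(centers) < 2:
            out[day] = np.nan
            continue
        pairs = [abs(a - b) for a, b in combinations(centers.to_numpy(), 2)]
        out[day] = float(np.mean(pairs))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# e-divisive change-point analysis
# ---------------------------------------------------------------------------


@dataclass
class ChangePointResult:
    change_points: list  # strictly increasing interior indices
    windows: list  # list of (start, end) half-open index ranges
    per_window: pd.DataFrame  # median_h2, clust_dist_slope per window
    alpha: float
    n_permutations: int
    otw: int | None = None
    otw_rule: str | None = None


def _segment_best_split(dist: np.ndarray, s: int, e: int, min_size: int):
    """Best single split of [s, e) by the energy divergence statistic."""
    best_q, best_tau = -np.inf, None
    for tau in range(s + min_size, e - min_size + 1):
        a = np.arange(s, tau)
        b = np.arange(tau, e)
        n1, n2 = len(a), len(b)
        between = dist[np.ix_(a, b)].mean()
        wa = dist[np.ix_(a, a)][np.triu_indices(n1, 1)].mean() if n1 > 1 else 0.0
        wb = dist[np.ix_(b, b)][np.triu_indices(n2, 1)].mean() if n2 > 1 else 0.0
        q = (n1 * n2 / (n1 + n2)) * (2.0 * between - wa - wb)
        if q > best_q:
            best_q, best_tau = q, tau
    return best_q, best_tau


def _max_q_over_segments(dist: np.ndarray, bounds: list, min_size: int):
    best = (-np.inf, None, None)
    for s, e in bounds:
        if e - s < 2 * min_size:
            continue
        q, tau = _segment_best_split(dist, s, e, min_size)
        if tau is not None and q > best[0]:
            best = (q, tau, (s, e))
    return best


def e_divisive(
    series2d,
    alpha: float = 0.05,
    min_size: int = 3,
    n_perm: int = 199,
    seed: int = 0,
) -> ChangePointResult:
    """Hierarchical e-divisive change-point detection on a days x 2 series.

    The two columns (daily heritability and Clust-Dist) are z-scored
    internally so both contribute on comparable scales.  At each step, the
    split maximizing the between-segment energy divergence over all current
    segments is tested by permuting observations within segments; accepted
    splits (permutation p-value <= alpha) recurse until no candidate is
    significant.
    """
    raw = (
        series2d.to_numpy(dtype=float)
        if isinstance(series2d, pd.DataFrame)
        else np.asarray(series2d, dtype=float)
    )
    if raw.ndim == 1:
        raw = raw[:, None]
    n = len(raw)
    if n < 2 * min_size:
        raise ValueError(f"series too short ({n}) for min_size={min_size}")
    mu = np.nanmean(raw, axis=0)
    sd = np.nanstd(raw, axis=0)
    sd[sd == 0] = 1.0
    z = (raw - mu) / sd
    if np.isnan(z).any():
        warnings.warn("NaNs in change-point input; filled with column means")
        z = np.where(np.isnan(z), 0.0, z)

    dist = np.sqrt(np.sum((z[:, None, :] - z[None, :, :]) ** 2, axis=-1))
    rng = np.random.default_rng(seed)
    cps: list[int] = []
    while True:
        bounds = _windows_from_cps(cps, n)
        q_obs, tau, seg = _max_q_over_segments(dist, bounds, min_size)
        if tau is None:
            break
        exceed = 0
        for _ in range(n_perm):
            perm = np.arange(n)
            for s, e in bounds:
                perm[s:e] = rng.permutation(perm[s:e])
            dperm = dist[np.ix_(perm, perm)]
            q_p, _, _ = _max_q_over_segments(dperm, bounds, min_size)
            if q_p >= q_obs:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        if p > alpha:
            break
        cps.append(tau)
        cps.sort()

    windows = _windows_from_cps(cps, n)
    per_window = _window_summaries(raw, windows)
    return ChangePointResult(
        change_points=cps,
        windows=windows,
        per_window=per_window,
        alpha=alpha,
        n_permutations=n_perm,
    )


def _windows_from_cps(cps: list, n: int) -> list:
    edges = [0] + sorted(cps) + [n]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _window_summaries(raw: np.ndarray, windows: list) -> pd.DataFrame:
    rows = []
    for s, e in windows:
        h2 = raw[s:e, 0]
        cd = raw[s:e, 1] if raw.shape[1] > 1 else raw[s:e, 0]
        keep = ~np.isnan(cd)
        slope = (
            float(np.polyfit(np.arange(s, e)[keep], cd[keep], 1)[0])
            if keep.sum() > 1
            else 0.0
        )
        rows.append(
            {
                "start": s,
                "end": e,
                "median_h2": float(np.nanmedian(h2)),
                "clust_dist_slope": slope,
            }
        )
    return pd.DataFrame(rows)


def select_otw(result: ChangePointResult) -> int:
    """Codified optimal-time-window rule.

    Among interior windows (first and last excluded) whose Clust-Dist trend
    is non-negative, take the one with the highest median heritability
    (earliest on ties).  If no interior window qualifies, fall back to the
    global median-h2 maximizer.  The applied rule is recorded on the result.
    """
    pw = result.per_window
    n_win = len(pw)
    if n_win == 1:
        warnings.warn("single window; returned as OTW")
        result.otw, result.otw_rule = 0, "single-window"
        return 0
    interior = pw.iloc[1 : n_win - 1] if n_win >= 3 else pw.iloc[0:0]
    rising = interior[interior["clust_dist_slope"] >= 0]
    if len(rising):
        otw = int(rising["median_h2"].idxmax())
        rule = "interior-rising-max-median-h2"
    else:
        otw = int(pw["median_h2"].idxmax())
        rule = "global-max-median-h2"
    result.otw, result.otw_rule = otw, rule
    return otw


# ---------------------------------------------------------------------------
# Genotype-cluster x time-window ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    table: pd.DataFrame  # Gc, TW, Gc:TW, Residual rows
    groups: pd.Series  # genotype -> "low"/"medium"/"high"
    total_ss: float


def gc_tw_anova(
    series,
    windows: list,
    otw: int,
    n_groups: int = 3,
    seed: int = 0,
) -> AnovaResult:
    """Two-way sequential ANOVA of cluster, time window and interaction.

    Genotypes are k-means grouped (k = ``n_groups``, labels ordered low to
    high) on their mean adjusted means inside the OTW; the response is the
    genotype x window mean adjusted mean; sums of squares are sequential
    (Type I) in the order Gc, TW, Gc x TW.
    """
    blues = series.blues if hasattr(series, "blues") else pd.DataFrame(series)
    days = list(blues.columns)

    s, e = windows[otw]
    otw_mean = blues.iloc[:, s:e].mean(axis=1).dropna()
    if len(otw_mean) < n_groups:
        raise ValueError("not enough genotypes with data inside the OTW")
    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed).fit(
        otw_mean.to_numpy()[:, None]
    )
    order = np.argsort(km.cluster_centers_.ravel())
    names = ["low", "medium", "high"] if n_groups == 3 else [f"g{i}" for i in range(n_groups)]
    label_map = {int(c): names[i] for i, c in enumerate(order)}
    groups = pd.Series([label_map[int(c)] for c in km.labels_], index=otw_mean.index)

    rows = []
    for w, (ws, we) in enumerate(windows):
        if we <= ws:
            raise ValueError(f"window {w} is empty")
        wmean = blues.iloc[:, ws:we].mean(axis=1)
        for g in otw_mean.index:
            v = wmean.get(g, np.nan)
            if np.isnan(v):
                continue
            rows.append({"y": v, "gc": groups[g], "tw": f"TW{w + 1}"})
    df = pd.DataFrame(rows)
    model = ols("y ~ C(gc) + C(tw) + C(gc):C(tw)", data=df).fit()
    aov = anova_lm(model, typ=1)
    total_ss = float(aov["sum_sq"].sum())
    table = aov.rename(
        index={
            "C(gc)": "Gc",
            "C(tw)": "TW",
            "C(gc):C(tw)": "Gc:TW",
            "Residual": "Residuals",
        }
    )
    table = table.rename(columns={"df": "Df", "sum_sq": "SS", "mean_sq": "MS", "PR(>F)": "p"})
    table["SS_pct"] = 100.0 * table["SS"] / total_ss
    table = table[["Df", "SS", "SS_pct", "MS", "F", "p"]]
    return AnovaResult(table=table, groups=groups, total_ss=total_ss)
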