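"""Clustering, Clust-Dist, change-point analysis, OTW rule, and the ANOVA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import phenopipe as pp
from phenopipe.temporal import ChangePointResult, _segment_best_split, _window_summaries


def _growth_matrix(families, n_days=15, noise=0.3, seed=0):
    """Stack logistic series per family with small perturbations."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_days, dtype=float)
    rows, names = [], []
    for fam, (a, k, t0, n) in enumerate(families):
        for i in range(n):
            y = a / (1 + np.exp(-k * (t - t0))) + rng.normal(0, noise, n_days)
            rows.append(y)
            names.append(f"F{fam}_{i}")
    return pd.DataFrame(rows, index=names)


class TestKernelKMeans:
    def test_separable_families_recovered(self):
        m = _growth_matrix([(60, 0.5, 7, 6), (20, 0.3, 5, 6)])
        model = pp.kernel_kmeans(m, 2, seed=1)
        fam = pd.Series([n.split("_")[0] for n in m.index], index=m.index)
        tab = pd.crosstab(model.assignment, fam)
        assert (tab.max(axis=1) == tab.sum(axis=1)).all()  # pure clusters

    def test_duplicates_co_clustered(self):
        m = _growth_matrix([(50, 0.5, 7, 4), (15, 0.3, 5, 4)], noise=0.2, seed=2)
        m.loc["dup"] = m.iloc[0]
        model = pp.kernel_kmeans(m, 2, seed=3)
        assert model.assignment["dup"] == model.assignment[m.index[0]]

    def test_objective_matches_exhaustive_minimum(self):
        """n=8, k=2: the kernel objective equals the brute-force optimum."""
        rng = np.random.default_rng(5)
        x = rng.normal(0, 2, size=(8, 4))
        m = pd.DataFrame(x)
        sigma = 2.0
        model = pp.kernel_kmeans(m, 2, bandwidth=sigma, seed=1)
        d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
        kmat = np.exp(-d2 / (2 * sigma**2))

        def dispersion(idx):
            if len(idx) == 0:
                return np.inf
            sub = kmat[np.ix_(idx, idx)]
            return np.trace(sub) - sub.sum() / len(idx)

        best = np.inf
        for size in range(1, 8):
            for grp in combinations(range(8), size):
                other = [i for i in range(8) if i not in grp]
                best = min(best, dispersion(list(grp)) + dispersion(other))
        assert model.objective == pytest.approx(best, rel=1e-10)

    def test_invariant_to_genotype_reordering(self):
        m = _growth_matrix([(60, 0.5, 7, 5), (30, 0.4, 6, 5), (10, 0.3, 5, 5)])
        a = pp.kernel_kmeans(m, 3, seed=1)
        perm = m.sample(frac=1.0, random_state=9)
        b = pp.kernel_kmeans(perm, 3, seed=1)
        parts_a = {frozenset(a.assignment[a.assignment == c].index) for c in range(3)}
        parts_b = {frozenset(b.assignment[b.assignment == c].index) for c in range(3)}
        assert parts_a == parts_b
        assert a.silhouette == pytest.approx(b.silhouette)


class TestSelectK:
    def test_three_separable_families(self):
        m = _growth_matrix([(70, 0.5, 7, 5), (40, 0.4, 6, 5), (10, 0.3, 5, 5)])
        assert pp.select_k(m, range(2, 6), seed=1) == 3

    def test_homogeneous_blob_flagged(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(0, 1, size=(30, 8)))
        with pytest.warns(UserWarning, match="silhouette"):
            k = pp.select_k(m, [2, 3, 4], seed=1)
        assert 2 <= k <= 4

    def test_silhouette_matches_direct_formula(self):
        """Mean (b-a)/max(a,b) over points, computed from scratch."""
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(6, 1, (5, 3))])
        m = pd.DataFrame(x)
        model = pp.kernel_kmeans(m, 2, seed=1)
        labels = model.assignment.to_numpy()
        d = np.sqrt(np.sum((x[:, None] - x[None, :]) ** 2, axis=-1))
        scores = []
        for i in range(len(x)):
            same = (labels == labels[i]) & (np.arange(len(x)) != i)
            a = d[i, same].mean()
            b = min(
                d[i, labels == c].mean() for c in set(labels) if c != labels[i]
            )
            scores.append((b - a) / max(a, b))
        assert model.silhouette == pytest.approx(np.mean(scores), abs=1e-12)


class TestClustDist:
    def _series(self, blues):
        return type("S", (), {"blues": blues})()

    def test_identical_clusters_zero(self):
        blues = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]],
            index=list("abcd"), columns=["d1", "d2"],
        )
        model = type("M", (), {"assignment": pd.Series([0, 0, 1, 1], index=list("abcd"))})()
        cd = pp.clust_dist_series(model, self._series(blues))
        assert (cd == 0).all()

    def test_two_cluster_arithmetic(self):
        blues = pd.DataFrame(
            [[10.0], [10.0], [30.0], [30.0]], index=list("abcd"), columns=["d1"]
        )
        model = type("M", (), {"assignment": pd.Series([0, 0, 1, 1], index=list("abcd"))})()
        cd = pp.clust_dist_series(model, self._series(blues))
        assert cd["d1"] == pytest.approx(20.0)

    def test_three_cluster_mean_pairwise(self):
        blues = pd.DataFrame(
            [[0.0], [6.0], [9.0]], index=list("abc"), columns=["d1"]
        )
        model = type("M", (), {"assignment": pd.Series([0, 1, 2], index=list("abc"))})()
        cd = pp.clust_dist_series(model, self._series(blues))
        assert cd["d1"] == pytest.approx(np.mean([6.0, 9.0, 3.0]))


class TestEDivisive:
    def test_null_series_mostly_clean(self):
        hits = 0
        for seed in range(10):
            z = np.random.default_rng(seed).normal(size=(22, 2))
            res = pp.e_divisive(z, alpha=0.05, min_size=3, n_perm=99, seed=seed)
            hits += len(res.change_points) == 0
        assert hits >= 9

    def test_single_shift_located_and_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(22, 2))
        z[11:] += 5.0
        res = pp.e_divisive(z, alpha=0.05, min_size=3, n_perm=199, seed=1)
        assert len(res.change_points) >= 1
        assert abs(res.change_points[0] - 11) <= 1

        # brute-force single-split oracle on the standardized series
        zs = (z - z.mean(0)) / z.std(0)
        dist = np.sqrt(np.sum((zs[:, None] - zs[None, :]) ** 2, axis=-1))
        best_q, best_tau = -np.inf, None
        for tau in range(3, 20):
            a, b = np.arange(0, tau), np.arange(tau, 22)
            between = dist[np.ix_(a, b)].mean()
            wa = dist[np.ix_(a, a)][np.triu_indices(len(a), 1)].mean()
            wb = dist[np.ix_(b, b)][np.triu_indices(len(b), 1)].mean()
            q = len(a) * len(b) / 22 * (2 * between - wa - wb)
            if q > best_q:
                best_q, best_tau = q, tau
        impl_q, impl_tau = _segment_best_split(dist, 0, 22, 3)
        assert impl_tau == best_tau
        assert impl_q == pytest.approx(best_q, rel=1e-12)
        assert res.change_points[0] == best_tau

    def test_four_phase_series_splits(self):
        rng = np.random.default_rng(2)
        h2 = np.concatenate([
            np.full(6, 0.3), np.full(6, 0.75), np.full(6, 0.5), np.full(6, 0.2)
        ]) + rng.normal(0, 0.02, 24)
        cd = np.concatenate([
            np.linspace(0, 1, 6), np.linspace(1, 8, 6),
            np.linspace(8, 10, 6), np.full(6, 10.0)
        ]) + rng.normal(0, 0.1, 24)
        res = pp.e_divisive(np.column_stack([h2, cd]), n_perm=199, seed=3)
        assert len(res.change_points) >= 2

    def test_affine_invariance_of_inputs(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=(20, 2))
        z[10:, 0] += 4.0
        res1 = pp.e_divisive(z.copy(), n_perm=99, seed=5)
        z2 = z.copy()
        z2[:, 0] = z2[:, 0] * 250.0 - 14.0
        z2[:, 1] = z2[:, 1] * 0.001 + 3.0
        res2 = pp.e_divisive(z2, n_perm=99, seed=5)
        assert res1.change_points == res2.change_points

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=(24, 2))
        z[8:16] += 2.0
        counts = []
        for alpha in (0.5, 0.05, 0.005):
            res = pp.e_divisive(z, alpha=alpha, n_perm=199, seed=2)
            counts.append(len(res.change_points))
        assert counts == sorted(counts, reverse=True)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            pp.e_divisive(np.zeros((5, 2)), min_size=3)


def _cp_result(medians, slopes):
    n = len(medians)
    pw = pd.DataFrame(
        {
            "start": range(n), "end": range(1, n + 1),
            "median_h2": medians, "clust_dist_slope": slopes,
        }
    )
    return ChangePointResult([], [(i, i + 1) for i in range(n)], pw, 0.05, 199)


class TestSelectOTW:
    def test_interior_rising_max_h2(self):
        res = _cp_result([0.3, 0.7, 0.5, 0.2], [1.0, 1.0, 1.0, -1.0])
        assert pp.select_otw(res) == 1  # the second window

    def test_tie_takes_earliest_interior(self):
        res = _cp_result([0.5, 0.5, 0.5, 0.5], [1.0, 1.0, 1.0, 1.0])
        assert pp.select_otw(res) == 1

    def test_two_windows_fall_back_to_max_median(self):
        res = _cp_result([0.4, 0.6], [1.0, 1.0])
        assert pp.select_otw(res) == 1
        assert res.otw_rule == "global-max-median-h2"

    def test_single_window_warns(self):
        res = _cp_result([0.4], [1.0])
        with pytest.warns(UserWarning, match="single"):
            assert pp.select_otw(res) == 0


class TestGcTwAnova:
    def _series(self, blues):
        return type("S", (), {"blues": blues})()

    def _balanced_blues(self, cell_means, per_group=4, noise=0.0, seed=0):
        """Genotype x day matrix whose window means hit given 3x3 cell means."""
        rng = np.random.default_rng(seed)
        rows, names = [], []
        for grp in range(3):
            for i in range(per_group):
                days = []
                for win in range(3):
                    days += [cell_means[grp][win] + rng.normal(0, noise)] * 2
                rows.append(days)
                names.append(f"g{grp}_{i}")
        cols = [f"d{j}" for j in range(6)]
        return pd.DataFrame(rows, index=names, columns=cols)

    def test_additive_construction_has_no_interaction(self):
        grp_eff = [0.0, 5.0, 10.0]
        win_eff = [0.0, 20.0, 40.0]
        cells = [[g + w for w in win_eff] for g in grp_eff]
        blues = self._balanced_blues(cells, noise=0.05, seed=1)
        windows = [(0, 2), (2, 4), (4, 6)]
        res = pp.gc_tw_anova(self._series(blues), windows, otw=1, seed=1)
        assert res.table.loc["Gc:TW", "SS_pct"] < 0.5
        assert res.table.loc["Gc:TW", "p"] > 0.05

    def test_balanced_closed_form_sums_of_squares(self):
        cells = [[1.0, 4.0, 2.0], [6.0, 9.0, 3.0], [11.0, 15.0, 8.0]]
        blues = self._balanced_blues(cells, noise=0.2, seed=3)
        windows = [(0, 2), (2, 4), (4, 6)]
        res = pp.gc_tw_anova(self._series(blues), windows, otw=1, seed=1)

        # closed-form two-way ANOVA sums of squares (balanced design)
        y, gc, tw = [], [], []
        groups = res.groups
        for g in blues.index:
            for w, (s, e) in enumerate(windows):
                y.append(blues.loc[g].iloc[s:e].mean())
                gc.append(groups[g])
                tw.append(w)
        df = pd.DataFrame({"y": y, "gc": gc, "tw": tw})
        grand = df["y"].mean()
        n_a = df.groupby("gc")["y"].count()
        ss_a = float((n_a * (df.groupby("gc")["y"].mean() - grand) ** 2).sum())
        n_b = df.groupby("tw")["y"].count()
        ss_b = float((n_b * (df.groupby("tw")["y"].mean() - grand) ** 2).sum())
        cell = df.groupby(["gc", "tw"])["y"].agg(["mean", "count"])
        ss_cells = float((cell["count"] * (cell["mean"] - grand) ** 2).sum())
        ss_ab = ss_cells - ss_a - ss_b
        ss_tot = float(((df["y"] - grand) ** 2).sum())
        ss_err = ss_tot - ss_cells

        assert res.table.loc["Gc", "SS"] == pytest.approx(ss_a, rel=1e-8)
        assert res.table.loc["TW", "SS"] == pytest.approx(ss_b, rel=1e-8)
        assert res.table.loc["Gc:TW", "SS"] == pytest.approx(ss_ab, rel=1e-8)
        assert res.table.loc["Residuals", "SS"] == pytest.approx(ss_err, rel=1e-8)
        assert res.total_ss == pytest.approx(ss_tot, rel=1e-8)

    def test_ss_components_sum_to_total(self):
        cells = [[1.0, 2.0, 3.0], [2.0, 6.0, 4.0], [3.0, 9.0, 12.0]]
        blues = self._balanced_blues(cells, noise=0.3, seed=5)
        res = pp.gc_tw_anova(self._series(blues), [(0, 2), (2, 4), (4, 6)], otw=1)
        assert res.table["SS"].sum() == pytest.approx(res.total_ss, rel=1e-10)
        assert res.table["SS_pct"].sum() == pytest.approx(100.0, rel=1e-8)


def test_window_summaries_slope_and_median():
    raw = np.column_stack([
        np.array([0.2, 0.4, 0.6, 0.5, 0.5, 0.5]),
        np.array([1.0, 2.0, 3.0, 7.0, 7.0, 7.0]),
    ])
    pw = _window_summaries(raw, [(0, 3), (3, 6)])
    assert pw.loc[0, "median_h2"] == pytest.approx(0.4)
    assert pw.loc[0, "clust_dist_slope"] == pytest.approx(1.0)
    assert pw.loc[1, "clust_dist_slope"] == pytest.approx(0.0)
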