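import numpy as np
import pandas as pd
import pytest

from dormqtl._rng import substream
from dormqtl.binmap import BinMap
from dormqtl.qtl import (RidgeQTLScanner, calls_to_f2_classes, cluster_sd_regions,
                         declare_qtls, epistasis_anova, f2_single_marker,
                         lmg_decomposition)


def _binmap(n, chrom="chr1"):
    bins = pd.DataFrame({
        "bin_id": [f"Bin{i + 1}" for i in range(n)],
        "chrom": [chrom] * n,
        "start": np.arange(n) * 1000,
        "end": (np.arange(n) + 1) * 1000,
    })
    return BinMap(bins, {chrom: n * 1000})


class TestRidgeScanner:
    def _design(self, n=60, p=8, seed=0):
        rng = substream(seed, "design")
        return rng.choice([0.0, 1.0], size=(n, p), p=[0.75, 0.25])

    def test_duplicate_column_no_collinearity_failure(self):
        X = self._design()
        X = np.column_stack([X, X[:, 0]])  # exact duplicate of the signal bin
        rng = substream(1, "y")
        y = 5 * X[:, 0] + rng.normal(size=len(X))
        sc = RidgeQTLScanner(n_permutations=200, random_state=0).fit(X, y)
        # both copies share the signal
        assert sc.pvalues_[0] < 0.05 and sc.pvalues_[-1] < 0.05
        assert np.isfinite(sc.coef_).all()

    def test_permutation_pvalues_reproducible_and_order_invariant(self):
        X = self._design()
        rng = substream(2, "y")
        y = 3 * X[:, 2] + rng.normal(size=len(X))
        sc1 = RidgeQTLScanner(n_permutations=300, random_state=7).fit(X, y)
        sc2 = RidgeQTLScanner(n_permutations=300, random_state=7).fit(X, y)
        assert np.array_equal(sc1.pvalues_, sc2.pvalues_)
        # at a fixed penalty the fit depends on the data only through X'X and
        # X'y, so reordering the (line, trait) pairs leaves it unchanged;
        # with penalty='cv' the fold split (not the fit) depends on row order
        order = substream(3, "perm").permutation(len(y))
        sca = RidgeQTLScanner(n_permutations=300, penalty=10.0, random_state=7).fit(X, y)
        scb = RidgeQTLScanner(n_permutations=300, penalty=10.0,
                              random_state=7).fit(X[order], y[order])
        assert np.allclose(scb.coef_, sca.coef_)
        assert np.argmax(np.abs(scb.coef_)) == np.argmax(np.abs(sca.coef_))

    def test_constant_trait_rejected(self):
        X = self._design()
        with pytest.raises(ValueError, match="constant trait"):
            RidgeQTLScanner(n_permutations=200).fit(X, np.ones(len(X)))

    def test_too_few_lines_rejected(self):
        X = self._design(n=10)
        with pytest.raises(ValueError, match="need >="):
            RidgeQTLScanner(n_permutations=200).fit(X, np.arange(10.0))

    def test_ridge_t_alternative(self):
        X = self._design()
        rng = substream(4, "y")
        y = 4 * X[:, 1] + rng.normal(size=len(X))
        sc = RidgeQTLScanner(p_method="ridge-t").fit(X, y)
        assert sc.pvalues_[1] < 0.01
        assert ((sc.pvalues_ >= 0) & (sc.pvalues_ <= 1)).all()


class TestDeclareQTLs:
    def test_run_collapse_and_peak(self):
        bm = _binmap(3)
        recs = declare_qtls(np.array([0.001, 0.002, 0.5]), np.array([1, 1, -1]),
                            bm, "G3d")
        assert len(recs) == 1
        assert recs[0].peak_bin_id == "Bin1" and recs[0].n_span_bins == 2
        assert recs[0].name == "qG3d1.1"

    def test_two_runs_split_by_gap(self):
        bm = _binmap(5)
        p = np.array([0.001, 0.5, 0.001, 0.002, 0.9])
        recs = declare_qtls(p, np.ones(5, dtype=int), bm, "AUC")
        assert [r.peak_bin_id for r in recs] == ["Bin1", "Bin3"]
        assert [r.name for r in recs] == ["qAUC1.1", "qAUC1.2"]

    def test_empty_when_nothing_significant(self):
        bm = _binmap(4)
        assert declare_qtls(np.full(4, 0.5), np.ones(4, dtype=int), bm, "T50") == []

    def test_nan_breaks_adjacency(self):
        bm = _binmap(3)
        p = np.array([0.001, np.nan, 0.001])
        recs = declare_qtls(p, np.ones(3, dtype=int), bm, "G7d")
        assert len(recs) == 2

    def test_tie_break_prefers_stat_then_lower_coordinate(self):
        bm = _binmap(4)
        p = np.array([0.001, 0.001, 0.001, 0.5])
        stats = np.array([0.1, 0.9, 0.3, 0.0])
        recs = declare_qtls(p, np.ones(4, dtype=int), bm, "G3d", stats=stats)
        assert recs[0].peak_bin_id == "Bin2"
        recs = declare_qtls(p, np.ones(4, dtype=int), bm, "G3d")
        assert recs[0].peak_bin_id == "Bin1"

    def test_order_of_input_does_not_matter(self):
        # supplying the same aligned arrays twice yields identical records
        bm = _binmap(6)
        rng = substream(5, "p")
        p = rng.uniform(size=6) * 0.01
        recs1 = declare_qtls(p, np.ones(6, dtype=int), bm, "G3d")
        recs2 = declare_qtls(p.copy(), np.ones(6, dtype=int), bm, "G3d")
        assert [(r.name, r.peak_bin_id) for r in recs1] == \
               [(r.name, r.peak_bin_id) for r in recs2]


class TestLMG:
    def test_orthogonal_shares_equal_marginal_r2(self):
        rng = substream(6, "lmg")
        n = 400
        X = rng.normal(size=(n, 3))
        X = np.linalg.qr(X - X.mean(axis=0))[0]  # orthonormal, mean-zero columns
        y = 2 * X[:, 0] + 1 * X[:, 1] + rng.normal(size=n)
        shares, r2, _ = lmg_decomposition(X, y)
        yc = y - y.mean()
        for j in range(3):
            xj = X[:, j] - X[:, j].mean()
            marginal = float((xj @ yc) ** 2 / ((xj @ xj) * (yc @ yc)))
            assert shares[j] == pytest.approx(marginal, abs=1e-6)

    def test_shares_sum_to_full_r2(self):
        rng = substream(7, "lmg")
        X = rng.normal(size=(100, 6)) @ rng.normal(size=(6, 6))  # correlated
        y = X @ rng.normal(size=6) + rng.normal(size=100)
        shares, r2, _ = lmg_decomposition(X, y)
        assert shares.sum() == pytest.approx(r2, abs=1e-9)
        assert (shares >= -1e-12).all()

    def test_two_predictor_case_matches_ordering_average(self):
        rng = substream(8, "lmg")
        x1 = rng.normal(size=200)
        x2 = 0.6 * x1 + 0.8 * rng.normal(size=200)
        y = x1 + 0.5 * x2 + rng.normal(size=200)
        X = np.column_stack([x1, x2])
        shares, r2, _ = lmg_decomposition(X, y)

        def ols_r2(cols):
            if not cols:
                return 0.0
            A = np.column_stack([X[:, c] for c in cols])
            A = np.column_stack([np.ones(len(A)), A])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            return 1 - resid.var() / y.var()

        # brute force over the 2! orderings
        expect_1 = 0.5 * (ols_r2([0]) + (ols_r2([0, 1]) - ols_r2([1])))
        expect_2 = 0.5 * (ols_r2([1]) + (ols_r2([0, 1]) - ols_r2([0])))
        assert shares[0] == pytest.approx(expect_1, abs=1e-9)
        assert shares[1] == pytest.approx(expect_2, abs=1e-9)

    def test_symmetry_under_relabeling(self):
        rng = substream(9, "lmg")
        X = rng.normal(size=(150, 4)) @ rng.normal(size=(4, 4))
        y = X @ np.array([1.0, -0.5, 0.3, 0.0]) + rng.normal(size=150)
        shares, _, _ = lmg_decomposition(X, y)
        perm = [2, 0, 3, 1]
        shares_p, _, _ = lmg_decomposition(X[:, perm], y)
        assert np.allclose(shares_p, shares[perm], atol=1e-9)

    def test_collinear_duplicates_merged(self):
        rng = substream(10, "lmg")
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        y = x + rng.normal(size=100)
        shares, r2, merges = lmg_decomposition(X, y)
        assert merges == [(1, 0)]
        assert shares[0] == shares[1]
        assert shares[0] + shares[2] == pytest.approx(r2, abs=1e-9)

    def test_monte_carlo_close_to_exact(self):
        rng = substream(11, "lmg")
        X = rng.normal(size=(120, 5)) @ rng.normal(size=(5, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=120)
        exact, r2, _ = lmg_decomposition(X, y)
        mc, r2mc, _ = lmg_decomposition(X, y, exact_limit=0, n_orderings=4000, seed=1)
        assert np.allclose(mc, exact, atol=0.02)
        assert r2mc == pytest.approx(r2, abs=1e-9)


class TestClusterRegions:
    def _rec(self, trait, chrom, start, end, serial=1):
        from dormqtl.qtl import QTLRecord
        return QTLRecord(trait, f"q{trait}{chrom[-1]}.{serial}", chrom, "Bin1", 0,
                         start, end, 0.001, 1, start, end, 1)

    def test_same_region_three_traits(self):
        recs = [self._rec(t, "chr3", 100, 200) for t in ("G3d", "AUC", "T50")]
        regions = cluster_sd_regions(recs)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_traits == 3 and not r.all_traits and r.name == "qSD3.1"

    def test_disjoint_qtls_give_no_region(self):
        recs = [self._rec(t, "chr3", i * 1000, i * 1000 + 100)
                for i, t in enumerate(("G3d", "AUC", "T50", "G7d"))]
        assert cluster_sd_regions(recs) == []

    def test_all_four_traits_flagged(self):
        recs = [self._rec(t, "chr5", 0, 500) for t in ("G3d", "AUC", "T50", "G7d")]
        regions = cluster_sd_regions(recs)
        assert regions[0].all_traits and regions[0].n_traits == 4

    def test_two_traits_insufficient(self):
        recs = [self._rec(t, "chr2", 100, 300) for t in ("G3d", "AUC")]
        assert cluster_sd_regions(recs) == []


class TestF2SingleMarker:
    def _population(self, means, n_per=(25, 50, 25), noise=0.0, seed=0):
        rng = substream(seed, "f2")
        g, y = [], []
        for cls, m, n in zip(("AA", "AB", "BB"), means, n_per):
            g += [cls] * n
            y += list(m + noise * rng.normal(size=n))
        return np.array(g), np.array(y)

    def test_additive_dominance_closed_form(self):
        g, y = self._population((20.0, 44.0, 60.0))
        res = f2_single_marker(g, y)
        assert res.additive == pytest.approx(-20.0)
        assert res.dominance == pytest.approx(4.0)

    def test_midparent_heterozygote_zero_dominance(self):
        g, y = self._population((20.0, 40.0, 60.0))
        assert f2_single_marker(g, y).dominance == pytest.approx(0.0)

    def test_zero_residual_full_pve(self):
        g, y = self._population((10.0, 20.0, 30.0))
        res = f2_single_marker(g, y)
        assert res.pve == pytest.approx(100.0)
        assert res.pvalue == 0.0 and np.isinf(res.lod)

    def test_missing_class_reports_computable_remainder(self):
        g = np.array(["AA"] * 30 + ["AB"] * 30)
        y = np.concatenate([np.full(30, 10.0), np.full(30, 20.0)]) \
            + substream(1, "e").normal(size=60)
        res = f2_single_marker(g, y)
        assert res.additive is None and res.dominance is None
        assert res.pvalue < 0.001

    def test_pve_between_class_share(self):
        g, y = self._population((20.0, 30.0, 40.0), noise=5.0, seed=2)
        res = f2_single_marker(g, y)
        grand = y.mean()
        ssb = sum((y[g == c].mean() - grand) ** 2 * (g == c).sum()
                  for c in ("AA", "AB", "BB"))
        assert res.pve == pytest.approx(100 * ssb / ((y - grand) ** 2).sum())


class TestEpistasisANOVA:
    def _balanced(self, cell_means, reps=5, noise=0.0, seed=0):
        rng = substream(seed, "epi")
        g1, g2, y = [], [], []
        for (a, b), m in cell_means.items():
            for _ in range(reps):
                g1.append(a)
                g2.append(b)
                y.append(m + noise * rng.normal())
        return np.array(g1), np.array(g2), np.array(y)

    def test_additive_cells_zero_interaction_ss(self):
        classes = ("AA", "AB", "BB")
        effects = {"AA": 0.0, "AB": 5.0, "BB": 10.0}
        cells = {(a, b): effects[a] + effects[b] for a in classes for b in classes}
        g1, g2, y = self._balanced(cells)
        tab = epistasis_anova(g1, g2, y)
        assert tab.anova.loc["interaction", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
        assert tab.n_cells == 9

    def test_balanced_zero_noise_matches_hand_sums_of_squares(self):
        classes = ("AA", "AB", "BB")
        cells = {("AA", "AA"): 19.1, ("AA", "AB"): 30.0, ("AA", "BB"): 40.0,
                 ("AB", "AA"): 35.0, ("AB", "AB"): 45.0, ("AB", "BB"): 55.0,
                 ("BB", "AA"): 50.0, ("BB", "AB"): 60.0, ("BB", "BB"): 72.1}
        reps = 4
        g1, g2, y = self._balanced(cells, reps=reps)
        tab = epistasis_anova(g1, g2, y)
        # classical balanced two-way sums of squares by hand
        M = np.array([[cells[(a, b)] for b in classes] for a in classes])
        grand = M.mean()
        ss_a = reps * 3 * ((M.mean(axis=1) - grand) ** 2).sum()
        ss_b = reps * 3 * ((M.mean(axis=0) - grand) ** 2).sum()
        ss_int = reps * ((M - M.mean(1, keepdims=True) - M.mean(0, keepdims=True)
                          + grand) ** 2).sum()
        assert tab.anova.loc["locus1", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
        assert tab.anova.loc["locus2", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert tab.anova.loc["interaction", "sum_sq"] == pytest.approx(ss_int, rel=1e-9)
        assert tab.anova.loc["residual", "sum_sq"] == pytest.approx(0.0, abs=1e-16)
        assert tab.anova["df"].sum() == len(y) - 1

    def test_empty_cell_noted_with_reduced_df(self):
        cells = {(a, b): 1.0 for a in ("AA", "BB") for b in ("AA", "AB", "BB")}
        cells.update({("AB", "AA"): 2.0, ("AB", "AB"): 3.0})  # (AB, BB) absent
        g1, g2, y = self._balanced(cells, reps=3, noise=1.0, seed=3)
        tab = epistasis_anova(g1, g2, y)
        assert tab.n_cells == 8 and "reduced" in tab.note

    def test_single_class_locus_rejected(self):
        g1 = np.array(["AA"] * 20)
        g2 = np.array(["AA", "BB"] * 10)
        with pytest.raises(ValueError, match="fewer than two"):
            epistasis_anova(g1, g2, np.arange(20.0))


def test_f2_class_conversion():
    calls = np.array(["A", "H", "B", "-"])
    assert list(calls_to_f2_classes(calls)) == ["AA", "AB", "BB", ""]
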