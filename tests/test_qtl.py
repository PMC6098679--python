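"""Genotype-probability HMM, Haley-Knott scans, thresholds, stepwise models."""

import numpy as np
import pandas as pd
import pytest

from berrymorph.qtl import (calc_genoprob, collocate, covariate_diallel,
                            explained_variance, hk_scan, hk_scan_batch,
                            models_to_table, perm_threshold, stepwise_additive,
                            support_interval, Penalty, QTL, QTLModel)
from berrymorph.synthetic import (PlantedQTL, SimCross, TraitModel, haldane_r,
                                  make_linkage_map, simulate_cross,
                                  simulate_phenotypes)


def _two_marker_cross(codes: np.ndarray, d_cm: float = 20.0) -> SimCross:
    gmap = pd.DataFrame({"marker": ["m1", "m2"], "lg": [1, 1], "cm": [0.0, d_cm]})
    ids = [f"i{k}" for k in range(codes.shape[0])]
    return SimCross(gmap, codes, ids)


def _midpoint_oracle(o1: int, o2: int, d_cm: float) -> np.ndarray:
    """Brute-force two-locus conditional: enumerate parental gamete chains."""
    r = float(haldane_r(d_cm / 2.0))
    T = np.array([[1 - r, r], [r, 1 - r]])
    post = np.zeros(4)
    m1, p1 = (o1 - 1) // 2, (o1 - 1) % 2
    m2, p2 = (o2 - 1) // 2, (o2 - 1) % 2
    for mm in range(2):
        for pm in range(2):
            w = T[m1, mm] * T[mm, m2] * T[p1, pm] * T[pm, p2]
            post[2 * mm + pm] += w
    return post / post.sum()


class TestGenoProb:
    def test_typed_marker_certain_without_error(self):
        codes = np.array([[1, 3], [2, 4], [4, 1]])
        cross = _two_marker_cross(codes)
        probs = calc_genoprob(cross, step_cm=0.0, error_rate=0.0)
        markers = probs.positions["is_marker"].to_numpy()
        for i in range(3):
            for j in np.nonzero(markers)[0]:
                obs = codes[i, int(probs.positions.loc[j, "cm"] > 0)]
                assert probs.probs[i, j, obs - 1] == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one(self, cross351):
        probs = calc_genoprob(cross351, step_cm=2.0)
        assert np.allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)
        assert probs.probs.min() >= 0.0

    def test_midpoint_matches_bruteforce_enumeration(self):
        d = 20.0
        codes = np.array([[o1, o2] for o1 in range(1, 5) for o2 in range(1, 5)])
        cross = _two_marker_cross(codes, d)
        probs = calc_genoprob(cross, step_cm=10.0, error_rate=0.0)
        mid = int(np.nonzero(np.isclose(probs.positions["cm"], 10.0))[0][0])
        for i, (o1, o2) in enumerate(codes):
            expect = _midpoint_oracle(o1, o2, d)
            assert np.allclose(probs.probs[i, mid], expect, atol=1e-9)

    def test_missing_genotype_uniform_at_isolated_marker(self):
        gmap = pd.DataFrame({"marker": ["m1"], "lg": [1], "cm": [0.0]})
        cross = SimCross(gmap, np.array([[0]]), ["i0"])
        probs = calc_genoprob(cross, step_cm=0.0)
        assert np.allclose(probs.probs[0, 0], 0.25)


class TestScan:
    def test_constant_phenotype_zero_lod(self, cross351):
        probs = calc_genoprob(cross351, step_cm=5.0)
        sc = hk_scan(probs, np.full(351, 1.0))
        assert np.allclose(sc.table["lod"], 0.0, atol=1e-9)

    def test_noise_free_class_means_peak_at_marker(self, cross351):
        probs = calc_genoprob(cross351, step_cm=1.0)
        cls = cross351.qtl_geno[(1, 30.0)]
        y = np.array([0.0, 1.0, 2.0, 3.0])[cls - 1]
        sc = hk_scan(probs, y)
        peak = sc.peak()
        assert peak["lg"] == 1
        assert abs(peak["cm"] - 30.0) <= 1.0

    def test_twelve_individual_ols_oracle(self):
        codes = np.array([[1, 1], [1, 2], [2, 2], [2, 3], [3, 3], [3, 4],
                          [4, 4], [4, 1], [1, 3], [2, 4], [3, 1], [4, 2]])
        cross = _two_marker_cross(codes, 25.0)
        probs = calc_genoprob(cross, step_cm=0.0, error_rate=0.0)
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        sc = hk_scan(probs, y)
        for j in range(len(sc.table)):
            X = np.column_stack([np.ones(12), probs.probs[:, j, 1:]])
            # normal-equations least squares, computed independently
            beta = np.linalg.solve(X.T @ X + 1e-12 * np.eye(4), X.T @ y)
            rss1 = np.sum((y - X @ beta) ** 2)
            rss0 = np.sum((y - y.mean()) ** 2)
            lod = 6.0 * np.log10(rss0 / rss1)
            assert sc.table.loc[j, "lod"] == pytest.approx(lod, abs=1e-6)

    def test_affine_invariance(self, cross351):
        probs = calc_genoprob(cross351, step_cm=5.0)
        rng = np.random.default_rng(4)
        y = rng.normal(size=351)
        l0 = hk_scan(probs, y).table["lod"]
        l1 = hk_scan(probs, 3.0 * y - 7.0).table["lod"]
        assert np.allclose(l0, l1, atol=1e-9)

    def test_batch_matches_single(self, cross351):
        probs = calc_genoprob(cross351, step_cm=5.0)
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(351, 3))
        batch = hk_scan_batch(probs, Y)
        for j in range(3):
            single = hk_scan(probs, Y[:, j]).table["lod"].to_numpy()
            assert np.allclose(batch[:, j], single, atol=1e-6)


class TestPermutationThreshold:
    def test_same_seed_identical(self, cross351):
        probs = calc_genoprob(cross351, step_cm=5.0)
        rng = np.random.default_rng(6)
        y = rng.normal(size=351)
        p1 = perm_threshold(probs, y, n_perm=100, seed=9)
        p2 = perm_threshold(probs, y, n_perm=100, seed=9)
        assert p1.T_m == p2.T_m

    def test_type7_quantile_convention(self, cross351):
        # recompute the quantile by hand from the same permutation stream
        probs = calc_genoprob(cross351, step_cm=5.0)
        rng = np.random.default_rng(7)
        y = rng.normal(size=351)
        pen = perm_threshold(probs, y, n_perm=200, alpha=0.05, seed=13)
        rng2 = np.random.default_rng(13)
        perms = np.stack([rng2.permutation(351) for _ in range(200)], axis=1)
        maxlod = hk_scan_batch(probs, y[perms]).max(axis=0)
        s = np.sort(maxlod)
        h = (200 - 1) * 0.95
        expect = s[int(h)] + (h - int(h)) * (s[int(h) + 1] - s[int(h)])
        assert pen.T_m == pytest.approx(expect, abs=1e-12)

    def test_too_few_permutations_rejected(self, cross351):
        probs = calc_genoprob(cross351, step_cm=5.0)
        with pytest.raises(ValueError):
            perm_threshold(probs, np.zeros(351), n_perm=50)


class TestSupportInterval:
    def test_triangular_curve_crossings(self):
        cm = np.arange(0.0, 21.0)
        lod = 10.0 - np.abs(cm - 10.0)  # peak 10 at 10 cM
        curve = pd.DataFrame({"lg": 1, "cm": cm, "lod": lod})
        lo, hi = support_interval(curve, 10.0, drop=1.5)
        # LOD >= 8.5 on [8.5, 11.5] -> grid run [9, 11], expanded one point
        assert (lo, hi) == (8.0, 12.0)

    def test_flat_curve_whole_lg(self):
        curve = pd.DataFrame({"lg": 1, "cm": np.arange(0.0, 50.0, 5.0), "lod": 3.0})
        assert support_interval(curve, 20.0) == (0.0, 45.0)

    def test_zero_drop_degenerate(self):
        cm = np.arange(0.0, 21.0)
        lod = 10.0 - np.abs(cm - 10.0)
        curve = pd.DataFrame({"lg": 1, "cm": cm, "lod": lod})
        lo, hi = support_interval(curve, 10.0, drop=0.0)
        assert (lo, hi) == (9.0, 11.0)  # peak point expanded one grid step

    def test_interval_contains_peak(self):
        rng = np.random.default_rng(11)
        cm = np.arange(0.0, 60.0, 2.0)
        lod = np.abs(np.cumsum(rng.normal(size=len(cm))))
        curve = pd.DataFrame({"lg": 1, "cm": cm, "lod": lod})
        peak = cm[int(np.argmax(lod))]
        lo, hi = support_interval(curve, peak)
        assert lo <= peak <= hi


class TestExplainedVariance:
    def test_empty_model_zero(self, cross351):
        probs = calc_genoprob(cross351, step_cm=5.0)
        rng = np.random.default_rng(12)
        model = QTLModel()
        out = explained_variance(model, probs, rng.normal(size=351))
        assert out.full_model_pct_var == 0.0

    def test_single_qtl_equals_r_squared(self):
        codes = np.array([[1, 1], [1, 2], [2, 2], [2, 3], [3, 3], [3, 4],
                          [4, 4], [4, 1], [1, 3], [2, 4], [3, 1], [4, 2]])
        cross = _two_marker_cross(codes, 25.0)
        probs = calc_genoprob(cross, step_cm=0.0, error_rate=0.0)
        rng = np.random.default_rng(13)
        y = rng.normal(size=12)
        q = QTL(1, 0.0, 0.0, np.zeros(4), 0.0, 0.0, 0.0)
        model = explained_variance(QTLModel([q]), probs, y)
        X = np.column_stack([np.ones(12), probs.probs[:, 0, 1:]])
        beta = np.linalg.solve(X.T @ X + 1e-12 * np.eye(4), X.T @ y)
        r2 = 1 - np.sum((y - X @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
        assert model.full_model_pct_var == pytest.approx(100 * r2, abs=1e-6)
        assert model.qtls[0].pct_var == pytest.approx(100 * r2, abs=1e-6)

    def test_unlinked_qtl_contributions_additive(self, two_lg_map):
        cross = simulate_cross(two_lg_map, 400, seed=41,
                               extra_loci=[(1, 30.0), (2, 30.0)])
        probs = calc_genoprob(cross, step_cm=0.0, error_rate=0.0)
        c1 = cross.qtl_geno[(1, 30.0)]
        c2 = cross.qtl_geno[(2, 30.0)]
        rng = np.random.default_rng(42)
        y = (np.array([1.0, 0, 0, -1.0])[c1 - 1]
             + np.array([0, 1.0, -1.0, 0])[c2 - 1] + rng.normal(0, 1, 400))
        pos = probs.positions
        qtls = []
        for lg in (1, 2):
            sub = pos[(pos["lg"] == lg)]
            cm = sub.loc[(sub["cm"] - 30.0).abs().idxmin(), "cm"]
            qtls.append(QTL(lg, float(cm), 0.0, np.zeros(4), 0.0, 0.0, 0.0))
        model = explained_variance(QTLModel(qtls), probs, y)
        total = sum(q.pct_var for q in model.qtls)
        assert total <= model.full_model_pct_var + 1e-6


class TestStepwise:
    def test_planted_qtl_recovered(self, cross351, qtl_trait_model):
        _, pg = simulate_phenotypes(cross351, [qtl_trait_model], n_years=1, seed=50)
        y = pg["t"].to_numpy()
        probs = calc_genoprob(cross351, step_cm=2.0)
        pen = perm_threshold(probs, y, n_perm=200, seed=51)
        model = stepwise_additive(probs, y, pen)
        assert model.size >= 1
        best = max(model.qtls, key=lambda q: q.lod)
        assert best.lg == 1
        assert abs(best.cm - 30.0) <= 10.0
        assert best.ci_lo <= best.cm <= best.ci_hi
        assert 0.0 <= best.pct_var <= 100.0
        assert model.full_model_pct_var >= best.pct_var - 1e-6

    def test_effects_track_planted_pattern(self, cross351):
        cls = cross351.qtl_geno[(1, 30.0)]
        rng = np.random.default_rng(52)
        y = np.array([2.0, 0.0, 0.0, -2.0])[cls - 1] + rng.normal(0, 1, 351)
        probs = calc_genoprob(cross351, step_cm=2.0)
        model = stepwise_additive(probs, y, Penalty(3.5, 0.05, 0, 0))
        best = max(model.qtls, key=lambda q: q.lod)
        assert best.effects[0] > best.effects[3]  # ac above bd, as planted
        assert best.effects.mean() == pytest.approx(0.0, abs=1e-9)


class TestCollocation:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["trait", "year", "covariate", "lg",
                                           "peak_cm", "lod", "pct_var",
                                           "ci_lo", "ci_hi"])

    def test_three_year_group(self):
        tab = self._table([("lw", y, "", 4, p, 5.0, 10.0, p - 3, p + 3)
                           for y, p in [(2014, 10.0), (2015, 12.0), (2016, 14.0)]])
        rep = collocate(tab, window_cm=8.0, min_years=3)
        assert len(rep) == 1
        assert rep.loc[0, "n_years"] == 3

    def test_nine_cm_apart_not_grouped(self):
        tab = self._table([("lw", 2014, "", 4, 10.0, 5.0, 10.0, 7.0, 13.0),
                           ("lw", 2015, "", 4, 19.0, 5.0, 10.0, 16.0, 22.0)])
        rep = collocate(tab, window_cm=8.0, min_years=2)
        assert rep.empty

    def test_exactly_eight_cm_grouped(self):
        tab = self._table([("lw", 2014, "", 4, 10.0, 5.0, 10.0, 7.0, 13.0),
                           ("lw", 2015, "", 4, 18.0, 5.0, 10.0, 15.0, 21.0)])
        rep = collocate(tab, window_cm=8.0, min_years=2)
        assert len(rep) == 1  # threshold is inclusive

    def test_single_year_empty(self):
        tab = self._table([("lw", 2014, "", 4, 10.0, 5.0, 10.0, 7.0, 13.0)])
        assert collocate(tab, min_years=2).empty

    def test_interval_overlap_mode(self):
        tab = self._table([("lw", 2014, "", 4, 10.0, 5.0, 10.0, 5.0, 15.0),
                           ("lw", 2015, "", 4, 25.0, 5.0, 10.0, 14.0, 30.0)])
        assert len(collocate(tab, min_years=2, mode="interval")) == 1
        tab2 = self._table([("lw", 2014, "", 4, 10.0, 5.0, 10.0, 5.0, 12.0),
                            ("lw", 2015, "", 4, 25.0, 5.0, 10.0, 20.0, 30.0)])
        assert collocate(tab2, min_years=2, mode="interval").empty


def test_trait_as_own_covariate_rejected(two_lg_map):
    cross = simulate_cross(two_lg_map, 60, seed=61)
    probs = calc_genoprob(cross, step_cm=10.0)
    rng = np.random.default_rng(62)
    y = rng.normal(size=60)
    cov = rng.normal(size=60)
    with pytest.raises(ValueError, match="own covariate"):
        hk_scan(probs, y, cov, trait="lw", covariate_names=("lw",))
    with pytest.raises(ValueError, match="own covariate"):
        stepwise_additive(probs, y, Penalty(3.0, 0.05, 0, 0), cov,
                          trait="lw", covariate_names=("lw",))


def test_covariate_diallel_independent_covariate_keeps_qtl():
    """With an independent covariate, the diallel recovers the same
    cross-year QTL as the univariate analysis (flagged as not novel)."""
    gmap = make_linkage_map(42, 2, 60.0)
    cross = simulate_cross(gmap, 150, seed=81, extra_loci=[(1, 30.0)])
    tm_a = TraitModel("a", [PlantedQTL(1, 30.0, var_frac=0.3)])
    tm_b = TraitModel("b")  # pure-noise trait used as covariate
    _, per_geno = simulate_phenotypes(cross, [tm_a, tm_b], n_years=2, seed=82)
    probs = calc_genoprob(cross, step_cm=2.0)
    tab = covariate_diallel(probs, per_geno[["genotype", "year", "a", "b"]],
                            ["a", "b"], n_perm=100, seed=83)
    hit = tab[(tab["trait"] == "a") & (tab["covariate"] == "b")]
    assert len(hit) == 1
    assert hit.iloc[0]["lg"] == 1
    assert abs(hit.iloc[0]["mean_cm"] - 30.0) <= 8.0
    assert not hit.iloc[0]["novel"]
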