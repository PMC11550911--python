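"""QC filters, diversity, Weir–Cockerham theta, Mantel, Dunn/BH, DAPC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import morphopop as mp
from morphopop.popgen import bh_adjust, per_locus_he


def _hand_matrix(geno, pops):
    """Build GenotypeMatrix + PopulationMap from a plain array and labels."""
    geno = np.asarray(geno, dtype=float)
    n, L = geno.shape
    inds = [f"i{k}" for k in range(n)]
    g = mp.GenotypeMatrix(geno, inds, [f"l{j}" for j in range(L)],
                          [f"t{j}" for j in range(L)])
    pm = mp.PopulationMap(dict(zip(inds, pops)))
    return g, pm


class TestFilterSnps:
    def test_planted_design_survivors_enumerated(self):
        """Apply every rule by hand to a planted design; the filter must
        retain exactly the hand-enumerated survivor set."""
        g, _, _ = mp.simulate_genotypes(3, 20, 10, 0.05, seed=100)
        degraded, planted = mp.degrade_genotypes(
            g, locus_dropout=0.2, n_low_maf=2, n_monomorphic=1,
            n_multi_per_tag=1, seed=101)
        filtered, rep = mp.filter_snps(degraded)

        # independent enumeration, rule by rule
        call = degraded.locus_call_rate()
        survive = [l for l, c in zip(degraded.loci, call) if c >= 0.95]
        keep = degraded.subset_loci(np.array([l in survive for l in degraded.loci]))
        maf = keep.maf()
        survive2 = [l for l, m in zip(keep.loci, maf) if m >= 0.05]
        keep2 = keep.subset_loci(np.array([l in survive2 for l in keep.loci]))
        survive3 = [l for l, m in zip(keep2.loci, keep2.maf()) if m > 0]
        keep3 = keep2.subset_loci(np.array([l in survive3 for l in keep2.loci]))
        best = {}
        c3 = keep3.locus_call_rate()
        for j, t in enumerate(keep3.tags):
            if t not in best or c3[j] > c3[best[t]]:
                best[t] = j
        expected = {keep3.loci[j] for j in best.values()}
        assert set(filtered.loci) == expected
        # the planted failures were all removed
        assert not expected & set(planted["low_maf"])
        assert not expected & set(planted["monomorphic"])

    def test_no_thresholds_is_identity(self, island_genotypes):
        g, _, _ = island_genotypes
        out, rep = mp.filter_snps(g, 0.0, 0.0, 0.0, one_per_tag=False)
        assert out.loci == g.loci and out.individuals == g.individuals

    def test_all_missing_locus_reported(self):
        geno = np.array([[0, np.nan], [1, np.nan], [2, np.nan], [1, np.nan]])
        g, _ = _hand_matrix(geno, ["a", "a", "b", "b"])
        out, rep = mp.filter_snps(g, maf_min=0.0)
        assert rep.removed["locus_call_rate"] == ["l1"]
        assert out.loci == ["l0"]

    def test_all_individuals_dropped_flags_empty(self):
        geno = np.full((4, 10), np.nan)
        geno[:, 0] = 1.0   # one called locus: 10% call rate per individual
        g, _ = _hand_matrix(geno, ["a"] * 4)
        with pytest.warns(UserWarning):
            out, rep = mp.filter_snps(g, locus_call_min=0.0)
        assert rep.empty and out.n_individuals == 0

    def test_report_partitions_removals(self):
        g, _, _ = mp.simulate_genotypes(3, 15, 30, 0.05, seed=7)
        degraded, _ = mp.degrade_genotypes(
            g, locus_dropout=0.2, n_low_maf=3, n_monomorphic=2,
            n_multi_per_tag=2, seed=8)
        filtered, rep = mp.filter_snps(degraded)
        all_removed = sum((rep.removed[r] for r in rep.removed), [])
        assert len(all_removed) == len(set(all_removed))   # no double counting
        assert set(degraded.loci) == set(filtered.loci) | rep.all_removed_loci()


class TestDiversity:
    def test_fixed_population_zero_diversity(self):
        geno = np.array([[0, 2], [0, 2], [0, 2], [2, 0], [2, 0], [0, 2]])
        g, pm = _hand_matrix(geno, ["a", "a", "a", "b", "b", "b"])
        div = mp.diversity(g, pm)
        assert div.loc["a", "He"] == 0 and div.loc["a", "Ho"] == 0
        assert np.isnan(div.loc["a", "Fis"])

    def test_hardy_weinberg_fis_near_zero(self):
        g, pm, _ = mp.simulate_genotypes(4, 60, 800, 0.0, seed=3)
        div = mp.diversity(g, pm)
        se = div["Fis"].std() / np.sqrt(len(div))
        assert abs(div["Fis"].mean()) <= max(3 * se, 0.01)

    def test_planted_inbreeding_recovered(self):
        vals = []
        for s in range(20):
            g, pm, _ = mp.simulate_genotypes(2, 50, 300, 0.0, seed=200 + s,
                                             f_within=0.1)
            vals.append(mp.diversity(g, pm)["Fis"].mean())
        assert np.mean(vals) == pytest.approx(0.1, abs=0.02)


class TestWcFst:
    def test_fixed_differences_theta_one(self):
        geno = np.vstack([np.zeros((10, 50)), np.full((10, 50), 2.0)])
        g, pm = _hand_matrix(geno, ["a"] * 10 + ["b"] * 10)
        res = mp.wc_fst(g, pm)
        assert res.theta == pytest.approx(1.0, abs=1e-12)
        lo, hi = mp.bootstrap_fst_ci(res, n_boot=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_duplicated_population_theta_zero(self):
        g, pm, _ = mp.simulate_genotypes(2, 40, 400, 0.0, seed=5)
        res = mp.wc_fst(g, pm)
        lo, hi = mp.bootstrap_fst_ci(res, n_boot=500, seed=5)
        se = (hi - lo) / (2 * 1.96)
        assert abs(res.theta) <= 3 * se

    def test_allele_label_swap_invariance(self, island_genotypes):
        g, pm, _ = island_genotypes
        theta1 = mp.wc_fst(g, pm).theta
        swapped = g.copy()
        swapped.genotypes = 2.0 - swapped.genotypes
        theta2 = mp.wc_fst(swapped, pm).theta
        assert theta1 == pytest.approx(theta2, abs=1e-12)

    def test_against_indicator_anova_oracle(self):
        """Independent route: WC components from the allele-indicator ANOVA
        sums of squares (Weir's algebra), computed from first principles."""
        rng = np.random.default_rng(9)
        geno = rng.integers(0, 3, size=(30, 1)).astype(float)
        pops = np.repeat(["a", "b", "c"], 10)
        g, pm = _hand_matrix(geno, pops)
        res = mp.wc_fst(g, pm)

        # oracle: explicit scalar implementation of the 1984 equations
        r = 3
        ns = np.array([10.0, 10, 10])
        ps = np.array([geno[pops == p, 0].mean() / 2 for p in ("a", "b", "c")])
        hs = np.array([(geno[pops == p, 0] == 1).mean() for p in ("a", "b", "c")])
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        pbar = (ns * ps).sum() / (r * nbar)
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        assert res.a[0] == pytest.approx(a, abs=1e-12)
        assert res.b[0] == pytest.approx(b, abs=1e-12)
        assert res.c[0] == pytest.approx(c, abs=1e-12)

    def test_pairwise_matrix_symmetric(self, island_genotypes):
        g, pm, _ = island_genotypes
        sub = g.subset_loci(np.arange(100))
        mat = mp.pairwise_fst(sub, pm)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 0.0)

    def test_single_population_rejected(self):
        geno = np.random.default_rng(0).integers(0, 3, (10, 5)).astype(float)
        g, pm = _hand_matrix(geno, ["a"] * 10)
        with pytest.raises(ValueError):
            mp.wc_fst(g, pm)

    def test_bootstrap_deterministic(self, island_genotypes):
        g, pm, _ = island_genotypes
        res = mp.wc_fst(g, pm)
        assert mp.bootstrap_fst_ci(res, 200, seed=4) == mp.bootstrap_fst_ci(res, 200, seed=4)


class TestMantel:
    @staticmethod
    def _random_dist(rng, n):
        d = np.abs(rng.normal(0, 1, (n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        return d

    def test_identity(self, rng):
        d = self._random_dist(rng, 12)
        r, p = mp.mantel(d, d, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_perfect_negative(self, rng):
        d = self._random_dist(rng, 10)
        r, _ = mp.mantel(d, d.max() - d + np.diag(np.full(10, d.max() - d.max())), n_perm=99, seed=1)
        # off-diagonal entries are an affine decreasing transform of d
        assert r == pytest.approx(-1.0)

    def test_null_p_uniform(self):
        pvals = []
        for s in range(300):
            rng = np.random.default_rng(5000 + s)
            d1 = self._random_dist(rng, 10)
            d2 = self._random_dist(rng, 10)
            _, p = mp.mantel(d1, d2, n_perm=199, seed=s)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_skbio_oracle_agreement(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(6)
        d1 = self._random_dist(rng, 9)
        d2 = d1 + self._random_dist(rng, 9) * 0.5
        r_ours, _ = mp.mantel(d1, d2, n_perm=99, seed=0)
        r_ref, _, _ = skbio_dist.mantel(d1, d2, permutations=0)
        assert r_ours == pytest.approx(float(r_ref), abs=1e-10)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            mp.mantel(self._random_dist(rng, 5), self._random_dist(rng, 6))


class TestDiversityContrast:
    def test_identical_distributions_non_significant(self, rng):
        he = pd.DataFrame({p: rng.uniform(0.1, 0.5, 200) for p in "abc"})
        base = he["a"].to_numpy()
        he = pd.DataFrame({p: base for p in "abc"})
        out = mp.diversity_contrast(he)
        assert out["kw_p"] > 0.99
        assert (out["pairwise"]["p_adj"] > 0.99).all()

    def test_bh_stepup_arithmetic(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_low_diversity_population_stands_out(self):
        g1, pm1, _ = mp.simulate_genotypes(2, 30, 400, 0.0, seed=11)
        he = per_locus_he(g1, pm1)
        rng = np.random.default_rng(12)
        he["P03"] = he["P01"].to_numpy() * 0.5  # halved diversity
        out = mp.diversity_contrast(he)
        tab = out["pairwise"]
        has_p03 = tab[(tab["pop1"] == "P03") | (tab["pop2"] == "P03")]
        others = tab[(tab["pop1"] != "P03") & (tab["pop2"] != "P03")]
        assert has_p03["p_adj"].max() < others["p_adj"].min()


class TestDapc:
    def test_three_demes_found(self):
        g, _, _ = mp.simulate_genotypes(3, 30, 300, 0.3, seed=21)
        res = mp.dapc_cluster(g, k_max=8, seed=1)
        assert res.best_k == 3
        assert res.discriminant_scores.shape[1] == 2

    def test_panmixia_gives_one_cluster(self):
        g, _, _ = mp.simulate_genotypes(2, 45, 300, 0.0, seed=22)
        assert mp.dapc_cluster(g, k_max=8, seed=1).best_k == 1

    def test_order_invariance(self):
        g, _, _ = mp.simulate_genotypes(3, 20, 200, 0.3, seed=23)
        res1 = mp.dapc_cluster(g, k_max=5, seed=2)
        perm = np.random.default_rng(3).permutation(g.n_individuals)
        res2 = mp.dapc_cluster(g.subset_individuals(perm), k_max=5, seed=2)
        a1 = res1.assignments
        a2 = res2.assignments.reindex(a1.index)
        # same partition up to label permutation
        tab = pd.crosstab(a1, a2)
        assert (tab.gt(0).sum(axis=1) == 1).all()

    def test_k_max_guard(self):
        g, _, _ = mp.simulate_genotypes(2, 3, 50, 0.1, seed=1)
        with pytest.raises(ValueError):
            mp.dapc_cluster(g, k_max=6)


class TestHeDistanceRegression:
    @staticmethod
    def _pm_with_coords(pops, coords):
        pm = mp.PopulationMap({f"i{k}": p for k, p in enumerate(pops)})
        pm.coords_of = coords
        return pm

    def test_constant_he_flat(self):
        div = pd.DataFrame({"He": [0.3] * 5},
                           index=[f"P{i}" for i in range(5)])
        coords = {f"P{i}": (-20.0 - i, 130.0 + i) for i in range(5)}
        pm = self._pm_with_coords([], coords)
        out = mp.he_distance_regression(div, pm, origin=(-19.25, 146.8))
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_planted_gradient_recovered(self):
        rng = np.random.default_rng(30)
        coords = {f"P{i}": (-20.0 - i * 2, 140.0) for i in range(10)}
        origin = (-20.0, 140.0)
        dist = np.array([mp.popgen.haversine_km(*origin, *coords[f"P{i}"])
                         for i in range(10)])
        slope_true = -1e-4
        he = 0.4 + slope_true * dist + rng.normal(0, 0.005, 10)
        div = pd.DataFrame({"He": he}, index=[f"P{i}" for i in range(10)])
        pm = self._pm_with_coords([], coords)
        out = mp.he_distance_regression(div, pm, origin=origin)
        se = abs(out["slope"] / max(np.sqrt(out["F"]), 1e-9))
        assert abs(out["slope"] - slope_true) < 2 * se

    def test_two_points_rejected(self):
        div = pd.DataFrame({"He": [0.3, 0.4]}, index=["A", "B"])
        pm = self._pm_with_coords([], {"A": (0.0, 0.0), "B": (1.0, 1.0)})
        with pytest.raises(ValueError):
            mp.he_distance_regression(div, pm, origin=(0.0, 0.0))


@given(st.lists(st.floats(0.0001, 1.0), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_bh_is_monotone_stepup(pvals):
    """BH q-values are a monotone transform of p-values, bounded by 1."""
    p = np.array(pvals)
    q = bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q <= 1.0) and np.all(q >= p - 1e-12)
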