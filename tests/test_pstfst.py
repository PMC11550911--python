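"""P_ST machinery: size adjustment, variance components, the formula, the
c/h² trace with bootstrap bands, pairwise matrices and Mantel comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import morphopop as mp


class TestSizeAdjust:
    def test_uncorrelated_trait_nearly_unchanged(self, rng):
        cs = rng.uniform(90, 110, 200)
        trait = rng.normal(0, 1, 200)
        adj = mp.size_adjust(trait, cs)
        slope = np.polyfit(cs, trait, 1)[0]
        assert np.abs(adj - trait).max() <= abs(slope) * np.ptp(cs) + 1e-9

    def test_pure_allometry_collapses_to_mean(self, rng):
        cs = rng.uniform(50, 150, 100)
        trait = 2.0 * cs
        adj = mp.size_adjust(trait, cs)
        assert np.allclose(adj, trait.mean())

    def test_planted_allometry_removed(self, rng):
        cs = rng.uniform(90, 110, 300)
        trait = 0.3 * cs + rng.normal(0, 1, 300)
        adj = mp.size_adjust(trait, cs)
        assert abs(np.corrcoef(adj, cs)[0, 1]) < 1e-10

    def test_constant_cs_warns_identity(self, rng):
        trait = rng.normal(0, 1, 10)
        with pytest.warns(UserWarning):
            adj = mp.size_adjust(trait, np.full(10, 5.0))
        assert np.array_equal(adj, trait)


class TestVarianceComponents:
    def test_null_distribution(self):
        """Identical populations: sigma2_B small (bounded by a null oracle)."""
        null = []
        for s in range(200):
            rng = np.random.default_rng(7000 + s)
            trait = rng.normal(0, 1, 100)
            pops = np.repeat([f"p{i}" for i in range(5)], 20)
            s2b, _ = mp.variance_components(trait, pops)
            null.append(s2b)
        q95 = np.quantile(null, 0.95)
        rng = np.random.default_rng(123)
        s2b, _ = mp.variance_components(rng.normal(0, 1, 100),
                                        np.repeat([f"p{i}" for i in range(5)], 20))
        assert s2b <= max(q95, 0.2)

    def test_planted_recovery(self):
        ests = []
        for s in range(100):
            rng = np.random.default_rng(8000 + s)
            k, n = 5, 30
            mu = rng.normal(0, np.sqrt(2.0), k)
            trait = np.concatenate([m + rng.normal(0, 1.0, n) for m in mu])
            pops = np.repeat([f"p{i}" for i in range(k)], n)
            ests.append(mp.variance_components(trait, pops))
        b = np.array([e[0] for e in ests])
        w = np.array([e[1] for e in ests])
        assert b.mean() == pytest.approx(2.0, abs=3 * b.std() / 10)
        assert w.mean() == pytest.approx(1.0, abs=3 * w.std() / 10)

    def test_two_constant_populations_closed_form(self):
        # populations of constants a=1, b=3, n=4 each:
        # MS_within = 0; MS_between = n*(a-gbar)^2 + n*(b-gbar)^2 = 4*1+4*1 = 8
        # n0 = (8 - 32/8)/1 = 4 -> sigma2_B = 8/4 = 2 = (a-b)^2/2
        trait = np.array([1.0] * 4 + [3.0] * 4)
        pops = np.array(["a"] * 4 + ["b"] * 4)
        s2b, s2w = mp.variance_components(trait, pops)
        assert s2w == 0.0
        assert s2b == pytest.approx(2.0, abs=1e-12)

    def test_singleton_population_rejected(self):
        with pytest.raises(ValueError):
            mp.variance_components(np.arange(5.0),
                                   np.array(["a", "a", "a", "a", "b"]))


class TestPstFormula:
    @pytest.mark.parametrize("s2b,s2w,phi,expected", [
        (2.0, 1.0, 1.0, 0.5),
        (1.0, 1.0, 0.5, 0.2),
        (0.0, 1.0, 1.7, 0.0),
        (3.0, 0.0, 0.4, 1.0),
    ])
    def test_known_values(self, s2b, s2w, phi, expected):
        assert mp.pst(s2b, s2w, phi) == pytest.approx(expected, abs=1e-12)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            mp.pst(0.0, 0.0, 1.0)

    @given(st.floats(0.01, 10), st.floats(0.01, 10),
           st.floats(0.0, 5), st.floats(0.0, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_phi(self, s2b, s2w, phi1, phi2):
        lo, hi = sorted((phi1, phi2))
        assert mp.pst(s2b, s2w, lo) <= mp.pst(s2b, s2w, hi) + 1e-12

    def test_depends_on_ratio_only(self):
        # c=2,h2=1 and c=1,h2=0.5 give the same phi=2 and the same P_ST
        assert mp.pst(1.5, 0.7, 2.0 / 1.0) == mp.pst(1.5, 0.7, 1.0 / 0.5)


class TestTracePst:
    @staticmethod
    def _trait(seed, s2b=2.0, s2w=1.0, k=12, n=15):
        rng = np.random.default_rng(seed)
        mu = rng.normal(0, np.sqrt(s2b), k)
        trait = np.concatenate([m + rng.normal(0, np.sqrt(s2w), n) for m in mu])
        pops = np.repeat([f"p{i}" for i in range(k)], n)
        return trait, pops

    def test_curve_shape_invariants(self):
        trait, pops = self._trait(1)
        tr = mp.trace_pst(trait, pops, fst_global=0.118, n_boot=200, seed=2)
        assert tr.pst_curve[0] == 0.0
        assert np.all(np.diff(tr.pst_curve) >= -1e-12)
        assert np.all((tr.pst_curve >= 0) & (tr.pst_curve <= 1))
        assert np.all(tr.ci_lower <= tr.pst_curve + 1e-9)
        assert np.all(tr.pst_curve <= tr.ci_upper + 1e-9)

    def test_strong_signal_robust(self):
        hits = 0
        for s in range(10):
            trait, pops = self._trait(100 + s, s2b=2.0, s2w=1.0)
            tr = mp.trace_pst(trait, pops, fst_global=0.118, n_boot=300, seed=s)
            hits += tr.robust_flag
        assert hits >= 9

    def test_boundary_signal_not_robust(self):
        # variances tuned so the true P_ST equals fst_global = 0.118:
        # s2b/(s2b + 2 s2w) = 0.118 with s2w=1 -> s2b = 0.2676
        hits = 0
        for s in range(10):
            trait, pops = self._trait(200 + s, s2b=0.2676, s2w=1.0)
            tr = mp.trace_pst(trait, pops, fst_global=0.118, n_boot=300, seed=s)
            hits += (not tr.robust_flag)
        assert hits >= 9

    def test_bootstrap_bands_deterministic_given_seed(self):
        trait, pops = self._trait(3)
        t1 = mp.trace_pst(trait, pops, fst_global=0.1, ci_method="bootstrap",
                          n_boot=150, seed=9)
        t2 = mp.trace_pst(trait, pops, fst_global=0.1, ci_method="bootstrap",
                          n_boot=150, seed=9)
        assert np.array_equal(t1.ci_lower, t2.ci_lower)
        assert np.array_equal(t1.ci_upper, t2.ci_upper)

    def test_band_methods_agree_on_strong_signal(self):
        """Pivot and bootstrap bands both bracket the point curve and give
        the same qualitative robustness call on a strong planted signal."""
        trait, pops = self._trait(4, s2b=2.0, s2w=1.0)
        ta = mp.trace_pst(trait, pops, fst_global=0.118, ci_method="anova")
        tb = mp.trace_pst(trait, pops, fst_global=0.118, ci_method="bootstrap",
                          n_boot=500, seed=0)
        for t in (ta, tb):
            assert np.all(t.ci_lower <= t.pst_curve + 1e-9)
            assert np.all(t.pst_curve <= t.ci_upper + 1e-9)
        assert ta.robust_flag == tb.robust_flag

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (10, 30, 100):
            trait, pops = self._trait(5, k=8, n=n)
            tr = mp.trace_pst(trait, pops, fst_global=0.1, n_boot=300, seed=1)
            i1 = int(np.argmin(np.abs(tr.phi_grid - 1.0)))
            widths.append(tr.ci_upper[i1] - tr.ci_lower[i1])
        assert widths[2] < widths[0]


class TestPairwisePst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(11)
        trait = rng.normal(0, 1, 90)
        pops = np.repeat(["a", "b", "c"], 30)
        mat = mp.pairwise_pst(trait, pops)
        assert np.allclose(np.diag(mat.to_numpy()), 0)
        assert (mat.to_numpy()[np.triu_indices(3, 1)] < 0.2).all()

    def test_shifted_population_dominates(self):
        rng = np.random.default_rng(12)
        trait = rng.normal(0, 1, 90)
        trait[60:] += 10.0
        pops = np.repeat(["a", "b", "c"], 30)
        mat = mp.pairwise_pst(trait, pops)
        assert mat.loc["c", "a"] > 0.9 and mat.loc["c", "b"] > 0.9

    def test_order_invariance(self):
        rng = np.random.default_rng(13)
        trait = rng.normal(0, 1, 60) + np.repeat([0.0, 1.0, 2.0], 20)
        pops = np.repeat(["a", "b", "c"], 20)
        perm = rng.permutation(60)
        m1 = mp.pairwise_pst(trait, pops)
        m2 = mp.pairwise_pst(trait[perm], pops[perm])
        m2 = m2.loc[m1.index, m1.columns]
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)


class TestComparePstFst:
    @staticmethod
    def _mat(rng, n, labels):
        import pandas as pd
        d = np.abs(rng.normal(0, 1, (n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_identical_matrices(self, rng):
        labels = [f"p{i}" for i in range(8)]
        m = self._mat(rng, 8, labels)
        r, p = mp.compare_pst_fst(m, m, n_perm=499, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.01

    def test_independent_matrices_nonsignificant(self):
        from scipy import stats
        pvals = []
        for s in range(100):
            rng = np.random.default_rng(9000 + s)
            labels = [f"p{i}" for i in range(10)]
            m1 = self._mat(rng, 10, labels)
            m2 = self._mat(rng, 10, labels)
            _, p = mp.compare_pst_fst(m1, m2, n_perm=199, seed=s)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_label_mismatch_rejected(self, rng):
        m1 = self._mat(rng, 4, list("abcd"))
        m2 = self._mat(rng, 4, list("abce"))
        with pytest.raises(ValueError):
            mp.compare_pst_fst(m1, m2)


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_ratio(self):
        """simulate -> GPA -> RW1 -> size adjust -> trace recovers the
        planted sigma2_B/(sigma2_B + 2 sigma2_W) within the bootstrap CI
        in most seeded runs (10-seed screen of the 50-seed property)."""
        cover = 0
        for s in range(10):
            configs, _ = mp.simulate_landmarks(12, 15, 2.0, 1.0, nuisance=True,
                                               seed=600 + s)
            al = mp.gpa_align(configs, slide=True)
            rw = mp.relative_warps(al)
            pops = np.array([c.population for c in configs])
            adj = mp.size_adjust(rw.scores["RW1"].to_numpy(), al.centroid_size)
            tr = mp.trace_pst(adj, pops, fst_global=0.118, seed=s)
            i1 = int(np.argmin(np.abs(tr.phi_grid - 1.0)))
            cover += tr.ci_lower[i1] <= 0.5 <= tr.ci_upper[i1]
        assert cover >= 8
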