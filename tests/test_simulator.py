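import numpy as np
import pytest
from scipy import stats

from propcoloc import simulator as sim


class TestPanel:
    def test_rho_zero_gives_unlinked_snps(self):
        panel = sim.make_panel(n_hap=4000, n_snp=30, block_size=10, rho=0.0,
                               seed=1)
        r = np.corrcoef(panel.haplotypes.T.astype(float))
        off = np.abs(r[np.triu_indices(30, 1)])
        assert off.mean() < 2 / np.sqrt(panel.n_hap)

    def test_block_ld_structure(self):
        """Adjacent within-block r^2 well above between-block r^2."""
        panel = sim.make_panel(n_hap=4000, n_snp=50, block_size=25, rho=0.95,
                               seed=2)
        r2 = panel.r2_matrix()
        within = [r2[j, j + 1] for j in range(24)]
        between = [r2[i, j] for i in range(25) for j in range(25, 50)]
        assert np.mean(within) > 10 * np.mean(between)
        assert np.mean(within) > 0.3

    def test_maf_floor_respected(self):
        panel = sim.make_panel(n_hap=2000, n_snp=60, seed=3, maf_floor=0.05)
        maf = np.minimum(panel.maf, 1 - panel.maf)
        assert maf.min() >= 0.04  # floor within sampling tolerance

    def test_deterministic_given_seed(self):
        a = sim.make_panel(n_hap=500, n_snp=20, seed=7)
        b = sim.make_panel(n_hap=500, n_snp=20, seed=7)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_infeasible_maf_floor_rejected(self):
        with pytest.raises(ValueError):
            sim.make_panel(maf_floor=0.5)


class TestAdmix:
    def test_boundaries(self):
        a = sim.make_panel(n_hap=400, n_snp=10, seed=4, population="A")
        b = sim.make_panel(n_hap=400, n_snp=10, seed=5, population="B",
                           shift=1.0)
        only_a = sim.admix_panels(a, b, pi=0.0, seed=6)
        assert set(only_a.population) == {"A"}
        only_b = sim.admix_panels(a, b, pi=1.0, seed=6)
        assert set(only_b.population) == {"B"}

    def test_mixing_fraction(self):
        a = sim.make_panel(n_hap=4000, n_snp=10, seed=7, population="A")
        b = sim.make_panel(n_hap=4000, n_snp=10, seed=8, population="B")
        mixed = sim.admix_panels(a, b, pi=0.25, seed=9)
        frac = np.mean(mixed.population == "B")
        assert frac == pytest.approx(0.25, abs=0.03)

    def test_snp_mismatch_rejected(self):
        a = sim.make_panel(n_hap=100, n_snp=10, seed=1)
        b = sim.make_panel(n_hap=100, n_snp=12, seed=2)
        with pytest.raises(ValueError):
            sim.admix_panels(a, b, 0.5)


class TestCaseControl:
    def test_rr_one_is_null(self, small_panel):
        causal = small_panel.snp_ids[3]
        g, y = sim.simulate_case_control(small_panel, causal, rr=1.0,
                                         n_case=2000, n_control=2000, seed=10)
        j = g.snp_index(causal)
        case_f = g.dosages[y.values == 1, j].mean() / 2
        ctrl_f = g.dosages[y.values == 0, j].mean() / 2
        z = (case_f - ctrl_f) / np.sqrt(
            ctrl_f * (1 - ctrl_f) * (1 / 4000 + 1 / 4000))
        assert abs(z) < 3.5

    def test_case_allele_frequency_matches_closed_form(self, small_panel):
        """Case allele frequency f*rr / (1 - f + f*rr) under the
        multiplicative per-allele model, within Monte-Carlo error."""
        causal = small_panel.snp_ids[3]
        f = small_panel.maf[3]
        rr = 1.3
        g, y = sim.simulate_case_control(small_panel, causal, rr=rr,
                                         n_case=4000, n_control=1000, seed=11)
        j = g.snp_index(causal)
        case_f = g.dosages[y.values == 1, j].mean() / 2
        expect = f * rr / (1 - f + f * rr)
        se = np.sqrt(expect * (1 - expect) / 8000)
        assert case_f == pytest.approx(expect, abs=4 * se)

    def test_deterministic_given_seed(self, small_panel):
        a = sim.simulate_case_control(small_panel, small_panel.snp_ids[0],
                                      1.2, 100, 100, seed=12)
        b = sim.simulate_case_control(small_panel, small_panel.snp_ids[0],
                                      1.2, 100, 100, seed=12)
        np.testing.assert_array_equal(a[0].dosages, b[0].dosages)
        np.testing.assert_array_equal(a[1].values, b[1].values)


class TestQuantitative:
    def test_variance_explained(self, small_panel):
        causal = small_panel.snp_ids[5]
        g, y = sim.simulate_quantitative(small_panel, [causal], [0.3],
                                         n=10000, seed=13)
        x = g.dosages[:, g.snp_index(causal)]
        r2 = np.corrcoef(x, y.values)[0, 1] ** 2
        assert r2 == pytest.approx(0.30, abs=0.02)

    def test_two_linked_variants_covariance_algebra(self, small_panel):
        """Total explained variance includes the 2*beta1*beta2*cov term."""
        a, b = small_panel.snp_ids[6], small_panel.snp_ids[7]  # same block
        v = [0.1, 0.1]
        g, y = sim.simulate_quantitative(small_panel, [a, b], v, n=20000,
                                         seed=14)
        X = g.dosages[:, [g.snp_index(a), g.snp_index(b)]]
        f = small_panel.maf[[6, 7]]
        beta = np.sqrt(np.array(v) / (2 * f * (1 - f)))
        signal = X @ beta
        expect_var = (beta[0] ** 2 * X[:, 0].var() +
                      beta[1] ** 2 * X[:, 1].var() +
                      2 * beta[0] * beta[1] *
                      np.cov(X[:, 0], X[:, 1], bias=True)[0, 1])
        assert signal.var() == pytest.approx(expect_var, rel=1e-6)
        # and the realised trait variance exceeds the naive sum + noise
        naive = v[0] + v[1] + (1 - sum(v))
        assert y.values.var() > naive  # positive LD inflates the total

    def test_invalid_fractions_rejected(self, small_panel):
        with pytest.raises(ValueError):
            sim.simulate_quantitative(small_panel, [small_panel.snp_ids[0]],
                                      [1.2], n=100)


class TestTagAndScreen:
    def test_fraction_one_is_identity(self, small_panel):
        g, _ = sim.simulate_quantitative(small_panel, [small_panel.snp_ids[0]],
                                         [0.1], n=50, seed=15)
        assert sim.tag_subset(g, 1.0) is g

    def test_subset_size_and_determinism(self, small_panel):
        g, _ = sim.simulate_quantitative(small_panel, [small_panel.snp_ids[0]],
                                         [0.1], n=50, seed=16)
        a = sim.tag_subset(g, 0.3, seed=17)
        b = sim.tag_subset(g, 0.3, seed=17)
        assert a.n_snps == int(np.ceil(0.3 * g.n_snps))
        assert a.snps == b.snps

    def test_screen_strong_effect_kept(self, small_panel):
        g, y = sim.simulate_quantitative(small_panel, [small_panel.snp_ids[9]],
                                         [0.4], n=2000, seed=18)
        assert sim.screen_min_p(g, y)

    def test_screen_threshold_one_always_keeps(self, small_panel):
        rng = np.random.default_rng(19)
        g, _ = sim.simulate_quantitative(small_panel, [small_panel.snp_ids[0]],
                                         [0.1], n=200, seed=20)
        from propcoloc.genotype_data import TraitVector
        y = TraitVector("quantitative", rng.standard_normal(200))
        assert sim.screen_min_p(g, y, threshold=1.0)

    def test_screen_matches_permutation_oracle(self, small_panel):
        """Keep fraction of null data equals the empirical
        P(min p <= threshold) from an independent permutation oracle."""
        rng = np.random.default_rng(21)
        g, _ = sim.simulate_quantitative(small_panel, [small_panel.snp_ids[0]],
                                         [0.1], n=500, seed=22)
        from propcoloc.genotype_data import TraitVector
        thr = 0.01  # raised threshold so the rate is estimable at 200 reps
        keep = np.mean([
            sim.screen_min_p(g, TraitVector("quantitative",
                                            rng.standard_normal(500)), thr)
            for _ in range(200)])
        X = g.dosages
        Xc = (X - X.mean(0)) / np.sqrt(((X - X.mean(0)) ** 2).sum(0))
        hits = 0
        for _ in range(200):
            y = rng.standard_normal(500)
            yc = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())
            rho = Xc.T @ yc
            t = rho * np.sqrt(498 / (1 - rho ** 2))
            hits += 2 * stats.t.sf(np.abs(t), 498).min() <= thr
        oracle = hits / 200
        se = np.sqrt(oracle * (1 - oracle) / 200 + keep * (1 - keep) / 200)
        assert abs(keep - oracle) <= 4 * max(se, 0.02)


class TestAdmixtureSensitivity:
    def test_mild_admixture_leaves_type1_error_unchanged(self):
        """5% admixture from a mildly diverged panel: the relative
        type-1-error ratio vs no mixing is compatible with 1 (delta-method
        CI), while strong admixture pushes the rate up."""
        scs = [
            sim.SimScenario(name=f"pi{int(100 * p)}",
                            trait_kind="quantitative", n_shared=1,
                            effect=0.1, n_samples=1000, tag_fraction=0.3,
                            admix_pi=p)
            for p in (0.0, 0.05, 0.8)
        ]
        tab = sim.run_study(scs, ["PC"], n_reps=120, alpha=0.05, seed=13,
                            panel_kwargs=dict(n_hap=2000, n_snp=50,
                                              block_size=25))
        r = {row.scenario_id: (int(row.rejections), int(row.n_reps))
             for row in tab.itertuples()}
        _, lo, hi = sim.rate_ratio_ci(*r["pi5"], *r["pi0"])
        assert lo <= 1.0 <= hi
        strong, _, _ = sim.rate_ratio_ci(*r["pi80"], *r["pi0"])
        assert strong > 1.0

    def test_rate_ratio_ci_contains_point_estimate(self):
        ratio, lo, hi = sim.rate_ratio_ci(8, 100, 5, 100)
        assert lo < ratio < hi
        assert ratio == pytest.approx(1.6)


class TestRunStudy:
    def test_zero_reps_empty_table(self):
        sc = sim.SimScenario(name="s", trait_kind="quantitative",
                             effect=0.1, n_samples=100)
        tab = sim.run_study([sc], ["PC"], n_reps=0, seed=1)
        assert len(tab) == 0

    def test_table_schema_and_determinism(self):
        sc = sim.SimScenario(name="mini", trait_kind="quantitative",
                             n_shared=1, effect=0.15, n_samples=400,
                             tag_fraction=1.0)
        kw = dict(n_hap=600, n_snp=20, block_size=10)
        a = sim.run_study([sc], ["MAX", "C1"], n_reps=5, seed=3,
                          panel_kwargs=kw)
        b = sim.run_study([sc], ["MAX", "C1"], n_reps=5, seed=3,
                          panel_kwargs=kw)
        assert set(a.columns) >= {"scenario_id", "method", "n_reps",
                                  "rejections", "rate", "se"}
        assert a.equals(b)
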