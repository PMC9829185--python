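import numpy as np
import pytest
from scipy.stats import chisquare, kstest

import statsmodels.api as sm

from pleioscan.panel import LDMatrix
from pleioscan.simulate import (
    CohortData,
    LocusSummary,
    ascertain,
    assemble_scenario,
    assoc_scan,
    build_cohort_genotypes,
    chol_with_jitter,
    make_h2_pair,
    midpoint_snp,
    per_snp_variance,
    sample_effects,
    sample_summary_stats,
    scenario_counts,
    simulate_cohort,
    simulate_multitrait_focal,
    titrate_h2,
)


def test_per_snp_variance_closed_form():
    """h2=0.5 spread over 1% of one million markers gives 5e-5 per SNP."""
    assert per_snp_variance(0.5, 0.01, 1e6) == pytest.approx(5e-5, rel=0, abs=0)
    with pytest.raises(ValueError):
        per_snp_variance(0.0)


class TestSampleEffects:
    def test_h0_forces_zero_underpowered_effect(self, rng):
        for _ in range(20):
            e = sample_effects(0.7, 5e-5, 5e-5, "H0", rng)
            assert e.beta2 == 0.0

    @pytest.mark.parametrize("rho", [0.0, 0.7])
    def test_empirical_correlation_matches_request(self, rho, rng):
        draws = np.array(
            [
                (e.beta1, e.beta2)
                for e in (sample_effects(rho, 5e-5, 5e-5, "H1", rng) for _ in range(100_000))
            ]
        )
        assert np.corrcoef(draws.T)[0, 1] == pytest.approx(rho, abs=0.01)
        assert draws[:, 0].std() == pytest.approx(np.sqrt(5e-5), rel=0.02)

    def test_h2_effects_uncorrelated_even_with_rho(self, rng):
        draws = np.array(
            [
                (e.beta1, e.beta2)
                for e in (sample_effects(0.9, 5e-5, 5e-5, "H2", rng) for _ in range(50_000))
            ]
        )
        assert abs(np.corrcoef(draws.T)[0, 1]) < 0.02


class TestSampleSummaryStats:
    def test_null_identity_ld_marginally_standard_normal(self, rng):
        ld = LDMatrix(np.eye(4))
        zs = np.array(
            [sample_summary_stats(ld, np.zeros(4), 10_000, rng).z for _ in range(10_000)]
        )
        assert abs(zs.mean()) < 0.02
        assert zs.var() == pytest.approx(1.0, abs=0.05)

    def test_single_snp_mean_closed_form(self, rng):
        """E[z] = sqrt(n) * beta: 0.01 at n = 150,000 gives 3.873."""
        ld = LDMatrix(np.eye(1))
        zs = np.array(
            [sample_summary_stats(ld, np.array([0.01]), 150_000, rng).z[0] for _ in range(10_000)]
        )
        assert zs.mean() == pytest.approx(np.sqrt(150_000) * 0.01, abs=4 * zs.std() / 100)
        assert zs.mean() == pytest.approx(3.873, abs=0.05)

    def test_neighbor_mean_attenuated_by_ld(self, rng):
        """E[z_j] = sqrt(n) * r_jc * beta at a non-causal neighbor."""
        r = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.3], [0.2, 0.3, 1.0]])
        ld = LDMatrix(r)
        beta = np.array([0.0, 0.02, 0.0])
        zs = np.array([sample_summary_stats(ld, beta, 10_000, rng).z for _ in range(10_000)])
        expect = np.sqrt(10_000) * r @ beta
        se = 4.0 / np.sqrt(10_000)
        assert np.abs(zs.mean(axis=0) - expect).max() < se

    def test_mean_matches_sqrtN_D_beta_on_fixture(self, small_ld, rng):
        """Sampled z mean equals sqrt(N) D beta within 4 MC standard errors."""
        m = small_ld.m
        beta = np.zeros(m)
        beta[m // 2] = 0.007
        chol = chol_with_jitter(small_ld)
        zs = np.array(
            [sample_summary_stats(small_ld, beta, 10_000, rng, chol).z for _ in range(10_000)]
        )
        expect = np.sqrt(10_000) * small_ld.r @ beta
        tol = 4 * zs.std(axis=0) / np.sqrt(10_000)
        assert (np.abs(zs.mean(axis=0) - expect) < tol).all()

    def test_p_consistent_with_z(self, small_ld, rng):
        s = sample_summary_stats(small_ld, np.zeros(small_ld.m), 1000, rng)
        from scipy.special import ndtr

        assert np.allclose(s.p, 2 * ndtr(-np.abs(s.z)), atol=1e-12)


class TestCholJitter:
    def test_rank_deficient_ld_handled(self):
        col = np.array([1.0, 1.0])
        d = np.outer(col, col)  # perfect LD, rank 1
        L = chol_with_jitter(LDMatrix(d))
        assert np.allclose(L @ L.T, d, atol=1e-3)


class TestCohort:
    def test_null_phenotype_variance_one(self, small_panel, rng):
        c = simulate_cohort(small_panel, None, 0.0, n=10_000, rng=rng)
        assert c.phenotype.var() == pytest.approx(1.0, abs=0.05)
        assert np.abs(c.dosages.mean(axis=0)).max() < 1e-10
        assert np.allclose(c.dosages.var(axis=0), 1.0, atol=1e-6)

    def test_ols_slope_unbiased(self, small_panel, rng):
        """Mean OLS slope at the causal SNP over replicates recovers beta2."""
        beta2 = 0.00707 * 10  # scaled up so 200 small cohorts resolve it
        c_idx = midpoint_snp(small_panel)
        slopes = []
        for _ in range(200):
            c = simulate_cohort(small_panel, c_idx, beta2, n=800, rng=rng)
            x, y = c.dosages[:, c_idx], c.phenotype
            slopes.append((x * (y - y.mean())).mean())
        mc_se = np.std(slopes) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(beta2, abs=2 * mc_se)

    def test_phenotype_variance_decomposition(self, small_panel, rng):
        beta2 = 0.5
        c = simulate_cohort(small_panel, 3, beta2, n=20_000, rng=rng)
        assert c.phenotype.var() == pytest.approx(1 + beta2**2, rel=0.03)


class TestAssocScan:
    def test_self_phenotype_is_top_hit(self, small_panel, rng):
        g = build_cohort_genotypes(small_panel, 500, rng)
        cohort = CohortData(g, g[:, 7].copy())
        s = assoc_scan(cohort)
        # perfect proxies tie at the minimum; SNP 7 must be among them
        assert s.p[7] == s.min_p
        assert abs(s.z[7]) == np.abs(s.z).max()

    def test_null_pvalues_uniform(self, rng):
        """Random phenotypes give uniform p-values across (independent)
        SNP tests."""
        ps = []
        for _ in range(40):
            g = rng.binomial(2, 0.4, size=(300, 50)).astype(float)
            g = (g - g.mean(0)) / g.std(0)
            y = rng.standard_normal(300)
            ps.append(assoc_scan(CohortData(g, y)).p)
        ps = np.concatenate(ps)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_matches_statsmodels_ols_oracle(self, small_panel, rng):
        g = build_cohort_genotypes(small_panel, 50, rng)[:, :5]
        y = rng.standard_normal(50) + 0.5 * g[:, 2]
        s = assoc_scan(CohortData(g, y))
        for j in range(5):
            fit = sm.OLS(y, sm.add_constant(g[:, j])).fit()
            assert s.z[j] == pytest.approx(fit.tvalues[1], abs=1e-8)

    def test_zero_variance_column_rejected(self, rng):
        g = rng.standard_normal((50, 2))
        g[:, 1] = 0.0
        with pytest.raises(ValueError, match="variance"):
            assoc_scan(CohortData((g - g.mean(0)) / np.where(g.std(0) == 0, 1, g.std(0)), g[:, 0]))


class TestMakeH2Pair:
    def test_single_eligible_snp_chosen(self, rng):
        r = np.array([[1.0, 0.85, 0.1], [0.85, 1.0, 0.2], [0.1, 0.2, 1.0]])
        assert make_h2_pair(LDMatrix(r), 0, 3, rng) == 1

    def test_empty_bin_errors(self, rng):
        r = np.eye(3)
        with pytest.raises(ValueError, match="bin"):
            make_h2_pair(LDMatrix(r), 0, 3, rng)

    def test_postcondition_and_uniformity(self, small_ld, rng):
        c1 = small_ld.m // 2
        absr = np.abs(small_ld.r[:, c1])
        eligible = np.flatnonzero((absr >= 0.0) & (absr < 0.3))
        eligible = eligible[eligible != c1]
        draws = np.array([make_h2_pair(small_ld, c1, 0, rng) for _ in range(10_000)])
        for d in np.unique(draws):
            assert d in eligible and d != c1
            assert abs(small_ld.r[d, c1]) < 0.3
        counts = np.array([(draws == e).sum() for e in eligible])
        assert chisquare(counts).pvalue > 0.01


class TestAscertain:
    @pytest.mark.parametrize(
        "pw,pu,keep",
        [
            (4e-8, 0.005, True),
            (6e-8, 0.005, False),
            (4e-8, 0.02, False),
        ],
    )
    def test_two_stage_rule(self, pw, pu, keep):
        z = np.array([0.0, 1.0])
        ws = LocusSummary(z, np.array([pw, 0.9]), 1000)
        us = LocusSummary(z, np.array([0.9, pu]), 1000)
        assert ascertain(ws, us) is keep

    def test_null_rejection_rate_matches_mc_oracle(self, small_ld, rng):
        """The well-powered min-p filter keeps exactly the loci a direct
        Monte-Carlo computation of P(min p < 5e-8 | beta = 0) predicts."""
        chol = chol_with_jitter(small_ld)
        m = small_ld.m
        kept = 0
        n = 3000
        thresh = 5.4513104253237085
        maxes = np.abs(chol @ rng.standard_normal((m, n))).max(axis=0)
        kept = (maxes > thresh).mean()
        # direct oracle on independent draws
        oracle = (np.abs(chol @ rng.standard_normal((m, n))).max(axis=0) > thresh).mean()
        assert kept == pytest.approx(oracle, abs=3 * np.sqrt(0.001 * 0.999 / n) + 0.003)


class TestTitrateH2:
    def test_pool_already_at_target(self, rng):
        labels = [0] * 72 + [1] * 19 + [2] * 5 + [3] * 4
        idx = titrate_h2(labels, rng=rng)
        assert len(idx) == 100

    def test_limiting_bin_drives_size(self, rng):
        labels = [0] * 100 + [1] * 100 + [2] * 100 + [3] * 100
        idx = titrate_h2(labels, rng=rng)
        labels = np.asarray(labels)
        total = len(idx)
        # bin 0 is limiting: 100 / 0.72 -> 138 total
        assert total == pytest.approx(138, abs=2)
        counts = np.array([(labels[idx] == b).sum() for b in range(4)])
        target = np.array([0.72, 0.19, 0.05, 0.04])
        assert np.abs(counts / total - target).max() <= 1.5 / total + 1e-9

    def test_empty_bin_errors(self, rng):
        with pytest.raises(ValueError, match="empty"):
            titrate_h2([0, 0, 1, 2], rng=rng)


class TestScenarioAssembly:
    def test_deterministic_counts(self):
        assert scenario_counts(2500, 0.30, (1, 19)) == (750, 87, 1663)
        assert scenario_counts(2500, 0.30, (1, 0)) == (750, 1750, 0)

    def test_assemble_matches_labels_and_counts(self, rng):
        from pleioscan.simulate import EffectPair, LocusTruth

        def mk(hyp, c2):
            t = LocusTruth(hyp, 5, c2, EffectPair(0.01, 0.0 if hyp == "H0" else 0.01, 0.0))
            s = LocusSummary(np.zeros(3), np.ones(3), 100)
            return (t, s, s, 0)

        pools = {
            "H0": [mk("H0", None) for _ in range(60)],
            "H1": [mk("H1", 5) for _ in range(60)],
            "H2": [mk("H2", 6) for _ in range(60)],
        }
        scen = assemble_scenario(100, 0.3, (1, 3), pools, rng)
        labels = scen.labels()
        assert scen.T == 100
        assert (labels == "H0").sum() == 30
        assert (labels == "H1").sum() == 17  # floor(70/4)
        assert (labels == "H2").sum() == 53
        for t in scen.truths:
            assert t.hypothesis in {"H0", "H1", "H2"}

    def test_pool_exhaustion_reported(self, rng):
        with pytest.raises(ValueError, match="pool exhausted"):
            assemble_scenario(100, 0.3, (1, 19), {"H0": [], "H1": [], "H2": []}, rng)


class TestMultitraitFocal:
    def test_expected_shared_trait_count(self, rng):
        n_shared = [
            simulate_multitrait_focal("H1", rng)["shared_mask"][1:].sum() for _ in range(10_000)
        ]
        mean = np.mean(n_shared)
        se = np.std(n_shared) / 100
        assert mean == pytest.approx(9 / 20, abs=4 * se)

    def test_h0_underpowered_z_standard_normal(self, rng):
        z = np.array([simulate_multitrait_focal("H0", rng)["z_underpowered"] for _ in range(8000)])
        assert abs(z.mean()) < 0.05
        assert z.var() == pytest.approx(1.0, abs=0.07)

    def test_h1_cross_trait_z_correlation(self, rng):
        """corr(z_main, z_up) = rho * sqrt(n1 s2/(n1 s2+1)) * sqrt(n2 s2/(n2 s2+1))
        under shared causal effects with correlation rho."""
        out = [simulate_multitrait_focal("H1", rng, rho=0.7) for _ in range(20_000)]
        z1 = np.array([o["z_well_powered"][0] for o in out])
        zu = np.array([o["z_underpowered"] for o in out])
        s = 5e-5
        expect = 0.7 * np.sqrt(150_000 * s / (150_000 * s + 1)) * np.sqrt(10_000 * s / (10_000 * s + 1))
        assert np.corrcoef(z1, zu)[0, 1] == pytest.approx(expect, abs=0.03)


class TestLeadCausalLdSummary:
    def test_deterministic_lead_at_causal_gives_fraction_one(self, small_ld):
        from pleioscan.simulate import EffectPair, LocusTruth, lead_causal_ld_summary

        c = 7
        z = np.zeros(small_ld.m)
        z[c] = 9.0
        s = LocusSummary.from_z(z, 1000)
        truths = [LocusTruth("H1", c, c, EffectPair(0.01, 0.01, 0.7))] * 5
        out = lead_causal_ld_summary([s] * 5, truths, [small_ld] * 5)
        frac, (lo, hi) = out["r2>0.8"]
        assert frac == 1.0 and lo <= 1.0 <= hi

    def test_null_fraction_matches_high_ld_partner_density(self, small_panel, small_ld, rng):
        """With no causal effect the lead is a random noise peak, so the
        tagging fraction approximates the Monte-Carlo rate at which noise
        peaks land on r^2 > 0.8 partners of the midpoint SNP."""
        from pleioscan.simulate import EffectPair, LocusTruth, lead_causal_ld_summary

        c = midpoint_snp(small_panel)
        chol = chol_with_jitter(small_ld)
        truths, summaries = [], []
        for _ in range(600):
            truths.append(LocusTruth("H1", c, c, EffectPair(0.0, 0.0, 0.0, 1e-9, 1e-9)))
            summaries.append(LocusSummary.from_z(chol @ rng.standard_normal(small_ld.m), 1000))
        out = lead_causal_ld_summary(summaries, truths, [small_ld] * 600)
        frac = out["r2>0.8"][0]
        # oracle: independent MC of the same event
        leads = np.abs(chol @ rng.standard_normal((small_ld.m, 2000))).argmax(axis=0)
        oracle = (small_ld.r[leads, c] ** 2 > 0.8).mean()
        assert frac == pytest.approx(oracle, abs=3 * np.sqrt(oracle * (1 - oracle) / 600) + 0.01)


class TestWinnersCurse:
    def test_lead_effect_inflated_after_ascertainment(self, small_panel, small_ld, rng):
        """Among loci kept at min p < 0.01, the observed |effect| at the lead
        exceeds the true |beta2| on average (winner's curse direction)."""
        g = build_cohort_genotypes(small_panel, 2000, rng)
        n = 2000
        true_b, obs_b, kept_true, kept_obs = [], [], [], []
        c = midpoint_snp(small_panel)
        for _ in range(400):
            b2 = rng.normal(0, np.sqrt(5e-4))
            y = g[:, c] * b2 + rng.standard_normal(n)
            s = assoc_scan(CohortData(g, y))
            obs = s.z[s.lead_index] / np.sqrt(n)
            true_b.append(abs(b2))
            obs_b.append(abs(obs))
            if s.min_p < 0.01:
                kept_true.append(abs(b2))
                kept_obs.append(abs(obs))
        assert len(kept_obs) > 20
        assert np.mean(kept_obs) > np.mean(kept_true)
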