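"""PGI construction and evaluation tests: weight building, scoring,
incremental R^2, Nagelkerke R^2, decile reports, accuracy summaries, the
expected-R^2 curve and the power model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famgwas.meta import LdLookup
from famgwas.pgi import (build_ct_weights, build_infinitesimal_weights,
                         decile_report, detectable_r2, fit_expected_r2,
                         gwas_power, incremental_r2, nagelkerke_incremental,
                         relative_accuracy, score, weighted_mean_r2)
from famgwas.sim import SimConfig, simulate_unrelated_study
from .conftest import toy_sumstats


TOY_LD = LdLookup({("A", "B"): 0.2, ("A", "C"): 0.05, ("B", "C"): 0.2})


class TestBuildWeights:
    def test_threshold_one_trivial_ld_keeps_all(self):
        w = build_ct_weights(toy_sumstats(), LdLookup(), 1.0)
        assert len(w) == 3
        assert np.allclose(w["weight"], [0.5, 0.4, 0.3])

    def test_toy_clump_composition(self):
        w = build_ct_weights(toy_sumstats(), TOY_LD, 1e-3)
        assert w["snp_id"].tolist() == ["A", "C"]
        assert np.allclose(w["weight"], [0.5, 0.3])

    def test_nested_thresholds_give_nested_sets(self):
        strict = set(build_ct_weights(toy_sumstats(), TOY_LD, 2e-6)["snp_id"])
        loose = set(build_ct_weights(toy_sumstats(), TOY_LD, 1e-3)["snp_id"])
        assert strict <= loose

    def test_empty_survivors_warn(self):
        with pytest.warns(UserWarning, match="empty"):
            w = build_ct_weights(toy_sumstats(), TOY_LD, 1e-12)
        assert w.empty

    def test_infinitesimal_shrinkage_shrinks_toward_zero(self):
        stats_df = toy_sumstats(n=[100, 100, 100])
        w = build_infinitesimal_weights(stats_df, [0, 0, 0], 0.2, h2=0.5)
        assert (np.abs(w["weight"]) < np.abs(stats_df["beta"])).all()


class TestScore:
    INFO = pd.DataFrame({"snp_id": ["A", "B", "C"], "a1": ["A", "A", "A"],
                         "a2": ["G", "G", "G"]})

    def test_single_snp_unit_weight_is_dosage(self):
        w = pd.DataFrame({"snp_id": ["B"], "a1": ["A"], "weight": [1.0], "method": "x"})
        G = np.array([[0, 2, 1], [1, 0, 2]])
        assert np.allclose(score(G, w, self.INFO), [2, 0])

    def test_swapped_allele_weight_flips_dosage(self, rng):
        G = rng.integers(0, 3, size=(30, 3))
        w1 = pd.DataFrame({"snp_id": ["A", "B"], "a1": ["A", "A"],
                           "weight": [0.5, -0.2], "method": "x"})
        w2 = w1.copy()
        w2.loc[0, "a1"] = "G"
        w2.loc[0, "weight"] = -0.5
        s1, s2 = score(G, w1, self.INFO), score(G, w2, self.INFO)
        # sign/dosage flip changes the score only by a constant offset
        assert np.allclose(s1 - s1.mean(), s2 - s2.mean())

    def test_oracle_weights_track_genetic_value(self):
        cfg = SimConfig(n_snps=400, n_blocks=80, within_block_r=0.3, h2_add=0.5, seed=71)
        G, y, arch, info = simulate_unrelated_study(800, cfg)
        w = pd.DataFrame(
            {
                "snp_id": info["snp_id"],
                "a1": info["a1"],
                "weight": arch.beta_add / np.sqrt(2 * arch.freq * (1 - arch.freq)),
                "method": "oracle",
            }
        )
        from famgwas.coding import standardize_additive

        g = standardize_additive(G, arch.freq) @ arch.beta_add
        assert np.corrcoef(score(G, w, info), g)[0, 1] > 0.99

    def test_missing_genotype_mean_imputed(self):
        w = pd.DataFrame({"snp_id": ["A"], "a1": ["A"], "weight": [1.0], "method": "x"})
        G = np.array([[0, 0, 0], [2, 0, 0], [-1, 0, 0]])
        s = score(G, w, self.INFO)
        assert s[2] == pytest.approx(1.0)  # mean dosage of the observed values

    def test_no_overlap_errors(self):
        w = pd.DataFrame({"snp_id": ["Z"], "a1": ["A"], "weight": [1.0], "method": "x"})
        with pytest.raises(ValueError, match="overlap"):
            score(np.zeros((3, 3)), w, self.INFO)


class TestIncrementalR2:
    def test_independent_pgi_adds_nothing(self, rng):
        y = rng.standard_normal(500)
        r2, ci = incremental_r2(y, rng.standard_normal(500), n_boot=100, seed=0)
        assert r2 < 0.02

    def test_exact_pgi_fills_residual_variance(self, rng):
        n = 400
        C = rng.standard_normal((n, 1))
        y = 0.5 * C[:, 0] + rng.standard_normal(n)
        import statsmodels.api as sm

        base = sm.OLS(y, sm.add_constant(C)).fit().rsquared
        r2, _ = incremental_r2(y, y, C, n_boot=50, seed=0)
        assert r2 == pytest.approx(1.0 - base, abs=1e-10)

    def test_known_correlation_recovered(self, rng):
        n = 4000
        pgi = rng.standard_normal(n)
        rho = 0.45
        y = rho * pgi + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        r2, (lo, hi) = incremental_r2(y, pgi, n_boot=300, seed=1)
        assert lo <= rho**2 <= hi


class TestNagelkerke:
    def test_independent_pgi_near_zero(self, rng):
        y = (rng.random(800) < 0.3).astype(float)
        assert nagelkerke_incremental(y, rng.standard_normal(800)) < 0.01

    @pytest.mark.parametrize("link", ["logistic", "probit"])
    def test_increasing_in_liability_correlation(self, rng, link):
        n = 1500
        pgi = rng.standard_normal(n)
        vals = []
        for rho in (0.1, 0.3, 0.5):
            liab = rho * pgi + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            y = (liab > np.quantile(liab, 0.6)).astype(float)
            vals.append(nagelkerke_incremental(y, pgi, link=link))
        assert vals[0] < vals[1] < vals[2]
        assert all(0 <= v <= 1 for v in vals)

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError):
            nagelkerke_incremental(np.ones(50), rng.standard_normal(50))

    def test_perfect_separation_flagged(self):
        pgi = np.linspace(-2, 2, 60)
        y = (pgi > 0).astype(float)
        with pytest.raises(ValueError, match="separation"):
            nagelkerke_incremental(y, pgi)


class TestDecileReport:
    def test_deciles_partition_evenly(self, rng):
        rep = decile_report(rng.standard_normal(100), (rng.random(100) < 0.5).astype(float))
        assert rep["n"].tolist() == [10] * 10

    def test_constant_outcome_flat(self, rng):
        rep = decile_report(rng.standard_normal(200), np.zeros(200))
        assert np.allclose(rep["prevalence"], 0.0)
        assert np.allclose(rep["odds_ratio"], 1.0)

    def test_monotone_liability_gives_increasing_prevalence(self, rng):
        n = 4000
        pgi = rng.standard_normal(n)
        liab = 0.6 * pgi + rng.standard_normal(n)
        y = (liab > np.quantile(liab, 0.6)).astype(float)
        rep = decile_report(pgi, y)
        rho = stats.spearmanr(rep["decile"], rep["prevalence"]).statistic
        assert rho > 0.9
        assert rep["odds_ratio"].iloc[-1] > rep["odds_ratio"].iloc[0]


def test_weighted_mean_r2_printed_values():
    assert round(weighted_mean_r2([15.8, 12.0], [5653, 10843]), 1) == 13.3
    assert round(weighted_mean_r2([17.0, 12.9], [5653, 10843]), 1) == 14.3
    assert weighted_mean_r2([10.0, 20.0], [7, 7]) == pytest.approx(15.0)


def test_relative_accuracy_printed_values():
    assert round(relative_accuracy(1.3, 12.0)) == 11
    assert round(relative_accuracy(2.3, 15.8)) == 15
    assert relative_accuracy(0.12, 0.12) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        relative_accuracy(0.1, 0.0)


class TestExpectedR2Curve:
    def test_two_points_exact(self):
        curve = fit_expected_r2([(1e5, 0.05), (1e6, 0.11)])
        assert curve.predict(1e5) == pytest.approx(0.05)
        assert curve.predict(1e6) == pytest.approx(0.11)

    def test_recovery_from_noisy_points(self, rng):
        A, B = 2e-7, 1.5e-6
        Ns = [5e4, 1e5, 3e5, 1e6, 3e6]
        pts = [(n, A / (B + 1 / n) * (1 + 0.01 * rng.standard_normal())) for n in Ns]
        c = fit_expected_r2(pts)
        assert c.A == pytest.approx(A, rel=0.05)
        assert c.B == pytest.approx(B, rel=0.05)

    def test_monotone_with_asymptote(self):
        c = fit_expected_r2([(1e5, 0.05), (1e6, 0.11)])
        Ns = np.logspace(4, 8, 20)
        preds = c.predict(Ns)
        assert (np.diff(preds) > 0).all()
        assert preds[-1] < c.asymptote


class TestPower:
    def test_zero_r2_gives_alpha(self):
        assert gwas_power(1000, 0.0, 0.05) == pytest.approx(0.05)

    def test_mutual_inverse(self):
        for N, p, a in [(1e5, 0.5, 5e-8), (2574253, 0.8, 5e-8), (5e4, 0.9, 1e-5)]:
            r2 = detectable_r2(N, p, a)
            assert gwas_power(N, r2, a) == pytest.approx(p, rel=1e-6)

    def test_printed_dominance_power_value(self):
        r2_pct = detectable_r2(2574253, 0.80, 5e-8) * 100
        assert float(f"{r2_pct:.2g}") == 0.0015

    def test_monte_carlo_rejection_rate(self, rng):
        N, r2, alpha = 20000, 0.001, 1e-3
        analytic = gwas_power(N, r2, alpha)
        crit = stats.chi2.isf(alpha, 1)
        draws = rng.noncentral_chisquare(1, N * r2, size=10000)
        assert abs((draws > crit).mean() - analytic) < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gwas_power(100, 1.5, 0.05)
        with pytest.raises(ValueError):
            detectable_r2(100, 0.04, 0.05)
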