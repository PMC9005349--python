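"""Harmonization, meta-analysis, intercept inflation and clumping tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famgwas.meta import (LdLookup, QcThresholds, clump, harmonize, inflate_se,
                          mean_chisq, meta_sample_size)
from .conftest import toy_sumstats


def reference(**kw):
    return pd.DataFrame({"snp_id": ["A", "B", "C"], "a1": ["A", "A", "A"], "a2": ["G", "G", "G"]}) \
        if not kw else pd.DataFrame(kw)


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_freq(self):
        df = toy_sumstats(a1=["G", "A", "A"], a2=["A", "G", "G"])
        out, = harmonize([df], reference())
        assert out.loc[out.snp_id == "A", "beta"].iloc[0] == pytest.approx(-0.5)
        assert out.loc[out.snp_id == "A", "freq_a1"].iloc[0] == pytest.approx(0.7)
        assert out.loc[out.snp_id == "A", "a1"].iloc[0] == "A"

    def test_strand_flip_resolved(self):
        df = toy_sumstats(a1=["T", "A", "A"], a2=["C", "G", "G"])  # T/C complements A/G
        out, = harmonize([df], reference())
        assert len(out) == 3
        assert out.loc[out.snp_id == "A", "beta"].iloc[0] == pytest.approx(0.5)

    def test_palindromic_at_half_dropped(self):
        ref = pd.DataFrame({"snp_id": ["A"], "a1": ["A"], "a2": ["T"]})
        df = toy_sumstats().iloc[[0]].assign(a1="A", a2="T", freq_a1=0.5)
        out, = harmonize([df], ref)
        assert out.empty

    def test_five_record_toy_keeps_four(self):
        # 5 records: 3 clean, one low-frequency G/C palindrome (kept), one mismatch
        ref = pd.DataFrame(
            {"snp_id": ["A", "B", "C", "D", "E"],
             "a1": ["A", "A", "A", "G", "A"],
             "a2": ["G", "G", "G", "C", "G"]}
        )
        df = pd.DataFrame(
            {
                "snp_id": list("ABCDE"), "chr": 1, "pos": range(5),
                "a1": ["A", "A", "A", "G", "A"], "a2": ["G", "G", "G", "C", "C"],
                "freq_a1": [0.3, 0.3, 0.3, 0.1, 0.3], "n": 100,
                "beta": 0.1, "se": 0.1, "z": 1.0, "p": 0.3, "coding": "additive_012",
            }
        )
        out, = harmonize([df], ref)
        assert sorted(out["snp_id"]) == ["A", "B", "C", "D"]

    def test_idempotent(self):
        df = toy_sumstats(a1=["G", "A", "A"], a2=["A", "G", "G"])
        once, = harmonize([df], reference())
        twice, = harmonize([once], reference())
        pd.testing.assert_frame_equal(once, twice)

    def test_duplicate_snp_id_raises(self):
        df = toy_sumstats(snp_id=["A", "A", "C"])
        with pytest.raises(ValueError, match="duplicate"):
            harmonize([df], reference())


class TestMetaSampleSize:
    def test_single_study_identity(self):
        df = toy_sumstats()
        out = meta_sample_size([df]).set_index("snp_id")
        assert np.allclose(out.loc[["A", "B", "C"], "z"], [5, 4, 3])
        assert (out["n"] == 100).all()

    def test_two_equal_studies_scale_z_by_sqrt2(self):
        df = toy_sumstats(z=[1.0, 1.0, 1.0])
        out = meta_sample_size([df, df])
        assert np.allclose(out["z"], np.sqrt(2))
        assert (out["n"] == 200).all()

    def test_matches_ivw_when_se_proportional(self, rng):
        # se_i proportional to 1/sqrt(N_i) makes sqrt-N and 1/se^2 weights agree
        rows = []
        for n in (400, 1600):
            beta = rng.standard_normal(3) * 0.1
            se = 1.0 / np.sqrt(n)
            rows.append(toy_sumstats(n=n, beta=beta, se=se, z=beta / se))
        ss = meta_sample_size(rows)
        from famgwas.meta import meta_inverse_variance

        ivw = meta_inverse_variance(rows)
        assert np.allclose(ss["z"], ivw["z"], rtol=1e-10)

    def test_order_invariance(self):
        a = toy_sumstats()
        b = toy_sumstats(n=400, z=[2.0, 1.0, 0.5])
        z1 = meta_sample_size([a, b]).set_index("snp_id")["z"]
        z2 = meta_sample_size([b, a]).set_index("snp_id")["z"]
        assert np.allclose(z1.sort_index(), z2.sort_index())

    def test_variable_snp_coverage(self):
        a = toy_sumstats()
        b = toy_sumstats().iloc[[0, 1]]
        out = meta_sample_size([a, b]).set_index("snp_id")
        assert out.loc["A", "n"] == 200 and out.loc["C", "n"] == 100


class TestInflateSe:
    def test_intercept_one_unchanged(self):
        df = toy_sumstats()
        out = inflate_se(df, 1.0)
        pd.testing.assert_frame_equal(out, df)

    def test_printed_intercept_arithmetic(self):
        df = toy_sumstats(z=[10.0, 10.0, 10.0], se=[0.1] * 3)
        out = inflate_se(df, 1.663)
        assert out["z"].iloc[0] == pytest.approx(10 / np.sqrt(1.663), abs=5e-4)
        assert out["z"].iloc[0] == pytest.approx(7.755, abs=1e-3)

    def test_mean_chisq_divides_exactly(self):
        df = toy_sumstats()
        out = inflate_se(df, 1.5)
        assert (out["z"] ** 2).mean() == pytest.approx((df["z"] ** 2).mean() / 1.5)

    def test_bad_intercepts(self):
        with pytest.raises(ValueError):
            inflate_se(toy_sumstats(), 0.0)
        with pytest.warns(UserWarning):
            out = inflate_se(toy_sumstats(), 0.9)
        assert np.allclose(out["z"], toy_sumstats()["z"])


def brute_force_clump(stats_df, r2, p_threshold, r2_threshold):
    """Independent reference: literal restatement of the greedy rule with
    explicit sets, used as the oracle."""
    cand = stats_df[stats_df["p"] < p_threshold]
    remaining = sorted(
        cand.itertuples(), key=lambda r: (r.p, r.chr, r.pos, r.snp_id)
    )
    leads = []
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead.snp_id)
        remaining = [
            r for r in remaining
            if r2.get((lead.snp_id, r.snp_id), r2.get((r.snp_id, lead.snp_id), 0.0)) <= r2_threshold
        ]
    return leads


class TestClump:
    def test_empty_below_threshold(self):
        out = clump(toy_sumstats(), LdLookup(), 1e-10)
        assert out.empty

    def test_three_snp_hand_trace(self):
        lk = LdLookup({("A", "B"): 0.2, ("A", "C"): 0.05, ("B", "C"): 0.2})
        out = clump(toy_sumstats(), lk, 1e-3)
        assert out["snp_id"].tolist() == ["A", "C"]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            m = rng.integers(2, 11)
            ids = [f"s{i}" for i in range(m)]
            stats_df = pd.DataFrame(
                {
                    "snp_id": ids, "chr": rng.integers(1, 3, m),
                    "pos": rng.integers(1, 1000, m), "a1": "A", "a2": "G",
                    "freq_a1": 0.3, "n": 100, "beta": 0.1, "se": 0.1,
                    "z": 1.0, "p": rng.random(m),
                    "coding": "additive_012",
                }
            )
            pairs = {}
            for i in range(m):
                for j in range(i + 1, m):
                    if rng.random() < 0.5:
                        pairs[(ids[i], ids[j])] = rng.random()
            thr = rng.random()
            got = clump(stats_df, LdLookup(pairs), 0.5, thr)["snp_id"].tolist()
            want = brute_force_clump(stats_df, pairs, 0.5, thr)
            assert got == want

    def test_output_pairwise_independent(self, rng):
        m = 40
        ids = [f"s{i}" for i in range(m)]
        stats_df = toy_sumstats().iloc[:0]
        stats_df = pd.DataFrame(
            {"snp_id": ids, "chr": 1, "pos": range(m), "a1": "A", "a2": "G",
             "freq_a1": 0.3, "n": 100, "beta": 0.1, "se": 0.1, "z": 1.0,
             "p": rng.random(m), "coding": "additive_012"}
        )
        pairs = {(ids[i], ids[j]): rng.random() for i in range(m) for j in range(i + 1, m)}
        lk = LdLookup(pairs)
        leads = clump(stats_df, lk, 1.0, 0.1)["snp_id"].tolist()
        for i, a in enumerate(leads):
            for b in leads[i + 1:]:
                assert lk.r2(a, b) <= 0.1


class TestMeanChisq:
    def test_all_unit_z(self):
        assert mean_chisq(toy_sumstats(z=[1.0, 1.0, 1.0])) == pytest.approx(1.0)

    def test_low_n_snp_excluded(self):
        df = toy_sumstats(n=[100, 100, 50], z=[1.0, 1.0, 100.0])
        assert mean_chisq(df) == pytest.approx(1.0)

    def test_null_simulation(self, rng):
        z = rng.standard_normal(4000)
        df = pd.DataFrame({"snp_id": range(4000), "freq_a1": 0.3, "n": 100,
                           "z": z, "se": 0.1})
        assert abs(mean_chisq(df) - 1.0) < 0.05

    def test_all_filtered_raises(self):
        df = toy_sumstats(freq_a1=[0.001, 0.001, 0.001])
        with pytest.raises(ValueError):
            mean_chisq(df)
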