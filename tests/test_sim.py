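"""Tests of the synthetic-cohort generator: Mendelian transmission, LD
structure, assortative pairing, pedigree inbreeding, phenotype recoding and
file round-trips."""

import numpy as np
import pandas as pd
import pytest

from famgwas.sim import (SimConfig, assortative_pairing, pedigree_inbreeding,
                         read_cohort, recode_eduyears, simulate_cohort,
                         simulate_unrelated_study, write_cohort)


def mendelian_violations(cohort):
    idx = cohort.index_of
    nonf = cohort.individuals[cohort.individuals["father_id"] > 0]
    gi = cohort.genotypes[idx(nonf["id"])]
    gf = cohort.genotypes[idx(nonf["father_id"])]
    gm = cohort.genotypes[idx(nonf["mother_id"])]
    bad = (
        ((gf == 0) & (gm == 0) & (gi > 0))
        | ((gf == 2) & (gm == 2) & (gi < 2))
        | ((gf == 0) & (gm == 2) & (gi != 1))
        | ((gf == 2) & (gm == 0) & (gi != 1))
        | ((gf == 0) & (gi == 2))
        | ((gm == 0) & (gi == 2))
        | ((gf == 2) & (gi == 0))
        | ((gm == 2) & (gi == 0))
    )
    return int(bad.sum())


def test_mendelian_consistency_exhaustive(small_cohort):
    _, cohort, _ = small_cohort
    assert mendelian_violations(cohort) == 0


def test_block_ld_structure(small_cohort):
    cfg, cohort, _ = small_cohort
    founders = cohort.individuals[cohort.individuals["generation"] == 0]
    G = cohort.genotypes[cohort.index_of(founders["id"])].astype(float)
    blocks = cohort.snp_info["block"].to_numpy()
    R = np.corrcoef(G, rowvar=False)
    same = blocks[:, None] == blocks[None, :]
    off = ~np.eye(len(blocks), dtype=bool)
    assert abs(R[same & off].mean() - cfg.within_block_r) < 0.05
    assert abs(R[~same].mean()) < 0.01


def test_identical_seed_reproduces_cohort(small_cohort):
    cfg, cohort, arch = small_cohort
    cohort2, arch2 = simulate_cohort(cfg)
    assert np.array_equal(cohort.genotypes, cohort2.genotypes)
    assert np.array_equal(cohort.individuals["y"], cohort2.individuals["y"])
    assert np.array_equal(arch.beta_add, arch2.beta_add)


def test_realized_genetic_variance_matches_targets():
    cfg = SimConfig(n_snps=1000, n_blocks=1000, h2_add=0.4, h2_dom=0.1,
                    n_founder_pairs=800, n_generations=1, seed=2)
    cohort, _ = simulate_cohort(cfg)
    founders = cohort.individuals[cohort.individuals["generation"] == 0]
    assert abs(founders["g_add"].var() / 0.4 - 1) < 0.05
    assert abs(founders["g_dom"].var() / 0.1 - 1) < 0.05


def test_null_architecture_gives_uncorrelated_phenotype(rng):
    cfg = SimConfig(n_snps=300, n_blocks=300, h2_add=0.0, h2_dom=0.0,
                    indirect_scale=0.0, n_founder_pairs=600, n_generations=1, seed=9)
    cohort, _ = simulate_cohort(cfg)
    # any PGI: random weights on the genotypes
    w = rng.standard_normal(cohort.n_snps)
    pgi = cohort.genotypes.astype(float) @ w
    r = np.corrcoef(pgi, cohort.individuals["y"])[0, 1]
    assert abs(r) < 3.0 / np.sqrt(cohort.n)


def test_mating_score_correlation_hits_target(small_cohort):
    cfg, cohort, _ = small_cohort
    mp = cohort.mate_pairs_final()
    ind = cohort.individuals.set_index("id")
    r = np.corrcoef(ind.loc[mp["father_id"], "y"], ind.loc[mp["mother_id"], "y"])[0, 1]
    # mate score is the phenotype here; small-sample slack on top of +-0.02
    assert abs(r - cfg.target_mate_r) < 0.07


def test_ancestry_assortment_concordance(rng):
    cfg = SimConfig(n_snps=200, n_blocks=200, h2_add=0.2, ancestry_divergence=0.1,
                    mate_score_weights=(0.0, 0.0, 1.0), target_mate_r=0.8,
                    n_founder_pairs=500, n_generations=2, seed=13)
    cohort, _ = simulate_cohort(cfg)
    mp = cohort.mate_pairs_final()
    sub = cohort.individuals.set_index("id")["subpop"]
    conc = (sub.loc[mp["father_id"]].to_numpy() == sub.loc[mp["mother_id"]].to_numpy()).mean()
    # permutation null for concordance
    f = sub.loc[mp["father_id"]].to_numpy()
    m = sub.loc[mp["mother_id"]].to_numpy()
    null = np.array([(f == rng.permutation(m)).mean() for _ in range(200)])
    assert conc > np.quantile(null, 0.999)


def test_assortment_inflates_genetic_variance():
    kw = dict(n_snps=400, n_blocks=400, h2_add=0.5, n_founder_pairs=1500,
              n_generations=4, seed=3)
    random_mating, _ = simulate_cohort(SimConfig(target_mate_r=0.0, **kw))
    assorted, _ = simulate_cohort(SimConfig(target_mate_r=0.6, **kw))
    v_r = random_mating.final_generation()["g_add"].var()
    v_a = assorted.final_generation()["g_add"].var()
    assert v_a > v_r * 1.1


@pytest.mark.parametrize("target", [0.0, 0.2, 0.43, 0.8])
def test_assortative_pairing_calibration(target, rng):
    n = 6000
    sm, sf = rng.standard_normal(n), rng.standard_normal(n)
    perm = assortative_pairing(sm, sf, target, seed=1)
    realized = np.corrcoef(sm, sf[perm])[0, 1]
    tol = 3.0 / np.sqrt(n) if target == 0 else 0.02
    assert abs(realized - target) < tol
    assert sorted(perm) == list(range(n))  # one-to-one


def test_assortative_pairing_rank_matching_and_ties(rng):
    sm, sf = rng.standard_normal(50), rng.standard_normal(50)
    perm = assortative_pairing(sm, sf, 1.0, seed=0)
    from scipy.stats import spearmanr

    assert spearmanr(sm, sf[perm]).statistic == pytest.approx(1.0)
    with pytest.warns(UserWarning, match="ties"):
        assortative_pairing(np.ones(10), rng.standard_normal(10), 1.0, seed=0)
    with pytest.raises(ValueError):
        assortative_pairing(sm, sf[:10], 0.5)


def test_pedigree_inbreeding_known_values():
    # founders -> sibs -> (cousin marriage) -> offspring with F = 1/16
    cousins = pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6, 7, 8, 9],
            "father_id": [0, 0, 1, 1, 0, 0, 3, 4, 7],
            "mother_id": [0, 0, 2, 2, 0, 0, 5, 6, 8],
        }
    )
    F = pedigree_inbreeding(cousins)
    assert F.iloc[:8].eq(0).all()
    assert F.iloc[8] == pytest.approx(1 / 16)

    sibs = pd.DataFrame(
        {"id": [1, 2, 3, 4, 5], "father_id": [0, 0, 1, 1, 3], "mother_id": [0, 0, 2, 2, 4]}
    )
    assert pedigree_inbreeding(sibs).iloc[4] == pytest.approx(0.25)


def test_pedigree_cycle_raises():
    loop = pd.DataFrame({"id": [1, 2], "father_id": [2, 1], "mother_id": [0, 0]})
    with pytest.raises(ValueError, match="ancestor"):
        pedigree_inbreeding(loop)


def test_simulated_inbred_matings_have_quarter_F():
    cfg = SimConfig(n_snps=100, n_blocks=100, n_founder_pairs=200, n_generations=2,
                    inbred_fraction=0.2, seed=5)
    cohort, _ = simulate_cohort(cfg)
    fin = cohort.final_generation()
    vals = set(np.round(fin["F"].unique(), 6))
    assert vals <= {0.0, 0.25}
    assert 0.25 in vals
    assert mendelian_violations(cohort) == 0


class TestRecodeEduyears:
    MAPPING = {"degree": 20, "a_levels": 13}

    def test_vocational_minus_five(self):
        assert recode_eduyears("vocational", 16, self.MAPPING) == 11

    def test_vocational_early_leaver_dropped(self):
        assert recode_eduyears("vocational", 11, self.MAPPING) is None

    def test_mapping_table_ignores_age(self):
        assert recode_eduyears("degree", 14, self.MAPPING) == 20
        assert recode_eduyears("degree", 30, self.MAPPING) == 20

    def test_unknown_category(self):
        with pytest.raises(KeyError):
            recode_eduyears("mystery", 18, self.MAPPING)


def test_cohort_round_trip(tmp_path, small_cohort):
    _, cohort, arch = small_cohort
    # inject a missing genotype to exercise the NA dialect
    import copy

    cohort = copy.deepcopy(cohort)
    cohort.genotypes[0, 0] = -1
    write_cohort(cohort, tmp_path, arch)
    raw_lines = (tmp_path / "genotypes.raw").read_text().splitlines()
    assert len(raw_lines) == cohort.n + 1
    assert raw_lines[0].split("\t")[:6] == ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    assert raw_lines[1].split("\t")[6] == "NA"
    back, arch2 = read_cohort(tmp_path)
    assert np.array_equal(back.genotypes, cohort.genotypes)
    assert np.allclose(back.individuals["y"], cohort.individuals["y"])
    assert np.allclose(arch2.beta_add, arch.beta_add)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(h2_add=0.7, h2_dom=0.5)
    with pytest.raises(ValueError):
        SimConfig(n_founder_pairs=1)
    with pytest.raises(ValueError):
        SimConfig(target_mate_r=1.0)
    with pytest.raises(ValueError):
        SimConfig(freq_range=(0.0, 0.5))


def test_unrelated_study_matches_targets():
    cfg = SimConfig(n_snps=1000, n_blocks=200, within_block_r=0.3, h2_add=0.4,
                    h2_dom=0.1, seed=4)
    G, y, arch, info = simulate_unrelated_study(1500, cfg)
    assert G.shape == (1500, 1000)
    from famgwas.coding import standardize_additive

    g = standardize_additive(G, arch.freq) @ arch.beta_add
    assert abs(g.var() / 0.4 - 1) < 0.05
    assert abs(y.var() - 1.0) < 0.1
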