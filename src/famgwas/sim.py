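"""Synthetic family-structured cohorts with controllable genetic architecture.

The generator produces multi-generation pedigrees of biallelic genotypes with

* block-wise linkage disequilibrium (LD), simulated by thresholding
  equicorrelated Gaussians per haplotype so the within-block genotype
  correlation is known analytically;
* additive effects, dominance deviations and indirect parental effects on a
  quantitative phenotype;
* assortative mating on a weighted composite of phenotype, a latent factor
  correlated with the additive genetic value, and genetic ancestry;
* optional two-subpopulation allele-frequency divergence (Balding-Nichols);
* optional inbred (full-sib) matings so that the pedigree inbreeding
  coefficient F varies across the cohort.

Blocks are transmitted as units (no recombination within a block, free
recombination between blocks), which preserves the within-block LD across
generations and makes every offspring genotype Mendelian-consistent with its
parents by construction.
"""

from __future__ import annotations

import functools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._seeds import as_generator, substream
from .coding import standardize_additive, standardize_dominance

__all__ = [
    "SimConfig",
    "TraitArchitecture",
    "Cohort",
    "simulate_cohort",
    "simulate_panel",
    "assortative_pairing",
    "pedigree_inbreeding",
    "recode_eduyears",
    "write_cohort",
    "read_cohort",
]

MISSING_GENOTYPE = -1  # sentinel in the int8 genotype matrix; written as "NA"


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Knobs of the cohort generator.

    Heritabilities are proportions of phenotypic variance in the founder
    generation; ``indirect_scale`` multiplies the sum of the parents' true
    additive genetic values; ``mate_score_weights`` weighs the
    (phenotype, latent factor, ancestry) channels of the mating score;
    ``target_mate_r`` is the mate-pair correlation of that score;
    ``ancestry_divergence`` is the Balding-Nichols F_ST between the two
    subpopulations (0 = single population); ``inbred_fraction`` is the
    proportion of matings made between full siblings (requires at least two
    generations of offspring).
    """

    n_snps: int = 1000
    n_blocks: int = 200
    within_block_r: float = 0.0
    freq_range: tuple = (0.05, 0.5)
    n_founder_pairs: int = 500
    n_generations: int = 2
    h2_add: float = 0.4
    h2_dom: float = 0.0
    indirect_scale: float = 0.0
    mate_score_weights: tuple = (1.0, 0.0, 0.0)
    target_mate_r: float = 0.0
    latent_pgi_corr: float = 0.5
    ancestry_divergence: float = 0.0
    inbred_fraction: float = 0.0
    directional_dominance: bool = False
    children_per_pair: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.h2_add < 0 or self.h2_dom < 0 or self.h2_add + self.h2_dom > 1:
            raise ValueError("require h2_add >= 0, h2_dom >= 0, h2_add + h2_dom <= 1")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder allele frequencies must lie in (0, 1)")
        if not (0.0 <= self.target_mate_r < 1.0):
            raise ValueError("target_mate_r must be in [0, 1)")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must be in [0, 1)")
        if self.n_founder_pairs < 2:
            raise ValueError("need at least 2 founder pairs")
        if self.n_generations < 1:
            raise ValueError("need at least one offspring generation")
        if self.n_blocks < 1 or self.n_blocks > self.n_snps:
            raise ValueError("n_blocks must be in [1, n_snps]")
        if not (0.0 <= self.inbred_fraction < 1.0):
            raise ValueError("inbred_fraction must be in [0, 1)")
        if self.indirect_scale < 0:
            raise ValueError("indirect_scale must be nonnegative")
        if any(w < 0 for w in self.mate_score_weights):
            raise ValueError("mate_score_weights must be nonnegative")
        if self.inbred_fraction > 0 and self.n_generations < 2:
            warnings.warn(
                "inbred matings are full-sib matings and only occur from the "
                "second offspring generation on; with n_generations < 2 all F are 0"
            )


@dataclass
class TraitArchitecture:
    """Ground-truth per-SNP effects on the standardized (founder-frequency)
    genotype codings, plus the indirect-effect scale."""

    beta_add: np.ndarray
    delta_dom: np.ndarray
    eta: float
    freq: np.ndarray


@dataclass
class Cohort:
    """A simulated pedigree with genotypes and phenotypes.

    ``individuals`` holds one row per individual: id, fid (family id), sex
    (1 = male, 2 = female), father_id / mother_id (0 for founders),
    generation, subpop, F (pedigree inbreeding coefficient), y, g_add, g_dom
    (realized genetic values) and roles (comma-joined tags).  ``genotypes``
    is an (n_individuals, n_snps) int8 matrix of allele counts aligned with
    ``individuals``; ``snp_info`` describes the markers; ``mate_pairs``
    records every mating with the generation of its offspring.
    """

    individuals: pd.DataFrame
    genotypes: np.ndarray
    snp_info: pd.DataFrame
    mate_pairs: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def index_of(self, ids) -> np.ndarray:
        pos = pd.Series(np.arange(self.n), index=self.individuals["id"].to_numpy())
        return pos.loc[np.asarray(ids)].to_numpy()

    def final_generation(self) -> pd.DataFrame:
        last = self.individuals["generation"].max()
        return self.individuals[self.individuals["generation"] == last]

    def sib_pairs(self) -> pd.DataFrame:
        """Final-generation full siblings, one row per sibship member."""
        fin = self.final_generation()
        sizes = fin.groupby(["father_id", "mother_id"])["id"].transform("size")
        return fin[sizes >= 2]

    def trios(self) -> pd.DataFrame:
        """Final-generation children with both parents genotyped."""
        fin = self.final_generation()
        return fin[(fin["father_id"] != 0) & (fin["mother_id"] != 0)]

    def mate_pairs_final(self) -> pd.DataFrame:
        """Parent couples of the final generation."""
        last = self.individuals["generation"].max()
        return self.mate_pairs[self.mate_pairs["offspring_generation"] == last]

    def allele_freqs(self) -> np.ndarray:
        g = self.genotypes.astype(float)
        g[g < 0] = np.nan
        return np.nanmean(g, axis=0) / 2.0


# ---------------------------------------------------------------------------
# LD machinery: thresholded equicorrelated Gaussians
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=4096)
def _latent_rho(p: float, target_r: float) -> float:
    """Latent Gaussian correlation inducing allele correlation `target_r`
    between two thresholded standard normals that are both 1 with
    probability `p`."""
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(1.0 - p)
    pq = p * (1.0 - p)

    def allele_r(rho):
        both = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ).cdf([t, t])
        p11 = 1.0 - 2.0 * stats.norm.cdf(t) + both
        return (p11 - p * p) / pq

    if allele_r(0.999) <= target_r:
        return 0.999
    return optimize.brentq(lambda r: allele_r(r) - target_r, 1e-9, 0.999, xtol=1e-6)


def _block_assignments(n_snps: int, n_blocks: int) -> np.ndarray:
    """Deterministic block sizes with spread (cycling 1:2:3:4:5 weights), so
    LD scores vary across SNPs and LD-score regressions are identified."""
    w = (np.arange(n_blocks) % 5) + 1
    sizes = np.maximum(1, np.floor(n_snps * w / w.sum()).astype(int))
    # distribute the rounding remainder over the largest blocks
    i = 0
    order = np.argsort(-w, kind="stable")
    while sizes.sum() < n_snps:
        sizes[order[i % n_blocks]] += 1
        i += 1
    while sizes.sum() > n_snps:
        j = order[::-1][i % n_blocks]
        if sizes[j] > 1:
            sizes[j] -= 1
        i += 1
    return np.repeat(np.arange(n_blocks), sizes)


def _draw_haplotypes(rng, n_hap, freq, block_of_snp, rho_of_block):
    """(n_hap, n_snps) int8 haplotypes with equicorrelated latent Gaussians
    per block; allele j is 1 iff the latent exceeds Phi^{-1}(1 - freq[j])."""
    m = len(freq)
    t = stats.norm.ppf(1.0 - np.asarray(freq, float))
    rho = np.asarray(rho_of_block, float)[block_of_snp]
    n_blocks = int(block_of_snp.max()) + 1
    common = rng.standard_normal((n_hap, n_blocks))[:, block_of_snp]
    noise = rng.standard_normal((n_hap, m))
    latent = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * noise
    return (latent > t).astype(np.int8)


def simulate_panel(n: int, config: SimConfig, seed=None):
    """Unrelated genotype panel drawn from the founder distribution.

    Returns ``(genotypes, snp_info)`` where snp_info has snp_id, chr, pos,
    a1, a2, freq and block columns.  Useful for LD-score panels and
    quick GWAS experiments that do not need pedigree structure.
    """
    rng = as_generator(seed if seed is not None else substream(config.seed, "panel"))
    freq, block_of_snp, rho_of_block = _panel_parameters(config, rng)
    h1 = _draw_haplotypes(rng, n, freq, block_of_snp, rho_of_block)
    h2 = _draw_haplotypes(rng, n, freq, block_of_snp, rho_of_block)
    geno = (h1 + h2).astype(np.int8)
    return geno, _snp_frame(freq, block_of_snp)


def _panel_parameters(config: SimConfig, rng):
    block_of_snp = _block_assignments(config.n_snps, config.n_blocks)
    lo, hi = config.freq_range
    freq = rng.uniform(lo, hi, size=config.n_snps)
    if config.within_block_r > 0:
        # one frequency per block keeps the latent-correlation calibration exact
        first = np.full(config.n_blocks, config.n_snps, dtype=int)
        np.minimum.at(first, block_of_snp, np.arange(config.n_snps))
        freq = freq[first][block_of_snp]
        rho_of_block = np.array(
            [
                _latent_rho(round(float(freq[first[b]]), 6), config.within_block_r)
                for b in range(config.n_blocks)
            ]
        )
    else:
        rho_of_block = np.zeros(config.n_blocks)
    return freq, block_of_snp, rho_of_block


def _snp_frame(freq, block_of_snp):
    m = len(freq)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{j + 1}" for j in range(m)],
            "chr": 1,
            "pos": (np.arange(m) + 1) * 1000,
            "a1": "A",
            "a2": "G",
            "freq": freq,
            "block": block_of_snp,
        }
    )


def simulate_unrelated_study(n: int, config: SimConfig, seed=None):
    """Unrelated individuals with genotypes, phenotype and ground truth.

    A lightweight alternative to :func:`simulate_cohort` for analyses that
    need no pedigree (GWAS nulls, LD-score experiments): draws a founder
    panel and a trait architecture at the configured heritabilities.
    Returns ``(genotypes, y, architecture, snp_info)``.
    """
    root = seed if seed is not None else config.seed
    rng = substream(root, "unrelated-study")
    freq, block_of_snp, rho_of_block = _panel_parameters(config, rng)
    h1 = _draw_haplotypes(rng, n, freq, block_of_snp, rho_of_block)
    h2 = _draw_haplotypes(rng, n, freq, block_of_snp, rho_of_block)
    geno = (h1 + h2).astype(np.int8)
    p_real = np.clip(geno.mean(axis=0) / 2.0, 1e-4, 1 - 1e-4)
    beta_raw = rng.standard_normal(config.n_snps)
    delta_raw = rng.standard_normal(config.n_snps)
    if config.directional_dominance:
        delta_raw = np.abs(delta_raw)
    z_add = standardize_additive(geno, p_real)
    z_dom = standardize_dominance(geno, p_real)
    beta = _scale_effects(beta_raw, z_add @ beta_raw, config.h2_add)
    delta = _scale_effects(delta_raw, z_dom @ delta_raw, config.h2_dom)
    g_add = z_add @ beta if config.h2_add > 0 else np.zeros(n)
    g_dom = z_dom @ delta if config.h2_dom > 0 else np.zeros(n)
    sigma_e = np.sqrt(max(0.0, 1.0 - config.h2_add - config.h2_dom))
    y = g_add + g_dom + sigma_e * rng.standard_normal(n)
    arch = TraitArchitecture(beta_add=beta, delta_dom=delta, eta=0.0, freq=p_real)
    info = _snp_frame(freq, block_of_snp)
    info["freq"] = p_real
    return geno, y, arch, info


# ---------------------------------------------------------------------------
# assortative pairing
# ---------------------------------------------------------------------------


def assortative_pairing(scores_male, scores_female, target_r, seed=None) -> np.ndarray:
    """One-to-one pairing of males and females with a target score correlation.

    Returns ``perm`` such that male ``i`` is paired with female ``perm[i]``.
    A Gaussian-copula rank-noise scheme is used: the female ranking key is a
    mixture of her normal score and independent noise, and the mixing weight
    is calibrated by bisection so that the realized Pearson correlation of
    the paired scores hits ``target_r``.
    """
    sm = np.asarray(scores_male, dtype=float)
    sf = np.asarray(scores_female, dtype=float)
    if sm.shape != sf.shape or sm.ndim != 1:
        raise ValueError("score vectors must be one-dimensional and of equal length")
    n = len(sm)
    if n < 2:
        raise ValueError("need at least two pairs")
    rng = as_generator(seed)
    if target_r >= 1.0:
        if len(np.unique(sm)) < n or len(np.unique(sf)) < n:
            warnings.warn("ties in scores: perfect correlation unattainable, best-effort rank matching")
        perm = np.empty(n, dtype=int)
        perm[np.argsort(sm, kind="stable")] = np.argsort(sf, kind="stable")
        return perm
    if target_r <= 0.0:
        return rng.permutation(n)
    if sm.std() == 0 or sf.std() == 0:
        raise ValueError("constant scores cannot be correlated")

    nm = stats.norm.ppf(stats.rankdata(sm) / (n + 1))
    nf = stats.norm.ppf(stats.rankdata(sf) / (n + 1))
    del nm  # male side enters through its score ordering only
    eps = rng.standard_normal(n)
    order_m = np.argsort(sm, kind="stable")

    def pairing_for(a: float) -> np.ndarray:
        key = a * nf + np.sqrt(max(0.0, 1.0 - a * a)) * eps
        perm = np.empty(n, dtype=int)
        perm[order_m] = np.argsort(key, kind="stable")
        return perm

    def realized(a: float) -> float:
        perm = pairing_for(a)
        return float(np.corrcoef(sm, sf[perm])[0, 1])

    if realized(1.0) <= target_r:
        return pairing_for(1.0)
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_r:
            lo = mid
        else:
            hi = mid
    return pairing_for(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# pedigree inbreeding
# ---------------------------------------------------------------------------


def pedigree_inbreeding(pedigree: pd.DataFrame) -> pd.Series:
    """Pedigree inbreeding coefficient F for every individual.

    F(i) is the kinship coefficient of i's parents, computed by the standard
    recursive algorithm; founders have F = 0.  ``pedigree`` needs columns
    ``id``, ``father_id`` and ``mother_id`` (0, empty or NaN = unknown
    parent).  Raises if an individual is its own ancestor.
    """

    def norm_parent(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == 0 or v == "0" or v == "":
            return None
        return v

    parents = {
        row.id: (norm_parent(row.father_id), norm_parent(row.mother_id))
        for row in pedigree.itertuples()
    }

    depth: dict = {}

    def get_depth(i):
        stack = [(i, False)]
        in_progress = set()
        while stack:
            node, expanded = stack.pop()
            if node in depth:
                continue
            if expanded:
                in_progress.discard(node)
                f, m = parents.get(node, (None, None))
                d = 0
                for p in (f, m):
                    if p is not None and p in parents:
                        d = max(d, depth[p] + 1)
                depth[node] = d
            else:
                if node in in_progress:
                    raise ValueError(f"pedigree cycle: individual {node!r} is its own ancestor")
                in_progress.add(node)
                stack.append((node, True))
                f, m = parents.get(node, (None, None))
                for p in (f, m):
                    if p is not None and p in parents and p not in depth:
                        stack.append((p, False))
        return depth[i]

    for i in parents:
        get_depth(i)

    memo: dict = {}

    def kinship(a, b) -> float:
        if a is None or b is None:
            return 0.0
        if a not in parents or b not in parents:
            return 0.0
        key = (a, b) if depth[a] >= depth[b] else (b, a)
        if key in memo:
            return memo[key]
        a, b = key
        if a == b:
            fa, ma = parents[a]
            val = 0.5 * (1.0 + kinship(fa, ma))
        else:
            # expand the deeper individual (a); at equal depth a cannot be
            # an ancestor of b, so either order is valid
            fa, ma = parents[a]
            val = 0.5 * (kinship(fa, b) + kinship(ma, b))
        memo[key] = val
        return val

    out = {}
    for i, (f, m) in parents.items():
        out[i] = kinship(f, m)
    return pd.Series(out, name="F").loc[pedigree["id"].to_numpy()].reset_index(drop=True)


# ---------------------------------------------------------------------------
# phenotype recoding
# ---------------------------------------------------------------------------


def recode_eduyears(qualification, age_left_fte=None, mapping=None, *,
                    vocational=("vocational",), min_age=12):
    """Years-of-education equivalent for one record, or None if dropped.

    Non-vocational categories are mapped through the supplied ``mapping``
    table (category -> years).  Holders of a vocational-only qualification
    are coded as the age they left full-time education minus five; those who
    left before ``min_age`` are dropped (returns None).
    """
    if mapping is None:
        mapping = {}
    if qualification in vocational:
        if age_left_fte is None or (isinstance(age_left_fte, float) and np.isnan(age_left_fte)):
            raise ValueError("vocational records need age_left_fte")
        if age_left_fte < min_age:
            return None
        return float(age_left_fte) - 5.0
    if qualification in mapping:
        return float(mapping[qualification])
    raise KeyError(f"unknown qualification category: {qualification!r}")


# ---------------------------------------------------------------------------
# the cohort generator
# ---------------------------------------------------------------------------


def _scale_effects(raw, realized_values, target_var):
    """Scale raw effect sizes so that var(realized genetic value) hits target."""
    if target_var <= 0:
        return np.zeros_like(raw)
    sd = realized_values.std()
    if sd == 0:
        raise ValueError("degenerate genetic values; increase n_snps or sample size")
    return raw * np.sqrt(target_var) / sd


def simulate_cohort(config: SimConfig):
    """Simulate a multi-generation cohort; returns (Cohort, TraitArchitecture)."""
    rng_arch = substream(config.seed, "architecture")
    rng_founders = substream(config.seed, "founders")
    rng_mate = substream(config.seed, "mating")
    rng_env = substream(config.seed, "environment")
    rng_trans = substream(config.seed, "transmission")

    freq, block_of_snp, rho_of_block = _panel_parameters(config, rng_founders)
    m = config.n_snps
    n_f = config.n_founder_pairs

    # subpopulation-specific founder frequencies (Balding-Nichols drift)
    if config.ancestry_divergence > 0:
        fst = config.ancestry_divergence
        a = freq * (1.0 - fst) / fst
        b = (1.0 - freq) * (1.0 - fst) / fst
        pop_freqs = [np.clip(rng_founders.beta(a, b), 0.01, 0.99) for _ in range(2)]
        n_subpops = 2
    else:
        pop_freqs = [freq]
        n_subpops = 1

    # founders: n_f males + n_f females, split evenly across subpopulations
    n_founders = 2 * n_f
    subpop = np.zeros(n_founders, dtype=int)
    sex = np.tile([1, 2], n_f)
    if n_subpops == 2:
        # alternate so both sexes occur in both subpopulations
        subpop = (np.arange(n_founders) // 2) % 2
    hap = np.empty((n_founders, 2, m), dtype=np.int8)
    for k in range(n_subpops):
        idx = np.flatnonzero(subpop == k)
        for h in range(2):
            hap[idx, h, :] = _draw_haplotypes(
                rng_founders, len(idx), pop_freqs[k], block_of_snp, rho_of_block
            )
    geno = hap.sum(axis=1, dtype=np.int16).astype(np.int8)

    # architecture scaled on the founder sample (pooled frequencies)
    p_real = np.clip(geno.mean(axis=0) / 2.0, 1e-4, 1 - 1e-4)
    beta_raw = rng_arch.standard_normal(m)
    delta_raw = rng_arch.standard_normal(m)
    if config.directional_dominance:
        delta_raw = np.abs(delta_raw)
    z_add = standardize_additive(geno, p_real)
    z_dom = standardize_dominance(geno, p_real)
    beta = _scale_effects(beta_raw, z_add @ beta_raw, config.h2_add)
    delta = _scale_effects(delta_raw, z_dom @ delta_raw, config.h2_dom)
    arch = TraitArchitecture(beta_add=beta, delta_dom=delta, eta=config.indirect_scale, freq=p_real)
    sigma_e = np.sqrt(max(0.0, 1.0 - config.h2_add - config.h2_dom))

    def genetic_values(g):
        ga = standardize_additive(g, p_real) @ beta if config.h2_add > 0 else np.zeros(len(g))
        gd = standardize_dominance(g, p_real) @ delta if config.h2_dom > 0 else np.zeros(len(g))
        return ga, gd

    g_add, g_dom = genetic_values(geno)
    y = g_add + g_dom + sigma_e * rng_env.standard_normal(n_founders)

    ids = np.arange(1, n_founders + 1)
    next_id = n_founders + 1
    rows = [
        pd.DataFrame(
            {
                "id": ids,
                "sex": sex,
                "father_id": 0,
                "mother_id": 0,
                "generation": 0,
                "subpop": subpop,
                "y": y,
                "g_add": g_add,
                "g_dom": g_dom,
            }
        )
    ]
    haps = [hap]
    mate_records = []

    cur = rows[0]
    cur_hap = hap

    w_p, w_l, w_a = config.mate_score_weights

    for gen in range(1, config.n_generations + 1):
        # --- mating score for the parent generation -----------------------
        yv = cur["y"].to_numpy()
        ystd = (yv - yv.mean()) / yv.std() if yv.std() > 0 else np.zeros(len(yv))
        gstd = cur["g_add"].to_numpy()
        gstd = (gstd - gstd.mean()) / gstd.std() if gstd.std() > 0 else np.zeros(len(yv))
        lam = config.latent_pgi_corr
        latent = lam * gstd + np.sqrt(max(0.0, 1.0 - lam**2)) * rng_mate.standard_normal(len(yv))
        anc = cur["subpop"].to_numpy().astype(float)
        anc = (anc - anc.mean()) / anc.std() if anc.std() > 0 else np.zeros(len(yv))
        score = w_p * ystd + w_l * latent + w_a * anc
        if score.std() == 0 and config.target_mate_r > 0:
            score = score + 1e-9 * rng_mate.standard_normal(len(score))
            if w_p == w_l == w_a == 0:
                raise ValueError("cannot target a mating correlation with zero score weights")

        males = cur[cur["sex"] == 1]
        females = cur[cur["sex"] == 2]
        n_pairs_total = min(len(males), len(females))

        # --- full-sib (inbred) matings ------------------------------------
        inbred_father, inbred_mother = [], []
        if config.inbred_fraction > 0 and gen >= 2:
            k_target = int(round(config.inbred_fraction * n_pairs_total))
            sibships = cur.groupby(["father_id", "mother_id"])
            eligible = []
            for (f, mo), grp in sibships:
                if f == 0:
                    continue
                ms = grp[grp["sex"] == 1]["id"].to_numpy()
                fs = grp[grp["sex"] == 2]["id"].to_numpy()
                if len(ms) and len(fs):
                    eligible.append((ms[0], fs[0]))
            if eligible:
                pick = rng_mate.permutation(len(eligible))[:k_target]
                for j in pick:
                    inbred_father.append(eligible[j][0])
                    inbred_mother.append(eligible[j][1])
        inbred_ids = set(inbred_father) | set(inbred_mother)

        pool_m = males[~males["id"].isin(inbred_ids)]
        pool_f = females[~females["id"].isin(inbred_ids)]
        n_pairs = min(len(pool_m), len(pool_f))
        pool_m = pool_m.iloc[:n_pairs]
        pool_f = pool_f.iloc[:n_pairs]

        score_s = pd.Series(score, index=cur["id"].to_numpy())
        sm = score_s.loc[pool_m["id"].to_numpy()].to_numpy()
        sf = score_s.loc[pool_f["id"].to_numpy()].to_numpy()
        perm = assortative_pairing(sm, sf, config.target_mate_r, seed=rng_mate)
        father_ids = np.concatenate([pool_m["id"].to_numpy(), np.asarray(inbred_father, dtype=int)])
        mother_ids = np.concatenate(
            [pool_f["id"].to_numpy()[perm], np.asarray(inbred_mother, dtype=int)]
        )
        inbred_flag = np.concatenate(
            [np.zeros(n_pairs, dtype=bool), np.ones(len(inbred_father), dtype=bool)]
        )
        mate_records.append(
            pd.DataFrame(
                {
                    "offspring_generation": gen,
                    "father_id": father_ids,
                    "mother_id": mother_ids,
                    "inbred": inbred_flag,
                }
            )
        )

        # --- offspring ----------------------------------------------------
        cpp = config.children_per_pair
        n_children = len(father_ids) * cpp
        child_father = np.repeat(father_ids, cpp)
        child_mother = np.repeat(mother_ids, cpp)
        # alternate sexes within each sibship -> balanced and sib pairs mixed
        child_sex = np.tile(np.resize([1, 2], cpp), len(father_ids))

        pos = pd.Series(np.arange(len(cur)), index=cur["id"].to_numpy())
        fi = pos.loc[child_father].to_numpy()
        mi = pos.loc[child_mother].to_numpy()
        n_blocks = int(block_of_snp.max()) + 1
        pat_pick = rng_trans.integers(0, 2, size=(n_children, n_blocks))[:, block_of_snp]
        mat_pick = rng_trans.integers(0, 2, size=(n_children, n_blocks))[:, block_of_snp]
        cols = np.arange(m)[None, :]
        child_hap = np.empty((n_children, 2, m), dtype=np.int8)
        child_hap[:, 0, :] = cur_hap[fi[:, None], pat_pick, cols]
        child_hap[:, 1, :] = cur_hap[mi[:, None], mat_pick, cols]
        child_geno = child_hap.sum(axis=1, dtype=np.int16).astype(np.int8)

        ga, gd = genetic_values(child_geno)
        parent_g = pd.Series(cur["g_add"].to_numpy(), index=cur["id"].to_numpy())
        indirect = config.indirect_scale * (
            parent_g.loc[child_father].to_numpy() + parent_g.loc[child_mother].to_numpy()
        )
        yc = ga + gd + indirect + sigma_e * rng_env.standard_normal(n_children)

        sub_f = pd.Series(cur["subpop"].to_numpy(), index=cur["id"].to_numpy())
        sp_f = sub_f.loc[child_father].to_numpy()
        sp_m = sub_f.loc[child_mother].to_numpy()
        mix = sp_f != sp_m
        child_sub = sp_f.copy()
        if mix.any():
            child_sub[mix] = rng_trans.integers(0, 2, size=int(mix.sum()))

        child_ids = np.arange(next_id, next_id + n_children)
        next_id += n_children
        rows.append(
            pd.DataFrame(
                {
                    "id": child_ids,
                    "sex": child_sex,
                    "father_id": child_father,
                    "mother_id": child_mother,
                    "generation": gen,
                    "subpop": child_sub,
                    "y": yc,
                    "g_add": ga,
                    "g_dom": gd,
                }
            )
        )
        haps.append(child_hap)
        cur = rows[-1]
        cur_hap = child_hap

    individuals = pd.concat(rows, ignore_index=True)
    genotypes = np.concatenate([h.sum(axis=1, dtype=np.int16).astype(np.int8) for h in haps])
    mate_pairs = (
        pd.concat(mate_records, ignore_index=True)
        if mate_records
        else pd.DataFrame(columns=["offspring_generation", "father_id", "mother_id", "inbred"])
    )

    # inbreeding coefficients (skip the recursion when no inbred matings exist)
    if config.inbred_fraction > 0:
        individuals["F"] = pedigree_inbreeding(individuals).to_numpy()
    else:
        individuals["F"] = 0.0

    # family ids and role tags
    fid = np.where(
        individuals["father_id"] > 0,
        "F" + individuals["father_id"].astype(str) + "_" + individuals["mother_id"].astype(str),
        "F" + individuals["id"].astype(str),
    )
    individuals["fid"] = fid
    last = individuals["generation"].max()
    is_final = individuals["generation"] == last
    sib_size = individuals.groupby("fid")["id"].transform("size")
    final_parents = set(mate_pairs.loc[mate_pairs["offspring_generation"] == last, "father_id"]) | set(
        mate_pairs.loc[mate_pairs["offspring_generation"] == last, "mother_id"]
    )
    role_sib = (is_final & (sib_size >= 2)).to_numpy()
    role_trio = (is_final & (individuals["father_id"] != 0)).to_numpy()
    role_mate = individuals["id"].isin(final_parents).to_numpy()
    individuals["roles"] = [
        ",".join(t for t, on in (("sib", s), ("trio_child", tr), ("mate", ma)) if on)
        for s, tr, ma in zip(role_sib, role_trio, role_mate)
    ]

    snp_info = _snp_frame(freq, block_of_snp)
    snp_info["freq"] = p_real  # realized pooled founder frequency
    cohort = Cohort(
        individuals=individuals,
        genotypes=genotypes,
        snp_info=snp_info,
        mate_pairs=mate_pairs,
    )
    return cohort, arch


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, directory, architecture: TraitArchitecture | None = None):
    """Write a cohort as plain-text tables.

    Emits a PLINK RAW-style dosage table (``genotypes.raw``: tab-separated,
    header FID IID PAT MAT SEX PHENOTYPE then one column per SNP named
    SNP_A1, missing genotypes as NA), a header-less FAM pedigree table
    (``pedigree.fam``), a phenotype table, the full individual metadata, the
    marker table and, if given, the trait architecture.  ``read_cohort``
    round-trips these files losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ind = cohort.individuals
    if ind.empty:
        raise ValueError("cohort is empty")

    snp_cols = [f"{s}_{a1}" for s, a1 in zip(cohort.snp_info["snp_id"], cohort.snp_info["a1"])]
    geno = pd.DataFrame(cohort.genotypes, columns=snp_cols)
    geno = geno.astype("Int64").mask(geno < 0)
    raw = pd.concat(
        [
            pd.DataFrame(
                {
                    "FID": ind["fid"],
                    "IID": ind["id"],
                    "PAT": ind["father_id"],
                    "MAT": ind["mother_id"],
                    "SEX": ind["sex"],
                    "PHENOTYPE": ind["y"],
                }
            ).reset_index(drop=True),
            geno,
        ],
        axis=1,
    )
    raw.to_csv(directory / "genotypes.raw", sep="\t", index=False, na_rep="NA")

    fam = ind[["fid", "id", "father_id", "mother_id", "sex", "y"]]
    fam.to_csv(directory / "pedigree.fam", sep="\t", index=False, header=False)

    pheno_cols = ["id", "y"] + (["eduyears"] if "eduyears" in ind.columns else [])
    ind[pheno_cols].rename(columns={"id": "IID"}).to_csv(
        directory / "phenotypes.tsv", sep="\t", index=False
    )
    ind.to_csv(directory / "individuals.tsv", sep="\t", index=False)
    cohort.snp_info.to_csv(directory / "snps.tsv", sep="\t", index=False)
    cohort.mate_pairs.to_csv(directory / "mate_pairs.tsv", sep="\t", index=False)

    if architecture is not None:
        pd.DataFrame(
            {
                "snp_id": cohort.snp_info["snp_id"],
                "freq": architecture.freq,
                "beta_add": architecture.beta_add,
                "delta_dom": architecture.delta_dom,
            }
        ).to_csv(directory / "architecture.tsv", sep="\t", index=False)
        (directory / "sim_meta.json").write_text(json.dumps({"eta": architecture.eta}))


def read_cohort(directory):
    """Read a cohort written by :func:`write_cohort`.

    Returns ``(Cohort, TraitArchitecture | None)``.
    """
    directory = Path(directory)
    ind = pd.read_csv(directory / "individuals.tsv", sep="\t")
    ind["roles"] = ind["roles"].fillna("")
    snp_info = pd.read_csv(directory / "snps.tsv", sep="\t")
    mate_pairs = pd.read_csv(directory / "mate_pairs.tsv", sep="\t")
    raw = pd.read_csv(directory / "genotypes.raw", sep="\t")
    geno = raw.iloc[:, 6:].to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING_GENOTYPE, geno).astype(np.int8)
    cohort = Cohort(individuals=ind, genotypes=geno, snp_info=snp_info, mate_pairs=mate_pairs)
    arch = None
    arch_path = directory / "architecture.tsv"
    if arch_path.exists():
        a = pd.read_csv(arch_path, sep="\t")
        eta = 0.0
        meta = directory / "sim_meta.json"
        if meta.exists():
            eta = json.loads(meta.read_text()).get("eta", 0.0)
        arch = TraitArchitecture(
            beta_add=a["beta_add"].to_numpy(),
            delta_dom=a["delta_dom"].to_numpy(),
            eta=eta,
            freq=a["freq"].to_numpy(),
        )
    return cohort, arch
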