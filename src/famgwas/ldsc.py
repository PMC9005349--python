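"""LD-score regression for additive and dominance-deviation association
statistics.

For additive effects the LD score of SNP j is ``l_add(j) = sum_k r^2_jk``;
for dominance deviations the correlation between the dominance codings of
two SNPs is the square of their allele-count correlation under HWE, so the
information from tagged SNPs decays faster and the relevant score is
``l_dom(j) = sum_k r^4_jk``.  Regressing chi-square statistics on
``N * l / M`` with a free intercept separates polygenic signal (the slope,
an estimate of h^2) from confounding (the intercept minus one).  Standard
errors come from a delete-one block jackknife over contiguous SNP blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_ld_scores",
    "ld_scores_from_panel",
    "ld_scores_from_blocks",
    "ldsc_fit",
    "confounding_share",
    "cross_trait_rg",
    "dominance_signal_share",
    "LdscFit",
]


@dataclass
class LdscFit:
    h2: float
    intercept: float
    se_h2: float
    se_intercept: float
    M: int
    mean_chisq: float
    mode: str = "additive"

    @property
    def confounding_share(self):
        if self.mean_chisq <= 1:
            return None
        return confounding_share(self.intercept, self.mean_chisq)


def ld_scores_from_panel(genotypes, snp_ids=None, adjust=True,
                         n_jackknife_blocks=None) -> pd.DataFrame:
    """Empirical LD scores from a reference genotype panel.

    ``adjust`` applies the finite-sample bias correction
    r^2 - (1 - r^2)/(n - 2) to off-diagonal terms of the additive score
    (and its square for the dominance score).
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if n < 50:
        raise ValueError("panel too small; need at least 50 individuals")
    if (G.std(axis=0) == 0).any():
        raise ValueError("monomorphic SNP in the LD panel")
    R = np.corrcoef(G, rowvar=False)
    r2 = R**2
    if adjust:
        adj = r2 - (1.0 - r2) / (n - 2)
        np.fill_diagonal(adj, 1.0)
        r2 = adj
    l_add = r2.sum(axis=1)
    r4 = np.clip(r2, 0.0, None) ** 2
    np.fill_diagonal(r4, 1.0)
    l_dom = r4.sum(axis=1)
    return _score_frame(l_add, l_dom, m, snp_ids, n_jackknife_blocks)


def ld_scores_from_blocks(block_of_snp, r2_within, snp_ids=None,
                          n_jackknife_blocks=None) -> pd.DataFrame:
    """Analytic LD scores for block-equicorrelated genotypes.

    Every SNP in a block of size b has l_add = 1 + (b - 1) r^2 and
    l_dom = 1 + (b - 1) r^4.
    """
    blocks = np.asarray(block_of_snp)
    m = len(blocks)
    sizes = pd.Series(blocks).groupby(blocks).transform("size").to_numpy()
    l_add = 1.0 + (sizes - 1) * r2_within
    l_dom = 1.0 + (sizes - 1) * r2_within**2
    return _score_frame(l_add, l_dom, m, snp_ids, n_jackknife_blocks, ld_blocks=blocks)


def compute_ld_scores(genotype_panel=None, block_spec=None, mode="additive", **kw):
    """Dispatch to the panel-based or analytic LD-score computation.

    ``block_spec`` is a ``(block_of_snp, r2_within)`` pair.  The returned
    frame always carries both additive and dominance scores; ``mode`` is
    accepted for interface symmetry.
    """
    if (genotype_panel is None) == (block_spec is None):
        raise ValueError("supply exactly one of genotype_panel or block_spec")
    if genotype_panel is not None:
        return ld_scores_from_panel(genotype_panel, **kw)
    return ld_scores_from_blocks(*block_spec, **kw)


def _score_frame(l_add, l_dom, m, snp_ids, n_jackknife_blocks, ld_blocks=None):
    nb = n_jackknife_blocks or default_jackknife_blocks(m)
    if ld_blocks is not None:
        # jackknife units must not split an LD block, or delete-one
        # replicates would not be exchangeable and SEs come out too small
        uniq = pd.unique(ld_blocks)
        nb = min(nb, max(20, len(uniq) // 3))
        group_of_ld = {b: (i * nb) // len(uniq) for i, b in enumerate(uniq)}
        block_id = np.array([group_of_ld[b] for b in ld_blocks])
    else:
        edges = np.linspace(0, m, nb + 1).astype(int)
        block_id = np.zeros(m, dtype=int)
        for b in range(nb):
            block_id[edges[b]:edges[b + 1]] = b
    return pd.DataFrame(
        {
            "snp_id": list(snp_ids) if snp_ids is not None else [f"rs{j+1}" for j in range(m)],
            "l_add": l_add,
            "l_dom": l_dom,
            "jackknife_block": block_id,
        }
    )


def default_jackknife_blocks(m: int) -> int:
    return min(200, max(20, m // 10))


def _wls(x, y, w):
    X = np.column_stack([np.ones_like(x), x])
    W = w / w.sum()
    xtwx = X.T @ (X * W[:, None])
    xtwy = X.T @ (y * W)
    intercept, slope = np.linalg.solve(xtwx, xtwy)
    return intercept, slope


def ldsc_fit(chisq, ld_scores: pd.DataFrame, N, M=None, mode="additive") -> LdscFit:
    """Weighted regression of chi-square statistics on LD scores.

    E[chi^2_j] = intercept + (N h^2 / M) l_j, so the slope times M/N is the
    heritability estimate.  Weights are 1/max(l, 1) (a single pass, no
    iterative reweighting).  Jackknife SEs are computed over the contiguous
    SNP blocks carried by ``ld_scores``.
    """
    chisq = np.asarray(chisq, dtype=float)
    lcol = "l_dom" if mode == "dominance" else "l_add"
    l = ld_scores[lcol].to_numpy(dtype=float)
    m = len(chisq)
    if m != len(l):
        raise ValueError("chisq and LD scores disagree in length")
    if m < 200:
        raise ValueError("need at least 200 SNPs for LD-score regression")
    if np.ptp(l) == 0:
        raise ValueError("degenerate LD scores (no variance)")
    M = M or m
    N = np.asarray(N, dtype=float)
    Nbar = float(N.mean()) if N.ndim else float(N)
    blocks = ld_scores["jackknife_block"].to_numpy()
    ublocks = np.unique(blocks)
    if len(ublocks) < 20:
        raise ValueError("need at least 20 jackknife blocks")

    x = Nbar * l / M
    w = 1.0 / np.maximum(l, 1.0)
    intercept, slope = _wls(x, chisq, w)

    reps = np.empty((len(ublocks), 2))
    for i, b in enumerate(ublocks):
        keep = blocks != b
        reps[i] = _wls(x[keep], chisq[keep], w[keep])
    nb = len(ublocks)
    se_int, se_slope = np.sqrt((nb - 1) / nb * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))

    return LdscFit(
        h2=float(slope),
        intercept=float(intercept),
        se_h2=float(se_slope),
        se_intercept=float(se_int),
        M=int(M),
        mean_chisq=float(chisq.mean()),
        mode=mode,
    )


def confounding_share(intercept: float, mean_chisq: float) -> float:
    """Share of the mean chi-square inflation attributable to confounding:
    (intercept - 1) / (mean chi^2 - 1), clipped to [0, 1]."""
    if mean_chisq <= 1:
        raise ValueError("mean chi-square must exceed 1")
    return float(np.clip((intercept - 1.0) / (mean_chisq - 1.0), 0.0, 1.0))


def cross_trait_rg(z1, z2, ld_scores: pd.DataFrame, N1, N2):
    """Genetic correlation between two traits from their z statistics.

    The slope of z1*z2 on sqrt(N1 N2) l / M estimates the genetic
    covariance; dividing by the square root of the product of the two
    LD-score heritabilities gives r_g.  The jackknife repeats all three
    regressions per deleted block.  Returns ``(rg, se)``.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    l = ld_scores["l_add"].to_numpy(dtype=float)
    m = len(l)
    M = m
    blocks = ld_scores["jackknife_block"].to_numpy()
    w = 1.0 / np.maximum(l, 1.0)
    sqN = np.sqrt(float(N1) * float(N2))

    def est(keep):
        _, cov = _wls(sqN * l[keep] / M, (z1 * z2)[keep], w[keep])
        _, h1 = _wls(float(N1) * l[keep] / M, (z1**2)[keep], w[keep])
        _, h2 = _wls(float(N2) * l[keep] / M, (z2**2)[keep], w[keep])
        if h1 <= 0 or h2 <= 0:
            raise ValueError("nonpositive heritability estimate; r_g undefined")
        return cov / np.sqrt(h1 * h2)

    full = est(np.ones(m, dtype=bool))
    ublocks = np.unique(blocks)
    reps = np.array([est(blocks != b) for b in ublocks])
    nb = len(ublocks)
    se = float(np.sqrt((nb - 1) / nb * ((reps - reps.mean()) ** 2).sum()))
    return float(full), se


def dominance_signal_share(beta_hats, ses) -> float:
    """Share of the variance of estimated dominance effects due to true
    signal rather than sampling noise: max(0, 1 - mean(se^2)/var(beta_hat))."""
    beta_hats = np.asarray(beta_hats, float)
    ses = np.asarray(ses, float)
    if len(beta_hats) < 100:
        raise ValueError("need at least 100 SNPs")
    v = beta_hats.var()
    if v == 0:
        raise ValueError("zero variance of estimated effects")
    return float(max(0.0, 1.0 - np.mean(ses**2) / v))
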