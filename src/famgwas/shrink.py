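"""Empirical-Bayes winner's-curse adjustment, replication-record
predictions, and inbreeding-depression (ID) estimation.

Effects selected for genome-wide significance overestimate their true
magnitudes (the winner's curse).  Under a normal prior with variance tau^2
for the true standardized effect, the posterior mean given an unbiased
estimate beta_hat with standard error se is

    E[b | beta_hat] = beta_hat * tau^2 / (tau^2 + se^2),

which remains valid conditional on the observed data regardless of how the
SNP was selected (selection on the data does not change the posterior
given the data).  tau^2 is fitted by method of moments from the mean
chi-square; an optional two-component point-normal prior is fitted by
maximum likelihood.

Inbreeding depression is the slope of the phenotype on the pedigree
inbreeding coefficient F.  With the dominance coding {0, 2p, 4p-2}, a unit
of F shifts the expected coding by -2pq, so dominance GWAS summary
statistics yield the unlinked-approximation estimate
B_hat = -sum_j 2 p_j q_j delta_hat_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from ._seeds import as_generator
from .coding import DOMINANCE

__all__ = [
    "EBPrior",
    "fit_eb_prior",
    "winners_curse_adjust",
    "replication_expectations",
    "IdEstimate",
    "estimate_id_individual",
    "estimate_id_sumstats",
    "genomic_inbreeding",
]


@dataclass
class EBPrior:
    """Prior on true standardized per-SNP effects: b ~ N(0, tau2) with
    probability 1 - pi0, b = 0 with probability pi0."""

    tau2: float
    pi0: float = 0.0

    def __post_init__(self):
        if self.tau2 < 0 or not (0 <= self.pi0 <= 1):
            raise ValueError("tau2 >= 0 and pi0 in [0, 1] required")


def fit_eb_prior(stats_df: pd.DataFrame, intercept: float = 1.0,
                 point_normal: bool = False) -> EBPrior:
    """Method-of-moments prior fit from summary statistics.

    tau^2 = max(0, mean(chi^2)/intercept - 1) / mean(N) on the standardized
    scale (se ~= 1/sqrt(N)).  With ``point_normal`` a two-component prior
    (null mass pi0 plus N(0, tau2)) is fitted by maximum likelihood on the
    z statistics, seeded by the moment estimate.
    """
    df = stats_df[stats_df["se"].notna()]
    if len(df) < 1000:
        raise ValueError("need at least 1000 SNPs to fit the prior")
    z2 = (df["z"] ** 2).to_numpy()
    nbar = float(df["n"].mean())
    excess = z2.mean() / intercept - 1.0
    if excess < 0:
        import warnings

        warnings.warn("mean chi-square below the intercept; tau2 set to 0")
        return EBPrior(tau2=0.0)
    tau2 = excess / nbar
    if not point_normal:
        return EBPrior(tau2=tau2)

    z = df["z"].to_numpy()

    def negll(theta):
        logit_pi0, log_tau2 = theta
        pi0 = 1.0 / (1.0 + np.exp(-logit_pi0))
        t2 = np.exp(log_tau2)
        s2 = 1.0 + nbar * t2
        lik = pi0 * stats.norm.pdf(z) + (1 - pi0) * stats.norm.pdf(z, scale=np.sqrt(s2))
        return -np.log(np.maximum(lik, 1e-300)).sum()

    x0 = [0.0, np.log(max(2.0 * tau2, 1e-12))]
    sol = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-6})
    pi0 = 1.0 / (1.0 + np.exp(-sol.x[0]))
    return EBPrior(tau2=float(np.exp(sol.x[1])), pi0=float(pi0))


def _posterior_moments(beta, se, prior: EBPrior):
    """Posterior mean and variance of the true effect, plus the posterior
    non-null probability under a point-normal prior."""
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    shrink = prior.tau2 / (prior.tau2 + se**2)
    m1 = beta * shrink
    v1 = shrink * se**2
    if prior.pi0 == 0:
        return m1, v1, np.ones_like(m1)
    # posterior odds of the non-null component
    lik0 = stats.norm.pdf(beta, scale=se)
    lik1 = stats.norm.pdf(beta, scale=np.sqrt(prior.tau2 + se**2))
    w1 = (1 - prior.pi0) * lik1
    w = w1 / (w1 + prior.pi0 * lik0)
    return m1, v1, w


def winners_curse_adjust(beta, se, prior: EBPrior):
    """Posterior-mean effect sizes under the empirical-Bayes prior.

    With a pure normal prior this is beta * tau^2/(tau^2 + se^2); with a
    point-normal prior the shrunk mean is further weighted by the posterior
    probability of being non-null.
    """
    se = np.asarray(se, float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    if prior.tau2 == 0 and prior.pi0 == 0:
        return np.zeros_like(np.asarray(beta, float))
    m1, _, w = _posterior_moments(beta, se, prior)
    return w * m1


def replication_expectations(discovery_stats: pd.DataFrame, prior: EBPrior,
                             N_rep: float, alpha_rep: float,
                             n_mc: int = 0, seed=None) -> pd.DataFrame:
    """Per-SNP replication predictions under the posterior.

    For each discovery record, the true effect has posterior N(m, v); the
    replication estimate adds sampling noise se_rep = 1/sqrt(N_rep) (on the
    standardized scale).  Reports P(replication sign matches discovery) and
    P(two-sided replication p < alpha_rep).  With ``n_mc`` > 0 a Monte-Carlo
    version of both probabilities is added.
    """
    if not (0 < alpha_rep < 1):
        raise ValueError("alpha_rep must be in (0, 1)")
    beta = discovery_stats["beta"].to_numpy(float)
    se = discovery_stats["se"].to_numpy(float)
    m, v, w = _posterior_moments(beta, se, prior)
    se_rep = 1.0 / np.sqrt(float(N_rep))
    s = np.sqrt(v + se_rep**2)
    sgn = np.sign(beta)
    # mixture with the null point mass: null replicates with sign prob 0.5
    p_sign = w * stats.norm.cdf(sgn * m / s) + (1 - w) * 0.5
    crit = stats.norm.isf(alpha_rep / 2.0) * se_rep
    p_sig_nonnull = stats.norm.sf((crit - m) / s) + stats.norm.cdf((-crit - m) / s)
    p_sig = w * p_sig_nonnull + (1 - w) * alpha_rep
    out = pd.DataFrame(
        {
            "snp_id": discovery_stats["snp_id"].to_numpy(),
            "p_sign_concordant": p_sign,
            "p_significant": p_sig,
        }
    )
    if n_mc > 0:
        rng = as_generator(seed)
        b = m[None, :] + np.sqrt(v)[None, :] * rng.standard_normal((n_mc, len(m)))
        if prior.pi0 > 0:
            nullmask = rng.random((n_mc, len(m))) > w[None, :]
            b[nullmask] = 0.0
        rep = b + se_rep * rng.standard_normal((n_mc, len(m)))
        out["p_sign_concordant_mc"] = (np.sign(rep) == sgn[None, :]).mean(axis=0)
        out["p_significant_mc"] = (np.abs(rep) > crit).mean(axis=0)
    return out


@dataclass
class IdEstimate:
    """Inbreeding-depression regression summary.

    ``b`` is the slope of the phenotype on F (phenotype units per unit F);
    ``first_cousin_offspring_effect`` converts it to the expected shift for
    offspring of first cousins (F = 1/16) in months when the phenotype is
    measured in years.
    """

    b: float
    se: float
    p: float
    first_cousin_offspring_effect: float
    n: int


def _first_cousin_months(b: float) -> float:
    return b * (1.0 / 16.0) * 12.0


def estimate_id_individual(y, F, covariates=None) -> IdEstimate:
    """OLS slope of the phenotype on the inbreeding coefficient."""
    y = np.asarray(y, float)
    F = np.asarray(F, float)
    if F.std() == 0:
        raise ValueError("inbreeding coefficient is constant; slope undefined")
    X = F[:, None] if covariates is None else np.column_stack([F, np.asarray(covariates, float)])
    res = sm.OLS(y, sm.add_constant(X)).fit()
    b = float(res.params[1])
    return IdEstimate(
        b=b,
        se=float(res.bse[1]),
        p=float(res.pvalues[1]),
        first_cousin_offspring_effect=_first_cousin_months(b),
        n=len(y),
    )


def estimate_id_sumstats(stats_df: pd.DataFrame) -> IdEstimate:
    """Inbreeding-depression slope from dominance GWAS summary statistics.

    Under the {0, 2p, 4p-2} dominance coding, the expected coding shifts by
    -2 p q per unit F, so the phenotype-on-F slope is (unlinked
    approximation) B_hat = -sum_j 2 p_j q_j delta_hat_j, with sampling
    variance sum_j (2 p_j q_j)^2 se_j^2.
    """
    if not (stats_df["coding"] == DOMINANCE).all():
        raise ValueError("summary statistics must carry the dominance_dev coding")
    df = stats_df[stats_df["se"].notna()]
    p = df["freq_a1"].to_numpy(float)
    w = 2.0 * p * (1.0 - p)
    b = float(-(w * df["beta"].to_numpy(float)).sum())
    se = float(np.sqrt((w**2 * df["se"].to_numpy(float) ** 2).sum()))
    z = b / se if se > 0 else np.nan
    return IdEstimate(
        b=b,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        first_cousin_offspring_effect=_first_cousin_months(b),
        n=int(df["n"].max()) if len(df) else 0,
    )


def genomic_inbreeding(genotypes, freq=None) -> np.ndarray:
    """Excess-homozygosity inbreeding coefficient per individual:
    F_hom = 1 - O(het) / E(het), an alternative regressor to pedigree F."""
    G = np.asarray(genotypes, float)
    if freq is None:
        freq = G.mean(axis=0) / 2.0
    e_het = float((2.0 * freq * (1.0 - freq)).sum())
    o_het = (G == 1).sum(axis=1)
    return 1.0 - o_het / e_het
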