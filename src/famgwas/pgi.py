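"""Polygenic-index construction and evaluation.

Weights come from clumping + thresholding (C+T) of meta-analysis summary
statistics at the usual p-value cutoffs, or from a closed-form infinitesimal
shrinkage that solves (M/(N h^2) I + R) b = beta_hat per LD block.  Scores
are dosage-weighted sums with mean-dosage imputation of missing genotypes.
Predictive power is the incremental R^2 (gain over a covariate-only
regression), or the incremental Nagelkerke R^2 for binary outcomes; the
expected-accuracy curve E(R^2) = A / (B + 1/N) and a one-degree-of-freedom
noncentral chi-square power model complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._seeds import as_generator
from .meta import COMPLEMENT, LdLookup, clump

__all__ = [
    "build_ct_weights",
    "build_infinitesimal_weights",
    "score",
    "incremental_r2",
    "nagelkerke_incremental",
    "decile_report",
    "weighted_mean_r2",
    "relative_accuracy",
    "ExpectedR2Curve",
    "fit_expected_r2",
    "gwas_power",
    "detectable_r2",
]

CT_THRESHOLDS = {"ct_5e-8": 5e-8, "ct_5e-5": 5e-5, "ct_5e-3": 5e-3, "ct_1": 1.0}


def build_ct_weights(stats_df: pd.DataFrame, ld_lookup: LdLookup,
                     p_threshold: float, method: str | None = None) -> pd.DataFrame:
    """Clumping-and-thresholding weights: the meta-analysis betas of the
    lead SNPs surviving the clump at ``p_threshold``."""
    leads = clump(stats_df, ld_lookup, p_threshold)
    if leads.empty:
        import warnings

        warnings.warn(f"no SNPs survive p < {p_threshold}; empty weight set")
    if method is None:
        method = f"ct_{p_threshold:g}"
    return pd.DataFrame(
        {
            "snp_id": leads["snp_id"],
            "a1": leads["a1"],
            "weight": leads["beta"],
            "method": method,
        }
    ).reset_index(drop=True)


def build_infinitesimal_weights(stats_df: pd.DataFrame, block_of_snp, r_within,
                                h2: float, method="inf_shrink") -> pd.DataFrame:
    """Closed-form infinitesimal shrinkage per LD block.

    Solves (M/(N h^2) I + R) b = beta_hat within each block, with R the
    equicorrelation matrix of the block (r_within off the diagonal).
    """
    df = stats_df.reset_index(drop=True)
    M = len(df)
    lam = M / (df["n"].to_numpy(float) * h2)
    beta = df["beta"].to_numpy(float)
    blocks = np.asarray(block_of_snp)
    out = np.empty(M)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        k = len(idx)
        R = np.full((k, k), r_within)
        np.fill_diagonal(R, 1.0)
        A = R + np.diag(lam[idx])
        out[idx] = np.linalg.solve(A, beta[idx])
    return pd.DataFrame(
        {"snp_id": df["snp_id"], "a1": df["a1"], "weight": out, "method": method}
    )


def score(genotypes, weights: pd.DataFrame, snp_info: pd.DataFrame) -> np.ndarray:
    """Score individuals: sum_j dosage_ij * w_j.

    ``snp_info`` gives the cohort's marker order and allele coding (snp_id,
    a1, a2).  Weight rows whose effect allele is the cohort's other allele
    (directly or through a strand flip) have their dosage flipped (2 - g);
    weights on SNPs absent from the cohort are ignored; missing genotypes
    are imputed at the mean dosage of the SNP.
    """
    if weights["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in weights")
    info = snp_info.reset_index(drop=True)
    pos = pd.Series(info.index.to_numpy(), index=info["snp_id"])
    present = weights[weights["snp_id"].isin(pos.index)]
    if present.empty:
        raise ValueError("no overlap between weights and cohort SNPs")
    j = pos.loc[present["snp_id"]].to_numpy()
    a1_cohort = info.loc[j, "a1"].to_numpy()
    a2_cohort = info.loc[j, "a2"].to_numpy()
    w_a1 = present["a1"].to_numpy()
    same = (w_a1 == a1_cohort) | (w_a1 == np.array([COMPLEMENT.get(a, "?") for a in a1_cohort]))
    flip = (w_a1 == a2_cohort) | (w_a1 == np.array([COMPLEMENT.get(a, "?") for a in a2_cohort]))
    if not (same | flip).all():
        raise ValueError("weights contain alleles that cannot be aligned to the cohort")

    G = np.asarray(genotypes, dtype=float)[:, j]
    G[G < 0] = np.nan
    col_mean = np.nanmean(G, axis=0)
    nanmask = np.isnan(G)
    if nanmask.any():
        G[nanmask] = np.broadcast_to(col_mean, G.shape)[nanmask]
    G[:, flip & ~same] = 2.0 - G[:, flip & ~same]
    return G @ present["weight"].to_numpy(float)


def _r2(y, X):
    X = sm.add_constant(X)
    res = sm.OLS(y, X).fit()
    return res.rsquared


def incremental_r2(y, pgi, covariates=None, n_boot=1000, seed=None):
    """Incremental R^2 of the PGI over a covariate-only regression, with a
    percentile bootstrap CI over individuals.

    Returns ``(delta_r2, (lo, hi))``.
    """
    y = np.asarray(y, float)
    pgi = np.asarray(pgi, float)
    n = len(y)
    C = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    if n <= C.shape[1] + 2:
        raise ValueError("sample too small for the covariate design")

    def delta(idx):
        base = _r2(y[idx], C[idx]) if C.shape[1] else 0.0
        full = _r2(y[idx], np.column_stack([C[idx], pgi[idx]]))
        return max(full - base, 0.0)

    point = delta(np.arange(n))
    rng = as_generator(seed)
    reps = np.array([delta(rng.integers(0, n, n)) for _ in range(n_boot)])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(point), (float(lo), float(hi))


def _nagelkerke(y, X, link):
    n = len(y)
    model = sm.Probit if link == "probit" else sm.Logit
    Xc = sm.add_constant(X) if X is not None and np.size(X) else np.ones((n, 1))
    try:
        fit = model(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 1e3:
            raise PerfectSeparationError("divergent coefficients")
        ll1 = fit.llf
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise ValueError(f"perfect separation or singular fit: {err}") from err
    ll0 = model(y, np.ones((n, 1))).fit(disp=0).llf
    cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    cs_max = 1.0 - np.exp(2.0 * ll0 / n)
    return cs / cs_max


def nagelkerke_incremental(y_binary, pgi, covariates=None, link="logistic"):
    """Incremental Nagelkerke R^2 of the PGI for a binary outcome.

    Nagelkerke R^2 = (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n)) with L0 the
    intercept-only likelihood; the incremental value is the with-PGI minus
    the without-PGI model's R^2.  ``link`` is ``logistic`` or ``probit``.
    """
    y = np.asarray(y_binary, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if link not in ("logistic", "probit"):
        raise ValueError("link must be 'logistic' or 'probit'")
    C = None if covariates is None else np.asarray(covariates, float)
    pgi = np.asarray(pgi, float)
    base = _nagelkerke(y, C, link) if C is not None and np.size(C) else 0.0
    X = pgi[:, None] if C is None or not np.size(C) else np.column_stack([C, pgi])
    full = _nagelkerke(y, X, link)
    return float(full - base)


def decile_report(pgi, outcome, covariates=None, reference_decile=1) -> pd.DataFrame:
    """Outcome prevalence and odds ratios by PGI decile.

    Deciles partition the sample by PGI rank (stable ties); prevalences get
    Wilson binomial CIs; odds ratios versus the reference decile come from a
    logistic regression of the outcome on decile dummies plus covariates.
    Returns one row per decile.
    """
    pgi = np.asarray(pgi, float)
    y = np.asarray(outcome, float)
    n = len(pgi)
    if n < 100:
        raise ValueError("need at least 100 individuals")
    order = np.argsort(pgi, kind="stable")
    decile = np.empty(n, dtype=int)
    edges = np.linspace(0, n, 11).astype(int)
    for d in range(10):
        decile[order[edges[d]:edges[d + 1]]] = d + 1

    rows = []
    constant = len(np.unique(y)) < 2
    ors = {d: (1.0 if constant else np.nan) for d in range(1, 11)}
    if not constant:
        dummies = pd.get_dummies(pd.Categorical(decile, categories=range(1, 11)))
        dummies = dummies.drop(columns=reference_decile).to_numpy(dtype=float)
        X = dummies if covariates is None else np.column_stack([dummies, np.asarray(covariates, float)])
        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
        coefs = fit.params[1:10]
        k = 0
        for d in range(1, 11):
            if d == reference_decile:
                ors[d] = 1.0
            else:
                ors[d] = float(np.exp(coefs[k]))
                k += 1
    for d in range(1, 11):
        mask = decile == d
        cnt = int(y[mask].sum())
        lo, hi = proportion_confint(cnt, int(mask.sum()), method="wilson")
        rows.append(
            {
                "decile": d,
                "n": int(mask.sum()),
                "prevalence": y[mask].mean(),
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "odds_ratio": ors[d],
            }
        )
    return pd.DataFrame(rows)


def weighted_mean_r2(r2_values, sample_sizes) -> float:
    """Sample-size-weighted mean of R^2 values (same units as the input)."""
    r2 = np.asarray(r2_values, float)
    n = np.asarray(sample_sizes, float)
    if r2.size == 0 or r2.shape != n.shape:
        raise ValueError("need equal-length nonempty inputs")
    if (n <= 0).any():
        raise ValueError("sample sizes must be positive")
    return float((n * r2).sum() / n.sum())


def relative_accuracy(r2_target, r2_reference) -> float:
    """Relative accuracy in percent: 100 * R^2_target / R^2_reference."""
    if r2_reference <= 0:
        raise ValueError("reference accuracy must be positive")
    return 100.0 * r2_target / r2_reference


@dataclass
class ExpectedR2Curve:
    """Expected prediction accuracy as a function of GWAS sample size:
    E(R^2) = A / (B + 1/N), increasing in N with asymptote A/B."""

    A: float
    B: float
    rss: float = 0.0
    n_points: int = 0

    def predict(self, N):
        return self.A / (self.B + 1.0 / np.asarray(N, float))

    @property
    def asymptote(self):
        return self.A / self.B


def fit_expected_r2(points) -> ExpectedR2Curve:
    """Fit A and B of E(R^2) = A/(B + 1/N) to (N, R^2) points.

    Two points are solved exactly (the model is linear in 1/R^2 vs 1/N);
    more points go through grid-seeded Gauss-Newton least squares.
    """
    pts = [(float(n), float(r)) for n, r in points]
    if len({n for n, _ in pts}) < 2:
        raise ValueError("need at least 2 points with distinct N")
    N = np.array([p[0] for p in pts])
    R = np.array([p[1] for p in pts])
    # linearization 1/R = B/A + (1/A) * (1/N) seeds (and solves m=2 exactly)
    slope, icpt = np.polyfit(1.0 / N, 1.0 / R, 1)
    A0, B0 = 1.0 / slope, icpt / slope
    if len(pts) == 2:
        return ExpectedR2Curve(A=float(A0), B=float(B0), rss=0.0, n_points=2)

    def resid(theta):
        a, b = theta
        return R - a / (b + 1.0 / N)

    best = None
    for scale in (1.0, 0.5, 2.0, 5.0):
        try:
            sol = optimize.least_squares(
                resid, x0=[max(A0 * scale, 1e-12), max(B0 * scale, 1e-12)],
                bounds=([1e-15, 1e-15], [np.inf, np.inf]), max_nfev=200,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-6:
        raise RuntimeError("expected-R^2 curve fit did not converge")
    a, b = best.x
    return ExpectedR2Curve(A=float(a), B=float(b), rss=float(2 * best.cost), n_points=len(pts))


def gwas_power(N, r2, alpha) -> float:
    """Power of a 1-df association test for a SNP explaining ``r2`` of the
    phenotypic variance at sample size N and significance level alpha.

    The test statistic is noncentral chi-square with 1 df and noncentrality
    N * r2.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= r2 < 1):
        raise ValueError("r2 must be in [0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    crit = stats.chi2.isf(alpha, df=1)
    if r2 == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df=1, nc=N * r2))


def detectable_r2(N, power, alpha) -> float:
    """Smallest per-SNP R^2 detectable with the given power at level alpha
    (inverse of :func:`gwas_power` by root-finding)."""
    if not (alpha < power < 1):
        raise ValueError("power must lie in (alpha, 1)")
    f = lambda r2: gwas_power(N, r2, alpha) - power
    hi = 0.5
    while f(hi) < 0 and hi < 1 - 1e-9:
        hi = 0.5 * (1 + hi)
    return float(optimize.brentq(f, 1e-15, hi, xtol=1e-300, rtol=1e-12))
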