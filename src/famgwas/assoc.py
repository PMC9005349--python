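"""Per-SNP association testing under additive, dominance-deviation and
male-0/2 X-chromosome codings.

Covariates are projected out of the phenotype and of every coded genotype
column once (Frisch-Waugh-Lovell), after which each SNP test is a simple
univariate least-squares slope.  This gives the same estimates as refitting
the full model per SNP but scales linearly in the number of markers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.linalg import eigsh

from .coding import ADDITIVE, DOMINANCE, X_MALE02, CODINGS, dominance_code

__all__ = [
    "run_gwas",
    "compute_pcs",
    "sex_stratified_gwas",
    "CovariateSet",
    "write_sumstats",
    "read_sumstats",
    "SUMSTAT_COLUMNS",
]

SUMSTAT_COLUMNS = ["snp_id", "chr", "pos", "a1", "a2", "freq_a1", "n", "beta", "se", "z", "p", "coding"]

_TSV_NAMES = {
    "snp_id": "SNP", "chr": "CHR", "pos": "POS", "a1": "A1", "a2": "A2",
    "freq_a1": "FREQ_A1", "n": "N", "beta": "BETA", "se": "SE", "z": "Z",
    "p": "P", "coding": "CODING",
}


def build_covariates(sex=None, birth_year=None, pcs=None, include_interactions=True):
    """Assemble the standard covariate design: sex, birth-year dummies,
    sex x birth-year interactions and principal components.

    Returns an (n, q) array with collinear columns dropped; the caller adds
    no intercept (one is always included internally by the GWAS).
    """
    cols = []
    n = None
    if sex is not None:
        sex = np.asarray(sex, dtype=float)
        n = len(sex)
        cols.append(sex[:, None])
    if birth_year is not None:
        by = pd.get_dummies(pd.Series(birth_year), drop_first=True).to_numpy(dtype=float)
        n = len(by)
        cols.append(by)
        if include_interactions and sex is not None:
            cols.append(by * sex[:, None])
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        if pcs.ndim == 1:
            pcs = pcs[:, None]
        n = len(pcs)
        cols.append(pcs)
    if not cols:
        return np.empty((0, 0))
    X = np.hstack(cols)
    return drop_collinear(X)


def drop_collinear(X, tol=1e-10):
    """Drop columns until the design has full column rank (QR pivoting)."""
    if X.size == 0:
        return X
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    keep_rank = int((s > tol * max(s[0], 1.0)).sum()) if len(s) else 0
    if keep_rank == X.shape[1]:
        return X
    keep = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.hstack([basis, Xc[:, [j]]])
        if np.linalg.matrix_rank(cand, tol=tol * X.shape[0]) > basis.shape[1]:
            keep.append(j)
            basis = cand
    return X[:, keep]


class CovariateSet:
    """A full-rank covariate design matrix plus its projection machinery."""

    def __init__(self, X=None):
        self.X = None if X is None or np.size(X) == 0 else drop_collinear(np.asarray(X, float))

    def residualize(self, v):
        """Project the intercept and covariates out of v (vector or matrix)."""
        v = np.asarray(v, dtype=float)
        out = v - v.mean(axis=0)
        if self.X is None:
            return out
        Xc = self.X - self.X.mean(axis=0)
        coef, *_ = np.linalg.lstsq(Xc, out, rcond=None)
        return out - Xc @ coef

    @property
    def q(self) -> int:
        return 0 if self.X is None else self.X.shape[1]


def run_gwas(genotypes, y, covariates=None, coding=ADDITIVE, snp_info=None,
             sex=None, chunk=1024) -> pd.DataFrame:
    """Least-squares GWAS of a quantitative phenotype.

    Parameters
    ----------
    genotypes : (n, m) allele counts in {0, 1, 2}; for ``x_male02`` male rows
        must carry 0/2 values (``sex`` identifies males, 1 = male).
    y : (n,) phenotype, no missing values.
    covariates : CovariateSet, array or None.
    coding : one of ``additive_012``, ``dominance_dev``, ``x_male02``.
    snp_info : optional DataFrame with snp_id/chr/pos/a1/a2 to carry through.

    Returns a summary-statistics DataFrame (one row per SNP).  Monomorphic
    SNPs are flagged (``ok = False``) with NaN estimates.  ``p`` is the
    two-sided normal tail of ``z = beta / se``.
    """
    G = np.asarray(genotypes)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if len(y) != n:
        raise ValueError("genotypes and phenotype disagree on sample size")
    if np.isnan(y).any():
        raise ValueError("missing phenotype values are not allowed")
    if coding not in CODINGS:
        raise ValueError(f"unknown coding {coding!r}")
    if not isinstance(covariates, CovariateSet):
        covariates = CovariateSet(None if covariates is None else np.asarray(covariates))
    if n <= covariates.q + 2:
        raise ValueError("more parameters than observations")
    if coding == X_MALE02 and sex is not None:
        male = np.asarray(sex) == 1
        if not np.isin(G[male], (0, 2)).all():
            raise ValueError("x_male02 coding requires male genotypes in {0, 2}")

    freq = G.mean(axis=0) / 2.0
    mono = (G == G[0]).all(axis=0)

    ytil = covariates.residualize(y)
    dof = n - covariates.q - 2  # intercept + covariates + slope
    yss = float(ytil @ ytil)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        X = G[:, sl].astype(float)
        if coding == DOMINANCE:
            X = dominance_code(X, freq[sl])
        Xt = covariates.residualize(X)
        sxx = np.einsum("ij,ij->j", Xt, Xt)
        sxy = ytil @ Xt
        ok_chunk = sxx > 0
        b = np.where(ok_chunk, sxy / np.where(ok_chunk, sxx, 1.0), np.nan)
        rss = np.maximum(yss - b * sxy, 0.0)
        s = np.sqrt(rss / dof / np.where(ok_chunk, sxx, 1.0))
        beta[sl] = b
        se[sl] = np.where(ok_chunk, s, np.nan)

    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "snp_id": snp_info["snp_id"].to_numpy() if snp_info is not None else [f"rs{j+1}" for j in range(m)],
            "chr": snp_info["chr"].to_numpy() if snp_info is not None else 1,
            "pos": snp_info["pos"].to_numpy() if snp_info is not None else (np.arange(m) + 1) * 1000,
            "a1": snp_info["a1"].to_numpy() if snp_info is not None else "A",
            "a2": snp_info["a2"].to_numpy() if snp_info is not None else "G",
            "freq_a1": freq,
            "n": n,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "coding": coding,
            "ok": ~mono & np.isfinite(se),
        }
    )
    out.loc[~out["ok"], ["beta", "se", "z", "p"]] = np.nan
    return out


def compute_pcs(genotypes, k: int) -> np.ndarray:
    """Top-k principal components of the standardized genotype matrix.

    Eigenvectors (unit norm) of the individual-by-individual cross-product
    of column-standardized genotypes, ordered by decreasing eigenvalue.
    """
    if k == 0:
        return np.empty((len(genotypes), 0))
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if n < k + 1:
        raise ValueError("need at least k+1 individuals")
    sd = G.std(axis=0)
    poly = sd > 0
    Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
    K = Z @ Z.T
    if k > np.linalg.matrix_rank(K):
        raise ValueError("k exceeds the rank of the genotype matrix")
    if k >= n - 1:
        w, v = np.linalg.eigh(K)
        order = np.argsort(w)[::-1][:k]
        return v[:, order]
    w, v = eigsh(K, k=k, which="LA")
    order = np.argsort(w)[::-1]
    return v[:, order]


def sex_stratified_gwas(genotypes, y, sex, covariates=None, coding=ADDITIVE,
                        snp_info=None):
    """Independent per-sex GWAS (1 = male, 2 = female).

    Returns ``(stats_male, stats_female)``, suitable for inverse-variance
    combination and cross-trait genetic-correlation estimation.
    """
    sex = np.asarray(sex)
    results = []
    for code in (1, 2):
        mask = sex == code
        if mask.sum() == 0:
            raise ValueError(f"no individuals of sex {code}")
        cov = None
        if covariates is not None:
            X = covariates.X if isinstance(covariates, CovariateSet) else np.asarray(covariates)
            cov = None if X is None else X[mask]
            if cov is not None and mask.sum() <= cov.shape[1] + 2:
                raise ValueError("a sex stratum is smaller than the covariate count")
        results.append(
            run_gwas(
                np.asarray(genotypes)[mask],
                np.asarray(y, float)[mask],
                covariates=cov,
                coding=coding,
                snp_info=snp_info,
                sex=sex[mask],
            )
        )
    return tuple(results)


def write_sumstats(stats_df: pd.DataFrame, path):
    """Write summary statistics as the interchange TSV
    (SNP CHR POS A1 A2 FREQ_A1 N BETA SE Z P CODING)."""
    df = stats_df[SUMSTAT_COLUMNS].rename(columns=_TSV_NAMES)
    df.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    inv = {v: k for k, v in _TSV_NAMES.items()}
    df = df.rename(columns=inv)
    df["ok"] = df["se"].notna() & (df["se"] > 0)
    return df
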