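"""Genotype codings used throughout the package.

Additive coding is the usual 0/1/2 count of the effect allele.  Dominance
deviations are coded ``{0, 2p, 4p - 2}`` for genotypes ``{0, 1, 2}``, where
``p`` is the frequency of the counted allele.  Under Hardy-Weinberg
equilibrium this coding is orthogonal to the additive one: its covariance
with allele count is zero, so a regression on it isolates the within-locus
departure from additivity.  Its mean is ``2 p**2`` and its variance is
``(2 p q)**2`` with ``q = 1 - p``.
"""

from __future__ import annotations

import numpy as np

ADDITIVE = "additive_012"
DOMINANCE = "dominance_dev"
X_MALE02 = "x_male02"

CODINGS = (ADDITIVE, DOMINANCE, X_MALE02)


def dominance_code(genotypes: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Map 0/1/2 allele counts to the orthogonal dominance coding.

    Parameters
    ----------
    genotypes : array of shape (n,) or (n, m), values in {0, 1, 2}
    p : scalar or array of shape (m,), frequency of the counted allele
    """
    g = np.asarray(genotypes, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(g)
    het = g == 1
    hom = g == 2
    out[het] = np.broadcast_to(2.0 * p, g.shape)[het]
    out[hom] = np.broadcast_to(4.0 * p - 2.0, g.shape)[hom]
    return out


def dominance_mean_var(p):
    """Population mean and variance of the dominance coding under HWE."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 2.0 * p**2, (2.0 * p * q) ** 2


def standardize_additive(genotypes: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Center and scale allele counts to mean 0, variance 1 under HWE at p."""
    p = np.asarray(p, dtype=float)
    sd = np.sqrt(2.0 * p * (1.0 - p))
    return (np.asarray(genotypes, dtype=float) - 2.0 * p) / sd


def standardize_dominance(genotypes: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Dominance coding scaled to mean 0, variance 1 under HWE at p."""
    mean, var = dominance_mean_var(p)
    return (dominance_code(genotypes, p) - mean) / np.sqrt(var)
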