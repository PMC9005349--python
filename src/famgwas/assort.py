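"""Mate-pair PGI correlations and the phenotypic-assortment test.

Under purely phenotypic assortment -- mates match on the phenotype alone,
and the PGI relates linearly to the phenotype -- the mate-pair PGI
correlation equals the product r_y * r_p * r_m of the mate-pair phenotypic
correlation and the father's and mother's phenotype-PGI correlations, and
the correlation between the partners' own-phenotype-residualized PGIs is
zero.  Departures from these predictions indicate assortment on additional
PGI-correlated factors (ancestry, cognition, geography, ...).

All uncertainty here is percentile bootstrap over mate pairs with a
recorded seed, 1,000 repetitions by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import as_generator

__all__ = [
    "MatePairStats",
    "mate_pair_pgi_correlation",
    "predicted_under_phenotypic_assortment",
    "mate_pair_stats",
    "residualized_pgi_correlation",
    "percent_reduction",
]


@dataclass
class MatePairStats:
    r_pgi: float
    r_y: float
    r_p: float
    r_m: float
    predicted_pheno: float
    se_predicted: float
    ci_r_pgi: tuple
    n_pairs: int
    seed: int | None = None


def _corr(a, b):
    return float(np.corrcoef(a, b)[0, 1])


def _pair_bootstrap(n_pairs, n_boot, rng):
    return rng.integers(0, n_pairs, size=(n_boot, n_pairs))


def mate_pair_pgi_correlation(pairs: pd.DataFrame, n_boot=1000, seed=None):
    """Pearson correlation of mate-pair PGIs with a percentile bootstrap CI.

    ``pairs`` needs columns ``pgi_f`` and ``pgi_m`` (father/mother, i.e. the
    male and female partner).  Returns ``(r, (lo, hi))``.
    """
    if len(pairs) < 30:
        raise ValueError("need at least 30 mate pairs")
    pf = pairs["pgi_f"].to_numpy(dtype=float)
    pm = pairs["pgi_m"].to_numpy(dtype=float)
    if pf.std() == 0 or pm.std() == 0:
        raise ValueError("zero PGI variance in one partner")
    r = _corr(pf, pm)
    rng = as_generator(seed)
    idx = _pair_bootstrap(len(pf), n_boot, rng)
    reps = np.array([_corr(pf[i], pm[i]) for i in idx])
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return r, (float(lo), float(hi))


def predicted_under_phenotypic_assortment(r_y, r_p, r_m, pairs=None, n_boot=1000, seed=None):
    """Mate-pair PGI correlation predicted by phenotypic assortment:
    the product r_y * r_p * r_m.

    When ``pairs`` (with pgi_f, pgi_m, y_f, y_m) is supplied, the three
    correlations are re-estimated per joint pair-bootstrap replicate and the
    SE of the product is returned; otherwise the SE is NaN.
    """
    point = float(r_y * r_p * r_m)
    if pairs is None:
        return point, float("nan")
    rng = as_generator(seed)
    pf = pairs["pgi_f"].to_numpy(float)
    pm = pairs["pgi_m"].to_numpy(float)
    yf = pairs["y_f"].to_numpy(float)
    ym = pairs["y_m"].to_numpy(float)
    idx = _pair_bootstrap(len(pf), n_boot, rng)
    reps = np.array(
        [_corr(yf[i], ym[i]) * _corr(yf[i], pf[i]) * _corr(ym[i], pm[i]) for i in idx]
    )
    return point, float(reps.std(ddof=1))


def mate_pair_stats(pairs: pd.DataFrame, n_boot=1000, seed=None) -> MatePairStats:
    """All mate-pair correlations plus the phenotypic-assortment prediction."""
    r_pgi, ci = mate_pair_pgi_correlation(pairs, n_boot=n_boot, seed=seed)
    r_y = _corr(pairs["y_f"], pairs["y_m"])
    r_p = _corr(pairs["y_f"], pairs["pgi_f"])
    r_m = _corr(pairs["y_m"], pairs["pgi_m"])
    pred, se_pred = predicted_under_phenotypic_assortment(
        r_y, r_p, r_m, pairs=pairs, n_boot=n_boot, seed=seed
    )
    return MatePairStats(
        r_pgi=r_pgi, r_y=r_y, r_p=r_p, r_m=r_m,
        predicted_pheno=pred, se_predicted=se_pred, ci_r_pgi=ci,
        n_pairs=len(pairs),
        seed=seed if isinstance(seed, int) else None,
    )


def _residualize(v, X):
    X1 = np.column_stack([np.ones(len(v))] + [np.asarray(x, float) for x in X])
    resid = v - X1 @ np.linalg.lstsq(X1, v, rcond=None)[0]
    if resid.std() < 1e-10 * max(v.std(), 1e-300):
        raise ValueError("regressor collinear with the PGI: zero residual variance")
    return resid


def residualized_pgi_correlation(pairs: pd.DataFrame, regressor_sets,
                                 n_boot=1000, seed=None) -> pd.DataFrame:
    """Ladder of mate-pair PGI correlations after cumulative residualization.

    ``regressor_sets`` is an ordered list of lists of column stems; rung k
    residualizes each partner's PGI on that partner's own columns (stem +
    ``_f`` or ``_m``) from all sets up to and including k.  Rung 0 is always
    the raw correlation.  Returns one row per rung with a percentile
    bootstrap CI.
    """
    pf = pairs["pgi_f"].to_numpy(float)
    pm = pairs["pgi_m"].to_numpy(float)
    rng = as_generator(seed)
    idx = _pair_bootstrap(len(pf), n_boot, rng)

    rows = []
    cum: list = []
    for rung, names in enumerate([[]] + list(regressor_sets)):
        cum = cum + list(names)
        for stem in names:
            if pairs[f"{stem}_f"].equals(pairs["pgi_f"]) or pairs[f"{stem}_m"].equals(pairs["pgi_m"]):
                raise ValueError("cannot residualize the PGI on itself")
        if cum:
            Xf = [pairs[f"{s}_f"].to_numpy(float) for s in cum]
            Xm = [pairs[f"{s}_m"].to_numpy(float) for s in cum]
            rf = _residualize(pf, Xf)
            rm = _residualize(pm, Xm)
        else:
            rf, rm = pf, pm
        r = _corr(rf, rm)
        reps = np.array([_corr(rf[i], rm[i]) for i in idx])
        lo, hi = np.percentile(reps, [2.5, 97.5])
        rows.append(
            {
                "rung": rung,
                "regressors": "+".join(cum) if cum else "raw",
                "r": r,
                "ci_lo": float(lo),
                "ci_hi": float(hi),
                "se_boot": float(reps.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def percent_reduction(r_raw: float, r_resid: float, ndigits=None) -> float:
    """Percent fall of a correlation after residualization:
    100 * (1 - r_resid / r_raw)."""
    if r_raw == 0:
        raise ValueError("raw correlation is zero")
    out = 100.0 * (1.0 - r_resid / r_raw)
    return round(out, ndigits) if ndigits is not None else out
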