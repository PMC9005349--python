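"""Direct and population effects of a polygenic index from family designs.

The direct effect (delta) is the coefficient on an individual's PGI when
both parental PGIs are controlled (trio design) or, equivalently, the
coefficient on the deviation of the individual's PGI from the sibship mean
(sibling design).  The population effect (beta_pop) is the coefficient of a
plain regression of the phenotype on the PGI in unrelated individuals; it
additionally absorbs indirect parental effects, gene-environment
correlation and assortment-induced components.

Phenotypes and PGIs are expected standardized to variance one (see
``normalize_phenotype``), so effects are partial correlations and their
squares are shares of explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._seeds import as_generator

__all__ = [
    "EffectEstimate",
    "normalize_phenotype",
    "estimate_trio_effects",
    "estimate_sib_effects",
    "population_transform",
    "population_transform_sib",
    "attach_population_effect",
    "combine_designs",
    "ratio_and_share",
    "bootstrap_cross_design_cov",
]


@dataclass
class EffectEstimate:
    delta: float
    se_delta: float
    design: str
    alpha_f: float | None = None
    alpha_m: float | None = None
    between: float | None = None  # sibling-design between-family coefficient
    beta_pop: float | None = None
    se_beta_pop: float | None = None
    cov_delta_beta_pop: float | None = None
    vcov: np.ndarray | None = None  # over (delta, alpha_f, alpha_m) or (delta, between)
    n_families: int = 0

    @property
    def ratio(self):
        if self.beta_pop in (None, 0):
            return None
        return self.delta / self.beta_pop

    @property
    def share_pct(self):
        r = self.ratio
        return None if r is None else 100.0 * r**2


def normalize_phenotype(y, sex=None, covariates=None):
    """Residualize the phenotype on covariates and scale the residual to
    variance one within each sex (the two-step normalization used before
    family-based effect estimation)."""
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        X = sm.add_constant(np.asarray(covariates, float))
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    else:
        y = y - y.mean()
    if sex is None:
        return y / y.std()
    y = y.copy()
    for s in np.unique(sex):
        mask = np.asarray(sex) == s
        y[mask] = y[mask] / y[mask].std()
    return y


def _cluster_ols(y, X, groups):
    model = sm.OLS(y, sm.add_constant(X))
    res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(groups)})
    return res


def estimate_trio_effects(y, pgi_child, pgi_father, pgi_mother, family_id) -> EffectEstimate:
    """Regress phenotype on the child's, father's and mother's PGIs.

    The child-PGI coefficient is the direct effect; the parental
    coefficients absorb indirect effects and assortment.  Uncertainty is
    family-clustered.
    """
    y = np.asarray(y, float)
    pc, pf, pm = (np.asarray(v, float) for v in (pgi_child, pgi_father, pgi_mother))
    if pc.std() == 0 or pf.std() == 0 or pm.std() == 0:
        raise ValueError("zero PGI variance")
    if len(y) < 5:
        raise ValueError("fewer trios than parameters")
    X = np.column_stack([pc, pf, pm])
    res = _cluster_ols(y, X, family_id)
    params = res.params[1:]
    vcov = res.cov_params()[1:, 1:]
    return EffectEstimate(
        delta=float(params[0]),
        se_delta=float(np.sqrt(vcov[0, 0])),
        alpha_f=float(params[1]),
        alpha_m=float(params[2]),
        vcov=np.asarray(vcov),
        design="trio",
        n_families=len(np.unique(family_id)),
    )


def estimate_sib_effects(y, pgi, sibship_id) -> EffectEstimate:
    """Within/between sibship decomposition of the PGI effect.

    Regresses the phenotype on (i) the deviation of the individual's PGI
    from the sibship mean (coefficient = direct effect) and (ii) the sibship
    mean PGI (retained for the population-effect transform).  Requires at
    least two genotyped siblings per included family; singleton families are
    dropped.
    """
    df = pd.DataFrame({"y": np.asarray(y, float), "pgi": np.asarray(pgi, float),
                       "fam": np.asarray(sibship_id)})
    sizes = df.groupby("fam")["pgi"].transform("size")
    df = df[sizes >= 2]
    if df.empty:
        raise ValueError("no families with two or more siblings")
    mean = df.groupby("fam")["pgi"].transform("mean")
    dev = df["pgi"] - mean
    if dev.std() == 0:
        raise ValueError("no within-family PGI variance (identical twins only?)")
    X = np.column_stack([dev, mean])
    res = _cluster_ols(df["y"].to_numpy(), X, df["fam"].to_numpy())
    params = res.params[1:]
    vcov = res.cov_params()[1:, 1:]
    return EffectEstimate(
        delta=float(params[0]),
        se_delta=float(np.sqrt(vcov[0, 0])),
        between=float(params[1]),
        vcov=np.asarray(vcov),
        design="sib",
        n_families=df["fam"].nunique(),
    )


def population_transform(delta, alpha_f, alpha_m, r_mate_pgi) -> float:
    """Population effect implied by trio coefficients under equilibrium
    assortative mating with mate-pair PGI correlation r.

    At equilibrium cov(PGI_child, PGI_parent) = V (1 + r) / 2, so the
    marginal (population) slope is

        beta_pop = delta + (1 + r) / 2 * (alpha_f + alpha_m).
    """
    if not abs(r_mate_pgi) < 1:
        raise ValueError("|r_mate_pgi| must be < 1")
    return float(delta + (1.0 + r_mate_pgi) / 2.0 * (alpha_f + alpha_m))


def population_transform_sib(delta, between, r_mate_pgi) -> float:
    """Population effect from sib-pair coefficients.

    For sib pairs, cov(PGI_1, PGI_2) = V (1 + r) / 2 at equilibrium, so the
    between-family coefficient b satisfies
    b = delta + 4 (1 + r) / (3 + r) * eta-term, and the marginal slope is
    recovered as beta_pop = delta + (3 + r) / 4 * (b - delta).
    """
    if not abs(r_mate_pgi) < 1:
        raise ValueError("|r_mate_pgi| must be < 1")
    return float(delta + (3.0 + r_mate_pgi) / 4.0 * (between - delta))


def attach_population_effect(est: EffectEstimate, r_mate_pgi: float) -> EffectEstimate:
    """Fill beta_pop (and its variance and covariance with delta) on an
    estimate, propagating the linear transform through the coefficient
    covariance matrix."""
    if est.design == "trio":
        c = (1.0 + r_mate_pgi) / 2.0
        a = np.array([1.0, c, c])
        est.beta_pop = population_transform(est.delta, est.alpha_f, est.alpha_m, r_mate_pgi)
    elif est.design == "sib":
        k = (3.0 + r_mate_pgi) / 4.0
        a = np.array([1.0 - k, k])
        est.beta_pop = population_transform_sib(est.delta, est.between, r_mate_pgi)
    else:
        raise ValueError("population transform needs a sib or trio design")
    V = est.vcov
    est.se_beta_pop = float(np.sqrt(a @ V @ a))
    est.cov_delta_beta_pop = float(V[0] @ a)
    return est


def combine_designs(estimates, cross_cov: float | None = None) -> EffectEstimate:
    """Inverse-variance combination of direct-effect estimates.

    ``cross_cov`` is the covariance between the two delta estimates when the
    designs share a dataset (families contributing to both); obtain it from
    :func:`bootstrap_cross_design_cov`.  beta_pop (if present on every
    input) is combined the same way.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one estimate")
    if len(estimates) == 1:
        e = estimates[0]
        return e
    if len(estimates) > 2 and cross_cov is not None:
        raise ValueError("cross_cov is only supported for two estimates")

    def gls(vals, ses, cov):
        vals = np.asarray(vals, float)
        V = np.diag(np.asarray(ses, float) ** 2)
        if cov is not None:
            V[0, 1] = V[1, 0] = cov
        ones = np.ones(len(vals))
        Vi = np.linalg.inv(V)
        var = 1.0 / (ones @ Vi @ ones)
        est = var * (ones @ Vi @ vals)
        return float(est), float(np.sqrt(var))

    delta, se_delta = gls([e.delta for e in estimates], [e.se_delta for e in estimates], cross_cov)
    out = EffectEstimate(delta=delta, se_delta=se_delta, design="combined",
                         n_families=sum(e.n_families for e in estimates))
    if all(e.beta_pop is not None for e in estimates):
        out.beta_pop, out.se_beta_pop = gls(
            [e.beta_pop for e in estimates], [e.se_beta_pop for e in estimates], cross_cov
        )
        covs = [e.cov_delta_beta_pop for e in estimates]
        if all(c is not None for c in covs):
            w_d = np.array([1 / e.se_delta**2 for e in estimates])
            w_b = np.array([1 / e.se_beta_pop**2 for e in estimates])
            w_d, w_b = w_d / w_d.sum(), w_b / w_b.sum()
            out.cov_delta_beta_pop = float(np.sum(w_d * w_b * np.asarray(covs)))
    return out


def ratio_and_share(delta, beta_pop, vcov=None):
    """Ratio of direct to population effect, the direct share of the PGI's
    R^2 (100 * ratio^2), and a delta-method SE for the ratio.

    ``vcov`` is the 2x2 covariance matrix of (delta, beta_pop); omit it for
    a pure point calculation (SE returned as NaN).
    """
    if beta_pop == 0:
        raise ValueError("population effect is zero; ratio undefined")
    ratio = delta / beta_pop
    share = 100.0 * ratio**2
    if vcov is None:
        return ratio, share, float("nan")
    grad = np.array([1.0 / beta_pop, -delta / beta_pop**2])
    se = float(np.sqrt(grad @ np.asarray(vcov) @ grad))
    return ratio, share, se


def bootstrap_cross_design_cov(trio_data: pd.DataFrame, sib_data: pd.DataFrame,
                               n_boot=200, seed=None) -> float:
    """Covariance between trio and sibling delta estimates from a clustered
    bootstrap over families.

    Both frames need a ``family_id`` column; frames sharing family ids are
    resampled jointly.  ``trio_data`` needs y, pgi, pgi_father, pgi_mother;
    ``sib_data`` needs y, pgi.
    """
    rng = as_generator(seed)
    fams = np.union1d(trio_data["family_id"].unique(), sib_data["family_id"].unique())
    tg = dict(tuple(trio_data.groupby("family_id")))
    sg = dict(tuple(sib_data.groupby("family_id")))
    reps = []
    for _ in range(n_boot):
        pick = rng.choice(fams, size=len(fams), replace=True)
        tb = [tg[f] for f in pick if f in tg]
        sb = [sg[f] for f in pick if f in sg]
        if not tb or not sb:
            continue
        # relabel so resampled copies of a family stay distinct clusters
        tdf = pd.concat(tb, keys=range(len(tb))).reset_index(level=0, names="_rep")
        sdf = pd.concat(sb, keys=range(len(sb))).reset_index(level=0, names="_rep")
        try:
            et = estimate_trio_effects(
                tdf["y"], tdf["pgi"], tdf["pgi_father"], tdf["pgi_mother"],
                tdf["_rep"].astype(str) + ":" + tdf["family_id"].astype(str),
            )
            es = estimate_sib_effects(
                sdf["y"], sdf["pgi"], sdf["_rep"].astype(str) + ":" + sdf["family_id"].astype(str)
            )
        except ValueError:
            continue
        reps.append((et.delta, es.delta))
    reps = np.asarray(reps)
    if len(reps) < 10:
        raise ValueError("too few successful bootstrap replicates")
    return float(np.cov(reps[:, 0], reps[:, 1])[0, 1])
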