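"""End-to-end pipeline: simulate a cohort, run the association stages and
produce a report bundle with a reproducibility manifest.

The pipeline is driven by a plain dict (usually loaded from YAML).  All
randomness flows from one root seed through named substreams, so rerunning
the same configuration reproduces identical artifacts and manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import substream
from .assoc import CovariateSet, compute_pcs, run_gwas, write_sumstats
from .assort import mate_pair_stats, percent_reduction, residualized_pgi_correlation
from .coding import ADDITIVE, DOMINANCE
from .family import (attach_population_effect, combine_designs,
                     estimate_sib_effects, estimate_trio_effects, ratio_and_share)
from .ldsc import confounding_share, ld_scores_from_blocks, ldsc_fit
from .meta import LdLookup, QcThresholds, clump, harmonize, mean_chisq, meta_sample_size
from .pgi import build_ct_weights, incremental_r2, nagelkerke_incremental, score
from .shrink import estimate_id_individual, estimate_id_sumstats, fit_eb_prior, winners_curse_adjust
from .sim import SimConfig, simulate_cohort, write_cohort

STAGES = ["simulate", "gwas", "meta", "clump", "ldsc", "pgi", "family", "assort",
          "shrinkage", "report"]

REQUIRES = {
    "gwas": ["simulate"],
    "meta": ["gwas"],
    "clump": ["meta"],
    "ldsc": ["gwas"],
    "pgi": ["meta"],
    "family": ["pgi"],
    "assort": ["pgi"],
    "shrinkage": ["meta"],
    "report": ["simulate"],
}


class PipelineError(RuntimeError):
    pass


def validate_config(config: dict) -> list:
    """Check the stage list and dependencies; returns the execution order."""
    stages = config.get("stages", STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    chosen = set(stages)
    for s in stages:
        missing = [d for d in REQUIRES.get(s, []) if d not in chosen]
        if missing:
            raise PipelineError(f"stage '{s}' requires missing block(s): {missing}")
    if "seed" not in config:
        raise PipelineError("config is missing the required block: seed")
    return [s for s in STAGES if s in chosen]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``): package
    version, seed, per-stage parameters and SHA-256 hashes of every emitted
    artifact.
    """
    order = validate_config(config)
    seed = int(config["seed"])
    out = Path(out_dir or config.get("out_dir", "famgwas_run"))
    out.mkdir(parents=True, exist_ok=True)

    ctx: dict = {}
    artifacts: dict = {}
    report: dict = {"panels": {}}

    for stage in order:
        params = config.get(stage, {}) or {}
        try:
            _run_stage(stage, params, seed, ctx, out, artifacts, report)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage '{stage}' failed: {err}") from err

    manifest = {
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "stages": {s: config.get(s, {}) for s in order},
        "artifacts": {name: _sha256(path) for name, path in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _standardize(v):
    v = np.asarray(v, float)
    return (v - v.mean()) / v.std()


def _run_stage(stage, params, seed, ctx, out, artifacts, report):
    if stage == "simulate":
        cfg = SimConfig(seed=seed, **params)
        cohort, arch = simulate_cohort(cfg)
        cohort_dir = out / "cohort"
        write_cohort(cohort, cohort_dir, arch)
        for f in sorted(cohort_dir.iterdir()):
            artifacts[f"cohort/{f.name}"] = f
        ctx["cohort"], ctx["arch"], ctx["simcfg"] = cohort, arch, cfg
        fin = cohort.final_generation()
        rng = substream(seed, "pipeline-split")
        holdout_frac = params.get("holdout_fraction", 0.3) if isinstance(params, dict) else 0.3
        # holdout split by family so training and validation stay disjoint
        fams = fin["fid"].unique()
        hold_f = set(rng.permutation(fams)[: int(round(holdout_frac * len(fams)))])
        ctx["holdout"] = fin[fin["fid"].isin(hold_f)]
        ctx["train"] = fin[~fin["fid"].isin(hold_f)]
        report["panels"]["simulate"] = {
            "n_individuals": int(cohort.n),
            "n_snps": int(cohort.n_snps),
            "n_generations": int(cohort.individuals["generation"].max()),
            "n_mate_pairs_final": int(len(cohort.mate_pairs_final())),
        }

    elif stage == "gwas":
        cohort = ctx["cohort"]
        train = ctx["train"]
        idx = cohort.index_of(train["id"])
        G = cohort.genotypes[idx]
        y = train["y"].to_numpy()
        n_pcs = params.get("n_pcs", 0)
        cov = CovariateSet(compute_pcs(G, n_pcs)) if n_pcs else CovariateSet(None)
        add = run_gwas(G, y, covariates=cov, coding=ADDITIVE, snp_info=cohort.snp_info)
        dom = run_gwas(G, y, covariates=cov, coding=DOMINANCE, snp_info=cohort.snp_info)
        write_sumstats(add, out / "gwas_additive.tsv")
        write_sumstats(dom, out / "gwas_dominance.tsv")
        artifacts["gwas_additive.tsv"] = out / "gwas_additive.tsv"
        artifacts["gwas_dominance.tsv"] = out / "gwas_dominance.tsv"
        ctx["gwas_add"], ctx["gwas_dom"] = add, dom
        ctx["train_geno"], ctx["train_y"] = G, y
        report["panels"]["gwas"] = {
            "n": int(len(y)),
            "mean_chisq_additive": float(np.nanmean(add["z"] ** 2)),
            "mean_chisq_dominance": float(np.nanmean(dom["z"] ** 2)),
        }

    elif stage == "meta":
        cohort = ctx["cohort"]
        G, y = ctx["train_geno"], ctx["train_y"]
        half = len(y) // 2
        sets = [
            run_gwas(G[:half], y[:half], coding=ADDITIVE, snp_info=cohort.snp_info),
            run_gwas(G[half:], y[half:], coding=ADDITIVE, snp_info=cohort.snp_info),
        ]
        ref = cohort.snp_info[["snp_id", "a1", "a2"]]
        sets = harmonize(sets, ref)
        meta = meta_sample_size(sets)
        write_sumstats(meta, out / "meta_additive.tsv")
        artifacts["meta_additive.tsv"] = out / "meta_additive.tsv"
        ctx["meta"] = meta
        report["panels"]["meta"] = {
            "n_snps": int(len(meta)),
            "mean_chisq": float(mean_chisq(meta, QcThresholds())),
        }

    elif stage == "clump":
        cohort = ctx["cohort"]
        lookup = LdLookup.from_blocks(
            cohort.snp_info["snp_id"], cohort.snp_info["block"], ctx["simcfg"].within_block_r**2
        )
        leads = clump(ctx["meta"], lookup, params.get("p_threshold", 5e-8),
                      params.get("r2_threshold", 0.1))
        leads.to_csv(out / "lead_snps.tsv", sep="\t", index=False)
        artifacts["lead_snps.tsv"] = out / "lead_snps.tsv"
        ctx["leads"], ctx["ld_lookup"] = leads, lookup
        report["panels"]["clump"] = {"n_loci": int(len(leads))}

    elif stage == "ldsc":
        cohort = ctx["cohort"]
        scores = ld_scores_from_blocks(
            cohort.snp_info["block"], ctx["simcfg"].within_block_r**2,
            snp_ids=cohort.snp_info["snp_id"],
        )
        add, dom = ctx["gwas_add"], ctx["gwas_dom"]
        fits = {}
        for mode, stats_df in (("additive", add), ("dominance", dom)):
            ok = stats_df["z"].notna().to_numpy()
            fit = ldsc_fit(stats_df.loc[ok, "z"] ** 2, scores[ok],
                           N=stats_df.loc[ok, "n"].to_numpy(), mode=mode)
            fits[mode] = {
                "h2": fit.h2, "se_h2": fit.se_h2, "intercept": fit.intercept,
                "se_intercept": fit.se_intercept, "mean_chisq": fit.mean_chisq,
            }
            if fit.mean_chisq > 1:
                fits[mode]["confounding_share"] = confounding_share(fit.intercept, fit.mean_chisq)
        (out / "ldsc.json").write_text(json.dumps(fits, indent=2))
        artifacts["ldsc.json"] = out / "ldsc.json"
        ctx["ldsc"] = fits
        report["panels"]["ldsc"] = fits

    elif stage == "pgi":
        cohort = ctx["cohort"]
        lookup = ctx.get("ld_lookup") or LdLookup.from_blocks(
            cohort.snp_info["snp_id"], cohort.snp_info["block"], ctx["simcfg"].within_block_r**2
        )
        thresholds = params.get("thresholds", [5e-8, 5e-5, 5e-3, 1.0])
        hold = ctx["holdout"]
        hidx = cohort.index_of(hold["id"])
        Gh = cohort.genotypes[hidx]
        yh = hold["y"].to_numpy()
        panel = {}
        weight_frames = []
        pgis = {}
        for thr in thresholds:
            w = build_ct_weights(ctx["meta"], lookup, thr)
            weight_frames.append(w)
            if w.empty:
                panel[f"ct_{thr:g}"] = {"n_snps": 0, "incremental_r2": None}
                continue
            s = score(Gh, w, cohort.snp_info)
            r2, ci = incremental_r2(yh, s, n_boot=params.get("n_boot", 200),
                                    seed=substream(ctx["simcfg"].seed, f"pgi-boot-{thr:g}"))
            panel[f"ct_{thr:g}"] = {
                "n_snps": int(len(w)), "incremental_r2": r2,
                "ci": [ci[0], ci[1]],
            }
            pgis[thr] = s
        pd.concat(weight_frames, ignore_index=True).to_csv(
            out / "pgi_weights.tsv", sep="\t", index=False
        )
        artifacts["pgi_weights.tsv"] = out / "pgi_weights.tsv"
        # binary outcome: top-tercile phenotype, probing discrimination
        if 1.0 in [float(t) for t in thresholds] and pgis:
            thr = [t for t in thresholds if float(t) == 1.0][0]
            yb = (yh > np.quantile(yh, 0.7)).astype(float)
            panel["nagelkerke_ct_1"] = nagelkerke_incremental(yb, pgis[thr])
        ctx["pgi_panel"] = panel
        ctx["pgi_lookup"] = lookup
        # full-cohort PGI at the loosest threshold for family/assort stages
        loosest = max(float(t) for t in thresholds)
        w = build_ct_weights(ctx["meta"], lookup, loosest)
        ctx["pgi_all"] = pd.Series(
            score(cohort.genotypes, w, cohort.snp_info), index=cohort.individuals["id"].to_numpy()
        )
        report["panels"]["pgi"] = panel

    elif stage == "family":
        cohort = ctx["cohort"]
        pgi = ctx["pgi_all"]
        pgi = (pgi - pgi.mean()) / pgi.std()
        trios = cohort.trios()
        y = _standardize(trios["y"].to_numpy())
        est_t = estimate_trio_effects(
            y,
            pgi.loc[trios["id"]].to_numpy(),
            pgi.loc[trios["father_id"]].to_numpy(),
            pgi.loc[trios["mother_id"]].to_numpy(),
            trios["fid"].to_numpy(),
        )
        sibs = cohort.sib_pairs()
        est_s = estimate_sib_effects(
            _standardize(sibs["y"].to_numpy()), pgi.loc[sibs["id"]].to_numpy(), sibs["fid"].to_numpy()
        )
        mates = cohort.mate_pairs_final()
        r_mate = float(np.corrcoef(
            pgi.loc[mates["father_id"]].to_numpy(), pgi.loc[mates["mother_id"]].to_numpy()
        )[0, 1])
        attach_population_effect(est_t, r_mate)
        attach_population_effect(est_s, r_mate)
        comb = combine_designs([est_t, est_s])
        vc = np.array([[comb.se_delta**2, comb.cov_delta_beta_pop or 0.0],
                       [comb.cov_delta_beta_pop or 0.0, comb.se_beta_pop**2]])
        ratio, share, se_ratio = ratio_and_share(comb.delta, comb.beta_pop, vc)
        fam = {
            "trio": {"delta": est_t.delta, "se": est_t.se_delta,
                     "alpha_f": est_t.alpha_f, "alpha_m": est_t.alpha_m,
                     "beta_pop": est_t.beta_pop},
            "sib": {"delta": est_s.delta, "se": est_s.se_delta, "beta_pop": est_s.beta_pop},
            "combined": {"delta": comb.delta, "se": comb.se_delta,
                         "beta_pop": comb.beta_pop, "ratio": ratio,
                         "share_pct": share, "se_ratio": se_ratio},
            "r_mate_pgi": r_mate,
        }
        (out / "family.json").write_text(json.dumps(fam, indent=2))
        artifacts["family.json"] = out / "family.json"
        report["panels"]["family"] = fam

    elif stage == "assort":
        cohort = ctx["cohort"]
        pgi = ctx["pgi_all"]
        ind = cohort.individuals.set_index("id")
        mates = cohort.mate_pairs_final()
        pairs = pd.DataFrame(
            {
                "pgi_f": pgi.loc[mates["father_id"]].to_numpy(),
                "pgi_m": pgi.loc[mates["mother_id"]].to_numpy(),
                "y_f": ind.loc[mates["father_id"], "y"].to_numpy(),
                "y_m": ind.loc[mates["mother_id"], "y"].to_numpy(),
            }
        )
        n_boot = params.get("n_boot", 1000)
        mseed = int(substream(ctx["simcfg"].seed, "assort-boot").integers(0, 2**31 - 1))
        st = mate_pair_stats(pairs, n_boot=n_boot, seed=mseed)
        ladder = residualized_pgi_correlation(pairs, [["y"]], n_boot=n_boot, seed=mseed)
        panel = {
            "r_pgi": st.r_pgi, "ci_r_pgi": list(st.ci_r_pgi),
            "r_y": st.r_y, "r_p": st.r_p, "r_m": st.r_m,
            "predicted_phenotypic": st.predicted_pheno, "se_predicted": st.se_predicted,
            "n_pairs": st.n_pairs,
            "ladder": ladder.to_dict(orient="records"),
        }
        r1 = ladder.loc[ladder["rung"] == 1, "r"]
        if len(r1) and st.r_pgi != 0:
            panel["pct_reduction_after_pheno"] = percent_reduction(st.r_pgi, float(r1.iloc[0]))
        (out / "assort.json").write_text(json.dumps(panel, indent=2))
        artifacts["assort.json"] = out / "assort.json"
        report["panels"]["assort"] = panel

    elif stage == "shrinkage":
        meta = ctx["meta"]
        panel = {}
        if len(meta) >= 1000:
            prior = fit_eb_prior(meta)
            panel["tau2"] = prior.tau2
            leads = ctx.get("leads")
            if leads is not None and len(leads):
                adj = winners_curse_adjust(leads["beta"].to_numpy(), leads["se"].to_numpy(), prior)
                adj_df = pd.DataFrame(
                    {"SNP": leads["snp_id"], "BETA_RAW": leads["beta"],
                     "BETA_ADJ": adj, "P": leads["p"]}
                )
                adj_df.to_csv(out / "adjusted_effects.tsv", sep="\t", index=False)
                artifacts["adjusted_effects.tsv"] = out / "adjusted_effects.tsv"
                panel["mean_abs_shrinkage"] = float(np.mean(np.abs(leads["beta"]) - np.abs(adj)))
        else:
            panel["tau2"] = None
        cohort = ctx["cohort"]
        if cohort.individuals["F"].std() > 0:
            idest = estimate_id_individual(cohort.individuals["y"], cohort.individuals["F"])
            panel["id_individual_b"] = idest.b
            panel["id_individual_se"] = idest.se
            dom = ctx.get("gwas_dom")
            if dom is not None:
                ss = estimate_id_sumstats(dom[dom["ok"]])
                panel["id_sumstats_b"] = ss.b
                panel["id_sumstats_se"] = ss.se
        (out / "shrinkage.json").write_text(json.dumps(panel, indent=2))
        artifacts["shrinkage.json"] = out / "shrinkage.json"
        report["panels"]["shrinkage"] = panel

    elif stage == "report":
        rendered = render_report(report["panels"])
        (out / "report.json").write_text(json.dumps(rendered, indent=2))
        (out / "report.txt").write_text(rendered["summary_text"])
        artifacts["report.json"] = out / "report.json"
        artifacts["report.txt"] = out / "report.txt"


def render_report(panels: dict) -> dict:
    """Assemble the JSON + human-readable summary from stage artifacts."""
    if not panels:
        raise PipelineError("no artifacts to report")
    lines = ["famgwas run summary", "===================", ""]
    summary = {"panels": panels}
    table1 = {}
    if "gwas" in panels:
        table1["N"] = panels["gwas"]["n"]
        table1["mean_chisq_additive"] = round(panels["gwas"]["mean_chisq_additive"], 3)
        table1["mean_chisq_dominance"] = round(panels["gwas"]["mean_chisq_dominance"], 3)
    if "meta" in panels:
        table1["n_snps"] = panels["meta"]["n_snps"]
    table1["n_loci"] = panels.get("clump", {}).get("n_loci", 0)
    if "pgi" in panels:
        for k, v in panels["pgi"].items():
            if isinstance(v, dict) and v.get("incremental_r2") is not None:
                table1[f"incremental_r2_{k}"] = round(v["incremental_r2"], 4)
    summary["table1"] = table1
    for name, value in table1.items():
        lines.append(f"{name}: {value}")
    for panel in ("family", "assort", "ldsc", "shrinkage", "simulate"):
        if panel in panels:
            lines.append("")
            lines.append(f"[{panel}]")
            lines.append(json.dumps(panels[panel], indent=2, default=str))
    summary["summary_text"] = "\n".join(lines) + "\n"
    return summary
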