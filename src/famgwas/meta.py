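"""Summary-statistics harmonization, meta-analysis, SE inflation by the
LD-score intercept, iterative LD clumping and mean-chi-square reporting.

Sample-size weights follow the METAL convention (sqrt(N) weights on z);
per-study N is taken from the input column.  A SNP missing from some
studies is meta-analyzed over the studies that carry it, with the combined
N recording the realized total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "QcThresholds",
    "LdLookup",
    "harmonize",
    "meta_sample_size",
    "meta_inverse_variance",
    "inflate_se",
    "clump",
    "mean_chisq",
]


@dataclass
class QcThresholds:
    maf_min: float = 0.01
    n_min_fraction: float = 0.9
    drop_ambiguous_palindromic_above_freq: float = 0.4

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 < self.n_min_fraction <= 1):
            raise ValueError("n_min_fraction must be in (0, 1]")
        if not (0 <= self.drop_ambiguous_palindromic_above_freq <= 0.5):
            raise ValueError("palindromic frequency threshold must be in [0, 0.5]")


class LdLookup:
    """Pairwise r-squared lookup.  Absent pairs are treated as r^2 = 0."""

    def __init__(self, table=None):
        self._r2 = {}
        self._warned = False
        if table is not None:
            if isinstance(table, pd.DataFrame):
                for a, b, r2 in table.itertuples(index=False):
                    self.add(a, b, r2)
            else:
                for (a, b), r2 in dict(table).items():
                    self.add(a, b, r2)

    @classmethod
    def from_genotypes(cls, genotypes, snp_ids, min_r2=0.0):
        """Empirical r^2 between all SNP pairs of a panel."""
        G = np.asarray(genotypes, dtype=float)
        sd = G.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(G, rowvar=False)
        R = np.nan_to_num(R)
        out = cls()
        ids = list(snp_ids)
        m = len(ids)
        r2 = R**2
        for i in range(m):
            row = r2[i]
            js = np.flatnonzero(row[i + 1:] > min_r2) + i + 1
            for j in js:
                out.add(ids[i], ids[j], float(row[j]))
        return out

    @classmethod
    def from_blocks(cls, snp_ids, block_of_snp, r2_within):
        """Analytic block lookup: r^2 = ``r2_within`` inside a block, 0 across."""
        out = cls()
        ids = np.asarray(list(snp_ids))
        blocks = np.asarray(block_of_snp)
        for b in np.unique(blocks):
            members = ids[blocks == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    out.add(members[i], members[j], r2_within)
        return out

    def add(self, a, b, r2):
        self._r2[(a, b) if a <= b else (b, a)] = float(r2)

    def r2(self, a, b):
        if a == b:
            return 1.0
        val = self._r2.get((a, b) if a <= b else (b, a))
        if val is None:
            if not self._warned:
                log.debug("LD pair (%s, %s) absent from lookup; treated as r2=0", a, b)
                self._warned = True
            return 0.0
        return val

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in self._r2.items()]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def _flip(df, mask):
    df.loc[mask, "beta"] = -df.loc[mask, "beta"]
    df.loc[mask, "z"] = -df.loc[mask, "z"]
    df.loc[mask, "freq_a1"] = 1.0 - df.loc[mask, "freq_a1"]
    a1 = df.loc[mask, "a1"].copy()
    df.loc[mask, "a1"] = df.loc[mask, "a2"]
    df.loc[mask, "a2"] = a1


def harmonize(statsets, reference_alleles: pd.DataFrame,
              thresholds: QcThresholds | None = None):
    """Align each summary-statistics set to a reference allele table.

    Effect alleles are aligned to the reference A1 (beta and z negated and
    frequency complemented on a swap); strand flips are resolved through the
    base-complement map; ambiguous palindromic SNPs (A/T, G/C) with minor
    allele frequency above the threshold are dropped; allele mismatches are
    dropped with a log entry.  Harmonization is idempotent.
    """
    thresholds = thresholds or QcThresholds()
    ref = reference_alleles.set_index("snp_id")[["a1", "a2"]]
    out = []
    for si, df in enumerate(statsets):
        if df["snp_id"].duplicated().any():
            raise ValueError(f"duplicate snp_id in statset {si}")
        df = df.copy()
        shared = df["snp_id"].isin(ref.index)
        dropped_missing = int((~shared).sum())
        if dropped_missing:
            log.info("statset %d: %d SNPs absent from the reference, dropped", si, dropped_missing)
        df = df[shared].reset_index(drop=True)
        r1 = ref.loc[df["snp_id"], "a1"].to_numpy()
        r2 = ref.loc[df["snp_id"], "a2"].to_numpy()
        a1 = df["a1"].to_numpy()
        a2 = df["a2"].to_numpy()
        c1 = np.array([COMPLEMENT.get(a, "?") for a in a1])
        c2 = np.array([COMPLEMENT.get(a, "?") for a in a2])

        same = (a1 == r1) & (a2 == r2)
        swap = (a1 == r2) & (a2 == r1)
        strand = (c1 == r1) & (c2 == r2) & ~same & ~swap
        strand_swap = (c1 == r2) & (c2 == r1) & ~same & ~swap

        # strand-flipped records are re-expressed on the reference strand
        df.loc[strand, "a1"] = [COMPLEMENT[a] for a in a1[strand]]
        df.loc[strand, "a2"] = [COMPLEMENT[a] for a in a2[strand]]
        df.loc[strand_swap, "a1"] = [COMPLEMENT[a] for a in a1[strand_swap]]
        df.loc[strand_swap, "a2"] = [COMPLEMENT[a] for a in a2[strand_swap]]
        _flip(df, swap | strand_swap)

        keep = same | swap | strand | strand_swap
        n_mismatch = int((~keep).sum())
        if n_mismatch:
            log.info("statset %d: %d allele mismatches dropped", si, n_mismatch)

        palindromic = df["a1"].map(COMPLEMENT.get).to_numpy() == df["a2"].to_numpy()
        maf = np.minimum(df["freq_a1"], 1 - df["freq_a1"])
        ambiguous = palindromic & (maf > thresholds.drop_ambiguous_palindromic_above_freq)
        if ambiguous.any():
            log.info("statset %d: %d ambiguous palindromic SNPs dropped", si, int(ambiguous.sum()))
        out.append(df[keep & ~ambiguous].reset_index(drop=True))
    return out


def meta_sample_size(statsets) -> pd.DataFrame:
    """Sample-size-weighted z-score meta-analysis.

    z_meta = sum(sqrt(N_i) z_i) / sqrt(sum N_i); N_meta = sum N_i; p is the
    two-sided normal tail.  beta/se columns are combined by inverse variance
    so that downstream weight construction has effect sizes to work with.
    """
    frames = []
    for i, df in enumerate(statsets):
        d = df[df["se"].notna()].copy()
        d["_study"] = i
        frames.append(d)
    if not any(len(f) for f in frames):
        raise ValueError("no records to meta-analyze")
    allstats = pd.concat(frames, ignore_index=True)

    def combine(grp):
        ntot = grp["n"].sum()
        z = (np.sqrt(grp["n"]) * grp["z"]).sum() / np.sqrt(ntot)
        w = 1.0 / grp["se"] ** 2
        beta = (w * grp["beta"]).sum() / w.sum()
        se = np.sqrt(1.0 / w.sum())
        first = grp.iloc[0]
        return pd.Series(
            {
                "chr": first["chr"], "pos": first["pos"], "a1": first["a1"],
                "a2": first["a2"],
                "freq_a1": (grp["n"] * grp["freq_a1"]).sum() / ntot,
                "n": ntot, "beta": beta, "se": se, "z": z,
                "p": 2.0 * stats.norm.sf(abs(z)),
                "coding": first["coding"],
            }
        )

    out = allstats.groupby("snp_id", sort=False).apply(combine, include_groups=False).reset_index()
    out["ok"] = True
    return out


def meta_inverse_variance(statsets) -> pd.DataFrame:
    """Inverse-variance-weighted meta-analysis on the beta scale."""
    allstats = pd.concat([df[df["se"].notna()] for df in statsets], ignore_index=True)

    def combine(grp):
        w = 1.0 / grp["se"] ** 2
        beta = (w * grp["beta"]).sum() / w.sum()
        se = np.sqrt(1.0 / w.sum())
        z = beta / se
        first = grp.iloc[0]
        return pd.Series(
            {
                "chr": first["chr"], "pos": first["pos"], "a1": first["a1"],
                "a2": first["a2"],
                "freq_a1": (grp["n"] * grp["freq_a1"]).sum() / grp["n"].sum(),
                "n": grp["n"].sum(), "beta": beta, "se": se, "z": z,
                "p": 2.0 * stats.norm.sf(abs(z)),
                "coding": first["coding"],
            }
        )

    out = allstats.groupby("snp_id", sort=False).apply(combine, include_groups=False).reset_index()
    out["ok"] = True
    return out


def inflate_se(stats_df: pd.DataFrame, intercept: float) -> pd.DataFrame:
    """Inflate standard errors by sqrt(intercept) and rescale z and p.

    The LD-score intercept measures chi-square inflation not attributable to
    polygenic signal; dividing z by sqrt(intercept) divides the mean
    chi-square by the intercept exactly.  Intercepts below 1 are allowed but
    not applied (no deflation) unless ``intercept > 0`` and explicitly < 1,
    in which case a warning is emitted and statistics are left untouched.
    """
    if intercept <= 0:
        raise ValueError("intercept must be positive")
    out = stats_df.copy()
    if intercept == 1:
        return out
    if intercept < 1:
        warnings.warn("intercept < 1: standard errors left unchanged (no deflation)")
        return out
    root = np.sqrt(intercept)
    out["se"] = out["se"] * root
    out["z"] = out["z"] / root
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    return out


def clump(stats_df: pd.DataFrame, ld_lookup: LdLookup, p_threshold: float,
          r2_threshold: float = 0.1) -> pd.DataFrame:
    """Greedy iterative clumping with an r^2 exclusion rule.

    Repeatedly take the smallest-p SNP below ``p_threshold``, drop every
    remaining candidate with r^2 above ``r2_threshold`` to it, and iterate.
    Output rows are in selection order; p ties break by (chr, pos, snp_id).
    No physical-distance cutoff is applied.
    """
    cand = stats_df[stats_df["p"] < p_threshold].copy()
    cand = cand.sort_values(["p", "chr", "pos", "snp_id"], kind="stable").reset_index(drop=True)
    leads = []
    alive = np.ones(len(cand), dtype=bool)
    ids = cand["snp_id"].to_numpy()
    for i in range(len(cand)):
        if not alive[i]:
            continue
        leads.append(i)
        for j in range(i + 1, len(cand)):
            if alive[j] and ld_lookup.r2(ids[i], ids[j]) > r2_threshold:
                alive[j] = False
    return cand.iloc[leads].reset_index(drop=True)


def mean_chisq(stats_df: pd.DataFrame, thresholds: QcThresholds | None = None) -> float:
    """Mean z^2 over SNPs with MAF above ``maf_min`` and N above
    ``n_min_fraction`` of the maximum N."""
    thresholds = thresholds or QcThresholds()
    df = stats_df[stats_df["se"].notna()]
    maf = np.minimum(df["freq_a1"], 1 - df["freq_a1"])
    nmax = df["n"].max()
    keep = (maf > thresholds.maf_min) & (df["n"] > thresholds.n_min_fraction * nmax)
    if not keep.any():
        raise ValueError("all SNPs removed by the mean-chisq filters")
    return float((df.loc[keep, "z"] ** 2).mean())
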