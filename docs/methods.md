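# Methods

This note documents the models behind `famgwas`, the defaults and why they
were chosen, the numerical choices, and what passing the test suite does
and does not establish about real data.

## The synthetic cohort generator

### Genotypes and LD

Haplotypes are simulated by thresholding equicorrelated Gaussians per LD
block: within a block of size b, each haplotype's latent vector has
pairwise correlation ρ, and allele j is carried when the latent exceeds
Φ⁻¹(1 − p). The latent ρ is calibrated per block by root-finding
(Brent, tolerance 1e-6) so that the *allele* correlation equals the
configured `within_block_r`; because the thresholded correlation depends on
the allele frequency, all SNPs in a block share one frequency when LD is
on. Genotypes are sums of two independent haplotypes, so Hardy–Weinberg
proportions hold exactly and the genotype correlation equals the haplotype
allele correlation. The analytic consequences used downstream: a SNP in a
block of size b has additive LD score 1 + (b−1)r² and dominance LD score
1 + (b−1)r⁴.

Block sizes are deliberately unequal (a deterministic 1:2:3:4:5 cycle).
Equal blocks would make every LD score identical and leave the LD-score
regression unidentified; the spread is what lets the intercept and slope
separate.

Blocks are transmitted as units — a child inherits one of each parent's
two block haplotypes per block, independently across blocks (no
recombination within a block, free recombination between blocks). This
preserves within-block LD across generations and makes Mendelian
consistency hold by construction. Real chromosomes recombine within
haplotype blocks and LD decays with distance; none of that is modeled, and
results that depend on fine-scale LD decay (e.g. distance-based clumping
windows) are out of scope.

### Trait architecture

Per-SNP additive effects β and dominance deviations δ are drawn i.i.d.
standard normal (|N(0,1)| for δ under `directional_dominance`) and then
rescaled so that the realized variance of the additive and dominance
genetic values in the founder sample equals `h2_add` and `h2_dom` exactly.
Genetic values use codings standardized at founder frequencies; the
environmental variance is 1 − h2_add − h2_dom, so the founder phenotypic
variance is 1 and later generations drift upward under assortment, as they
should. Dominance deviations use the coding {0, 2p, 4p−2}, which is
orthogonal to allele count under HWE; its mean is 2p² and its variance
(2pq)².

Indirect parental effects enter the phenotype as
`indirect_scale × (g_father + g_mother)` with g the true additive genetic
value. This is the simplest generative form that opens a gap between the
direct and population effects of a PGI; it does not model sibling indirect
effects or more elaborate gene–environment transmission.

### Assortative mating

Each generation, individuals receive a mating score
`w_p·ŷ + w_l·L + w_a·ancestry` (channels standardized); L is a latent
factor with correlation `latent_pgi_corr` to the standardized additive
genetic value, which is how "assortment on a PGI-correlated composite that
is not the phenotype" is realized. Pairing uses a Gaussian-copula
rank-noise scheme: the female ranking key mixes her normal score with
independent noise, males sorted by score are paired with females sorted by
key, and the mixing weight is calibrated by 40 bisection steps so the
realized Pearson correlation of paired scores hits `target_mate_r` (to
well within ±0.02 at 5,000+ pairs). Target 1 reduces to rank matching;
target 0 to a random permutation.

Under pure phenotypic assortment the additive variance follows
V' = V(1+r_g)/2 + V0/2 with r_g the mate correlation of genetic values and
V0 the linkage-equilibrium variance, giving the fixed point V0/(1−r_g).
The test suite verifies the simulator sits on this fixed point within 3%
after 8 generations of 5,000 couples.

Inbred matings, when enabled, are full-sib couples (offspring F = 1/4)
replacing a fraction of the assortative pairings from the second offspring
generation on. Full sibs rather than cousins keep the pedigree two
generations deep; the inbreeding-depression conversion to first-cousin
offspring uses F = 1/16 regardless of how variation in F was generated.
Pedigree F is computed by the standard recursive kinship algorithm with
memoization and cycle detection.

Defaults: founder allele frequencies uniform on [0.05, 0.5]; two children
per couple with alternating sexes (balanced sexes, sib pairs and trios in
every family); subpopulation divergence via Balding–Nichols Beta draws at
the configured F_ST.

## Association testing

Covariates are projected out of the phenotype and each coded genotype
column once (Frisch–Waugh–Lovell); each SNP test is then a univariate
slope with n − q − 2 residual degrees of freedom and a normal two-sided
p-value from z = β̂/se. Dominance coding uses the sample allele frequency,
which keeps in-sample orthogonality to the additive coding as tight as
possible. Monomorphic SNPs are flagged, not estimated. Mixed-model
association is not implemented: the intended samples are either unrelated
(the panel generator) or family-clustered in ways the family module
handles by clustering. Consequently, running a GWAS on a sample that mixes
siblings inflates test statistics — this is real confounding-by-relatedness
that the LD-score intercept then picks up, and the null-calibration tests
use unrelated samples on purpose.

## Meta-analysis and clumping

Sample-size weighting follows the √N-weights convention
(z_meta = Σ√N_i z_i / √ΣN_i); per-study N comes from the input column.
Effect-size columns are combined by inverse variance so that weight
construction downstream has betas to use; when se ∝ 1/√N the two schemes
coincide. Harmonization aligns effect alleles to a reference (sign and
frequency flips, strand complements), drops ambiguous palindromic SNPs
with MAF above 0.4 (config-overridable) and drops mismatches with a log
entry. Clumping is the greedy loop — smallest p first, remove r² > 0.1
neighbors, repeat — with ties broken by (chr, pos, snp_id) and no distance
cutoff; the suite checks it against a literal re-implementation on
thousands of small random instances. SE inflation multiplies by
√intercept, which divides the mean χ² by the intercept exactly.

## LD-score regression

χ² statistics are regressed on N·l/M with a free intercept and single-pass
1/max(l,1) weights; the slope is the h² estimate. No iterative
reweighting is done — at the sample sizes this package targets the
efficiency loss is minor, and a single pass keeps the estimator
transparent. Standard errors are a delete-one block jackknife. Jackknife
units are built to respect LD-block boundaries (at least 20 units, at most
one third of the number of LD blocks): splitting an LD block across
jackknife units makes delete-one replicates non-exchangeable and
understates the SE. The dominance mode uses l_dom = Σ r⁴, which follows
from corr(d_j, d_k) = r²_jk under HWE. The confounding share is
(intercept − 1)/(mean χ² − 1), clipped to [0,1] — the attenuation-ratio
convention. Cross-trait r_g divides the z₁z₂ slope by the geometric mean
of the two h² slopes, jackknifing all three regressions jointly.

## Family-based decomposition

Direct effects come from OLS with family-clustered (sandwich) standard
errors — trios: phenotype on child/father/mother PGIs; siblings: phenotype
on the within-sibship deviation and the sibship mean. A family random
intercept would model the same clustering; cluster-robust OLS was chosen
because it gives identical point estimates without distributional
assumptions on the family effect, and with one trio per family a random
intercept is barely identified.

The population effect is recovered from the equilibrium moments of
assortative mating. With r the mate-pair PGI correlation,
cov(PGI_child, PGI_parent) = V(1+r)/2, hence for trios
β_pop = δ + (1+r)/2·(α_f + α_m). For sib pairs the between-family
coefficient b satisfies b = δ + 4(1+r)/(3+r) × (parental contribution), so
β_pop = δ + (3+r)/4·(b − δ); the derivation uses var(PGI sib-mean) =
V(3+r)/4 and cov with both parents 2·V(1+r)/2, and assumes sibships of
two (the generator's default). Both transforms are first-order equilibrium
results; higher-order disequilibrium terms are ignored, and the test suite
validates them instead against the marginal regression slope in unrelated
individuals of the same simulated population (agreement within 2 Monte
Carlo SEs). Sibling indirect effects are assumed zero — a documented
limitation, not a finding.

Estimates from the two designs combine by generalized least squares; when
the designs share families, their covariance is estimated by a clustered
bootstrap over families. The ratio δ/β_pop gets a delta-method SE and the
direct share of the PGI's R² is 100·ratio².

## Assortment tests

All mate-pair uncertainty is a percentile bootstrap over pairs (1,000
repetitions, recorded seed). The phenotypic-assortment prediction is the
product r_y·r_p·r_m with its SE from the joint pair bootstrap.
Residualization ladders are cumulative and strictly per-partner (each
partner's PGI on that partner's own covariates); residualizing a PGI on a
regressor collinear with it raises. Percent reduction is
100·(1 − r_resid/r_raw).

## PGI evaluation

C+T weights are the meta-analysis betas of clump survivors at the standard
cutoffs (5e-8, 5e-5, 5e-3, 1). The infinitesimal option solves
(M/(Nh²)I + R)b = β̂ per LD block — the closed-form LD-aware shrinkage for
a Gaussian effect prior; posterior-sampling weight methods are out of
scope. Scoring is Σ dosage·w with allele alignment (direct, swapped or
strand-flipped) and mean-dosage imputation for missing genotypes.

Incremental R² is the gain over the covariate-only regression, CI by
percentile bootstrap over individuals; Nagelkerke R² is
(1 − (L0/L1)^{2/n})/(1 − L0^{2/n}) with L0 the intercept-only likelihood,
offered for logistic and probit links, with perfect separation flagged as
an error. Decile reports partition by PGI rank with stable ties, Wilson
binomial CIs on prevalences, and odds ratios from a logistic regression of
the outcome on decile dummies (reference = lowest decile) plus covariates.

The expected-accuracy curve E(R²) = A/(B + 1/N) is linear in 1/R² versus
1/N, which solves two points exactly and seeds the bounded least-squares
fit for more. GWAS power uses a 1-df noncentral χ² with NCP = N·r²; the
NCP convention N·r² (rather than N·r²/(1−r²)) is immaterial at per-SNP R²
of 10⁻⁵–10⁻³ and is documented here once. `detectable_r2` inverts the
power function by Brent root-finding; the pair are mutual inverses to
1e-6 relative tolerance.

## Winner's curse and inbreeding depression

The empirical-Bayes prior is b ~ N(0, τ²), with τ² from the method of
moments: τ² = max(0, mean χ²/intercept − 1)/N̄ on the standardized scale.
An optional point-normal prior (null mass π₀) is fitted by maximum
likelihood on the z statistics. The posterior mean β̂·τ²/(τ²+se²) needs no
explicit truncation correction for significance selection: selection is a
function of the observed data, and the posterior conditions on the
observed data, so it is unchanged — the simulations confirm the adjusted
effects of genome-wide-significant SNPs are unbiased while raw effects are
inflated. Replication predictions propagate the posterior through the
replication sampling distribution, with an optional Monte Carlo check.

Inbreeding depression is the slope of the phenotype on F. From dominance
summary statistics, the expected dominance coding shifts by −2pq per unit
F (at F, genotype frequencies are q²+Fpq, 2pq(1−F), p²+Fpq, so
E[d] = 2p² − 2pqF), giving the unlinked-approximation estimator
B̂ = −Σ 2p_j q_j δ̂_j with variance Σ(2p_j q_j)² se_j². On this coding a
*positive* δ is heterozygote advantage, so directional dominance that is
deleterious under inbreeding corresponds to positive δ and negative B̂.
No LD correction is applied to the summary-statistic estimator; the test
suite compares it with the individual-level regression only on unlinked
simulations. Pedigree F is the default regressor; an excess-homozygosity
genomic F is available as an alternative.

## Problem sizes, seeds and tolerances

The simulation-based checks run at sizes chosen to make their tolerances
meaningful at interactive timescales: null calibrations at 2,500
individuals × 2,500 SNPs, LD-score recovery at 2,500 × 2,500 over 20
replicate seeds, the mating equilibrium at 5,000 couples × 8 generations,
family designs at 3,000 founder couples, mate-pair tests at 6,000 couples,
winner's-curse calibration at 20,000 SNPs × 20 seeds. All randomness flows
from one root seed through named, CRC-keyed substreams, so any stage can
be reproduced in isolation; identical seeds give bit-identical cohorts.

## What passing tests does and does not show

The generator produces unlinked-or-block-LD biallelic SNPs, Gaussian
environments, within-block-constant allele frequencies, equilibrium HWE
founders and idealized mating markets. Passing tests therefore shows the
estimators are correct under their own assumptions and calibrated at
realistic effect sizes — it does not certify behavior under fine-scale LD
decay, genotyping error, imputation dosage uncertainty, phenotype
measurement error that correlates with genotype, population structure
beyond two discrete subpopulations, or participation bias. The headline
empirical findings of large studies in this area depend on
access-controlled cohorts and are not reproduced here; what is reproduced
is their printed self-contained arithmetic and the statistical behavior of
the machinery under known truth.
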