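# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data generator behind `pedimeth`, including what the passing
test suite does and does not demonstrate about real data.

## The polygenic model

Every scan in the package rests on the variance-components model

    t_i = m + Σ_k b_k x_ik + g_i + e_i,
    g ~ MVN(0, σ²_g A),   e ~ MVN(0, σ²_e I),

where **A** is the additive genetic relationship matrix computed from the
pedigree by the tabular recursion (A_ii = 1 + ½A_{father,mother};
A_ij = ½(A_{j,father(i)} + A_{j,mother(i)})). A is twice the kinship
matrix; we use the additive-relationship convention throughout, so
parent-offspring and sibling pairs sit at 0.5, second-degree pairs at
0.25, and the coefficient halves per further degree. Founders are assumed
non-inbred and mutually unrelated. Monozygotic twins cannot be expressed
in PED structure, so an optional sixth PED column labels twin groups and
their pairwise coefficient is forced to 1 (their rows toward third
parties already coincide because co-twins share both parents).
`RelationshipMatrix.degree_table` additionally stores the conventional
reporting constants used in family-study tables for 3rd–6th-degree
relatives (0.0078, 0.0020, 0.0005, 0.0001); these do not follow the exact
halving series, their provenance is not documented in the literature we
mirror, and they are used for labeling only — never in computation.

### Fitting

Parameters are estimated by full maximum likelihood (ML), not REML,
because every downstream inference is a likelihood-ratio test between
nested models and ML likelihoods are the objects those tests compare.
One eigendecomposition A = UΛUᵀ per analysis sample set rotates the data
(y* = Uᵀy, X* = UᵀX) so that the covariance is diagonal,
σ²_tot·(h²λ_i + 1 − h²). At fixed h² the fixed effects are closed-form
GLS and σ²_tot is profiled analytically, leaving a one-dimensional profile
likelihood in h². That profile is evaluated on a 64-point grid over
[0, 1 − 10⁻⁶] (guarding against flat ridges) and refined by bounded
scalar minimization between the best grid point's neighbours to an h²
tolerance of 10⁻⁸, with a guard that the refined optimum is never worse
than the best grid value. The rotated likelihood is validated against an
independent dense multivariate-normal log-density oracle (agreement to
10⁻⁸ on small pedigrees, 10⁻⁶ asserted in tests). An `EigenA` object
caches the decomposition so per-probe scans on a common cohort pay for it
once.

Degenerate input handling: a non-PSD A (beyond −10⁻⁶) is an error; tiny
negative eigenvalues are clipped to zero. With A = I the likelihood is
exactly flat in h² — h² is unidentifiable — so the fit logs a warning and
lands on the boundary (matching the σ²_g = 0 model's likelihood). Samples
with missing trait or covariates are dropped listwise per model, with A
subset accordingly; rank-deficient covariate sets raise an error naming
the offending columns.

### Tests of heritability and covariates

σ²_g sits on the boundary of its parameter space under the null, so the
heritability LRT uses the boundary mixture ½χ²₀ + ½χ²₁:
p = ½·Pr(χ²₁ > λ), and p = 0.5 when λ = 0. Covariate tests compare models
with and without one fixed effect (polygenic background retained in both)
against plain χ²₁. Reported standardized coefficients are
b̂·sd(x)/sd(t), signed so that positive means higher methylation with
increasing age, in females, or per copy of the minor allele; the
measured-genotype effect is standardized by the covariate-residualized
trait SD instead, so it is a per-allele shift in residual-trait SD units.

**Finite-sample conservativeness.** The ½:½ mixture weights are an
asymptotic result. On pedigrees of the size this package targets
(~200 members), the estimated null mass at λ = 0 is ≈ 0.59 rather than
0.50, while λ | λ > 0 follows χ²₁ essentially exactly (KS p ≈ 1 in our
diagnostics). The mixture p-value is therefore valid but conservative:
the realized type-I error at nominal 0.05 is ≈ 0.03. The test suite
asserts exactly this (no inflation, correct conditional distribution,
boundary mass ≥ ½) rather than pretending the asymptotic size holds at
n ≈ 200.

### Covariates

The default covariate set is sex, age, age², sex×age and sex×age², built
by `default_covariates`; all are retained in every model (no
significance screening), since joint modeling is the cleaner default when
the alternative is an unstated pruning rule. Sex enters as a female
indicator; age is mean-centered before squaring purely for numerical
conditioning (LRTs and standardized effects are unchanged). Beta values
are analyzed untransformed — the QC chain has already removed
strongly non-normal probes — and an inverse-normal transform is
deliberately not applied by default.

## Methylation QC

The chain runs in a fixed order, each stage appending to an auditable
report (stage name, threshold, exclusions, remainder; conservation of
counts is enforced):

1. **Sample call rate** ≥ 0.90, where a measurement is "called" when its
   detection p-value is < 0.05.
2. **Sample CV outliers**: CV = sd/mean of beta across probes; samples
   strictly above the 97.5th percentile (linear-interpolation quantile)
   are removed. Strict exceedance means fully tied CVs remove nobody.
3. **Probe call rate** ≥ 0.97.
4. **Beta variation**: max − min across non-missing samples ≥ 0.17 —
   the platform's discriminable methylation difference, read as a range
   criterion on beta.
5. **Lilliefors normality** at FDR 0.1: D = sup|ECDF − Φ((x−x̄)/s)|, with
   a Monte-Carlo p-value from 10,000 standard-normal samples of the same
   size (the null distribution of D depends only on n, so one null table
   per sample size is drawn with a fixed seed and shared across probes —
   exact at any n and reproducible, unlike the Dallal–Wilkinson
   approximation, which we keep only as a cross-check oracle in tests).
   Probes with Benjamini–Hochberg q < 0.1 are removed.
6. **Autosomal only**: X/Y-linked probes are dropped.

Missing betas are ignored pairwise-complete in the variation and
normality computations. Whether the CV percentile should be computed
before or after other exclusions is ambiguous in the conventions we
mirror; the chain computes it on the samples surviving stage 1, and the
report records the order so the choice is visible.

Probe-body variant annotation counts supplied variants inside each probe
interval, reports the distance of the nearest one to the CpG, and flags
probes containing a variant with MAF > 5% (probes where the assay may
read genotype rather than methylation). Chromosome naming ("chr1" vs
"1") is normalized.

## Genotype QC and cis-mQTL association

SNP QC removes, in order: call rate < 0.95, monomorphic SNPs, SNPs whose
minor allele is carried by < 10 individuals, and SNPs failing a
founders-only chi-square Hardy-Weinberg test at p ≤ 10⁻⁴ (a pedigree-aware
HWE statistic is out of scope; with no founders available the filter is
skipped with a warning). Missing dosages are then filled with the SNP's
observed mean dosage (2p̂ with p̂ from all called samples), which
preserves each SNP's mean exactly; reported MAF is computed from founder
allele counts where founders exist. Pedigree-aware imputation of missing
genotypes from relatives is deliberately not implemented; the synthetic
generator produces complete dosages.

Cis windows are ±100 kb around the CpG position, closed at the boundary
(a SNP at exactly 100,000 bp is included), with the signed distance
SNP − CpG retained. Unannotated probes are skipped and logged, not
errors. The measured-genotype test adds the dosage to the fixed effects
and refers 2Δlog-likelihood to χ²₁; with A = I and no covariates it
reduces exactly to the OLS likelihood-ratio slope test (asserted to 10⁻⁶
in tests). The same machinery tests each probe's methylation as a
covariate of waist circumference or BMI, with per-trait listwise
missingness (n_used reported per trait).

## Multiple testing

- **Bonferroni**: α/m (0.05/395 = 1.27×10⁻⁴; 0.05/4209 = 1.19×10⁻⁵).
- **Li–Ji effective tests**: Meff = Σ f(|λ_i|), f(x) = 1{x ≥ 1} + (x − ⌊x⌋),
  over eigenvalues of the post-QC SNP dosage correlation matrix, computed
  per chromosome and summed. The per-test threshold defaults to α/Meff
  (division) because that is the convention whose printed thresholds the
  family-mQTL literature we mirror actually matches; exact Šidák
  (1 − (1−α)^(1/Meff)) is available by flag and is never smaller.
- **Tail-area FDR**: Benjamini–Hochberg step-up q-values scaled by
  Storey's η̂₀ = #{p ≥ 0.5}/(0.5·n), clamped to (0, 1]. The tie-inclusive
  `p ≥ λ` matters: boundary-mixture LRT p-values have a null atom at
  exactly 0.5, and counting it preserves η̂₀ ≈ 1 under the null for both
  uniform and mixture p-value distributions. This estimator targets the
  same quantity as density-based tail-area FDR implementations but is
  simpler and directly testable against the step-up definition.

## The synthetic study generator

The generator produces data with the statistical structure the analysis
assumes, so every stage is testable without access to any real cohort. It
emulates a family study of ~183 profiled members; what it reproduces, and
what it does not, is listed explicitly below.

- **Pedigrees.** 17 extended families, each three generations: a founder
  couple, three married children (spouses are unrelated founders), three
  grandchildren per couple. The profiled subset per family is one founder
  grandparent, one middle-generation child and all nine grandchildren —
  11 of 17 members — giving 187 profiled individuals. The resulting
  relative-pair census (221 first-degree, 255 second-degree, 459
  third-degree pairs) sits within ~15% of the 196/221/401 profile typical
  of such cohorts; exact reproduction of a printed census is an
  under-determined combinatorial problem and is not attempted.
  Three-generation families contain no 4th/5th-degree pairs, so those
  bins are empty — a known structural simplification.
- **Demographics.** Ages are drawn per generation — founders ≈ N(68, 6²),
  middle generation ≈ N(52, 8²), grandchildren ≈ N(37.5, 9.5²), truncated
  to 19–75 — calibrated analytically from the 1/11 : 1/11 : 9/11 sampling
  mix to give a cohort mean/sd near 42.15/13.74. Sex is ~55% female.
- **Genotypes.** Founder haplotypes are Markov chains over loci with
  adjacent-locus correlation ρ (default 0.6; conditional Bernoulli
  probabilities clipped to [0,1], which caps achievable correlation for
  extreme MAF pairs). Offspring inherit one whole parental haplotype per
  meiosis — no recombination, a fair approximation within ≤200 kb cis
  windows — so genotypes are Mendelian-consistent by construction, and
  LD is first-order only (sufficient to exercise Li–Ji, not a genome-wide
  LD map).
- **Methylation.** Latent per-probe traits
  y = b_age·age_z + b_sex·female + a·(dosage − 2p) + g + e with
  Var(g) = h², a²Var(dosage) = q², Var(e) = 1 − h² − q²; polygenic values
  are drawn by the exact pedigree recursion (founders N(0,1), child =
  parent midpoint + segregation noise of variance ½), which samples
  MVN(0, A) exactly for non-inbred parents in O(n). "Latent" mode maps y
  affinely to a beta scale (recovery tests are exact up to rare clipping);
  "bounded" mode squashes through an inverse-logit around logit(baseline),
  guaranteeing values in (0, 1) at the cost of mild attenuation.
  Detection p-values are near zero except a configurable failure fraction
  (default 0.5%), whose betas are masked. A truth table records every
  generating parameter. The default labeled panel is 50 probes: 10
  heritable (h² = 0.6), 10 cis-regulated (q² = 0.3), 10 age-affected, 20
  null.
- **Phenotypes.** BMI and waist = sex-specific mean (31.21/33.38 kg/m²;
  104.08/105.50 cm) + familial component (polygenic, sd 3.5 / 6.0) +
  residual noise (sd 6.43 / 15.0), reproducing cohort-level means and SDs
  (32.40 ± 7.40; 104.86 ± 16.14) at the default sex mix; optional
  methylation→trait effects are injected in SD units for recovery tests.
- **Determinism.** A study is a pure function of (config, seed); child
  seeds are spawned via `SeedSequence`. Reruns are byte-identical.

**What passing tests show — and don't.** The generator matches the
analysis model by construction (additive genetics, linear covariate
effects, near-normal latent traits). Passing recovery, power and
discrimination tests therefore demonstrates the correctness of the
machinery, not robustness to real-data pathologies: cellular
heterogeneity, batch effects, probe cross-reactivity, non-additive
genetic architecture and heavy-tailed beta distributions are all outside
the generator's scope. Power numbers (e.g. ≈ 0.74–0.78 at h² = 0.36,
α = 0.05 on the default cohort) are properties of this synthetic pedigree
set, close to — but not a reproduction of — any particular real cohort's
power, whose exact pedigree is not public.

## The engineered QC panel

`qc_chain_fixture` builds a 1,505-probe panel whose groups trip the four
probe filters at exactly 103 (call rate), 355 (variation), 641
(normality) and 11 (X-linked), leaving 395 survivors. Clean and X-linked
probes are rejection-sampled to Lilliefors Monte-Carlo p ≥ 0.5 and the
non-normal group is two tight modes (p at the Monte-Carlo floor), so the
BH screen at FDR 0.1 separates the groups with a wide margin. This
fixture validates the chain's bookkeeping arithmetic; it is synthetic and
is not a reconstruction of any real array's data.

## Pipeline, problem sizes and runtime choices

`run_study` executes sample QC → probe QC → heritability → cis-mQTL →
age/sex → obesity → corrections, from one flat YAML/dict config whose
defaults are the thresholds listed above; every threshold actually
applied is logged, stages can be skipped explicitly, and reruns with the
same seed produce bit-identical TSVs. Excluded probes carry exactly one
primary exclusion reason (the first stage that removed them). End-to-end
discrimination on the labeled 50-probe study is summarized per scan as
the AUC of ranking true-positive probes above nulls, computed over the
probes that reach each scan (QC exclusions are assigned the worst rank).

Simulation sizes in the test suite — 200 replicates for recovery, 500
for power, 600–1,000 for null calibration, Monte-Carlo tables of
2,000–10,000 draws — were chosen as the smallest sizes at which the
Monte-Carlo error is comfortably below the asserted tolerances; the whole
suite is a few minutes on one CPU.

## Known limitations

ML variance components carry the usual downward finite-sample bias
(measured ≈ −0.02 at h² ∈ {0.3, 0.6}, n ≈ 200). The heritability LRT is
conservative at these sample sizes (above). X-linked relationship
matrices, dominance/household components, bivariate models, trans-mQTL
scans, LD pruning and conditional multi-SNP models are not implemented.
The founders-only chi-square HWE test is less powerful than a
pedigree-aware statistic. The Li–Ji correction is computed on
pairwise-complete post-QC dosages; with heavy missingness the correlation
matrix may not be PSD, though eigenvalue magnitudes are used, which keeps
Meff defined.
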