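# pedimeth

Family-based heritability and cis-mQTL analysis of DNA methylation array
data.

## The problem

DNA methylation at a CpG site, measured on bead arrays as a beta value in
[0, 1], behaves like a quantitative trait: it runs in families, is shaped
by nearby genetic variants, and drifts with age and sex. Estimating how
much of its variance is genetic requires cohorts of *related* individuals
— extended pedigrees — and statistical machinery that models the
relatedness instead of being confounded by it. `pedimeth` is a toolkit for
exactly that setting: methylation panels (hundreds to thousands of CpG
sites) profiled in a few hundred members of extended families, with dense
SNP genotypes and anthropometric phenotypes on the side.

It provides, as importable library modules:

- **`pedimeth.pedigree`** — PED-file parsing, the additive genetic
  relationship matrix **A** by the tabular recursion
  (A_ii = 1 + ½A_{fm}, A_ij = ½(A_{j,f} + A_{j,m})), and relative-pair
  censuses by degree (parent-offspring/sibling 0.5;
  grandparent-grandchild, avuncular, half-sib, double-first-cousin 0.25).
- **`pedimeth.qc`** — the methylation QC chain: sample detection-p call
  rate (≥ 0.90), sample coefficient-of-variation outliers (> 97.5th
  percentile), probe call rate (≥ 0.97), minimum beta variation (≥ 0.17),
  a Lilliefors normality screen with Monte-Carlo p-values at FDR 0.1, and
  removal of X-linked probes — every stage recorded in an auditable
  report. Plus annotation of known variants inside probe bodies (flagging
  MAF > 5%).
- **`pedimeth.polygenic`** — the variance-components model
  *t = m + Σ b_k x_k + g + e*, with g ~ MVN(0, σ²_g A), fitted by maximum
  likelihood through one eigendecomposition of A; heritability
  h² = σ²_g/(σ²_g + σ²_e) tested by the boundary-mixture ½χ²₀ + ½χ²₁
  likelihood-ratio test; covariate effects (sex, age, age², interactions)
  by χ²₁ LRTs; simulation-based power.
- **`pedimeth.mqtl`** — SNP QC (call rate, monomorphism, minor-carrier
  count, founders-only Hardy-Weinberg), the measured-genotype test (SNP
  dosage as a fixed effect in the polygenic model, χ²₁ LRT) over cis
  windows of ±100 kb, and methylation-as-covariate tests for obesity
  traits (waist circumference, BMI).
- **`pedimeth.correction`** — Bonferroni and Šidák thresholds, the Li–Ji
  effective number of independent tests from the eigenvalues of the SNP
  dosage correlation matrix (per chromosome, summed), and tail-area FDR
  q-values (Benjamini–Hochberg scaled by Storey's η̂₀).
- **`pedimeth.simulate`** — a fully labeled synthetic study generator:
  three-generation extended families with a profiled cohort of ~183–187
  members matching a realistic relative-pair census, gene-dropped SNP
  genotypes with first-order LD, methylation with additive genetic,
  cis-SNP, age and sex components, and BMI/waist phenotypes with familial
  correlation.
- **`pedimeth.pipeline`** / the **`pedimeth`** CLI — one-call
  orchestration of QC → heritability scan → cis-mQTL scan → covariate and
  obesity scans → corrected report tables.

## Worked example

```python
from pedimeth import default_covariates, fit_polygenic, lrt_h2
from pedimeth.polygenic import EigenA, heritability_power
from pedimeth.simulate import SyntheticStudyConfig, simulate_study

study = simulate_study(SyntheticStudyConfig(seed=7))   # 187 profiled members
rel = study.relationship
cov = default_covariates(study.phenotypes)
eigen = EigenA(rel)

for probe in list(study.methylation.probes)[:3]:
    tr = study.methylation.beta[probe]
    full = fit_polygenic(tr, cov, rel, eigen=eigen)
    null = fit_polygenic(tr, cov, rel, estimate_h2=False, eigen=eigen)
    print(probe, round(full.h2, 3), lrt_h2(full, null).p)
```

prints (true h² of these generator-labeled probes is 0.60):

```
SYN000_P100_F 0.748 6.31e-08
SYN001_P101_F 0.833 8.61e-10
SYN002_P102_F 0.523 0.000134
```

i.e. the ML heritability estimate per probe and the boundary-mixture LRT
p-value against σ²_g = 0. On the same cohort,

```python
heritability_power(rel, h2=0.36, alpha=0.05, n_reps=300, seed=1)["power"]
```

gives `0.78`: a cohort of this size and structure detects h² = 0.36 in
about four of five tries at the 5% level. The scripts in `examples/` walk
through each capability (pedigree relationships, the QC chain on an
engineered 1,505-probe panel, heritability, cis-mQTL with Li–Ji
correction, and the full pipeline) and print commented output.

The command-line equivalent of the full analysis:

```bash
pedimeth --seed 11 --out-dir out report   # synthetic demo via a config file
pedimeth --config study.yaml --out-dir out report
```

where `study.yaml` names the input files (`pedigree`, `beta`,
`detection_p`, `manifest`, `phenotypes`, optional `variants`) and any
threshold overrides; `pedimeth defaults` lists every tunable threshold.

## Limitations

Estimates are ML (not REML), so variance components carry the usual small
downward finite-sample bias, and the boundary-mixture heritability test is
conservative at n ≈ 200 (see `docs/methods.md`). Founders are assumed
non-inbred and mutually unrelated; X-linked inheritance, dominance and
household components, trans-mQTL scans, and pedigree-aware genotype
imputation are out of scope.
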