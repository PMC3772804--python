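"""Measured-genotype association of cis SNPs with methylation.

A SNP dosage (0-2 copies of the minor allele, fractional when imputed)
enters the polygenic model as an extra fixed effect; its significance is a
chi2(1) likelihood-ratio test against the model without the SNP, so family
structure is absorbed by the random genetic effect rather than inflating
the association statistics. "Proximal" (cis) SNPs are those within a fixed
window (default 100 kb) of the CpG position. The same machinery tests each
CpG as a covariate of an obesity trait (waist circumference or BMI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree, RelationshipMatrix
from .polygenic import FitError, fit_polygenic
from .qc import QCReport, normalize_chrom

log = logging.getLogger(__name__)

__all__ = [
    "VariantSet",
    "AssociationResult",
    "genotype_qc",
    "hwe_chisq",
    "select_proximal_snps",
    "measured_genotype_test",
    "obesity_covariate_test",
    "read_dosage_tsv",
    "read_vcf",
]


@dataclass
class VariantSet:
    """SNP metadata plus a sample x SNP dosage matrix.

    ``info`` columns: snp_id, chrom, pos (1-based), major, minor, and after
    QC also maf (minor-allele frequency from founder counting) and hwe_p.
    Dosages count copies of the minor allele; NaN = missing call.
    """

    info: pd.DataFrame  # indexed by snp_id
    dosage: pd.DataFrame  # samples x snp_id

    def __post_init__(self) -> None:
        if list(self.info.index) != list(self.dosage.columns):
            raise ValueError("info rows and dosage columns must align")
        self.info = self.info.copy()
        self.info["chrom"] = self.info["chrom"].map(normalize_chrom)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.info.index)

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.index)

    def select(self, snp_ids) -> "VariantSet":
        ids = list(snp_ids)
        return VariantSet(self.info.loc[ids], self.dosage[ids])

    def write_tsv(self, path) -> None:
        wide = self.info.reset_index(drop=True).merge(
            self.dosage.T, left_on="snp_id", right_index=True
        )
        wide.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> VariantSet:
    """Read a dosage TSV: snp_id chrom pos major minor <sample columns>."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in ("snp_id", "chrom", "pos", "major", "minor", "maf", "hwe_p") if c in df.columns]
    info = df[meta_cols].set_index("snp_id", drop=False)
    dosage = df.set_index("snp_id").drop(columns=[c for c in meta_cols if c != "snp_id"]).T
    dosage.index.name = "sample"
    return VariantSet(info, dosage.astype(float))


def read_vcf(path) -> VariantSet:
    """Read variants from a VCF, preferring DS (dosage) over GT."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if var.format("DS") is not None:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        else:
            # gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
            gt = np.asarray(var.gt_types, dtype=float)
            ds = np.select(
                [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
            )
        sid = var.ID or f"{var.CHROM}_{var.POS}"
        rows.append(
            {
                "snp_id": sid,
                "chrom": var.CHROM,
                "pos": int(var.POS),
                "major": var.REF,
                "minor": var.ALT[0] if var.ALT else ".",
            }
        )
        dosages.append(ds)
    info = pd.DataFrame(rows).set_index("snp_id", drop=False)
    dosage = pd.DataFrame(
        np.array(dosages).T, index=samples, columns=info.index
    )
    return VariantSet(info, dosage)


def hwe_chisq(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-square Hardy-Weinberg test p-value from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def genotype_qc(
    variants: VariantSet,
    ped: Pedigree | None,
    min_call: float = 0.95,
    min_minor_carriers: int = 10,
    hwe_alpha: float = 1e-4,
) -> tuple[VariantSet, QCReport]:
    """SNP-level QC and expected-dosage imputation of missing calls.

    Removes, in order: SNPs with call rate < ``min_call``; monomorphic
    SNPs; SNPs whose minor allele is carried by fewer than
    ``min_minor_carriers`` individuals; SNPs failing a founders-only
    chi-square Hardy-Weinberg test at ``hwe_alpha`` (hard calls required
    for HWE; skipped with a warning if the pedigree has no founders).
    Surviving SNPs have missing dosages replaced by their observed mean
    dosage (2x allele frequency), which preserves each SNP's mean exactly;
    reported MAF comes from founder allele counting where founders exist.
    """
    dos = variants.dosage.to_numpy(dtype=float)
    n_samples = dos.shape[0]
    report = QCReport(axis="snps", initial=len(variants.snp_ids))

    call = np.mean(np.isfinite(dos), axis=0)
    keep = call >= min_call
    report.add("snp_call_rate", f">={min_call}", int((~keep).sum()), int(keep.sum()))
    variants = variants.select(np.array(variants.snp_ids)[keep])
    dos = variants.dosage.to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        mono = np.array([np.nanstd(dos[:, j]) == 0 for j in range(dos.shape[1])])
    keep = ~mono
    report.add("monomorphic", "polymorphic", int(mono.sum()), int(keep.sum()))
    variants = variants.select(np.array(variants.snp_ids)[keep])
    dos = variants.dosage.to_numpy(dtype=float)

    hard = np.round(dos)
    # orient to the minor allele before counting carriers
    freq = np.nanmean(dos, axis=0) / 2.0
    minor_dosage = np.where(freq <= 0.5, hard, 2 - hard)
    carriers = np.nansum(minor_dosage > 0, axis=0)
    keep = carriers >= min_minor_carriers
    report.add(
        "minor_allele_carriers",
        f">={min_minor_carriers}",
        int((~keep).sum()),
        int(keep.sum()),
    )
    variants = variants.select(np.array(variants.snp_ids)[keep])
    dos = variants.dosage.to_numpy(dtype=float)

    founders = [f for f in (ped.founders if ped is not None else []) if f in variants.dosage.index]
    if not founders:
        log.warning("no founders available: Hardy-Weinberg filter skipped")
        hwe_p = np.ones(dos.shape[1])
        keep = np.ones(dos.shape[1], dtype=bool)
    else:
        fdos = np.round(variants.dosage.loc[founders].to_numpy(dtype=float))
        hwe_p = np.empty(fdos.shape[1])
        for j in range(fdos.shape[1]):
            col = fdos[:, j]
            col = col[np.isfinite(col)]
            hwe_p[j] = hwe_chisq(
                int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
            )
        keep = hwe_p > hwe_alpha
    report.add("hardy_weinberg", f"p>{hwe_alpha}", int((~keep).sum()), int(keep.sum()))
    variants = variants.select(np.array(variants.snp_ids)[keep])
    hwe_p = hwe_p[keep]

    info = variants.info.copy()
    dosage = variants.dosage.copy()
    mean_dos = dosage.mean(axis=0, skipna=True)
    dosage = dosage.fillna(mean_dos)  # expected dosage 2*p, mean-preserving

    if founders:
        fd = dosage.loc[[f for f in founders if f in dosage.index]]
        freq = fd.mean(axis=0) / 2.0
    else:
        freq = mean_dos / 2.0
    info["maf"] = np.minimum(freq, 1.0 - freq)
    info["hwe_p"] = hwe_p
    return VariantSet(info, dosage), report


def mendelian_check(ped: Pedigree, variants: VariantSet) -> pd.DataFrame:
    """Trio-level Mendelian consistency of hard-called dosages.

    For each child with both parents genotyped, the child's dosage must be
    expressible as one transmitted allele from each parent (parent dosage 0
    transmits 0, 2 transmits 1, 1 transmits either). Returns a DataFrame of
    violations (empty = consistent); missing calls are skipped.
    """
    dos = variants.dosage
    rows = []
    transmit = {0.0: {0}, 1.0: {0, 1}, 2.0: {1}}
    for ind in ped.individuals:
        if ind.father is None or ind.father not in dos.index or ind.mother not in dos.index:
            continue
        if ind.iid not in dos.index:
            continue
        for snp in dos.columns:
            c, f, m = (
                dos.at[ind.iid, snp], dos.at[ind.father, snp], dos.at[ind.mother, snp]
            )
            if any(pd.isna(v) for v in (c, f, m)):
                continue
            c, f, m = round(c), round(f), round(m)
            ok = any(
                c == a + b for a in transmit[float(f)] for b in transmit[float(m)]
            )
            if not ok:
                rows.append(
                    {"iid": ind.iid, "snp_id": snp, "child": c, "father": f, "mother": m}
                )
    return pd.DataFrame(rows, columns=["iid", "snp_id", "child", "father", "mother"])


def select_proximal_snps(
    cpg: pd.Series | dict,
    variants: VariantSet,
    window: int = 100_000,
) -> pd.DataFrame | None:
    """SNPs within ``window`` bp of the CpG position (closed interval).

    Returns the variant info subset with a ``distance`` column
    (SNP pos - CpG pos, signed); ``None`` for unannotated probes (missing
    coordinates), which are skipped and logged rather than failing the scan.
    """
    chrom = cpg.get("chrom") if hasattr(cpg, "get") else cpg["chrom"]
    pos = cpg.get("cpg_pos") if hasattr(cpg, "get") else cpg["cpg_pos"]
    if pd.isna(pos) or pd.isna(chrom):
        log.info("probe %s has no annotation; skipped from the cis scan",
                 cpg.get("probe_id", "?"))
        return None
    chrom = normalize_chrom(chrom)
    info = variants.info
    hit = info[
        (info["chrom"] == chrom) & ((info["pos"] - int(pos)).abs() <= window)
    ].copy()
    hit["distance"] = hit["pos"] - int(pos)
    return hit


@dataclass
class AssociationResult:
    """One SNP-CpG (or methylation-obesity) association."""

    probe_id: str
    snp_id: str
    distance: int | None
    beta_std: float
    p: float
    lam: float
    n_used: int
    extra: dict = field(default_factory=dict)


def _lrt_fixed_effect(trait, covariates_with_x, covariates_without_x, rel, xname):
    full = fit_polygenic(trait, covariates_with_x, rel)
    reduced = fit_polygenic(trait, covariates_without_x, rel)
    lam = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = max(float(stats.chi2.sf(lam, df=1)), np.finfo(float).tiny)
    return full, lam, p


def _residual_sd(trait, covariates, ids):
    """sd of the trait after OLS residualization on the covariates."""
    y = trait.loc[ids].to_numpy(dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        r = y - y.mean()
    else:
        X = np.column_stack(
            [np.ones(len(ids)), covariates.loc[ids].to_numpy(dtype=float)]
        )
        r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(np.std(r, ddof=1))


def measured_genotype_test(
    trait: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame | None,
    rel: RelationshipMatrix,
    probe_id: str = "",
    snp_id: str = "",
    distance: int | None = None,
) -> AssociationResult:
    """Measured-genotype LRT of one SNP on one methylation trait.

    The dosage joins the fixed effects of the polygenic model; lambda =
    2*(ll_with - ll_without) is referred to chi2(1). The standardized
    effect is b_hat / sd(trait residualized on the covariates), i.e. the
    per-minor-allele shift in residual-trait SDs, positive when the minor
    allele increases methylation.
    """
    if covariates is None:
        covariates = pd.DataFrame(index=trait.index)
    common = trait.index.intersection(dosage.index).intersection(covariates.index)
    cov_x = covariates.loc[common].copy()
    cov_x["__dosage"] = dosage.loc[common].astype(float)
    sub = pd.concat([trait.loc[common].rename("__t"), cov_x], axis=1).dropna()
    if np.std(sub["__dosage"], ddof=0) == 0:
        raise FitError(
            f"SNP {snp_id!r} is monomorphic in the aligned analysis sample"
        )
    full, lam, p = _lrt_fixed_effect(
        trait, cov_x, cov_x.drop(columns="__dosage"), rel, "__dosage"
    )
    sd_resid = _residual_sd(trait, covariates if covariates.shape[1] else None, full.ids)
    return AssociationResult(
        probe_id=probe_id,
        snp_id=snp_id,
        distance=distance,
        beta_std=float(full.b["__dosage"] / sd_resid),
        p=p,
        lam=lam,
        n_used=full.n_used,
    )


def obesity_covariate_test(
    obesity_trait: pd.Series,
    methylation: pd.Series,
    covariates: pd.DataFrame,
    rel: RelationshipMatrix,
    probe_id: str = "",
    trait_name: str = "",
) -> AssociationResult:
    """Test one CpG's methylation as a covariate of an obesity trait.

    Fits the polygenic model for the obesity trait (waist or BMI) with the
    probe's beta value added to the standard covariates; chi2(1) LRT.
    Positive standardized beta = increased methylation associates with an
    increased obesity measure. Missing obesity values drop samples listwise
    (n_used is per trait).
    """
    cov_x = covariates.copy()
    cov_x["__meth"] = methylation.astype(float)
    full, lam, p = _lrt_fixed_effect(
        obesity_trait, cov_x, cov_x.drop(columns="__meth"), rel, "__meth"
    )
    meth_sd = float(methylation.loc[full.ids].std(ddof=1))
    trait_sd = float(obesity_trait.loc[full.ids].std(ddof=1))
    return AssociationResult(
        probe_id=probe_id,
        snp_id="",
        distance=None,
        beta_std=float(full.b["__meth"] * meth_sd / trait_sd),
        p=p,
        lam=lam,
        n_used=full.n_used,
        extra={"trait": trait_name},
    )
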