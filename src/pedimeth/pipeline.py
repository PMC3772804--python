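"""Study orchestration: QC -> heritability -> cis-mQTL -> covariates -> report.

``run_study`` drives the full analysis from a single flat configuration
(YAML or dict), either on supplied input files or on a synthetic study
generated in place, and writes self-documenting TSV reports. All stages
reuse one eigendecomposition-backed polygenic engine, and the whole run is
a deterministic function of the inputs and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mqtl as mqtl_mod
from .correction import CorrectionResult, bonferroni_threshold, li_ji_meff
from .pedigree import RelationshipMatrix, additive_relationship, read_pedigree
from .polygenic import (
    covariate_lrt,
    default_covariates,
    fit_polygenic,
    lrt_h2,
)
from .qc import (
    MethylationMatrix,
    QCReport,
    cv_outlier_filter,
    probe_filters,
    read_manifest,
    sample_call_rate_filter,
)
from .simulate import SyntheticStudyConfig, simulate_study

log = logging.getLogger(__name__)

__all__ = ["StudyInputs", "ScanReport", "run_study", "summarize_proportions",
            "load_config", "DEFAULT_THRESHOLDS"]

#: Default thresholds for every tunable step of the chain.
DEFAULT_THRESHOLDS = {
    "detect_alpha": 0.05,
    "sample_min_call": 0.90,
    "cv_upper_pct": 97.5,
    "probe_min_call": 0.97,
    "min_range": 0.17,
    "lillie_fdr": 0.1,
    "lillie_n_mc": 10000,
    "snp_min_call": 0.95,
    "min_minor_carriers": 10,
    "hwe_alpha": 1e-4,
    "cis_window": 100_000,
    "alpha": 0.05,
    "fdr_q": 0.05,
    "threshold_mode": "division",
}


@dataclass
class StudyInputs:
    """In-memory inputs for one study run."""

    relationship: RelationshipMatrix
    methylation: MethylationMatrix
    manifest: pd.DataFrame
    phenotypes: pd.DataFrame  # iid, age, sex, bmi, waist
    variants: mqtl_mod.VariantSet | None = None
    pedigree: object | None = None
    truth: pd.DataFrame | None = None


@dataclass
class ScanReport:
    """All per-probe scan tables plus QC and correction summaries."""

    qc_samples: QCReport
    qc_probes: QCReport
    heritability: pd.DataFrame
    mqtl_top: pd.DataFrame
    mqtl_full: pd.DataFrame
    agesex: pd.DataFrame
    obesity: pd.DataFrame
    corrections: pd.DataFrame
    summary: pd.DataFrame
    excluded_probes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.qc_samples.to_frame().to_csv(out / "qc_samples.tsv", sep="\t", index=False)
        self.qc_probes.to_frame().to_csv(out / "qc_probes.tsv", sep="\t", index=False)
        self.heritability.to_csv(out / "heritability.tsv", sep="\t", index=False)
        self.mqtl_top.to_csv(out / "mqtl_top.tsv", sep="\t", index=False)
        self.mqtl_full.to_csv(out / "mqtl_full.tsv", sep="\t", index=False)
        self.agesex.to_csv(out / "agesex.tsv", sep="\t", index=False)
        self.obesity.to_csv(out / "obesity.tsv", sep="\t", index=False)
        self.corrections.to_csv(out / "corrections.tsv", sep="\t", index=False)
        self.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        self.excluded_probes.to_csv(out / "excluded_probes.tsv", sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key/value mapping")
    return cfg


def _synthetic_inputs(cfg: dict, seed: int) -> StudyInputs:
    from .simulate import default_probe_models

    probe_kwargs = {
        k[len("probes_"):]: v for k, v in cfg.items() if k.startswith("probes_")
    }
    sconf = SyntheticStudyConfig(
        seed=seed,
        n_families=int(cfg.get("n_families", 17)),
        family_template=cfg.get("family_template", "extended"),
        probe_models=default_probe_models(**probe_kwargs) if probe_kwargs else [],
    )
    study = simulate_study(sconf)
    return StudyInputs(
        relationship=study.relationship,
        methylation=study.methylation,
        manifest=study.manifest,
        phenotypes=study.phenotypes,
        variants=study.variants,
        pedigree=study.pedigree,
        truth=study.truth,
    )


def _file_inputs(cfg: dict) -> StudyInputs:
    for key in ("pedigree", "beta", "detection_p", "manifest", "phenotypes"):
        if key not in cfg:
            raise FileNotFoundError(f"config does not name the {key!r} input file")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {cfg[key]}")
    ped = read_pedigree(cfg["pedigree"])
    mm = MethylationMatrix.read(cfg["beta"], cfg["detection_p"])
    manifest = read_manifest(cfg["manifest"])
    phen = pd.read_csv(cfg["phenotypes"], sep="\t", dtype={"iid": str})
    phen = phen.set_index("iid", drop=False)
    rel = additive_relationship(ped)
    unknown = [s for s in mm.samples if s not in rel.ids]
    if unknown:
        raise ValueError(
            f"methylation samples missing from the pedigree: {unknown[:5]}"
        )
    variants = None
    if cfg.get("variants"):
        p = str(cfg["variants"])
        variants = (
            mqtl_mod.read_vcf(p) if p.endswith(".vcf") or p.endswith(".vcf.gz")
            else mqtl_mod.read_dosage_tsv(p)
        )
    return StudyInputs(
        relationship=rel, methylation=mm, manifest=manifest,
        phenotypes=phen, variants=variants, pedigree=ped,
    )


def run_study(config, out_dir=None, seed: int | None = None) -> ScanReport:
    """Execute the full analysis chain from a configuration.

    ``config`` is a dict or a path to a flat YAML file. With
    ``synthetic: true`` the inputs are generated from the seed; otherwise
    the config must name pedigree/beta/detection_p/manifest/phenotypes
    files (variants optional). Stage order is fixed: sample QC, probe QC,
    heritability scan, cis-mQTL scan, age/sex covariate scan, obesity scan,
    multiple-testing corrections. Reports are written to ``out_dir`` when
    given.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    thr = {**DEFAULT_THRESHOLDS, **{k: v for k, v in cfg.items() if k in DEFAULT_THRESHOLDS}}
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)

    inputs = _synthetic_inputs(cfg, seed) if cfg.get("synthetic") else _file_inputs(cfg)
    report = analyze(inputs, thr, skip=set(cfg.get("skip_stages", [])))
    if out_dir is not None:
        report.write(out_dir)
    return report


def analyze(inputs: StudyInputs, thresholds: dict | None = None,
            skip: set | None = None) -> ScanReport:
    """Run the scans on prepared inputs (the engine behind ``run_study``)."""
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    skip = skip or set()
    mm = inputs.methylation
    all_probes = list(mm.probes)

    qc_s = QCReport(axis="samples", initial=len(mm.samples))
    if "sample_qc" not in skip:
        mm, qc_s = sample_call_rate_filter(
            mm, detect_alpha=thr["detect_alpha"], min_rate=thr["sample_min_call"],
            report=qc_s,
        )
        mm, qc_s = cv_outlier_filter(mm, upper_pct=thr["cv_upper_pct"], report=qc_s)

    if "probe_qc" not in skip:
        mm, qc_p = probe_filters(
            mm, inputs.manifest,
            min_call=thr["probe_min_call"], min_range=thr["min_range"],
            lillie_fdr=thr["lillie_fdr"], detect_alpha=thr["detect_alpha"],
            n_mc=thr["lillie_n_mc"],
        )
    else:
        qc_p = QCReport(axis="probes", initial=len(mm.probes))

    analyzed = list(mm.probes)
    kept = set(analyzed)
    excluded = pd.DataFrame(
        {
            "probe_id": [p for p in all_probes if p not in kept],
        }
    )
    excluded["reason"] = _exclusion_reasons(all_probes, kept, qc_p)

    rel = inputs.relationship.subset(
        [i for i in inputs.relationship.ids if i in mm.beta.index]
    )
    phen = inputs.phenotypes.loc[[i for i in rel.ids if i in inputs.phenotypes.index]]
    cov = default_covariates(phen)

    herit = _heritability_scan(mm, cov, rel, thr) if "heritability" not in skip else pd.DataFrame()
    mq_top, mq_full, meffs = (
        _mqtl_scan(mm, inputs, cov, rel, thr)
        if ("mqtl" not in skip and inputs.variants is not None)
        else (pd.DataFrame(), pd.DataFrame(), [])
    )
    agesex = _agesex_scan(mm, cov, rel) if "covariates" not in skip else pd.DataFrame()
    obesity = _obesity_scan(mm, phen, cov, rel) if "obesity" not in skip else pd.DataFrame()

    corrections = _corrections(herit, mq_full, agesex, obesity, meffs, thr)
    herit = _attach_q(herit, "p")
    agesex = _attach_q(agesex, "p_age", "q_age")
    agesex = _attach_q(agesex, "p_sex", "q_sex")
    obesity = _attach_q(obesity, "p")
    summary = (
        summarize_proportions(herit, alpha=thr["alpha"], fdr_q=thr["fdr_q"])
        if len(herit)
        else pd.DataFrame()
    )
    return ScanReport(
        qc_samples=qc_s,
        qc_probes=qc_p,
        heritability=herit,
        mqtl_top=mq_top,
        mqtl_full=mq_full,
        agesex=agesex,
        obesity=obesity,
        corrections=corrections,
        summary=summary,
        excluded_probes=excluded,
    )


def _exclusion_reasons(all_probes, kept, qc_p: QCReport) -> list[str]:
    # each excluded probe gets the single (first) stage that removed it
    reasons: dict[str, str] = {}
    for entry in qc_p.entries:
        for p in entry.get("excluded_ids", []):
            reasons.setdefault(p, entry["filter"])
    return [reasons.get(p, "probe_qc") for p in all_probes if p not in kept]


def _heritability_scan(mm, cov, rel, thr) -> pd.DataFrame:
    rows = []
    for probe in mm.probes:
        tr = mm.beta[probe]
        full = fit_polygenic(tr, cov, rel)
        null = fit_polygenic(tr, cov, rel, estimate_h2=False)
        res = lrt_h2(full, null)
        rows.append(
            {
                "probe_id": probe,
                "h2": full.h2,
                "p": res.p,
                "lambda": res.lam,
                "n": full.n_used,
                **{f"b_{k}": v for k, v in full.b.items()},
            }
        )
    return pd.DataFrame(rows)


def _mqtl_scan(mm, inputs, cov, rel, thr):
    variants, vreport = mqtl_mod.genotype_qc(
        inputs.variants.select(
            inputs.variants.snp_ids
        ),
        inputs.pedigree,
        min_call=thr["snp_min_call"],
        min_minor_carriers=thr["min_minor_carriers"],
        hwe_alpha=thr["hwe_alpha"],
    )
    rows_full, rows_top = [], []
    for probe in mm.probes:
        if probe not in inputs.manifest.index:
            continue
        rec = inputs.manifest.loc[probe]
        prox = mqtl_mod.select_proximal_snps(rec, variants, window=thr["cis_window"])
        if prox is None or not len(prox):
            continue
        best = None
        for snp in prox.itertuples():
            try:
                res = mqtl_mod.measured_genotype_test(
                    mm.beta[probe],
                    variants.dosage[snp.snp_id],
                    cov,
                    rel,
                    probe_id=probe,
                    snp_id=snp.snp_id,
                    distance=int(snp.distance),
                )
            except Exception as err:  # monomorphic-in-subset etc.
                log.info("skipping %s x %s: %s", probe, snp.snp_id, err)
                continue
            rows_full.append(
                {
                    "probe_id": probe,
                    "snp_id": snp.snp_id,
                    "maf": float(variants.info.loc[snp.snp_id, "maf"]),
                    "distance": int(snp.distance),
                    "beta_std": res.beta_std,
                    "p": res.p,
                    "n": res.n_used,
                }
            )
            if best is None or res.p < best["p"]:
                best = rows_full[-1]
        if best is not None:
            rows_top.append(best)
    full = pd.DataFrame(rows_full)
    top = pd.DataFrame(rows_top)
    # Li-Ji effective tests per chromosome on the post-QC dosage correlation
    meffs = []
    tested = sorted(set(full["snp_id"])) if len(full) else []
    if tested:
        sub = variants.select(tested)
        for chrom, grp in sub.info.groupby("chrom", sort=True):
            D = sub.dosage[grp.index].to_numpy(dtype=float)
            C = np.corrcoef(D, rowvar=False)
            C = np.atleast_2d(C)
            meffs.append(li_ji_meff(C))
    if len(full):
        thr_cis = (
            thr["alpha"] / sum(meffs) if meffs else thr["alpha"] / len(full)
        )
        full["significant"] = full["p"] < thr_cis
        n_sig = full.groupby("probe_id")["significant"].sum()
        top["n_significant"] = top["probe_id"].map(n_sig).fillna(0).astype(int)
    return top, full, meffs


def _agesex_scan(mm, cov, rel) -> pd.DataFrame:
    rows = []
    for probe in mm.probes:
        tr = mm.beta[probe]
        res_age, b_age = covariate_lrt(tr, cov, rel, "age")
        res_sex, b_sex = covariate_lrt(tr, cov, rel, "sex")
        rows.append(
            {
                "probe_id": probe,
                "beta_age": b_age,
                "p_age": res_age.p,
                "beta_sex": b_sex,
                "p_sex": res_sex.p,
            }
        )
    return pd.DataFrame(rows)


def _obesity_scan(mm, phen, cov, rel) -> pd.DataFrame:
    rows = []
    for trait_name in ("waist", "bmi"):
        if trait_name not in phen.columns:
            continue
        trait = phen[trait_name].astype(float)
        for probe in mm.probes:
            res = mqtl_mod.obesity_covariate_test(
                trait, mm.beta[probe], cov, rel,
                probe_id=probe, trait_name=trait_name,
            )
            rows.append(
                {
                    "probe_id": probe,
                    "trait": trait_name,
                    "beta_std": res.beta_std,
                    "p": res.p,
                    "n": res.n_used,
                }
            )
    return pd.DataFrame(rows)


def _attach_q(df: pd.DataFrame, pcol: str, qcol: str | None = None) -> pd.DataFrame:
    from .correction import tail_area_fdr

    if not len(df) or pcol not in df.columns:
        return df
    q, _ = tail_area_fdr(df[pcol].to_numpy())
    df = df.copy()
    df[qcol or pcol.replace("p", "q", 1)] = q
    return df


def _corrections(herit, mq_full, agesex, obesity, meffs, thr) -> pd.DataFrame:
    rows = []
    alpha = thr["alpha"]
    if len(herit):
        rows.append(
            {
                "scan": "heritability",
                "m": len(herit),
                "meff": len(herit),
                "threshold": bonferroni_threshold(alpha, len(herit)),
                "mode": "bonferroni",
            }
        )
    if len(mq_full):
        meff_total = sum(meffs) if meffs else len(mq_full)
        rows.append(
            {
                "scan": "cis_mqtl",
                "m": len(mq_full),
                "meff": meff_total,
                "threshold": alpha / meff_total
                if thr["threshold_mode"] == "division"
                else 1 - (1 - alpha) ** (1 / meff_total),
                "mode": f"li_ji_{thr['threshold_mode']}",
            }
        )
    for name, df in (("age_sex", agesex), ("obesity", obesity)):
        if len(df):
            m = len(df)
            rows.append(
                {
                    "scan": name,
                    "m": m,
                    "meff": m,
                    "threshold": bonferroni_threshold(alpha, m),
                    "mode": "bonferroni",
                }
            )
    return pd.DataFrame(rows)


def summarize_proportions(
    herit: pd.DataFrame, alpha: float = 0.05, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Tiered significance summary of the heritability scan.

    Rows: nominal (p < alpha), FDR (q < fdr_q), Bonferroni
    (p < alpha/m) tiers with counts, percentages of analyzed probes
    (one decimal, e.g. 27 of 393 -> 6.9) and mean h2 per tier, plus the
    overall mean h2.
    """
    if not len(herit):
        raise ValueError("empty heritability report")
    m = len(herit)
    bonf = bonferroni_threshold(alpha, m)
    tiers = {
        "all": np.ones(m, dtype=bool),
        "nominal": herit["p"].to_numpy() < alpha,
        "fdr": herit["q"].to_numpy() < fdr_q if "q" in herit else np.zeros(m, bool),
        "bonferroni": herit["p"].to_numpy() < bonf,
    }
    rows = []
    for tier, mask in tiers.items():
        n = int(mask.sum())
        rows.append(
            {
                "tier": tier,
                "count": n,
                "of": m,
                "percent": round(100.0 * n / m, 1),
                "mean_h2": float(herit.loc[mask, "h2"].mean()) if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
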