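"""Quality control of methylation-array beta values.

The QC chain mirrors standard practice for bead-array methylation panels:
sample-level filters first (detection-p call rate, coefficient-of-variation
outliers), then probe-level filters (call rate, minimum beta variation,
Lilliefors normality screened at FDR 0.1, autosomal-only). Every stage is
recorded in an auditable :class:`QCReport`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .correction import tail_area_fdr  # noqa: F401  (re-export convenience)
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "MethylationMatrix",
    "ProbeRecord",
    "QCReport",
    "QCError",
    "read_manifest",
    "parse_probe_id",
    "sample_call_rate_filter",
    "cv_outlier_filter",
    "probe_filters",
    "lilliefors_test",
    "annotate_probe_variants",
    "normalize_chrom",
]

SEX_CHROMS = {"X", "Y"}


class QCError(ValueError):
    pass


def normalize_chrom(c) -> str:
    """Map 'chr1'/'1' style names onto a bare convention ('1', 'X', ...)."""
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.upper() in {"X", "Y", "MT", "M"} else s


@dataclass
class MethylationMatrix:
    """Sample x probe beta values with paired detection p-values.

    Beta values are methylation fractions in [0, 1] (NaN = missing);
    detection p-values give the probability each measurement is background
    signal. Both tables share sample index and probe columns.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detection_p.index) or not (
            self.beta.columns.equals(self.detection_p.columns)
        ):
            raise QCError("beta and detection_p must share samples and probes")
        b = self.beta.to_numpy(dtype=float)
        if np.nanmin(b, initial=0.0) < -1e-12 or np.nanmax(b, initial=0.0) > 1 + 1e-12:
            raise QCError("beta values must lie in [0, 1] or be missing")
        d = self.detection_p.to_numpy(dtype=float)
        if np.nanmin(d, initial=0.0) < -1e-12 or np.nanmax(d, initial=0.0) > 1 + 1e-12:
            raise QCError("detection p-values must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.index)

    @property
    def probes(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def select_samples(self, samples) -> "MethylationMatrix":
        return MethylationMatrix(
            self.beta.loc[samples], self.detection_p.loc[samples]
        )

    def select_probes(self, probes) -> "MethylationMatrix":
        return MethylationMatrix(
            self.beta[list(probes)], self.detection_p[list(probes)]
        )

    @classmethod
    def read(cls, beta_path, detection_path) -> "MethylationMatrix":
        """Read paired sample x probe TSVs (first column = sample id)."""
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
        det = pd.read_csv(detection_path, sep="\t", index_col=0)
        return cls(beta, det)

    def write(self, beta_path, detection_path) -> None:
        self.beta.to_csv(beta_path, sep="\t")
        self.detection_p.to_csv(detection_path, sep="\t")


_PROBE_ID_RE = re.compile(r"^(?P<gene>.+)_(?P<pos>[PE]\d+)_(?P<strand>[FR])$")


def parse_probe_id(probe_id: str) -> tuple[str, str, str]:
    """Split a GENE_Position_Strand probe id into its three parts.

    Position is P<offset> (promoter) or E<offset> (exon) relative to the
    transcription start site; strand is F or R.
    """
    m = _PROBE_ID_RE.match(probe_id)
    if m is None:
        raise QCError(
            f"probe id {probe_id!r} does not follow GENE_Position_Strand"
        )
    return m.group("gene"), m.group("pos"), m.group("strand")


@dataclass(frozen=True)
class ProbeRecord:
    """Manifest entry for one CpG probe (1-based coordinates)."""

    probe_id: str
    chrom: str
    cpg_pos: int
    strand: str
    probe_start: int
    probe_end: int

    def __post_init__(self) -> None:
        if not self.probe_start <= self.cpg_pos <= self.probe_end:
            raise QCError(
                f"probe {self.probe_id}: CpG position {self.cpg_pos} outside "
                f"probe interval [{self.probe_start}, {self.probe_end}]"
            )
        parse_probe_id(self.probe_id)

    @property
    def autosomal(self) -> bool:
        return normalize_chrom(self.chrom) not in SEX_CHROMS


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV and validate each record.

    Columns: probe_id, chrom, cpg_pos, strand, probe_start, probe_end.
    Returns a DataFrame indexed by probe_id with an added ``autosomal``
    column. Probes whose coordinates are missing (unannotated) keep NaN
    positions and are flagged non-autosomal-aware downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.set_index("probe_id", drop=False)
    for rec in df.itertuples():
        if pd.notna(rec.cpg_pos):
            ProbeRecord(
                probe_id=rec.probe_id,
                chrom=str(rec.chrom),
                cpg_pos=int(rec.cpg_pos),
                strand=str(rec.strand),
                probe_start=int(rec.probe_start),
                probe_end=int(rec.probe_end),
            )
        else:
            parse_probe_id(rec.probe_id)
    df["autosomal"] = [
        pd.notna(c) and normalize_chrom(c) not in SEX_CHROMS
        for c in df["chrom"]
    ]
    return df


@dataclass
class QCReport:
    """Ordered, conservation-checked record of exclusions.

    Each entry is (filter name, threshold used, items excluded, items
    remaining); remaining counts are non-increasing along the chain.
    """

    axis: str  # "samples" or "probes"
    initial: int
    entries: list[dict] = field(default_factory=list)

    def add(self, name: str, threshold, excluded: int, remaining: int,
            excluded_ids=None) -> None:
        before = self.entries[-1]["remaining"] if self.entries else self.initial
        if before - excluded != remaining:
            raise QCError(
                f"QC bookkeeping error at {name!r}: "
                f"{before} - {excluded} != {remaining}"
            )
        self.entries.append(
            {
                "filter": name,
                "threshold": threshold,
                "excluded": int(excluded),
                "remaining": int(remaining),
                "excluded_ids": list(excluded_ids) if excluded_ids is not None else [],
            }
        )
        log.info(
            "QC %s | %s (threshold=%s): excluded %d, %d remaining",
            self.axis, name, threshold, excluded, remaining,
        )

    @property
    def final(self) -> int:
        return self.entries[-1]["remaining"] if self.entries else self.initial

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["filter", "threshold", "excluded", "remaining"]
        )

    def extend(self, other: "QCReport") -> None:
        for e in other.entries:
            self.add(e["filter"], e["threshold"], e["excluded"],
                     e["remaining"], e.get("excluded_ids"))


def sample_call_rate_filter(
    mm: MethylationMatrix,
    detect_alpha: float = 0.05,
    min_rate: float = 0.90,
    report: QCReport | None = None,
) -> tuple[MethylationMatrix, QCReport]:
    """Drop samples whose detection call rate falls below ``min_rate``.

    A probe is "called" in a sample when its detection p-value is below
    ``detect_alpha``; the call rate is the called fraction across probes.
    """
    det = mm.detection_p.to_numpy(dtype=float)
    rates = np.nanmean((det < detect_alpha) & np.isfinite(det), axis=1)
    keep = rates >= min_rate
    if report is None:
        report = QCReport(axis="samples", initial=len(mm.samples))
    report.add(
        "sample_call_rate",
        f">={min_rate} at detection p<{detect_alpha}",
        int((~keep).sum()),
        int(keep.sum()),
    )
    if not keep.any():
        raise QCError("empty cohort: every sample failed the call-rate filter")
    kept = [s for s, k in zip(mm.samples, keep) if k]
    return mm.select_samples(kept), report


def cv_outlier_filter(
    mm: MethylationMatrix,
    upper_pct: float = 97.5,
    report: QCReport | None = None,
) -> tuple[MethylationMatrix, QCReport]:
    """Drop samples whose beta coefficient of variation is extreme.

    CV = sd(beta over probes) / mean(beta over probes) per sample; samples
    strictly above the ``upper_pct`` empirical percentile (linear
    interpolation between order statistics) are removed. With ties at the
    cut (e.g. identical samples) nothing strictly exceeds it and nothing is
    removed.
    """
    if len(mm.samples) < 2:
        raise QCError("CV filter needs at least two samples")
    b = mm.beta.to_numpy(dtype=float)
    means = np.nanmean(b, axis=1)
    if np.any(means <= 0):
        bad = [s for s, m in zip(mm.samples, means) if m <= 0]
        raise QCError(f"undefined CV (non-positive mean beta) for: {bad}")
    cvs = np.nanstd(b, axis=1, ddof=1) / means
    cut = np.percentile(cvs, upper_pct)  # linear-interpolation quantile
    keep = cvs <= cut
    if report is None:
        report = QCReport(axis="samples", initial=len(mm.samples))
    report.add(
        "sample_cv_outlier",
        f"CV<= {upper_pct}th percentile ({cut:.4g})",
        int((~keep).sum()),
        int(keep.sum()),
    )
    kept = [s for s, k in zip(mm.samples, keep) if k]
    return mm.select_samples(kept), report


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors D statistic.

    Depends only on the sample size: D is invariant to location/scale, so
    standard-normal draws of size n suffice. Cached per (n, n_mc, seed).
    """
    rng = np.random.default_rng(seed)
    stats_out = np.empty(n_mc)
    batch = max(1, min(n_mc, int(2e6) // max(n, 1)))
    i = 0
    grid_lo = np.arange(n) / n
    grid_hi = np.arange(1, n + 1) / n
    while i < n_mc:
        k = min(batch, n_mc - i)
        x = rng.standard_normal((k, n))
        x -= x.mean(axis=1, keepdims=True)
        x /= x.std(axis=1, ddof=1, keepdims=True)
        x.sort(axis=1)
        cdf = stats.norm.cdf(x)
        d = np.maximum(
            np.max(grid_hi - cdf, axis=1), np.max(cdf - grid_lo, axis=1)
        )
        stats_out[i : i + k] = d
        i += k
    return np.sort(stats_out)


def lilliefors_statistic(x: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to Normal(mean-hat, sd-hat)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(n) / n)
    return float(max(d_plus, d_minus))


def lilliefors_test(
    x, n_mc: int = 10000, seed: int = 20130913
) -> tuple[float, float]:
    """Lilliefors normality test with a Monte-Carlo p-value.

    D is the supremum distance between the empirical CDF and the normal CDF
    with estimated mean and sd; the p-value is the fraction of ``n_mc``
    same-size standard-normal samples with D at least as large (with the
    +1 continuity correction, so p is never exactly 0).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise QCError(f"Lilliefors test needs >=4 finite values, got {x.size}")
    if np.std(x, ddof=1) == 0:
        raise QCError("Lilliefors test undefined for zero-variance input")
    d = lilliefors_statistic(x)
    null = _lilliefors_null(int(x.size), int(n_mc), int(seed))
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    return d, float(p)


def probe_filters(
    mm: MethylationMatrix,
    manifest: pd.DataFrame,
    min_call: float = 0.97,
    min_range: float = 0.17,
    lillie_fdr: float = 0.1,
    detect_alpha: float = 0.05,
    n_mc: int = 10000,
    seed: int = 20130913,
) -> tuple[MethylationMatrix, QCReport]:
    """Apply the probe-level QC chain in its fixed order.

    Stages: (1) probe call rate >= ``min_call``; (2) beta variation
    (max - min across non-missing samples) >= ``min_range``; (3) Lilliefors
    normality, retaining probes whose Benjamini-Hochberg q-value is >=
    ``lillie_fdr``; (4) autosomal probes only. Missing betas are ignored
    pairwise-complete. Sample filters are expected to have been applied
    already.
    """
    missing = [p for p in mm.probes if p not in manifest.index]
    if missing:
        raise QCError(f"probes absent from manifest: {missing[:5]}")

    report = QCReport(axis="probes", initial=len(mm.probes))
    cur = mm

    det = cur.detection_p.to_numpy(dtype=float)
    call = np.nanmean((det < detect_alpha) & np.isfinite(det), axis=0)
    keep = call >= min_call
    report.add("probe_call_rate", f">={min_call}", int((~keep).sum()),
               int(keep.sum()), np.array(cur.probes)[~keep])
    cur = cur.select_probes(np.array(cur.probes)[keep])

    b = cur.beta.to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        rng_ = np.nanmax(b, axis=0) - np.nanmin(b, axis=0)
    keep = rng_ >= min_range
    report.add("beta_variation", f">={min_range}", int((~keep).sum()),
               int(keep.sum()), np.array(cur.probes)[~keep])
    cur = cur.select_probes(np.array(cur.probes)[keep])

    pvals = np.array(
        [
            lilliefors_test(cur.beta[p].to_numpy(), n_mc=n_mc, seed=seed)[1]
            for p in cur.probes
        ]
    )
    q = multipletests(pvals, method="fdr_bh")[1]
    keep = q >= lillie_fdr
    report.add(
        "lilliefors_normality",
        f"BH q>={lillie_fdr}",
        int((~keep).sum()),
        int(keep.sum()),
        np.array(cur.probes)[~keep],
    )
    cur = cur.select_probes(np.array(cur.probes)[keep])

    keep = manifest.loc[cur.probes, "autosomal"].to_numpy(dtype=bool)
    report.add("autosomal_only", "chrom not in {X,Y}", int((~keep).sum()),
               int(keep.sum()), np.array(cur.probes)[~keep])
    cur = cur.select_probes(np.array(cur.probes)[keep])

    return cur, report


def annotate_probe_variants(
    manifest: pd.DataFrame, variants: pd.DataFrame, maf_flag: float = 0.05
) -> pd.DataFrame:
    """Annotate probes with known variants falling inside the probe body.

    ``variants`` needs columns chrom, pos (1-based), maf. Returns one row
    per probe: variant count, distance of the nearest variant to the CpG
    (bp), maximum MAF among overlapping variants, and a flag set when any
    overlapping variant has MAF > ``maf_flag`` (such probes may report
    genotype rather than methylation). Chromosome naming conventions are
    normalized ('chr1' == '1').
    """
    v = variants.copy()
    v["chrom"] = v["chrom"].map(normalize_chrom)
    rows = []
    for rec in manifest.itertuples():
        if pd.isna(rec.cpg_pos):
            rows.append(
                {
                    "probe_id": rec.probe_id,
                    "n_variants": 0,
                    "min_distance_bp": np.nan,
                    "max_maf": np.nan,
                    "flag_maf_gt_0.05": False,
                }
            )
            continue
        chrom = normalize_chrom(rec.chrom)
        hit = v[
            (v["chrom"] == chrom)
            & (v["pos"] >= int(rec.probe_start))
            & (v["pos"] <= int(rec.probe_end))
        ]
        rows.append(
            {
                "probe_id": rec.probe_id,
                "n_variants": int(len(hit)),
                "min_distance_bp": float(
                    (hit["pos"] - int(rec.cpg_pos)).abs().min()
                )
                if len(hit)
                else np.nan,
                "max_maf": float(hit["maf"].max()) if len(hit) else np.nan,
                "flag_maf_gt_0.05": bool((hit["maf"] > maf_flag).any()),
            }
        )
    return pd.DataFrame(rows).set_index("probe_id", drop=False)
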