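"""Multiple-testing corrections for the methylation scans.

Three flavours are used downstream: plain Bonferroni for the per-probe
heritability and covariate scans; the Li-Ji effective number of independent
tests (eigenvalues of the SNP x SNP dosage correlation matrix, computed per
chromosome and summed) for the cis-mQTL scan; and a tail-area FDR
(Benjamini-Hochberg step-up q-values scaled by Storey's null-proportion
estimate) reported alongside every scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrectionResult",
    "bonferroni_threshold",
    "sidak_threshold",
    "li_ji_meff",
    "combine_meff",
    "tail_area_fdr",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test level alpha/m controlling family-wise error over m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def sidak_threshold(alpha: float, m: float) -> float:
    """Per-test level 1-(1-alpha)^(1/m); exact for independent tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def li_ji_meff(correlation: np.ndarray) -> float:
    """Effective number of independent tests from a correlation matrix.

    Meff = sum_i f(|lambda_i|) with f(x) = I(x >= 1) + (x - floor(x)),
    over the eigenvalues lambda_i of the pairwise correlation matrix.
    A matrix of m duplicated tests (all r = 1) yields Meff = 1; the
    identity yields Meff = m.
    """
    C = np.asarray(correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation must be a square matrix")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.abs(np.linalg.eigvalsh((C + C.T) / 2.0))
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def combine_meff(
    per_chromosome_meffs,
    alpha: float = 0.05,
    threshold_mode: str = "division",
) -> tuple[float, float]:
    """Sum per-chromosome effective test counts into a per-test threshold.

    threshold_mode "division" gives alpha/Meff_total (the convention that
    reproduces printed thresholds in family mQTL reports); "sidak" gives
    the exact 1-(1-alpha)^(1/Meff_total).
    """
    meffs = list(per_chromosome_meffs)
    if not meffs:
        raise ValueError("need at least one per-chromosome Meff")
    if any(m < 1 for m in meffs):
        raise ValueError("each per-chromosome Meff must be >= 1")
    total = float(sum(meffs))
    if threshold_mode == "division":
        thr = alpha / total
    elif threshold_mode == "sidak":
        thr = sidak_threshold(alpha, total)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return total, thr


def tail_area_fdr(
    pvalues, lambda_: float = 0.5, eta0: float | None = None
) -> tuple[np.ndarray, float]:
    """Tail-area FDR q-values with an estimated null proportion.

    q-values are Benjamini-Hochberg step-up adjusted p-values multiplied by
    eta0, Storey's estimate of the proportion of true nulls,
    #{p > lambda} / ((1 - lambda) * n), clamped to (0, 1]. Pass ``eta0``
    explicitly to override the estimate. Tests with q < 0.05 form the
    "FDR of 5%" significant set.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if eta0 is None:
        # p >= lambda (not >): boundary-mixture LRT p-values have a null
        # atom at exactly 0.5, which must count as null evidence
        eta0 = np.mean(p >= lambda_) / (1.0 - lambda_)
        eta0 = float(min(1.0, max(eta0, 1.0 / p.size)))
    q_bh = multipletests(p, method="fdr_bh")[1]
    q = np.minimum(q_bh * eta0, 1.0)
    return q, float(eta0)


@dataclass
class CorrectionResult:
    """Summary of the multiple-testing correction applied to one scan."""

    m: int
    alpha: float = 0.05
    meff_per_chromosome: list[float] = field(default_factory=list)
    meff_total: float | None = None
    threshold_division: float | None = None
    threshold_sidak: float | None = None
    q_values: np.ndarray | None = None
    eta0: float | None = None

    @classmethod
    def from_scan(
        cls,
        pvalues,
        alpha: float = 0.05,
        meff_per_chromosome=None,
    ) -> "CorrectionResult":
        p = np.asarray(pvalues, dtype=float)
        meffs = list(meff_per_chromosome) if meff_per_chromosome else []
        m_eff = float(sum(meffs)) if meffs else float(p.size)
        q, eta0 = tail_area_fdr(p)
        return cls(
            m=int(p.size),
            alpha=alpha,
            meff_per_chromosome=meffs,
            meff_total=m_eff,
            threshold_division=alpha / m_eff,
            threshold_sidak=sidak_threshold(alpha, m_eff),
            q_values=q,
            eta0=eta0,
        )
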