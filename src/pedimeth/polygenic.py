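"""Polygenic variance-components models on pedigrees.

The trait model is t_i = m + sum_k b_k x_ik + g_i + e_i with additive
genetic effects g ~ MVN(0, sigma_g^2 A) and residuals e ~ MVN(0,
sigma_e^2 I), where A is the additive relationship matrix. Narrow-sense
heritability is h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

Fitting is by maximum likelihood via a single eigendecomposition of A:
rotating the data by the eigenvectors diagonalizes the covariance, so the
likelihood profile over h2 reduces to a cheap 1-D optimization with
closed-form generalized-least-squares estimates of the fixed effects and
the total variance at every candidate h2. ML (not REML) is used throughout
so that nested models are compared by likelihood-ratio tests: the
heritability test uses the boundary mixture null 1/2 chi2_0 + 1/2 chi2_1,
covariate tests use chi2_1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .pedigree import RelationshipMatrix

log = logging.getLogger(__name__)

__all__ = [
    "PolygenicFit",
    "LRTResult",
    "EigenA",
    "FitError",
    "default_covariates",
    "fit_polygenic",
    "lrt_h2",
    "covariate_lrt",
    "heritability_power",
]

_H2_MAX = 1.0 - 1e-6
_GRID_SIZE = 64


class FitError(ValueError):
    pass


@dataclass
class PolygenicFit:
    """ML estimates for one polygenic model fit."""

    m: float  # intercept (mean trait value at covariates = 0)
    b: pd.Series  # covariate coefficients
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    n_used: int
    ids: list[str]
    covariate_names: list[str]

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested polygenic models."""

    lam: float  # 2 * (loglik_full - loglik_null), clamped at 0
    df: int
    p: float
    null_type: str  # "mixture_boundary" | "chisq"


def default_covariates(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Build the standard covariate set: sex, age, age2 and interactions.

    ``phenotypes`` must carry ``age`` (years) and ``sex`` (coded so female
    is the higher level: 'female'/'male', 2/1 or 1/0). Sex enters as a
    female indicator, so positive sex coefficients mean higher values in
    females; age is mean-centered before squaring for conditioning (this
    changes no test and no standardized effect).
    """
    sex_raw = phenotypes["sex"]
    if sex_raw.dtype == object:
        female = sex_raw.astype(str).str.lower().map(
            {"female": 1.0, "f": 1.0, "2": 1.0, "male": 0.0, "m": 0.0, "1": 0.0}
        )
    else:
        female = (sex_raw == sex_raw.max()).astype(float) if sex_raw.nunique() > 1 else sex_raw * 0.0
    age = phenotypes["age"].astype(float)
    age_c = age - age.mean()
    out = pd.DataFrame(
        {
            "sex": female.astype(float),
            "age": age_c,
            "age2": age_c**2,
            "sex_age": female * age_c,
            "sex_age2": female * age_c**2,
        },
        index=phenotypes.index,
    )
    return out


class EigenA:
    """Cached eigendecomposition of an additive relationship matrix.

    Reused across the many per-probe fits that share one pedigree.
    """

    def __init__(self, rel: RelationshipMatrix, psd_tol: float = 1e-6):
        lam, U = np.linalg.eigh(rel.A)
        if lam[0] < -psd_tol:
            raise FitError(
                f"relationship matrix is not PSD (min eigenvalue {lam[0]:.3g})"
            )
        self.ids = list(rel.ids)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U


def _prepare(trait, covariates, rel):
    """Align trait/covariates/A on shared ids, dropping incomplete samples."""
    if not isinstance(trait, pd.Series):
        trait = pd.Series(np.asarray(trait, dtype=float), index=rel.ids)
    if covariates is None:
        covariates = pd.DataFrame(index=trait.index)
    elif not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(
            np.asarray(covariates, dtype=float), index=trait.index
        )
    ids = [i for i in rel.ids if i in trait.index and i in covariates.index]
    sub = pd.concat([trait.loc[ids].rename("__t"), covariates.loc[ids]], axis=1)
    sub = sub.dropna()
    ids = list(sub.index)
    y = sub["__t"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(ids))] + [sub[c].to_numpy(dtype=float) for c in covariates.columns]
    )
    names = ["intercept"] + list(covariates.columns)
    return y, X, names, ids


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise FitError(f"collinear covariate columns: {bad}")


def _profile_loglik(h2, ys, Xs, lam):
    """Profile ML log-likelihood at fixed h2 in the rotated basis."""
    n = ys.size
    v = h2 * lam + (1.0 - h2)
    w = 1.0 / v
    Xw = Xs * w[:, None]
    beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    r = ys - Xs @ beta
    s2 = float(np.sum(r * r * w) / n)
    ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(s2) + np.sum(np.log(v)) + n)
    return ll, beta, s2


def fit_polygenic(
    trait,
    covariates,
    rel: RelationshipMatrix,
    estimate_h2: bool = True,
    eigen: EigenA | None = None,
) -> PolygenicFit:
    """Fit the polygenic model by maximum likelihood.

    Samples with missing trait or covariates are dropped listwise (the
    relationship matrix is subset to match). With ``estimate_h2`` False the
    genetic variance is fixed at zero, giving the null model for the
    heritability LRT. Pass a precomputed :class:`EigenA` (for the already
    aligned sample set) to amortize the eigendecomposition across probes.
    """
    y, X, names, ids = _prepare(trait, covariates, rel)
    n, p = X.shape
    if n < p + 2:
        raise FitError(f"only {n} complete samples for {p} fixed effects")
    _check_rank(X, names)

    if eigen is not None and eigen.ids == ids:
        lam, U = eigen.lam, eigen.U
    else:
        sub = rel.subset(ids)
        e = EigenA(sub)
        lam, U = e.lam, e.U
    ys = U.T @ y
    Xs = U.T @ X

    if lam.max() - lam.min() < 1e-12:
        log.warning(
            "relationship matrix is (a multiple of) the identity: "
            "h2 is unidentifiable; returning the boundary fit"
        )

    if not estimate_h2:
        h2_hat = 0.0
        ll, beta, s2 = _profile_loglik(0.0, ys, Xs, lam)
    else:
        grid = np.linspace(0.0, _H2_MAX, _GRID_SIZE)
        lls = np.array([_profile_loglik(h, ys, Xs, lam)[0] for h in grid])
        k = int(np.argmax(lls))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, _GRID_SIZE - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda h: -_profile_loglik(h, ys, Xs, lam)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-8},
            )
            h2_hat = float(res.x)
            if -res.fun < lls[k]:  # guard: never worse than the grid point
                h2_hat = float(grid[k])
        else:
            h2_hat = float(grid[k])
        ll, beta, s2 = _profile_loglik(h2_hat, ys, Xs, lam)

    return PolygenicFit(
        m=float(beta[0]),
        b=pd.Series(beta[1:], index=names[1:]),
        sigma_g2=h2_hat * s2,
        sigma_e2=(1.0 - h2_hat) * s2,
        h2=h2_hat,
        loglik=float(ll),
        n_used=n,
        ids=ids,
        covariate_names=names[1:],
    )


def loglik_dense(trait, covariates, rel, sigma_g2, sigma_e2, beta_full):
    """Dense multivariate-normal log-density at given parameters.

    Independent of the eigendecomposition code path; used as an oracle for
    validating the rotated-likelihood fit.
    """
    y, X, _, ids = _prepare(trait, covariates, rel)
    V = sigma_g2 * rel.subset(ids).A + sigma_e2 * np.eye(len(ids))
    r = y - X @ np.asarray(beta_full, dtype=float)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise FitError("covariance not positive definite")
    return float(
        -0.5 * (len(ids) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    )


def lrt_h2(full: PolygenicFit, null: PolygenicFit) -> LRTResult:
    """Boundary-mixture LRT of sigma_g^2 = 0 (h2 = 0).

    Under the null the statistic follows the mixture 1/2 chi2_0 +
    1/2 chi2_1, so p = 0.5 * Pr(chi2_1 > lambda); lambda = 0 gives p = 0.5.
    """
    if full.n_used != null.n_used or full.covariate_names != null.covariate_names:
        raise FitError("full and null fits must use the same samples and covariates")
    lam = 2.0 * (full.loglik - null.loglik)
    if lam < -1e-6:
        raise FitError(
            f"likelihood decreased in the full model (lambda={lam:.3g}); "
            "optimization failure"
        )
    lam = max(lam, 0.0)
    p = 0.5 * float(stats.chi2.sf(lam, df=1)) if lam > 0 else 0.5
    return LRTResult(lam=lam, df=1, p=p, null_type="mixture_boundary")


def covariate_lrt(
    trait,
    covariates: pd.DataFrame,
    rel: RelationshipMatrix,
    target: str,
) -> tuple[LRTResult, float]:
    """Test one covariate by LRT with the polygenic background retained.

    Returns the chi2_1 LRT and the standardized coefficient
    b_hat * sd(x) / sd(t) (positive = trait increases with the covariate,
    e.g. higher methylation with age, or in females for the sex indicator).
    """
    if target not in covariates.columns:
        raise FitError(f"covariate {target!r} not in covariate table")
    y, X, names, ids = _prepare(trait, covariates, rel)
    x = covariates.loc[ids, target].to_numpy(dtype=float)
    if np.nanstd(x) == 0:
        raise FitError(f"covariate {target!r} is constant in the analysis sample")
    full = fit_polygenic(trait, covariates, rel)
    reduced = fit_polygenic(trait, covariates.drop(columns=[target]), rel)
    lam = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(lam, df=1))
    beta_std = float(
        full.b[target] * np.std(x, ddof=1) / np.std(y, ddof=1)
    )
    return LRTResult(lam=lam, df=1, p=max(p, np.finfo(float).tiny), null_type="chisq"), beta_std


def simulate_polygenic_trait(
    eigen: EigenA, h2: float, rng: np.random.Generator, mean: float = 0.0
) -> np.ndarray:
    """Draw one trait with the given heritability on a fixed pedigree."""
    n = eigen.lam.size
    g = eigen.U @ (np.sqrt(eigen.lam) * rng.standard_normal(n))
    e = rng.standard_normal(n)
    return mean + np.sqrt(h2) * g + np.sqrt(1.0 - h2) * e


def heritability_power(
    rel: RelationshipMatrix,
    h2: float,
    alpha: float = 0.05,
    n_reps: int = 500,
    seed: int = 0,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Simulation-based power of the mixture LRT for heritability.

    Simulates ``n_reps`` traits with true heritability ``h2`` on the given
    pedigree, fits full and null models, and reports the fraction rejected
    at level ``alpha`` with a binomial 95% Monte-Carlo CI.
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable power estimate")
    rng = np.random.default_rng(seed)
    eigen = EigenA(rel)
    hits = 0
    for _ in range(n_reps):
        y = simulate_polygenic_trait(eigen, h2, rng)
        tr = pd.Series(y, index=rel.ids)
        full = fit_polygenic(tr, covariates, rel, eigen=eigen)
        null = fit_polygenic(tr, covariates, rel, estimate_h2=False, eigen=eigen)
        if lrt_h2(full, null).p < alpha:
            hits += 1
    power = hits / n_reps
    half = 1.96 * np.sqrt(power * (1.0 - power) / n_reps)
    return {
        "power": power,
        "ci_low": max(0.0, power - half),
        "ci_high": min(1.0, power + half),
        "n_reps": n_reps,
        "h2": h2,
        "alpha": alpha,
    }
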