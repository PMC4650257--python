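"""GRM construction, single-component REML on the observed scale, and
conversion to the liability scale under extreme ascertainment.

The relationship matrix is the centered-and-scaled (GCTA-form) genotype
inner product A_ab = (1/m) sum_j (g_aj - 2 p_j)(g_bj - 2 p_j) / (2 p_j (1 - p_j)).
The variance fraction h2 on the 0/1 scale is estimated by profiling the
REML log-likelihood over h2 in the eigenbasis of A, with a Haseman-Elston
moment cross-check, and re-expressed on the liability scale with the
ascertainment-corrected multiplier K^2 (1-K)^2 / (z^2 P (1-P)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import ExtremeCCError, GenotypeMatrix, ParameterError
from .liability import observed_to_liability_multiplier


def compute_grm(gm: GenotypeMatrix, maf_min: float = 0.0) -> np.ndarray:
    """Centered-scaled genetic relationship matrix over variants with
    MAF >= maf_min (monomorphic variants never contribute). Missing dosages
    are mean-imputed (contributing zero after centering)."""
    if gm.n_samples < 2:
        raise ParameterError("GRM needs at least two samples")
    freq = gm.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    keep = np.nan_to_num(maf) > max(maf_min, 0.0) - 1e-15
    keep &= (freq > 0) & (freq < 1)
    if maf_min > 0:
        keep &= maf >= maf_min
    if keep.sum() == 0:
        raise ParameterError("no variants pass the GRM MAF filter")
    d = gm.dosages_float(impute_mean=True)[:, keep]
    p = freq[keep]
    Z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    return (Z @ Z.T) / keep.sum()


def grm_eig(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the (symmetric) GRM; tiny negative eigenvalues
    from finite m are clipped to zero."""
    vals, vecs = np.linalg.eigh(A)
    if vals.min() < -1e-6 * max(abs(vals).max(), 1.0):
        raise ExtremeCCError("GRM has substantially negative eigenvalues")
    return np.clip(vals, 0.0, None), vecs


def grm_pcs(gm: GenotypeMatrix, n_pcs: int, maf_min: float = 0.05) -> np.ndarray:
    """Top principal components of the common-variant GRM, for covariate use."""
    vals, vecs = grm_eig(compute_grm(gm, maf_min))
    order = np.argsort(vals)[::-1][:n_pcs]
    return vecs[:, order]


@dataclass
class HeritabilityEstimate:
    h2_observed: float
    se_observed: float
    P: float
    K: float
    multiplier: float
    h2_liability: float
    se_liability: float
    h2_he: float  # Haseman-Elston moment cross-check, observed scale
    converged: bool
    clamped: bool = False


def _reml_loglik(h2: float, d: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray) -> float:
    v = h2 * d + (1.0 - h2)
    vinv = 1.0 / v
    XtVX = Xstar.T @ (Xstar * vinv[:, None])
    XtVy = Xstar.T @ (ystar * vinv)
    beta = np.linalg.solve(XtVX, XtVy)
    r = ystar - Xstar @ beta
    n, p = Xstar.shape
    rss = float(r @ (r * vinv))
    sigma2 = rss / (n - p)
    _, logdet_xvx = np.linalg.slogdet(XtVX)
    return -0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(v)) + logdet_xvx)


def reml_h2(grm_eigendecomp: tuple[np.ndarray, np.ndarray], phenotype: np.ndarray,
            covariates: np.ndarray | None = None) -> tuple[float, float, bool]:
    """Single-component REML heritability on the phenotype's own scale.

    The likelihood is profiled over h2 in [0,1) in the GRM eigenbasis and
    maximized by bounded one-dimensional search; the standard error comes
    from the numerical curvature at the optimum. Returns
    (h2, se, converged); boundary estimates are flagged not-converged.
    """
    vals, vecs = grm_eigendecomp
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < 50:
        raise ParameterError("REML needs at least 50 samples")
    if np.var(y) <= 0:
        raise ParameterError("phenotype has zero variance")
    if covariates is None or np.size(covariates) == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, float))])
    ystar = vecs.T @ y
    Xstar = vecs.T @ X

    lo, hi = 1e-6, 1 - 1e-6
    res = minimize_scalar(
        lambda h: -_reml_loglik(h, vals, ystar, Xstar),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-7},
    )
    h2 = float(res.x)
    converged = bool(res.success) and lo * 2 < h2 < hi - 1e-5

    eps = max(1e-4, 1e-3 * h2)
    a, b = max(lo, h2 - eps), min(hi, h2 + eps)
    mid = (a + b) / 2
    ll = [_reml_loglik(x, vals, ystar, Xstar) for x in (a, mid, b)]
    curv = (ll[0] - 2 * ll[1] + ll[2]) / ((b - a) / 2) ** 2
    se = float(1.0 / np.sqrt(-curv)) if curv < 0 else float("nan")
    return h2, se, converged


def haseman_elston_h2(A: np.ndarray, phenotype: np.ndarray,
                      covariates: np.ndarray | None = None) -> float:
    """Moment estimate: regress phenotype cross-products on GRM entries.

    With the (covariate-residualized, standardized) phenotype y, the
    off-diagonal expectation E[y_a y_b] = h2 A_ab, so the regression slope
    estimates h2 on the observed scale.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if covariates is not None and np.size(covariates) > 0:
        X = np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, float))])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ coef
    else:
        y = y - y.mean()
    y = y / y.std()
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    prod = (y[:, None] * y[None, :])[iu]
    denom = float(a @ a)
    if denom <= 0:
        raise ParameterError("GRM off-diagonals are identically zero")
    return float(a @ prod / denom)


def observed_to_liability(h2_observed: float, K: float, P: float) -> tuple[float, bool]:
    """Re-express an observed-scale (0/1) h2 on the liability scale.

    Returns (h2_liability, clamped): estimates exceeding 1 are clamped with
    the flag set (the multiplier is exact only for modest h2).
    """
    mult = observed_to_liability_multiplier(K, P)
    h2_liab = h2_observed * mult
    if h2_liab > 1.0:
        return 1.0, True
    return float(h2_liab), False


def estimate_h2_liability(gm: GenotypeMatrix, pheno, K: float,
                          covariates: np.ndarray | None = None,
                          grm_maf_min: float = 0.0) -> HeritabilityEstimate:
    """End-to-end: GRM -> REML on the 0/1 scale -> liability conversion.

    The liability-scale standard error scales by the same multiplier
    (delta method with K and P treated as fixed).
    """
    pheno = pheno.align_to(gm)
    pheno.require_both_classes()
    A = compute_grm(gm, grm_maf_min)
    eig = grm_eig(A)
    h2_obs, se_obs, converged = reml_h2(eig, pheno.status, covariates)
    h2_he = haseman_elston_h2(A, pheno.status, covariates)
    P = float(np.mean(pheno.status))
    mult = observed_to_liability_multiplier(K, P)
    h2_liab, clamped = observed_to_liability(h2_obs, K, P)
    return HeritabilityEstimate(
        h2_observed=h2_obs, se_observed=se_obs, P=P, K=K, multiplier=mult,
        h2_liability=h2_liab, se_liability=se_obs * mult, h2_he=h2_he,
        converged=converged, clamped=clamped,
    )
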