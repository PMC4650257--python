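"""Per-variant case-control association.

The test is a covariate-adjusted linear score test: phenotype (0/1, treated
linearly) and dosage are each residualized on the covariates plus an
intercept, and the score statistic is chi2_1 = n * corr(resid_y, resid_g)^2.
With no covariates this is the Armitage trend test up to a factor n/(n-1).
Effects are reported for the minor allele (combined-sample MAF <= 0.5), the
orientation the allele-direction (I/D) statistic requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2 as chi2_dist

from .containers import ContractError, GenotypeMatrix, ParameterError, PhenotypeTable
from .liability import selection_intensity

CHI2_NULL_MEDIAN = float(chi2_dist.ppf(0.5, 1))  # 0.4549...


def _with_intercept(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    return np.column_stack([np.ones(n), covariates])


def _residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ coef


def score_test(dosages: np.ndarray, status: np.ndarray,
               covariates: np.ndarray | None = None) -> tuple[float, float, float, int]:
    """Covariate-adjusted linear score test for one variant.

    Returns ``(beta, se, p, n_used)`` computed on complete observations
    (dosage >= 0 and status not NaN). Raises on monomorphic input.
    """
    d = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    ok = (d >= 0) & ~np.isnan(d) & ~np.isnan(y)
    d, y = d[ok], y[ok]
    n = len(d)
    if n == 0 or np.ptp(d) == 0:
        raise ContractError("variant is monomorphic among complete observations")
    if len(np.unique(y)) < 2:
        raise ContractError("phenotype has no variation among complete observations")
    X = _with_intercept(covariates[ok] if covariates is not None else None, n)
    ry = _residualize(y, X)
    rg = _residualize(d, X)
    rgg = float(rg @ rg)
    ryy = float(ry @ ry)
    if rgg <= 0 or ryy <= 0:
        raise ContractError("no residual variation after covariate adjustment")
    beta = float(ry @ rg) / rgg
    r2 = (float(ry @ rg)) ** 2 / (rgg * ryy)
    chi2 = n * r2
    p = float(chi2_dist.sf(chi2, 1))
    dof = max(n - X.shape[1] - 1, 1)
    se = float(np.sqrt(max(ryy - beta**2 * rgg, 0.0) / dof / rgg))
    return beta, se, p, n


def orient_minor(beta: float, allele_freq_combined: float) -> tuple[float, float]:
    """Re-express an alt-allele effect as the minor-allele effect.

    If the combined-sample alt-allele frequency exceeds 0.5 the sign flips
    and maf = 1 - freq; at exactly 0.5 the alt allele is the minor allele by
    convention. Applying the flip twice is the identity.
    """
    if not 0.0 < allele_freq_combined < 1.0:
        raise ContractError("monomorphic variant cannot be oriented")
    if allele_freq_combined > 0.5:
        return -beta, 1.0 - allele_freq_combined
    return beta, allele_freq_combined


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic-control inflation: median association chi2 over the null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ParameterError("no p-values supplied")
    chi2 = chi2_dist.isf(p, 1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


# ----------------------------------------------------------------------
# vectorised scan (the permutation workhorse)


@dataclass
class ScanEngine:
    """Precomputed state for repeated genome-wide score tests.

    Residualizing the genotype matrix on the covariates does not depend on
    the phenotype, so permutation replicates only pay for one matrix-vector
    product per scan. Requires a complete dosage matrix (the synthetic
    cohorts are complete); missing data fall back to the per-variant path in
    :func:`association_scan`.
    """

    G_resid: np.ndarray
    gg: np.ndarray
    X: np.ndarray
    n: int
    testable: np.ndarray

    @classmethod
    def from_matrix(cls, gm: GenotypeMatrix, covariates: np.ndarray | None = None) -> "ScanEngine":
        if gm.missing_mask().any():
            raise ContractError("ScanEngine requires a complete dosage matrix")
        G = gm.dosages.astype(float)
        n = gm.n_samples
        X = _with_intercept(covariates, n)
        coef, *_ = np.linalg.lstsq(X, G, rcond=None)
        G_resid = G - X @ coef
        gg = np.einsum("ij,ij->j", G_resid, G_resid)
        testable = (gg > 1e-12) & (np.ptp(gm.dosages, axis=0) > 0)
        return cls(G_resid=G_resid, gg=gg, X=X, n=n, testable=testable)

    def scan(self, status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (beta, p) for every variant; NaN where not testable."""
        y = np.asarray(status, dtype=float)
        ry = _residualize(y, self.X)
        ryy = float(ry @ ry)
        s = ry @ self.G_resid
        beta = np.full(len(self.gg), np.nan)
        p = np.full(len(self.gg), np.nan)
        t = self.testable
        beta[t] = s[t] / self.gg[t]
        chi2 = self.n * s[t] ** 2 / (self.gg[t] * ryy)
        p[t] = chi2_dist.sf(chi2, 1)
        return beta, p


def association_scan(gm: GenotypeMatrix, pheno: PhenotypeTable,
                     covariates: np.ndarray | None = None,
                     maf_min: float = 0.0) -> pd.DataFrame:
    """Genome-wide single-variant association, minor-allele oriented.

    Returns one row per variant: variant_id, chrom, pos, maf, beta, se,
    p_cc, n_used, testable. Monomorphic variants (or MAF below ``maf_min``)
    carry ``testable=False`` and NaN statistics.
    """
    pheno = pheno.align_to(gm)
    if pheno.is_binary():
        pheno.require_both_classes()
    freq = gm.alt_freq()
    maf = np.minimum(freq, 1 - freq)
    m = gm.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    testable = (maf > max(maf_min, 0.0)) & ~np.isnan(maf) & (maf < 0.5 + 1e-12) & (freq > 0) & (freq < 1)

    complete = not gm.missing_mask().any()
    if complete:
        eng = ScanEngine.from_matrix(gm, covariates)
        testable &= eng.testable
        b_alt, p_all = eng.scan(pheno.status)
        # per-variant se via the OLS formula on residual sums
        y = pheno.status.astype(float)
        ry = _residualize(y, eng.X)
        ryy = float(ry @ ry)
        dof = max(gm.n_samples - eng.X.shape[1] - 1, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            se_all = np.sqrt(np.maximum(ryy - b_alt**2 * eng.gg, 0.0) / dof / eng.gg)
        n_used[:] = gm.n_samples
        sel = testable
        beta[sel], se[sel], p[sel] = b_alt[sel], se_all[sel], p_all[sel]
    else:
        cov = covariates
        for j in np.flatnonzero(testable):
            try:
                beta[j], se[j], p[j], n_used[j] = score_test(
                    gm.dosages[:, j], pheno.status, cov
                )
            except ContractError:
                testable[j] = False

    # orient to the minor allele
    flip = freq > 0.5
    beta = np.where(flip, -beta, beta)

    return pd.DataFrame(
        {
            "variant_id": gm.variant_ids,
            "chrom": gm.variants["chrom"].to_numpy(),
            "pos": gm.variants["pos"].to_numpy(),
            "maf": maf,
            "beta": beta,
            "se": se,
            "p_cc": p,
            "n_used": n_used,
            "testable": testable,
        }
    )


# ----------------------------------------------------------------------
# liability-scale variance explained for a single variant


def _freqs_from_beta(beta: float, maf: float, P: float) -> tuple[float, float]:
    delta = beta * maf * (1 - maf) / (P * (1 - P))
    p_case = maf + (1 - P) * delta
    p_ctrl = maf - P * delta
    return p_case, p_ctrl


def _freqs_from_or(or_: float, maf: float, P: float) -> tuple[float, float]:
    def f(p_ctrl: float) -> float:
        odds = or_ * p_ctrl / (1 - p_ctrl)
        p_case = odds / (1 + odds)
        return P * p_case + (1 - P) * p_ctrl - maf

    lo, hi = 1e-12, 1 - 1e-12
    p_ctrl = brentq(f, lo, hi)
    odds = or_ * p_ctrl / (1 - p_ctrl)
    return odds / (1 + odds), p_ctrl


def variance_explained_liability(effect: float, maf: float, K: float, P: float,
                                 effect_type: str = "beta") -> float:
    """Liability-scale variance explained by one variant's case-control effect.

    The observed effect is converted to the case/control allele-frequency
    difference it implies, the liability-threshold model is inverted for the
    per-allele liability effect b (frequency shift = b p (1-p) i with
    selection intensity i = phi(T)/K), and q = 2 p (1-p) b^2 on the
    population (control) frequency p.
    """
    if not 0.0 < maf < 1.0:
        raise ParameterError("allele frequency must be in (0,1)")
    if not (0.0 < K < 1.0 and 0.0 < P < 1.0):
        raise ParameterError("K and P must be in (0,1)")
    if maf > 0.5:  # unoriented input: swap the allele labelling (q is invariant)
        effect = -effect if effect_type == "beta" else 1.0 / effect
        maf = 1.0 - maf
    if effect_type == "beta":
        p_case, p_ctrl = _freqs_from_beta(effect, maf, P)
    elif effect_type == "or":
        p_case, p_ctrl = _freqs_from_or(effect, maf, P)
    else:
        raise ParameterError("effect_type must be 'beta' or 'or'")
    if not (0.0 < p_case < 1.0 and 0.0 < p_ctrl < 1.0):
        raise ParameterError("effect implies allele frequency outside (0,1)")
    i = selection_intensity(K)
    b = (p_case - p_ctrl) / (p_ctrl * (1 - p_ctrl) * i)
    q = 2 * p_ctrl * (1 - p_ctrl) * b**2
    return float(min(q, 1.0 - 1e-12))
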