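"""Gene-based rare-variant association.

Three grouping schemes select qualifying rare variants (MAF < 0.01 by
default) per gene by functional class; each gene is then tested with a
CMC-style burden test (collapse to a per-sample minor-allele count and apply
the single-variant score test), a variance-component kernel test (weighted
sum of squared per-variant scores, SKAT-type), and an optimal convex
combination of the two over a grid of mixing parameters rho, calibrated for
the grid minimum by phenotype permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2

from .assoc import _residualize, _with_intercept, score_test
from .containers import ContractError, GenotypeMatrix, ParameterError, PhenotypeTable

SCHEMES = {
    "SG_ESS_NS": ("StopGain", "EssentialSpliceSite", "NonSynonymous"),
    "SG_ESS_PP2": ("StopGain", "EssentialSpliceSite", "NonSynonymous"),
    "SG_ESS": ("StopGain", "EssentialSpliceSite"),
}

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.25, 0.5, 1.0)


@dataclass
class GeneGrouping:
    scheme: str
    rare_maf_max: float
    groups: dict  # gene -> np.ndarray of variant column indices
    excluded: pd.DataFrame  # gene, reason


def group_variants(gm: GenotypeMatrix, scheme: str = "SG_ESS_NS",
                   rare_maf_max: float = 0.01) -> GeneGrouping:
    """Assign rare qualifying variants to genes under one grouping scheme.

    ``SG_ESS_PP2`` additionally requires the damaging flag for NonSynonymous
    variants; StopGain and EssentialSpliceSite always qualify in every
    scheme that lists them. Genes with no qualifying variant are excluded
    with a reason.
    """
    if scheme not in SCHEMES:
        raise ParameterError(f"unknown grouping scheme {scheme!r}")
    classes = SCHEMES[scheme]
    v = gm.variants
    maf = gm.maf()
    qualifies = v["functional_class"].isin(classes).to_numpy()
    if scheme == "SG_ESS_PP2":
        ns = (v["functional_class"] == "NonSynonymous").to_numpy()
        qualifies &= ~ns | v["damaging"].to_numpy().astype(bool)
    qualifies &= np.nan_to_num(maf) < rare_maf_max
    qualifies &= np.nan_to_num(maf) > 0  # monomorphic never informative

    groups: dict = {}
    excluded = []
    for gene, idx in v.groupby("gene", sort=True).groups.items():
        idx = np.asarray(idx)
        sel = idx[qualifies[idx]]
        if len(sel) == 0:
            excluded.append({"gene": gene, "reason": "no_qualifying_variants"})
        else:
            groups[gene] = sel
    return GeneGrouping(scheme, rare_maf_max, groups,
                        pd.DataFrame(excluded, columns=["gene", "reason"]))


def _column_freqs(gm: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Alt-allele frequencies of the selected columns (complete observations)."""
    d = gm.dosages[:, idx].astype(float)
    d[d < 0] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(d, axis=0) / 2.0


def _minor_dosages(gm: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Minor-allele dosages (float, missing -> 0 alleles) for the columns idx."""
    d = gm.dosages[:, idx].astype(float)
    d[d < 0] = 0.0
    flip = _column_freqs(gm, idx) > 0.5
    d[:, flip] = 2.0 - d[:, flip]
    return d


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a,b) density weights on MAF — upweights the rarest variants."""
    return beta_dist.pdf(np.asarray(maf, dtype=float), a, b)


def _parse_weights(weights_spec, maf: np.ndarray) -> np.ndarray:
    if weights_spec is None:
        return np.ones(len(maf))
    if isinstance(weights_spec, str):
        if weights_spec == "unit":
            return np.ones(len(maf))
        if weights_spec.startswith("beta"):
            ab = weights_spec.split(":")[1] if ":" in weights_spec else "1,25"
            a, b = (float(x) for x in ab.split(","))
            return beta_maf_weights(maf, a, b)
        raise ParameterError(f"unknown weights spec {weights_spec!r}")
    w = np.asarray(weights_spec, dtype=float)
    if len(w) != len(maf):
        raise ParameterError("weights length does not match variant count")
    return w


def burden_test(gm: GenotypeMatrix, grouping: GeneGrouping, gene: str,
                pheno: PhenotypeTable, covariates: np.ndarray | None = None,
                weights=None) -> tuple[float, float, float, int]:
    """CMC-style collapse: per-sample (optionally weighted) count of rare
    minor alleles in the gene, tested with the score test.

    Returns (beta, se, p, n_used) of the collapsed count. Zero carriers ->
    ContractError (not-testable).
    """
    if gene not in grouping.groups:
        raise ParameterError(f"gene {gene!r} has no qualifying variants")
    idx = grouping.groups[gene]
    d = _minor_dosages(gm, idx)
    f = _column_freqs(gm, idx)
    w = _parse_weights(weights, np.minimum(f, 1 - f))
    count = d @ w
    if np.ptp(count) == 0:
        raise ContractError(f"gene {gene!r} has no carriers of qualifying alleles")
    return score_test(count, pheno.status, covariates)


def liu_mixture_sf(q: float, lambdas: np.ndarray) -> float:
    """Upper tail of Q ~ sum_k lambda_k chi2_1 by moment matching.

    Matches mean, variance and skewness/kurtosis to a (non)central
    chi-square; exact for a single eigenvalue. Scale-invariant in the
    eigenvalues.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(), 1.0)]
    if len(lam) == 0:
        raise ParameterError("mixture has no positive eigenvalues")
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(ncx2.sf(x, df, delta))
    return float(chi2_dist.sf(x, df))


@dataclass
class _GeneEngine:
    """Scores and null covariance for one gene's qualifying variants."""

    S: np.ndarray          # per-variant scores ry . g_resid
    sigma_g: np.ndarray    # G_resid' G_resid
    w: np.ndarray
    sigma2: float          # ryy / n
    ry: np.ndarray
    G_resid: np.ndarray
    X: np.ndarray
    y: np.ndarray

    @classmethod
    def build(cls, gm, grouping, gene, pheno, covariates, weights) -> "_GeneEngine":
        if gene not in grouping.groups:
            raise ParameterError(f"gene {gene!r} has no qualifying variants")
        idx = grouping.groups[gene]
        d = _minor_dosages(gm, idx)
        keep = np.ptp(d, axis=0) > 0
        if keep.sum() == 0:
            raise ContractError(f"gene {gene!r} has no carriers of qualifying alleles")
        d = d[:, keep]
        f = _column_freqs(gm, idx)[keep]
        maf = np.minimum(f, 1 - f)
        w = _parse_weights(weights if weights is not None else "beta:1,25", maf)
        y = np.asarray(pheno.status, dtype=float)
        n = len(y)
        X = _with_intercept(covariates, n)
        ry = _residualize(y, X)
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        G_resid = d - X @ coef
        sigma_g = G_resid.T @ G_resid
        if np.linalg.cond(X.T @ X) > 1e12:
            raise np.linalg.LinAlgError("singular covariate projection")
        S = G_resid.T @ ry
        sigma2 = float(ry @ ry) / n
        return cls(S, sigma_g, w, sigma2, ry, G_resid, X, y)

    def kernel_q(self, S=None) -> float:
        S = self.S if S is None else S
        return float(np.sum(self.w**2 * S**2))

    def kernel_lambdas(self, sigma2=None) -> np.ndarray:
        s2 = self.sigma2 if sigma2 is None else sigma2
        W = np.diag(self.w)
        return np.linalg.eigvalsh(s2 * W @ self.sigma_g @ W)

    def rho_lambdas(self, rho: float, sigma2=None) -> np.ndarray:
        s2 = self.sigma2 if sigma2 is None else sigma2
        m = len(self.w)
        # sqrt of R_rho = (1-rho) I + rho J, via its two distinct eigenvalues
        r1 = np.sqrt(1 - rho)
        r2 = np.sqrt(1 - rho + rho * m)
        R_half = r1 * np.eye(m) + (r2 - r1) / m * np.ones((m, m))
        W = np.diag(self.w)
        M = R_half @ W @ self.sigma_g @ W @ R_half
        return np.linalg.eigvalsh(s2 * M)

    def rho_q(self, rho: float, S=None) -> float:
        S = self.S if S is None else S
        q_kernel = float(np.sum(self.w**2 * S**2))
        q_burden = float(np.sum(self.w * S)) ** 2
        return (1 - rho) * q_kernel + rho * q_burden


def kernel_test(gm: GenotypeMatrix, grouping: GeneGrouping, gene: str,
                pheno: PhenotypeTable, covariates: np.ndarray | None = None,
                weights_spec="beta:1,25") -> tuple[float, float]:
    """SKAT-type variance-component test: Q = sum_j w_j^2 S_j^2.

    p comes from the moment-matched mixture of chi-squares; for a gene with
    one qualifying variant this collapses to the single-variant score test.
    """
    eng = _GeneEngine.build(gm, grouping, gene, pheno, covariates, weights_spec)
    q = eng.kernel_q()
    p = liu_mixture_sf(q, eng.kernel_lambdas())
    return q, p


def optimal_combination(gm: GenotypeMatrix, grouping: GeneGrouping, gene: str,
                        pheno: PhenotypeTable, covariates: np.ndarray | None = None,
                        rho_grid=DEFAULT_RHO_GRID, weights_spec="beta:1,25",
                        n_perm: int = 2000,
                        rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Optimal burden/kernel combination over a rho grid.

    For each rho, Q_rho = (1-rho) Q_kernel + rho Q_burden (the burden axis is
    the weighted-score burden statistic) with its own mixture p; the minimum
    over the grid is calibrated by phenotype permutation. A single-element
    grid needs no multiplicity correction and returns the analytic p.

    Returns (combined_p, rho_selected).
    """
    rho_grid = tuple(rho_grid)
    if len(rho_grid) == 0:
        raise ParameterError("rho grid is empty")
    if any(not 0.0 <= r <= 1.0 for r in rho_grid):
        raise ParameterError("rho grid values must lie in [0,1]")
    eng = _GeneEngine.build(gm, grouping, gene, pheno, covariates, weights_spec)
    lambdas = {rho: eng.rho_lambdas(rho, sigma2=1.0) for rho in rho_grid}

    def all_p(S: np.ndarray, sigma2: float) -> np.ndarray:
        return np.array(
            [liu_mixture_sf(eng.rho_q(rho, S), sigma2 * lambdas[rho]) for rho in rho_grid]
        )

    p_obs = all_p(eng.S, eng.sigma2)
    rho_selected = float(rho_grid[int(np.argmin(p_obs))])
    min_obs = float(p_obs.min())
    if len(rho_grid) == 1:
        return min_obs, rho_selected

    rng = rng or np.random.default_rng(0)
    n = len(eng.y)
    exceed = 0
    for _ in range(n_perm):
        yp = eng.y[rng.permutation(n)]
        ryp = _residualize(yp, eng.X)
        Sp = eng.G_resid.T @ ryp
        s2p = float(ryp @ ryp) / n
        if all_p(Sp, s2p).min() <= min_obs:
            exceed += 1
    combined_p = (1 + exceed) / (n_perm + 1)
    return float(combined_p), rho_selected


def gene_bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Study-wide per-gene significance threshold alpha / n_genes."""
    if n_genes <= 0:
        raise ParameterError("n_genes must be positive")
    return alpha / n_genes


def gene_scan(gm: GenotypeMatrix, pheno: PhenotypeTable,
              covariates: np.ndarray | None = None, scheme: str = "SG_ESS_NS",
              rare_maf_max: float = 0.01, rho_grid=DEFAULT_RHO_GRID,
              weights_spec="beta:1,25", n_perm: int = 2000,
              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Run burden, kernel and combined tests for every gene with qualifying
    variants; one row per gene."""
    pheno = pheno.align_to(gm)
    grouping = group_variants(gm, scheme, rare_maf_max)
    rng = rng or np.random.default_rng(0)
    rows = []
    for gene, idx in grouping.groups.items():
        row = {"gene": gene, "scheme": scheme, "n_variants": len(idx),
               "burden_p": np.nan, "kernel_Q": np.nan, "kernel_p": np.nan,
               "combined_p": np.nan, "rho_selected": np.nan}
        try:
            _, _, row["burden_p"], _ = burden_test(gm, grouping, gene, pheno, covariates)
            row["kernel_Q"], row["kernel_p"] = kernel_test(
                gm, grouping, gene, pheno, covariates, weights_spec
            )
            row["combined_p"], row["rho_selected"] = optimal_combination(
                gm, grouping, gene, pheno, covariates, rho_grid, weights_spec, n_perm, rng
            )
        except ContractError:
            row["scheme"] = scheme  # not testable: no carriers
        rows.append(row)
    return pd.DataFrame(rows)
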