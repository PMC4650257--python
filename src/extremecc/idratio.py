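"""The increaser/decreaser (I/D) allele-direction statistic.

Among LD-clumped variants passing a nominal association threshold, count
those whose minor allele is at elevated frequency in cases (increasers,
oriented beta > 0) versus controls (decreasers, beta < 0), in cells defined
by MAF bin x p-value threshold. The observed log2(I/D) is compared with its
null distribution from phenotype permutations (case/control counts
preserved; MAF, orientation and LD structure are permutation-invariant, so
clumping adjacency is built once and reused):

    Z = (log2(I/D)_obs - mu) / sigma,     p = upper tail of chi2_1 at Z^2

with mu, sigma the mean and s.d. of the permuted log2 ratios per cell. A
cell where either count is zero uses the +0.5/+0.5 continuity correction
and is flagged; a cell with I = D = 0 contributes no statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .assoc import ScanEngine
from .containers import ContractError, GenotypeMatrix, ParameterError, PhenotypeTable

MAF_BINS = ((0.0, 0.01), (0.01, 0.05), (0.05, 0.15), (0.15, 0.5))
P_THRESHOLDS = (0.01, 0.001)


# ----------------------------------------------------------------------
# LD clumping


@dataclass
class ClumpIndex:
    """Precomputed r^2 adjacency for greedy clumping.

    ``neighbors[j]`` lists the variants on the same chromosome within the
    window whose dosage r^2 with j exceeds the cutoff. r^2 is the squared
    Pearson correlation of (mean-imputed) dosage columns, symmetric, so the
    index serves every permutation replicate.
    """

    neighbors: list
    chrom: np.ndarray
    pos: np.ndarray

    @classmethod
    def build(cls, gm: GenotypeMatrix, r2_max: float = 0.1,
              window: int = 1_000_000) -> "ClumpIndex":
        d = gm.dosages_float(impute_mean=True)
        d = d - d.mean(axis=0)
        norms = np.sqrt(np.einsum("ij,ij->j", d, d))
        chrom = gm.variants["chrom"].to_numpy()
        pos = gm.variants["pos"].to_numpy(np.int64)
        m = gm.n_variants
        order = np.lexsort((pos, chrom))
        neighbors: list = [[] for _ in range(m)]
        for a_ in range(m):
            j = order[a_]
            b_ = a_ + 1
            while b_ < m:
                k = order[b_]
                if chrom[k] != chrom[j] or pos[k] - pos[j] > window:
                    break
                if norms[j] > 0 and norms[k] > 0:
                    r = float(d[:, j] @ d[:, k]) / (norms[j] * norms[k])
                    if r * r > r2_max:
                        neighbors[j].append(k)
                        neighbors[k].append(j)
                b_ += 1
        return cls([np.array(nb, dtype=int) for nb in neighbors], chrom, pos)


def clump(p_values: np.ndarray, index: ClumpIndex,
          candidate_mask: np.ndarray | None = None) -> np.ndarray:
    """Greedy LD clumping: retained variant indices.

    Variants are visited in ascending p (ties broken by chromosome then
    position, so output is deterministic and invariant to input row order);
    each unremoved index variant removes its r^2 > cutoff neighbors within
    the window. NaN p-values are never candidates.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if candidate_mask is not None:
        ok &= candidate_mask
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return idx
    order = idx[np.lexsort((index.pos[idx], index.chrom[idx], p[idx]))]
    removed = np.zeros(len(p), dtype=bool)
    kept = []
    for j in order:
        if removed[j]:
            continue
        kept.append(j)
        nb = index.neighbors[j]
        if len(nb):
            removed[nb] = True
    return np.array(sorted(kept), dtype=int)


# ----------------------------------------------------------------------
# counting and the log2 statistic


def count_id(maf: np.ndarray, beta: np.ndarray, p: np.ndarray,
             maf_bins=MAF_BINS, p_thresholds=P_THRESHOLDS) -> dict:
    """Per-cell (n_snps, I, D) over already-clumped, minor-oriented results.

    A variant enters cell (bin, t) iff maf in (lo, hi] and p < t. I counts
    oriented beta > 0, D counts beta < 0; beta exactly 0 is counted in
    n_snps but in neither direction.
    """
    maf = np.asarray(maf, float)
    beta = np.asarray(beta, float)
    p = np.asarray(p, float)
    if np.nanmax(maf, initial=0.0) > 0.5 + 1e-12:
        raise ContractError("unoriented input: maf > 0.5")
    out = {}
    for lo, hi in maf_bins:
        in_bin = (maf > lo) & (maf <= hi)
        for t in p_thresholds:
            sel = in_bin & (p < t)
            I = int(np.sum(beta[sel] > 0))
            D = int(np.sum(beta[sel] < 0))
            out[((lo, hi), t)] = (int(sel.sum()), I, D)
    return out


def log2_id(I: int, D: int) -> tuple[float, bool]:
    """log2 of the I/D ratio; (+0.5, +0.5) continuity when a count is zero.

    Returns (value, corrected). Raises when I = D = 0 (undefined cell).
    """
    if I < 0 or D < 0:
        raise ParameterError("counts must be non-negative")
    if I == 0 and D == 0:
        raise ParameterError("I/D undefined: both counts zero")
    if I > 0 and D > 0:
        return float(np.log2(I / D)), False
    return float(np.log2((I + 0.5) / (D + 0.5))), True


def z_and_p(obs_log2: float, mu: float, sigma: float) -> tuple[float, float]:
    """Z against the permutation null and the chi2_1 two-tailed p of Z^2."""
    if not sigma > 0:
        raise ParameterError("degenerate permutation null: sigma = 0")
    z = (obs_log2 - mu) / sigma
    return float(z), float(chi2_dist.sf(z * z, 1))


# ----------------------------------------------------------------------
# permutation null


@dataclass
class PermutationNull:
    n_perm: int
    log2_vectors: dict   # cell -> np.ndarray of permuted log2 ratios
    mu: dict
    sigma: dict
    n_corrected: dict    # continuity-corrected permutations per cell
    n_dropped: dict      # permutations with I = D = 0 per cell


def permute_null(gm: GenotypeMatrix, pheno: PhenotypeTable, n_perm: int,
                 rng: np.random.Generator,
                 covariates: np.ndarray | None = None,
                 index: ClumpIndex | None = None,
                 engine: ScanEngine | None = None,
                 maf_bins=MAF_BINS, p_thresholds=P_THRESHOLDS) -> PermutationNull:
    """Null distribution of per-cell log2(I/D) by phenotype permutation.

    Each permutation shuffles case/control labels (case count preserved
    exactly), re-runs the score scan, re-clumps and re-counts. MAF and
    minor-allele orientation are fixed from the genotypes.
    """
    if n_perm < 2:
        raise ParameterError("n_perm must be at least 2 (sigma undefined)")
    pheno = pheno.align_to(gm)
    engine = engine or ScanEngine.from_matrix(gm, covariates)
    index = index or ClumpIndex.build(gm)
    maf = gm.maf()
    y = pheno.status.copy()
    cells = [((lo, hi), t) for lo, hi in maf_bins for t in p_thresholds]
    acc = {c: [] for c in cells}
    n_corr = dict.fromkeys(cells, 0)
    n_drop = dict.fromkeys(cells, 0)
    for _ in range(n_perm):
        yp = y[rng.permutation(len(y))]
        beta, p = engine.scan(yp)
        kept = clump(p, index)
        counts = count_id(maf[kept], beta[kept], p[kept], maf_bins, p_thresholds)
        for c in cells:
            _, I, D = counts[c]
            if I == 0 and D == 0:
                n_drop[c] += 1
                continue
            val, corrected = log2_id(I, D)
            if corrected:
                n_corr[c] += 1
            acc[c].append(val)
    vectors = {c: np.asarray(v) for c, v in acc.items()}
    mu = {c: float(np.mean(v)) if len(v) else float("nan") for c, v in vectors.items()}
    sigma = {c: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
             for c, v in vectors.items()}
    return PermutationNull(n_perm, vectors, mu, sigma, n_corr, n_drop)


# ----------------------------------------------------------------------
# full analysis


def id_ratio_analysis(gm: GenotypeMatrix, pheno: PhenotypeTable,
                      n_perm: int = 1000, seed: int | np.random.Generator = 0,
                      covariates: np.ndarray | None = None,
                      r2_max: float = 0.1, window: int = 1_000_000,
                      maf_bins=MAF_BINS, p_thresholds=P_THRESHOLDS) -> pd.DataFrame:
    """Observed I/D table with permutation Z and p per (MAF bin, threshold) cell.

    Columns mirror the standard report layout: bin, threshold, n_snps,
    observed and expected ratios, observed and expected log2 (with s.d.),
    Z and p, plus audit columns (I, D, continuity flags, dropped
    permutations).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pheno = pheno.align_to(gm)
    pheno.require_both_classes()
    engine = ScanEngine.from_matrix(gm, covariates)
    index = ClumpIndex.build(gm, r2_max, window)
    maf = gm.maf()

    beta, p = engine.scan(pheno.status)
    kept = clump(p, index)
    counts = count_id(maf[kept], beta[kept], p[kept], maf_bins, p_thresholds)
    null = permute_null(gm, pheno, n_perm, rng, covariates, index, engine,
                        maf_bins, p_thresholds)

    rows = []
    for (lo, hi), t in [((lo, hi), t) for lo, hi in maf_bins for t in p_thresholds]:
        cell = ((lo, hi), t)
        n_snps, I, D = counts[cell]
        mu, sigma = null.mu[cell], null.sigma[cell]
        row = {
            "maf_bin": f"({lo:g},{hi:g}]",
            "p_threshold": t,
            "n_snps": n_snps,
            "I": I,
            "D": D,
            "obs_ratio": I / D if D > 0 else np.nan,
            "exp_ratio": 2.0**mu if np.isfinite(mu) else np.nan,
            "obs_log2": np.nan,
            "exp_log2_mean": mu,
            "exp_log2_sd": sigma,
            "z_score": np.nan,
            "p_id": np.nan,
            "corrected": False,
            "n_perm_used": len(null.log2_vectors[cell]),
            "n_perm_dropped": null.n_dropped[cell],
        }
        if I + D > 0:
            row["obs_log2"], row["corrected"] = log2_id(I, D)
            # sigma at floating-point noise level means every permutation hit
            # the same ratio: the null is degenerate, no Z is reported
            if np.isfinite(mu) and np.isfinite(sigma) and sigma > 1e-9:
                row["z_score"], row["p_id"] = z_and_p(row["obs_log2"], mu, sigma)
        rows.append(row)
    return pd.DataFrame(rows)
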