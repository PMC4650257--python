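"""Sample- and variant-level quality control.

Order of operations is fixed: samples are filtered first (call rate,
heterozygosity outliers), then variants (call rate, Hardy-Weinberg exact
test computed in controls only — cases are ascertained on phenotype, so HWE
can be legitimately distorted at trait loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import ContractError, ExtremeCCError, GenotypeMatrix, ParameterError, PhenotypeTable


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate_min: float = 0.95
    variant_call_rate_min: float = 0.99
    hwe_p_min: float = 1e-4
    het_sd_bound: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sample_call_rate_min <= 1.0 and 0.0 <= self.variant_call_rate_min <= 1.0):
            raise ParameterError("call-rate thresholds must be in [0,1]")
        if self.het_sd_bound <= 0:
            raise ParameterError("het_sd_bound must be positive")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ParameterError("hwe_p_min must be in [0,1]")


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic variant.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity as the minor-allele total) whose
    conditional probability does not exceed that of the observed
    configuration. Returns p in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ParameterError("all genotype counts are zero")
    n_minor = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    n_rare_hom = (n_minor - hets) // 2
    n_com_hom = n - hets - n_rare_hom
    valid = n_com_hom >= 0
    hets, n_rare_hom, n_com_hom = hets[valid], n_rare_hom[valid], n_com_hom[valid]

    # log P(het = h | n, n_minor) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_com_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa]
    if len(obs) == 0:
        raise ContractError("observed heterozygote count inconsistent with allele totals")
    p = prob[prob <= obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_p_values(gm: GenotypeMatrix, sample_mask: np.ndarray | None = None) -> np.ndarray:
    """HWE exact p per variant over the selected samples (default: all)."""
    d = gm.dosages if sample_mask is None else gm.dosages[sample_mask]
    out = np.ones(gm.n_variants)
    for j in range(gm.n_variants):
        col = d[:, j]
        obs = col[col >= 0]
        if len(obs) == 0:
            out[j] = np.nan
            continue
        n_aa = int(np.sum(obs == 2))
        n_Aa = int(np.sum(obs == 1))
        n_AA = int(np.sum(obs == 0))
        out[j] = hwe_exact_p(n_AA, n_Aa, n_aa)
    return out


def heterozygosity_rates(gm: GenotypeMatrix, maf_min: float = 0.01) -> np.ndarray:
    """Per-sample heterozygote fraction over variants with MAF > maf_min.

    The MAF restriction stabilises the statistic (rare variants contribute
    almost no heterozygotes).
    """
    maf = gm.maf()
    keep = np.nan_to_num(maf) > maf_min
    if keep.sum() == 0:
        keep = np.ones(gm.n_variants, dtype=bool)
    d = gm.dosages[:, keep]
    called = d >= 0
    n_called = called.sum(axis=1)
    het = (d == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, het / n_called, np.nan)


@dataclass
class QCResult:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    report: pd.DataFrame  # axis, unit_id, reason, value, threshold (+ reserved cols)
    n_samples_in: int
    n_variants_in: int

    def counts_reconcile(self) -> bool:
        rem_s = (self.report["axis"] == "sample").sum()
        rem_v = (self.report["axis"] == "variant").sum()
        return (
            self.n_samples_in == self.genotypes.n_samples + rem_s
            and self.n_variants_in == self.genotypes.n_variants + rem_v
        )


def apply_qc(gm: GenotypeMatrix, pheno: PhenotypeTable,
             th: QCThresholds | None = None) -> QCResult:
    """Filter samples then variants; every removal is logged with its reason.

    Reserved report columns ``cluster_sep`` and ``intensity`` are emitted as
    NaN — array-intensity filters need raw intensity data this pipeline does
    not consume.
    """
    th = th or QCThresholds()
    pheno = pheno.align_to(gm)
    rows: list[dict] = []

    # --- samples
    cr = gm.call_rate_samples()
    drop = cr < th.sample_call_rate_min
    for i in np.flatnonzero(drop):
        rows.append(dict(axis="sample", unit_id=gm.sample_ids[i], reason="call_rate",
                         value=cr[i], threshold=th.sample_call_rate_min))
    het = heterozygosity_rates(gm)
    mu, sd = np.nanmean(het), np.nanstd(het)
    if sd > 0:
        het_out = np.abs(het - mu) > th.het_sd_bound * sd
        for i in np.flatnonzero(het_out & ~drop):
            rows.append(dict(axis="sample", unit_id=gm.sample_ids[i], reason="heterozygosity",
                             value=het[i], threshold=th.het_sd_bound))
        drop |= het_out
    keep_s = ~drop
    if keep_s.sum() == 0:
        raise ExtremeCCError("QC removed every sample")
    gm2 = gm.take_samples(np.flatnonzero(keep_s))
    pheno2 = pheno.take(np.flatnonzero(keep_s))

    # --- variants
    cr_v = gm2.call_rate_variants()
    drop_v = cr_v < th.variant_call_rate_min
    for j in np.flatnonzero(drop_v):
        rows.append(dict(axis="variant", unit_id=gm2.variant_ids[j], reason="call_rate",
                         value=cr_v[j], threshold=th.variant_call_rate_min))
    if pheno2.is_binary() and (pheno2.status == 0).any():
        stratum = pheno2.status == 0  # controls only
    else:
        stratum = np.ones(gm2.n_samples, dtype=bool)
    hwe = hwe_p_values(gm2, stratum)
    hwe_fail = np.nan_to_num(hwe, nan=1.0) < th.hwe_p_min
    for j in np.flatnonzero(hwe_fail & ~drop_v):
        rows.append(dict(axis="variant", unit_id=gm2.variant_ids[j], reason="hwe",
                         value=hwe[j], threshold=th.hwe_p_min))
    drop_v |= hwe_fail
    gm3 = gm2.take_variants(np.flatnonzero(~drop_v))

    report = pd.DataFrame(rows, columns=["axis", "unit_id", "reason", "value", "threshold"])
    report["cluster_sep"] = np.nan
    report["intensity"] = np.nan
    return QCResult(gm3, pheno2, report, gm.n_samples, gm.n_variants)
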