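"""Shared domain containers for the extreme-sampling case-control pipeline.

The substrate of every stage is a samples x variants dosage matrix
(:class:`GenotypeMatrix`) with per-variant metadata, joined against a
phenotype/covariate table (:class:`PhenotypeTable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Missing-dosage sentinel in the int8 dosage matrix.
MISSING = np.int8(-1)

#: Functional-class vocabulary for exonic variants.
FUNCTIONAL_CLASSES = (
    "NonSynonymous",
    "StopGain",
    "StopLoss",
    "StartLoss",
    "EssentialSpliceSite",
    "Synonymous",
    "Other",
)

VARIANT_META_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "functional_class",
    "damaging",
)


class ExtremeCCError(Exception):
    """Base class for pipeline errors."""


class ParameterError(ExtremeCCError):
    """Invalid parameter or configuration value."""


class ContractError(ExtremeCCError):
    """An operation received input violating its preconditions."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNV dosages (alt-allele counts) with per-variant metadata.

    Parameters
    ----------
    sample_ids : array of str, length n
    dosages : int8 array, shape (n_samples, n_variants)
        Values in {0, 1, 2}; missing genotypes are coded ``-1``.
    variants : DataFrame with columns ``variant_id, chrom, pos, ref, alt,
        gene, functional_class, damaging`` (one row per matrix column).
    """

    sample_ids: np.ndarray
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ContractError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ContractError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise ContractError("variants table does not match dosage columns")
        self.variants = self.variants.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        d = self.dosages
        bad = (d < -1) | (d > 2)
        if bad.any():
            raise ContractError("dosage values outside {0,1,2,missing}")
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            dup = vid[vid.duplicated()].iloc[0]
            raise ContractError(f"duplicate variant_id {dup!r}")
        if (self.variants["pos"] <= 0).any():
            raise ContractError("variant positions must be positive")
        trip = self.variants[["chrom", "pos", "alt"]]
        if trip.duplicated().any():
            raise ContractError("duplicate (chrom, pos, alt) triple")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant over complete observations.

        Monomorphic-by-missingness variants (no calls) yield ``nan``.
        """
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def call_rate_variants(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def dosages_float(self, impute_mean: bool = False) -> np.ndarray:
        """Dosages as float with missing as NaN, optionally mean-imputed.

        Mean imputation is used only inside GRM/kernel computations;
        association and MAF use complete observations per variant.
        """
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        if impute_mean:
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids[index], self.dosages[index], self.variants.copy())

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids.copy(),
            self.dosages[:, index],
            self.variants.iloc[np.asarray(index)].reset_index(drop=True),
        )


@dataclass
class PhenotypeTable:
    """Sample phenotype (binary 1=case/0=control or quantitative) plus covariates."""

    sample_ids: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.status = np.asarray(self.status, dtype=float)
        if len(self.status) != len(self.sample_ids):
            raise ContractError("status length does not match sample_ids")
        if len(self.covariates) not in (0, len(self.sample_ids)):
            raise ContractError("covariate rows do not match sample_ids")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def is_binary(self) -> bool:
        vals = np.unique(self.status[~np.isnan(self.status)])
        return np.all(np.isin(vals, (0.0, 1.0)))

    def require_both_classes(self) -> None:
        if not self.is_binary():
            raise ContractError("status is not binary 0/1")
        vals = set(np.unique(self.status))
        if not {0.0, 1.0} <= vals:
            raise ContractError("binary status must contain both cases and controls")

    def covariate_matrix(self) -> np.ndarray:
        if self.covariates.empty:
            return np.empty((self.n_samples, 0))
        return self.covariates.to_numpy(dtype=float)

    def take(self, index: np.ndarray) -> "PhenotypeTable":
        cov = self.covariates.iloc[np.asarray(index)] if not self.covariates.empty else pd.DataFrame()
        return PhenotypeTable(self.sample_ids[index], self.status[index], cov)

    def align_to(self, gm: GenotypeMatrix) -> "PhenotypeTable":
        """Reorder/subset this table to match ``gm.sample_ids`` exactly."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in gm.sample_ids])
        except KeyError as e:  # pragma: no cover - message path
            raise ContractError(f"sample {e.args[0]!r} absent from phenotype table") from None
        return self.take(idx)


# Recognised RunConfig keys and their per-stage meaning (documented key list).
CONFIG_KEYS = {
    "seed": "master random seed recorded in every output header",
    "out_dir": "output directory",
    "sample_call_rate_min": "QC: drop samples below this call rate",
    "variant_call_rate_min": "QC: drop variants below this call rate",
    "hwe_p_min": "QC: drop variants with control-only HWE exact p below this",
    "het_sd_bound": "QC: drop samples with heterozygosity beyond this many s.d.",
    "assoc_maf_min": "association: minimum MAF to test",
    "rare_maf_max": "gene tests: MAF bound for rare qualifying variants",
    "grouping_scheme": "gene tests: SG_ESS_NS | SG_ESS_PP2 | SG_ESS",
    "clump_r2_max": "I/D: r^2 above which a weaker variant is clumped away",
    "clump_window": "I/D: clumping window in bp",
    "n_perm": "I/D: number of phenotype permutations",
    "prevalence": "liability model: population prevalence / selection fraction K",
    "grm_maf_min": "heritability: minimum MAF for GRM variants",
}


@dataclass
class RunConfig:
    """Stage thresholds and the master seed; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "."
    sample_call_rate_min: float = 0.95
    variant_call_rate_min: float = 0.99
    hwe_p_min: float = 1e-4
    het_sd_bound: float = 4.0
    assoc_maf_min: float = 0.0
    rare_maf_max: float = 0.01
    grouping_scheme: str = "SG_ESS_NS"
    clump_r2_max: float = 0.1
    clump_window: int = 1_000_000
    n_perm: int = 1000
    prevalence: float = 0.0003
    grm_maf_min: float = 0.01

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = set(mapping) - set(CONFIG_KEYS)
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    def to_mapping(self) -> dict:
        return {k: getattr(self, k) for k in CONFIG_KEYS}
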