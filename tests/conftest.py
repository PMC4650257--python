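import numpy as np
import pandas as pd
import pytest

from extremecc import GenotypeMatrix, PhenotypeTable, SimParams, simulate_cohort
from extremecc.simulate import VariantFrame


def make_gm(dosages, chrom=None, pos=None, gene=None, fclass=None, damaging=None):
    """Hand-build a GenotypeMatrix from a dosage array."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "ref": ["A"] * m,
            "alt": ["C"] * m,
            "gene": gene if gene is not None else ["G1"] * m,
            "functional_class": fclass if fclass is not None else ["NonSynonymous"] * m,
            "damaging": damaging if damaging is not None else [False] * m,
        }
    )
    return GenotypeMatrix(np.array([f"s{i}" for i in range(n)], dtype=object), d, variants)


def make_frame(p, beta):
    """Hand-build a VariantFrame with given frequencies and effects."""
    p = np.asarray(p, dtype=float)
    beta = np.asarray(beta, dtype=float)
    m = len(p)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": ["chr1"] * m,
            "pos": (np.arange(m) + 1) * 1_000_000,
            "ref": ["A"] * m,
            "alt": ["C"] * m,
            "gene": ["G1"] * m,
            "functional_class": ["NonSynonymous"] * m,
            "damaging": [False] * m,
        }
    )
    return VariantFrame(variants, p, beta)


def binary_pheno(status):
    status = np.asarray(status, dtype=float)
    ids = np.array([f"s{i}" for i in range(len(status))], dtype=object)
    return PhenotypeTable(ids, status)


@pytest.fixture(scope="session")
def null_cohort():
    """Small fully-null cohort (no causal variants, random labels)."""
    params = SimParams(
        n_cases=300, n_controls=300, n_variants=800, n_genes=80,
        h2_liability=0.0, n_causal=0, selection_quantile=0.5, seed=42,
    )
    return simulate_cohort(params, case_mode="pool")


@pytest.fixture(scope="session")
def causal_cohort():
    """Cohort with genetic signal and moderate ascertainment."""
    params = SimParams(
        n_cases=400, n_controls=800, n_variants=1500, n_genes=150,
        h2_liability=0.25, n_causal=150, selection_quantile=0.01, seed=7,
    )
    return simulate_cohort(params, case_mode="pool")
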