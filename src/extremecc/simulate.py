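"""Synthetic cohorts under the additive polygenic liability-threshold model.

The generator emulates the statistical structure an extreme-sampling exome
case-control study assumes: ~10^4-10^5 independent biallelic exonic variants
with a mixed MAF spectrum, gene grouping and functional-class labels, an
additive polygenic liability with specified h2, unselected controls, and
cases ascertained from the upper tail of the liability distribution — either
by exact pool simulation (simulate a population, keep the top K_sel fraction)
or by the first-order analytic frequency tilt that makes extreme fractions
like K_sel = 3e-4 tractable without a multi-million pool.

Optionally, a fraction ``pi_detrimental`` of rare causal minor alleles get a
negative liability effect, producing the allele-direction asymmetry the I/D
statistic is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ParameterError, PhenotypeTable
from .liability import selection_intensity

MAF_CLASSES = {
    "rare": (0.001, 0.01),
    "low": (0.01, 0.05),
    "common": (0.05, 0.5),
}

DEFAULT_CLASS_PROBS = {
    "NonSynonymous": 0.86,
    "StopGain": 0.02,
    "StopLoss": 0.005,
    "StartLoss": 0.005,
    "EssentialSpliceSite": 0.03,
    "Synonymous": 0.06,
    "Other": 0.02,
}


@dataclass
class SimParams:
    """Generative parameters; defaults mirror the study design being emulated.

    ``h2_liability`` is split equally over ``n_causal`` variants
    (q_j = h2/n_causal); the per-minor-allele liability effect is
    b_j = sqrt(q_j / (2 p_j (1-p_j))), negative with probability
    ``pi_detrimental`` when the causal variant is rare (MAF < 0.01) and with
    probability 1/2 otherwise. Cases are ascertained from the upper
    ``selection_quantile`` tail of the liability distribution.
    """

    n_cases: int = 1409
    n_controls: int = 3253
    n_variants: int = 20_000
    n_genes: int = 2_000
    maf_weights: dict = field(
        default_factory=lambda: {"rare": 0.5, "low": 0.2, "common": 0.3}
    )
    h2_liability: float = 0.174
    n_causal: int = 1_000
    pi_detrimental: float = 0.5
    selection_quantile: float = 0.0003
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    damaging_prob: float = 0.3
    n_chrom: int = 22
    clip_tol: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.h2_liability < 1.0:
            raise ParameterError("h2_liability must be in [0,1)")
        if self.n_causal > self.n_variants:
            raise ParameterError("n_causal exceeds n_variants")
        if not 0.0 < self.selection_quantile <= 1.0:
            raise ParameterError("selection_quantile must be in (0,1]")
        for name, (lo, hi) in MAF_CLASSES.items():
            if not (0.0 < lo < hi <= 0.5):
                raise ParameterError(f"bad MAF range for class {name}")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ParameterError("class_probs must sum to 1")

    def child_rngs(self, n: int) -> list:
        """Deterministic per-stage generators spawned from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in ss.spawn(n)]


@dataclass
class VariantFrame:
    """Variant metadata plus population frequencies and true causal effects."""

    variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt, gene, functional_class, damaging
    p: np.ndarray  # population minor-allele frequency per variant
    beta: np.ndarray  # liability effect of the minor allele (0 for non-causal)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def truth_table(self) -> pd.DataFrame:
        causal = self.beta != 0.0
        return pd.DataFrame(
            {
                "variant_id": self.variants.loc[causal, "variant_id"].to_numpy(),
                "maf": self.p[causal],
                "beta_liability": self.beta[causal],
                "q_liability": 2 * self.p[causal] * (1 - self.p[causal]) * self.beta[causal] ** 2,
            }
        )


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    liability: np.ndarray  # per sample; NaN for tilt-mode cases
    truth: pd.DataFrame
    params: SimParams

    def __post_init__(self) -> None:
        n_case = int(np.sum(self.phenotypes.status == 1))
        n_ctrl = int(np.sum(self.phenotypes.status == 0))
        if n_case != self.params.n_cases or n_ctrl != self.params.n_controls:
            raise ParameterError("case/control counts do not match parameters")


# ----------------------------------------------------------------------
# variant frame


def draw_variant_frame(params: SimParams, rng: np.random.Generator | None = None) -> VariantFrame:
    """Draw variant metadata, population frequencies and causal effects.

    Frequencies are uniform within each MAF class range; variants cluster
    into genes laid contiguously along chromosomes so clumping windows are
    meaningful. Effects satisfy sum q_j = h2_liability with equal shares.
    """
    params.validate()
    if rng is None:
        rng = params.child_rngs(1)[0]
    m = params.n_variants

    classes = list(MAF_CLASSES)
    w = np.array([params.maf_weights.get(c, 0.0) for c in classes], dtype=float)
    if w.sum() <= 0:
        raise ParameterError("maf_weights must have positive mass")
    w /= w.sum()
    cls_idx = rng.choice(len(classes), size=m, p=w)
    lo = np.array([MAF_CLASSES[c][0] for c in classes])[cls_idx]
    hi = np.array([MAF_CLASSES[c][1] for c in classes])[cls_idx]
    p = rng.uniform(lo, hi)

    # genes on chromosomes: contiguous gene territories, variants clustered
    gene_chrom = np.arange(params.n_genes) % params.n_chrom + 1
    order = np.argsort(gene_chrom, kind="stable")
    gene_chrom = gene_chrom[order]
    gene_start = np.empty(params.n_genes, dtype=np.int64)
    for c in range(1, params.n_chrom + 1):
        sel = np.where(gene_chrom == c)[0]
        gaps = rng.integers(200_000, 2_000_000, size=len(sel))
        gene_start[sel] = 1 + np.cumsum(gaps)
    gene_of = rng.integers(0, params.n_genes, size=m)

    pos = np.empty(m, dtype=np.int64)
    for g in np.unique(gene_of):
        sel = np.where(gene_of == g)[0]
        offs = rng.choice(50_000, size=len(sel), replace=False)
        pos[sel] = gene_start[g] + np.sort(offs)
    chrom = np.array([f"chr{gene_chrom[g]}" for g in gene_of], dtype=object)

    fclasses = list(params.class_probs)
    fprobs = np.array([params.class_probs[c] for c in fclasses])
    fclass = np.array(fclasses, dtype=object)[rng.choice(len(fclasses), size=m, p=fprobs)]
    damaging = rng.random(m) < params.damaging_prob

    bases = np.array(["A", "C", "G", "T"], dtype=object)
    ref = bases[rng.integers(0, 4, size=m)]
    alt = np.array([bases[(np.flatnonzero(bases != r))[rng.integers(0, 3)]] for r in ref], dtype=object)

    beta = np.zeros(m)
    if params.n_causal > 0 and params.h2_liability > 0:
        causal = rng.choice(m, size=params.n_causal, replace=False)
        q_j = params.h2_liability / params.n_causal
        b = np.sqrt(q_j / (2 * p[causal] * (1 - p[causal])))
        rare = p[causal] < 0.01
        neg_prob = np.where(rare, params.pi_detrimental, 0.5)
        sign = np.where(rng.random(params.n_causal) < neg_prob, -1.0, 1.0)
        beta[causal] = sign * b

    variants = pd.DataFrame(
        {
            "variant_id": [f"var{i:06d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "gene": [f"GENE{g:05d}" for g in gene_of],
            "functional_class": fclass,
            "damaging": damaging,
        }
    )
    order = np.lexsort((pos, np.array([int(c[3:]) for c in chrom])))
    variants = variants.iloc[order].reset_index(drop=True)
    return VariantFrame(variants=variants, p=p[order], beta=beta[order])


# ----------------------------------------------------------------------
# genotype / liability draws


def _liability(geno: np.ndarray, frame: VariantFrame, h2: float,
               rng: np.random.Generator) -> np.ndarray:
    causal = frame.beta != 0.0
    gshift = geno[:, causal] - 2 * frame.p[causal]
    genetic = gshift @ frame.beta[causal]
    e = rng.normal(0.0, np.sqrt(max(1.0 - h2, 0.0)), size=geno.shape[0])
    return genetic + e


def simulate_controls(frame: VariantFrame, n_controls: int,
                      rng: np.random.Generator, h2: float) -> tuple[np.ndarray, np.ndarray]:
    """Unselected samples: genotypes binomial(2, p_j) per variant, liability
    L = sum_j b_j (g_j - 2 p_j) + e with e ~ N(0, 1-h2)."""
    geno = rng.binomial(2, frame.p, size=(n_controls, frame.n_variants)).astype(np.int8)
    liab = _liability(geno, frame, h2, rng)
    return geno, liab


def tilted_case_freq(frame: VariantFrame, K_sel: float, clip_tol: float = 0.02) -> np.ndarray:
    """Expected minor-allele frequency among upper-K_sel-tail cases.

    First-order mean-shift: p_case_j = p_j + b_j p_j (1-p_j) i with
    i = phi(T)/K_sel. Frequencies are clipped into (0,1); an overshoot larger
    than ``clip_tol`` raises, advising smaller per-variant q_j.
    """
    i = selection_intensity(K_sel)
    p_case = frame.p + frame.beta * frame.p * (1 - frame.p) * i
    overshoot = np.maximum(np.maximum(-p_case, p_case - 1.0), 0.0)
    if overshoot.max() > clip_tol:
        j = int(np.argmax(overshoot))
        raise ParameterError(
            f"tilted case frequency {p_case[j]:.4g} for variant "
            f"{frame.variants['variant_id'].iloc[j]} is outside (0,1) beyond "
            f"tolerance; reduce per-variant q_j or use pool-mode ascertainment"
        )
    return np.clip(p_case, 1e-9, 1 - 1e-9)


def simulate_cases_tilted(frame: VariantFrame, n_cases: int, K_sel: float,
                          rng: np.random.Generator, clip_tol: float = 0.02) -> np.ndarray:
    """Analytic-tilt ascertainment: draw case genotypes binomial(2, p_case_j)."""
    p_case = tilted_case_freq(frame, K_sel, clip_tol)
    return rng.binomial(2, p_case, size=(n_cases, frame.n_variants)).astype(np.int8)


def simulate_cases_pool(frame: VariantFrame, n_cases: int, K_sel: float,
                        rng: np.random.Generator, h2: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact ascertainment: simulate a pool of ~n_cases/K_sel unselected
    individuals and keep the n_cases with the highest liability."""
    pool_n = int(np.ceil(n_cases / K_sel))
    geno, liab = simulate_controls(frame, pool_n, rng, h2)
    keep = np.argsort(liab)[::-1][:n_cases]
    return geno[keep], liab[keep]


def simulate_cohort(params: SimParams, case_mode: str = "auto") -> SimulatedCohort:
    """Generate a full case-control cohort.

    ``case_mode``: 'tilt' (analytic frequency shift), 'pool' (exact tail of a
    simulated population) or 'auto' (pool when K_sel >= 0.005, tilt below —
    the pool for K_sel = 3e-4 would need millions of individuals).
    """
    params.validate()
    rng_frame, rng_ctrl, rng_case = params.child_rngs(3)
    frame = draw_variant_frame(params, rng_frame)
    if case_mode == "auto":
        case_mode = "pool" if params.selection_quantile >= 0.005 else "tilt"

    ctrl_geno, ctrl_liab = simulate_controls(frame, params.n_controls, rng_ctrl, params.h2_liability)
    if case_mode == "pool":
        case_geno, case_liab = simulate_cases_pool(
            frame, params.n_cases, params.selection_quantile, rng_case, params.h2_liability
        )
    elif case_mode == "tilt":
        case_geno = simulate_cases_tilted(
            frame, params.n_cases, params.selection_quantile, rng_case, params.clip_tol
        )
        case_liab = np.full(params.n_cases, np.nan)
    else:
        raise ParameterError(f"unknown case_mode {case_mode!r}")

    geno = np.vstack([case_geno, ctrl_geno])
    liab = np.concatenate([case_liab, ctrl_liab])
    sample_ids = np.array(
        [f"case{i:05d}" for i in range(params.n_cases)]
        + [f"ctrl{i:05d}" for i in range(params.n_controls)],
        dtype=object,
    )
    status = np.concatenate([np.ones(params.n_cases), np.zeros(params.n_controls)])
    gm = GenotypeMatrix(sample_ids, geno, frame.variants)
    pheno = PhenotypeTable(sample_ids, status)
    return SimulatedCohort(gm, pheno, liab, frame.truth_table(), params)


# ----------------------------------------------------------------------
# controllable LD for clumping tests


def add_ld_duplicate(gm: GenotypeMatrix, source_id: str, new_id: str,
                     flip_prob: float, rng: np.random.Generator,
                     pos_offset: int = 10_000) -> GenotypeMatrix:
    """Append a copy of one variant's dosage column with flip noise.

    Each sample's genotype is kept with probability 1-flip_prob and redrawn
    from binomial(2, p_source) otherwise, creating a pair with known expected
    r^2 ~= (1-flip_prob)^2 for clumping tests. The default simulator draws
    variants independently (no LD); this is the controllable exception.
    """
    j = int(np.flatnonzero(gm.variant_ids == source_id)[0])
    g = gm.dosages[:, j].copy()
    p = float(np.mean(g) / 2.0)
    redraw = rng.random(len(g)) < flip_prob
    g[redraw] = rng.binomial(2, p, size=int(redraw.sum())).astype(np.int8)
    row = gm.variants.iloc[j].copy()
    row["variant_id"] = new_id
    row["pos"] = int(row["pos"]) + pos_offset
    variants = pd.concat([gm.variants, row.to_frame().T], ignore_index=True)
    dosages = np.column_stack([gm.dosages, g]).astype(np.int8)
    return GenotypeMatrix(gm.sample_ids, dosages, variants)
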