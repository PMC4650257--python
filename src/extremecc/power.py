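"""Analytic power for threshold-selected case-control association.

A variant explaining a fraction q of liability variance shifts its minor
allele frequency in upper-tail cases; the allelic 1-df test of the
case/control frequency difference then has a noncentral chi-square
distribution whose noncentrality gives power. Two case-frequency modes are
provided: the first-order mean-shift (case group mean = selection intensity
phi(T)/K, or an explicit standardized case-mean override for cohorts whose
realised mean exceeds the truncated-normal expectation) and exact
integration over genotype-stratified tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ncx2, norm

from .containers import ParameterError
from .liability import liability_threshold, selection_intensity

__all__ = [
    "PowerSpec", "liability_threshold", "case_allele_freq", "power_cc", "power_table",
]


@dataclass(frozen=True)
class PowerSpec:
    n_cases: int
    n_controls: int
    K_sel: float
    q: float
    maf: float
    alpha: float
    case_mean_override: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q < 1.0:
            raise ParameterError("q must be in [0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0,1)")
        if not 0.0 < self.maf <= 0.5:
            raise ParameterError("maf must be in (0, 0.5]")
        if not 0.0 < self.K_sel < 1.0:
            raise ParameterError("K_sel must be in (0,1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ParameterError("sample sizes must be positive")


def case_allele_freq(maf: float, q: float, K: float,
                     case_mean_override: float | None = None,
                     mode: str = "mean_shift") -> float:
    """Expected minor-allele frequency among upper-K-tail cases.

    mean_shift: p_case = maf + b maf (1-maf) m_case with
    b = sqrt(q / (2 maf (1-maf))) and m_case = phi(T)/K (or the override).
    exact: Bayes inversion over genotype-stratified tail probabilities
    P(case | g) = Phibar((T - b (g - 2 maf)) / sqrt(1 - q)).
    """
    if q == 0.0:
        return maf
    b = np.sqrt(q / (2 * maf * (1 - maf)))
    if mode == "mean_shift":
        m_case = case_mean_override if case_mean_override is not None else selection_intensity(K)
        p_case = maf + b * maf * (1 - maf) * m_case
    elif mode == "exact":
        T = liability_threshold(K)
        g = np.array([0.0, 1.0, 2.0])
        pg = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        tail = norm.sf((T - b * (g - 2 * maf)) / np.sqrt(1 - q))
        p_case = float(np.sum(pg * (g / 2) * tail) / np.sum(pg * tail))
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    if not 0.0 < p_case < 1.0:
        raise ParameterError(
            f"implied case frequency {p_case:.4g} outside (0,1); q too large for this maf/K"
        )
    return float(p_case)


def power_cc(spec: PowerSpec, mode: str = "mean_shift") -> float:
    """Power of the allelic 1-df case/control test at significance alpha.

    ncp = (p_case - maf)^2 / (pbar (1-pbar) (1/(2 n_cases) + 1/(2 n_controls)))
    with pbar the sample-size-weighted mean frequency; power is the upper
    tail of noncentral chi2_1(ncp) beyond the central critical value.
    """
    p_case = case_allele_freq(spec.maf, spec.q, spec.K_sel,
                              spec.case_mean_override, mode)
    n1, n0 = spec.n_cases, spec.n_controls
    pbar = (n1 * p_case + n0 * spec.maf) / (n1 + n0)
    denom = pbar * (1 - pbar) * (1 / (2 * n1) + 1 / (2 * n0))
    ncp = (p_case - spec.maf) ** 2 / denom
    crit = chi2_dist.isf(spec.alpha, 1)
    if ncp == 0.0:
        return float(spec.alpha)
    return float(ncx2.sf(crit, 1, ncp))


def power_table(n_cases: int, n_controls: int, K_sel: float, alpha: float,
                q_grid, maf: float = 0.25,
                case_mean_override: float | None = None,
                mode: str = "mean_shift") -> pd.DataFrame:
    """Power over a grid of liability variance fractions q."""
    rows = []
    for q in q_grid:
        spec = PowerSpec(n_cases, n_controls, K_sel, float(q), maf, alpha,
                         case_mean_override)
        rows.append({"q": float(q), "maf": maf, "power": power_cc(spec, mode)})
    return pd.DataFrame(rows)
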