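"""Liability-threshold model quantities shared by ascertainment, heritability
scale conversion and power.

Liability is a latent standard-normal score; individuals above the threshold
T = Phi^-1(1-K) are cases, where K is the population prevalence (here, the
tail fraction the case cohort was selected from). The selection intensity
i = phi(T)/K is the mean standardized liability of the selected tail.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .containers import ParameterError


def liability_threshold(K: float) -> float:
    """Threshold T with upper-tail mass K: T = Phi^-1(1-K)."""
    if not 0.0 < K < 1.0:
        raise ParameterError(f"prevalence K must be in (0,1), got {K}")
    return float(norm.isf(K))


def selection_intensity(K: float) -> float:
    """Mean standardized liability of the upper-K tail: phi(T)/K."""
    T = liability_threshold(K)
    return float(norm.pdf(T) / K)


@dataclass(frozen=True)
class LiabilityModel:
    """Derived constants of the threshold model at prevalence K."""

    K: float
    T: float
    z: float
    i: float

    @classmethod
    def from_prevalence(cls, K: float) -> "LiabilityModel":
        T = liability_threshold(K)
        z = float(norm.pdf(T))
        return cls(K=K, T=T, z=z, i=z / K)


def observed_to_liability_multiplier(K: float, P: float) -> float:
    """Scale factor taking case-control (0/1) h2 to the liability scale.

    multiplier = K^2 (1-K)^2 / (z^2 P (1-P)) with z the standard-normal
    density at the threshold; P is the sample case fraction. This is the
    ascertainment-corrected transformation for threshold-selected designs.
    """
    if not 0.0 < P < 1.0:
        raise ParameterError(f"case fraction P must be in (0,1), got {P}")
    m = LiabilityModel.from_prevalence(K)
    return (K * (1 - K)) ** 2 / (m.z**2 * P * (1 - P))
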