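"""Additive polygenic model linking allele frequency to BMI and obesity prevalence.

The trait is controlled by ``n_loci`` exchangeable loci sharing a single
pooled frequency of the BMI-raising allele. Each allele copy adds
``effect_per_allele`` kg/m^2. Under the ``haploid_accounting`` convention one
allele slot per locus is counted (so a frequency shift ``dp`` moves the mean
by ``n_loci * effect_per_allele * dp``); under ``diploid`` two slots are
counted and the shift doubles. Phenotypes are the additive genetic score plus
independent normal environmental noise, so prevalence above a BMI threshold
is computed with a normal approximation (valid for >= ~100 loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

HAPLOID_ACCOUNTING = "haploid_accounting"
DIPLOID = "diploid"
_DOSAGE_CONVENTIONS = (HAPLOID_ACCOUNTING, DIPLOID)


@dataclass(frozen=True)
class GeneticArchitecture:
    """Parameters of the additive large-standing-variation architecture.

    Parameters
    ----------
    n_loci : int
        Number of BMI-raising loci (>= 1).
    effect_per_allele : float
        BMI increment per allele copy, kg/m^2 (>= 0).
    baseline_bmi : float
        Population mean BMI at ``reference_freq``, kg/m^2.
    reference_freq : float
        Allele frequency at which the mean equals ``baseline_bmi``.
    dosage_convention : str
        ``"haploid_accounting"`` (one counted slot per locus) or
        ``"diploid"`` (two slots; frequency shifts have doubled effect).
    env_sd : float
        Environmental (non-genetic) phenotype standard deviation, kg/m^2.
    obesity_threshold : float
        BMI above which an individual is classified obese.
    """

    n_loci: int = 1000
    effect_per_allele: float = 0.1
    baseline_bmi: float = 25.0
    reference_freq: float = 0.10
    dosage_convention: str = HAPLOID_ACCOUNTING
    env_sd: float = 3.0
    obesity_threshold: float = 30.0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError(f"n_loci must be >= 1, got {self.n_loci}")
        if not math.isfinite(self.effect_per_allele) or self.effect_per_allele < 0:
            raise ValueError("effect_per_allele must be finite and >= 0")
        if not 0.0 <= self.reference_freq <= 1.0:
            raise ValueError("reference_freq must be in [0, 1]")
        if self.dosage_convention not in _DOSAGE_CONVENTIONS:
            raise ValueError(
                f"dosage_convention must be one of {_DOSAGE_CONVENTIONS}, "
                f"got {self.dosage_convention!r}"
            )
        if not math.isfinite(self.env_sd) or self.env_sd < 0:
            raise ValueError("env_sd must be finite and >= 0")
        if not math.isfinite(self.baseline_bmi):
            raise ValueError("baseline_bmi must be finite")

    @property
    def ploidy_factor(self) -> int:
        """Counted allele slots per locus (1 or 2)."""
        return 2 if self.dosage_convention == DIPLOID else 1


@dataclass(frozen=True)
class AlleleState:
    """Pooled BMI-raising allele frequency at a given generation."""

    freq: float
    generation: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError(f"freq must be in [0, 1], got {self.freq}")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")


def _freq_of(state: "AlleleState | float") -> float:
    freq = state.freq if isinstance(state, AlleleState) else float(state)
    if not 0.0 <= freq <= 1.0:
        raise ValueError(f"frequency must be in [0, 1], got {freq}")
    return freq


def bmi_shift(arch: GeneticArchitecture, delta_freq: float) -> float:
    """Mean-BMI change (kg/m^2) caused by an allele-frequency shift.

    Exactly linear in loci count, per-allele effect and the shift:
    ``n_loci * effect_per_allele * delta_freq`` (doubled under diploid
    accounting).
    """
    delta_freq = float(delta_freq)
    if not math.isfinite(delta_freq):
        raise ValueError("delta_freq must be finite")
    if abs(delta_freq) > 1.0:
        raise ValueError(f"|delta_freq| must be <= 1, got {delta_freq}")
    return arch.ploidy_factor * arch.n_loci * arch.effect_per_allele * delta_freq


def mean_bmi(arch: GeneticArchitecture, state: "AlleleState | float") -> float:
    """Population mean BMI at the given allele frequency."""
    return arch.baseline_bmi + bmi_shift(arch, _freq_of(state) - arch.reference_freq)


def genetic_variance(arch: GeneticArchitecture, state: "AlleleState | float") -> float:
    """Additive genetic variance of BMI: binomial variance across loci.

    ``ploidy * n_loci * p(1-p) * effect^2`` — one binomial slot per counted
    allele, consistent with the dosage convention used by :func:`bmi_shift`.
    """
    p = _freq_of(state)
    return arch.ploidy_factor * arch.n_loci * p * (1.0 - p) * arch.effect_per_allele**2


def phenotype_sd(arch: GeneticArchitecture, state: "AlleleState | float") -> float:
    """Total phenotype SD: genetic variance plus environmental variance."""
    return math.sqrt(genetic_variance(arch, state) + arch.env_sd**2)


def obesity_prevalence(arch: GeneticArchitecture, state: "AlleleState | float") -> float:
    """Fraction of the population with BMI above the obesity threshold.

    Normal approximation: ``1 - Phi((threshold - mean) / sd)``. In the
    degenerate zero-variance case the whole population sits at the mean, so
    the result is 0, 1, or 0.5 (mean exactly at the threshold).
    """
    mu = mean_bmi(arch, state)
    sd = phenotype_sd(arch, state)
    if sd == 0.0:
        if mu > arch.obesity_threshold:
            return 1.0
        if mu < arch.obesity_threshold:
            return 0.0
        return 0.5
    return float(norm.sf((arch.obesity_threshold - mu) / sd))
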