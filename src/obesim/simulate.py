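"""Forward-time trajectories of allele frequency, BMI and obesity prevalence.

A run iterates the balance recursion (deterministic mode) or an
individual-based Wright-Fisher scheme (stochastic mode) across generations.
A mortality-schedule switch at ``transition_generation`` models the
introduction of modern obstetrics; the stabilizing gain is calibrated so the
pre-transition schedule is stationary. Birth-cohort mixing then converts
per-cohort obesity into an adult population prevalence series by calendar
year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .polygenic import GeneticArchitecture, mean_bmi, obesity_prevalence
from .selection import (
    TERMINAL,
    BalanceModel,
    MortalitySchedule,
    balance_update,
    fitness_ratio,
    loss_from_mortality,
)

DETERMINISTIC = "deterministic"
WRIGHT_FISHER = "wright_fisher"
_MODES = (DETERMINISTIC, WRIGHT_FISHER)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a trajectory run.

    ``transition_generation`` is the first generation whose offspring are
    produced under ``post_schedule``; ``transition_year`` anchors that
    generation on the calendar. ``gain`` defaults to the loss implied by the
    pre-transition schedule (stationarity before the transition).
    """

    arch: GeneticArchitecture = field(default_factory=GeneticArchitecture)
    pre_schedule: MortalitySchedule = field(
        default_factory=lambda: MortalitySchedule(lmdr=0.15, neonatal_rate=0.14,
                                                 rr_maternal=4.0, rr_perinatal=4.0)
    )
    post_schedule: MortalitySchedule = field(
        default_factory=lambda: MortalitySchedule(lmdr=0.0001, neonatal_rate=0.003,
                                                  rr_maternal=4.0, rr_perinatal=4.0)
    )
    transition_generation: int = 0
    n_generations: int = 10
    generation_years: float = 25.0
    mode: str = DETERMINISTIC
    pop_size: int = 10_000
    seed: int = 0
    initial_freq: float = 0.10
    convention: str = TERMINAL
    gain: float | None = None
    transition_year: float = 1940.0
    adult_min_age: float = 20.0
    adult_max_age: float = 65.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.initial_freq <= 1.0:
            raise ValueError("initial_freq must be in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == WRIGHT_FISHER and self.pop_size < 2:
            raise ValueError("pop_size must be >= 2 in wright_fisher mode")
        if self.generation_years <= 0:
            raise ValueError("generation_years must be > 0")
        if not 0 <= self.adult_min_age < self.adult_max_age:
            raise ValueError("need 0 <= adult_min_age < adult_max_age")

    def resolved_gain(self) -> float:
        if self.gain is not None:
            return float(self.gain)
        return loss_from_mortality(self.pre_schedule, self.convention)

    def calendar_years(self) -> np.ndarray:
        gens = np.arange(self.n_generations)
        return self.transition_year + (gens - self.transition_generation) * self.generation_years


@dataclass(frozen=True)
class CohortStructure:
    """Per-calendar-year composition of the adult population by birth cohort.

    ``shares[i, g]`` is the fraction of adults in year ``years[i]`` born into
    cohort ``cohorts[g]``; each row sums to 1.
    """

    years: np.ndarray
    cohorts: tuple
    shares: np.ndarray

    def __post_init__(self) -> None:
        shares = np.asarray(self.shares, dtype=float)
        if shares.shape != (len(self.years), len(self.cohorts)):
            raise ValueError("shares must be (n_years, n_cohorts)")
        if np.any(shares < -1e-12):
            raise ValueError("cohort shares must be >= 0")
        if not np.allclose(shares.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("cohort shares must sum to 1 per year")


@dataclass(frozen=True)
class TrajectoryResult:
    """Per-generation series plus the cohort-mixed adult prevalence series."""

    generations: pd.DataFrame  # generation, calendar_year, allele_freq, mean_bmi, cohort_obesity_prevalence
    adult: pd.DataFrame        # calendar_year, adult_obesity_prevalence
    metadata: dict

    def __post_init__(self) -> None:
        freqs = self.generations["allele_freq"].to_numpy()
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")


def cohort_structure(
    config: SimulationConfig, years: np.ndarray | None = None
) -> CohortStructure:
    """Adult-population cohort shares from uniform ages in [min_age, max_age).

    Cohort ``g`` is born uniformly over ``[year_g, year_g + generation_years)``.
    The age window extending before the first simulated cohort is attributed
    to cohort 0 and beyond the last to the final cohort, so shares always sum
    to 1.
    """
    birth_years = config.calendar_years()
    if years is None:
        years = birth_years + config.adult_min_age
    years = np.asarray(years, dtype=float)
    n_cohorts = config.n_generations
    window = config.adult_max_age - config.adult_min_age
    shares = np.zeros((len(years), n_cohorts))
    for i, y in enumerate(years):
        lo, hi = y - config.adult_max_age, y - config.adult_min_age
        for g in range(n_cohorts):
            b_lo = birth_years[g] if g > 0 else -np.inf
            b_hi = birth_years[g] + config.generation_years if g < n_cohorts - 1 else np.inf
            overlap = max(0.0, min(hi, b_hi) - max(lo, b_lo))
            shares[i, g] = overlap / window
    return CohortStructure(years=years, cohorts=tuple(range(n_cohorts)), shares=shares)


def adult_prevalence(
    cohorts: CohortStructure, cohort_rates: "Mapping | Sequence[float]"
) -> np.ndarray:
    """Share-weighted mean of per-cohort obesity rates for each calendar year."""
    if isinstance(cohort_rates, Mapping):
        missing = [c for c in cohorts.cohorts if c not in cohort_rates]
        if missing:
            raise KeyError(f"cohort_rates missing labels: {missing}")
        rates = np.array([cohort_rates[c] for c in cohorts.cohorts], dtype=float)
    else:
        rates = np.asarray(cohort_rates, dtype=float)
        if rates.shape != (len(cohorts.cohorts),):
            raise ValueError(
                f"expected {len(cohorts.cohorts)} cohort rates, got {rates.shape}"
            )
    return cohorts.shares @ rates


def _active_schedule(config: SimulationConfig, generation: int) -> MortalitySchedule:
    if generation >= config.transition_generation:
        return config.post_schedule
    return config.pre_schedule


def _assemble(config: SimulationConfig, freqs: np.ndarray,
              bmis: np.ndarray, prevs: np.ndarray, extra_meta: dict) -> TrajectoryResult:
    years = config.calendar_years()
    generations = pd.DataFrame(
        {
            "generation": np.arange(config.n_generations),
            "calendar_year": years,
            "allele_freq": freqs,
            "mean_bmi": bmis,
            "cohort_obesity_prevalence": prevs,
        }
    )
    structure = cohort_structure(config)
    adult = pd.DataFrame(
        {
            "calendar_year": structure.years,
            "adult_obesity_prevalence": adult_prevalence(structure, prevs),
        }
    )
    metadata = {
        "mode": config.mode,
        "seed": config.seed,
        "gain": config.resolved_gain(),
        "loss_pre": loss_from_mortality(config.pre_schedule, config.convention),
        "loss_post": loss_from_mortality(config.post_schedule, config.convention),
        "transition_generation": config.transition_generation,
        "transition_year": config.transition_year,
        "generation_years": config.generation_years,
        "initial_freq": config.initial_freq,
        "n_generations": config.n_generations,
        "convention": config.convention,
    }
    metadata.update(extra_meta)
    return TrajectoryResult(generations=generations, adult=adult, metadata=metadata)


def deterministic_trajectory(config: SimulationConfig) -> TrajectoryResult:
    """Iterate the balance recursion across the obstetrics transition.

    The loss applied when generation ``g`` reproduces comes from the active
    schedule (post-transition once ``g >= transition_generation``); the gain
    is fixed at its calibrated value throughout.
    """
    gain = config.resolved_gain()
    freqs = np.empty(config.n_generations)
    freqs[0] = config.initial_freq
    for g in range(config.n_generations - 1):
        loss = loss_from_mortality(_active_schedule(config, g), config.convention)
        freqs[g + 1] = balance_update(freqs[g], BalanceModel(gain=gain, loss=loss))
    bmis = np.array([mean_bmi(config.arch, p) for p in freqs])
    prevs = np.array([obesity_prevalence(config.arch, p) for p in freqs])
    return _assemble(config, freqs, bmis, prevs, {})


def wright_fisher_trajectory(config: SimulationConfig) -> TrajectoryResult:
    """Individual-based stochastic counterpart of the deterministic recursion.

    Per generation: each of ``pop_size`` individuals draws a per-locus allele
    count (binomial at the current frequency) and an environmental deviate;
    obesity is assigned by threshold; obese parents are down-weighted by the
    active schedule's fitness ratio. The selection-weighted parental allele
    frequency, inflated by the stabilizing gain, parameterizes the next
    generation's binomial draws — which is the resampling (drift) step.
    Identical seeds give identical output.
    """
    if config.mode != WRIGHT_FISHER:
        config = replace(config, mode=WRIGHT_FISHER)
    rng = np.random.default_rng(config.seed)
    arch = config.arch
    gain = config.resolved_gain()
    slots = arch.ploidy_factor * arch.n_loci  # counted allele slots per individual

    freqs = np.empty(config.n_generations)
    bmis = np.empty(config.n_generations)
    prevs = np.empty(config.n_generations)
    p = config.initial_freq
    for g in range(config.n_generations):
        counts = rng.binomial(slots, p, size=config.pop_size)
        noise = rng.normal(0.0, arch.env_sd, size=config.pop_size)
        phenotypes = (
            arch.baseline_bmi
            + arch.effect_per_allele * (counts - slots * arch.reference_freq)
            + noise
        )
        obese = phenotypes > arch.obesity_threshold
        freqs[g] = counts.mean() / slots
        bmis[g] = phenotypes.mean()
        prevs[g] = obese.mean()

        sched = _active_schedule(config, g)
        w = np.where(obese, fitness_ratio(sched, config.convention), 1.0)
        total_w = w.sum()
        p_sel = float((w @ counts) / (total_w * slots)) if total_w > 0 else 0.0
        p = min(max(p_sel * (1.0 + gain), 0.0), 1.0)
    return _assemble(config, freqs, bmis, prevs, {"pop_size": config.pop_size})


def run(config: SimulationConfig) -> TrajectoryResult:
    """Dispatch on ``config.mode``."""
    if config.mode == WRIGHT_FISHER:
        return wright_fisher_trajectory(config)
    return deterministic_trajectory(config)
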