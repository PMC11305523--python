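"""Childbirth-mortality selection: fitness differentials and the balance update.

Obesity multiplies both the lifetime maternal death rate (LMDR) and
first-month newborn mortality by a relative risk. The resulting deficit in
surviving offspring of obese versus non-obese women is the per-generation
``loss`` of BMI-raising alleles; a free stabilizing ``gain`` opposes it. The
frequency recursion ``p' = p * (1 + gain - loss)`` is stationary when the two
balance and grows geometrically once the mortality loss is relaxed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

TERMINAL = "terminal"
MIDPOINT = "midpoint"
_CONVENTIONS = (TERMINAL, MIDPOINT)


@dataclass(frozen=True)
class MortalitySchedule:
    """Baseline childbirth mortality and the obesity relative risks acting on it.

    ``lmdr`` is the lifetime maternal death rate (probability a woman dies of
    maternal causes over her reproductive life), ``neonatal_rate`` the
    first-month newborn death probability. ``rr_maternal``/``rr_perinatal``
    multiply those baselines for the obese stratum. ``fertility`` is births
    per woman.
    """

    lmdr: float
    neonatal_rate: float
    rr_maternal: float = 1.0
    rr_perinatal: float = 1.0
    fertility: float = 6.0

    def __post_init__(self) -> None:
        for name in ("lmdr", "neonatal_rate"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("rr_maternal", "rr_perinatal", "fertility"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class BalanceModel:
    """Opposed per-generation proportional pressures on the allele pool."""

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gain) and self.gain >= 0.0):
            raise ValueError(f"gain must be finite and >= 0, got {self.gain}")
        if not (math.isfinite(self.loss) and self.loss >= 0.0):
            raise ValueError(f"loss must be finite and >= 0, got {self.loss}")

    @property
    def at_equilibrium(self) -> bool:
        return self.gain == self.loss


def adjusted_rate(base_rate: float, rr: float) -> float:
    """Stratum mortality probability: ``min(base_rate * rr, 1)``."""
    base_rate = float(base_rate)
    rr = float(rr)
    if not (math.isfinite(base_rate) and 0.0 <= base_rate <= 1.0):
        raise ValueError(f"base_rate must be a probability in [0, 1], got {base_rate}")
    if not (math.isfinite(rr) and rr >= 0.0):
        raise ValueError(f"rr must be finite and >= 0, got {rr}")
    return min(base_rate * rr, 1.0)


def _check_convention(convention: str) -> None:
    if convention not in _CONVENTIONS:
        raise ValueError(f"convention must be one of {_CONVENTIONS}, got {convention!r}")


def reproductive_output(
    sched: MortalitySchedule, obese: bool, convention: str = TERMINAL
) -> float:
    """Expected surviving offspring per woman in one stratum.

    With stratum rates ``L*`` (maternal) and ``N*`` (neonatal):

    - ``terminal``: ``fertility * (1 - L*) * (1 - N*)`` — maternal death
      forfeits the whole reproductive output.
    - ``midpoint``: ``fertility * (1 - L*/2) * (1 - N*)`` — maternal death
      occurs on average halfway through the reproductive span.
    """
    _check_convention(convention)
    if obese:
        l_star = adjusted_rate(sched.lmdr, sched.rr_maternal)
        n_star = adjusted_rate(sched.neonatal_rate, sched.rr_perinatal)
    else:
        l_star = sched.lmdr
        n_star = sched.neonatal_rate
    maternal_survival = 1.0 - (l_star / 2.0 if convention == MIDPOINT else l_star)
    return sched.fertility * maternal_survival * (1.0 - n_star)


def fitness_ratio(sched: MortalitySchedule, convention: str = TERMINAL) -> float:
    """Obese-to-non-obese ratio of expected surviving offspring.

    Fertility cancels; the ratio is in [0, 1] whenever both relative risks
    are >= 1.
    """
    denom = reproductive_output(sched, obese=False, convention=convention)
    if denom == 0.0:
        raise ZeroDivisionError(
            "non-obese reproductive output is zero; fitness ratio undefined"
        )
    return reproductive_output(sched, obese=True, convention=convention) / denom


def loss_from_mortality(sched: MortalitySchedule, convention: str = TERMINAL) -> float:
    """Per-generation proportional loss of BMI-raising alleles: ``1 - fitness_ratio``."""
    return 1.0 - fitness_ratio(sched, convention)


def balance_update(freq: float, model: BalanceModel) -> float:
    """One generation of the gain/loss recursion, clamped to [0, 1].

    ``clamp(freq * (1 + gain - loss), 0, 1)``; every frequency is a fixed
    point when ``gain == loss``, and 0 is absorbing.
    """
    freq = float(freq)
    if not (math.isfinite(freq) and 0.0 <= freq <= 1.0):
        raise ValueError(f"freq must be in [0, 1], got {freq}")
    return min(max(freq * (1.0 + model.gain - model.loss), 0.0), 1.0)
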