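"""Time-energy budgets and doubly-labeled-water (DLW) energetics.

A time-energy budget prices each observed behavior in multiples of basal
metabolic rate (BMR) and weights by the proportion of time spent in it:
``E_day = sum_i P_i * E_i`` with ``P_i = N_i / N_tot`` from instantaneous
behavior sampling (out-of-sight records excluded).  The DLW side converts
the differential washout of deuterium and oxygen-18 into CO2 production
with the one-pool model and into energy through a diet-derived
respiratory quotient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .constants import (
    MOLAR_VOLUME_STP,
    ONE_POOL_DIVISOR,
    ONE_POOL_FRACTIONATION,
    SUBSTRATES,
    WATTS_TO_KJ_PER_DAY,
)

#: Behavior costs in multiples of BMR (captive-crane ethogram).
DEFAULT_BEHAVIOR_COSTS: dict[str, float] = {
    "rest_sleep": 1.0,
    "rest_alert": 1.9,
    "forage": 1.95,
    "walk": 3.5,
    "comfort": 1.95,
    "alarm_call": 1.15,
    "unison_call": 1.15,
    "dance": 3.0,
    # Aggregated social category (dance + calls) priced at the call cost.
    "social": 1.15,
}

OUT_OF_SIGHT = "out_of_sight"


@dataclass(frozen=True)
class BehaviorCostTable:
    """Map behavior -> energetic cost in multiples of BMR (all >= 1)."""

    costs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BEHAVIOR_COSTS))

    def __post_init__(self) -> None:
        for name, cost in self.costs.items():
            if cost < 1.0:
                raise ValueError(f"behavior cost below basal for {name!r}")

    def cost(self, behavior: str) -> float:
        try:
            return self.costs[behavior]
        except KeyError:
            raise KeyError(f"behavior {behavior!r} missing from the cost table") from None


def behavior_proportions(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-behavior time proportions from instantaneous-sample counts.

    Out-of-sight observations are excluded from both numerator and
    denominator.  Proportions sum to 1.
    """
    total = sum(n for b, n in counts.items() if b != OUT_OF_SIGHT)
    if total <= 0:
        raise ValueError("no in-sight observations")
    return {b: n / total for b, n in counts.items() if b != OUT_OF_SIGHT}


@dataclass(frozen=True)
class ActivityBudget:
    """One day's behavior proportions (values sum to 1)."""

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"behavior proportions sum to {total}, not 1")

    @classmethod
    def from_percentages(cls, percents: Mapping[str, float]) -> "ActivityBudget":
        """Build from percent-time rows (normalised; rounding tolerated)."""
        total = sum(percents.values())
        if total <= 0:
            raise ValueError("percentages sum to zero")
        return cls({b: v / total for b, v in percents.items()})


def activity_multiplier(
    budget: ActivityBudget, costs: BehaviorCostTable | None = None
) -> float:
    """Behavior-cost-weighted mean activity expenditure, xBMR.

    Reported to two decimals, matching how daily multipliers are tabulated.
    """
    costs = costs or BehaviorCostTable()
    value = sum(p * costs.cost(b) for b, p in budget.proportions.items())
    return round(value, 2)


def whole_day_multiplier(
    active_multiplier: float, active_hours: float = 15.0, rest_hours: float = 9.0
) -> float:
    """Whole-day expenditure multiplier, xBMR, to one decimal.

    The active period (hours with solar radiation) runs at the activity
    multiplier; the nocturnal rest period at 1 x BMR.
    """
    if abs(active_hours + rest_hours - 24.0) > 1e-9:
        raise ValueError("active and rest hours must sum to 24")
    value = (active_multiplier * active_hours + 1.0 * rest_hours) / 24.0
    return round(value, 1)


def daily_ee_kj(multiplier_xbmr: float, bmr_w: float) -> float:
    """Daily energy expenditure, kJ/day, from a whole-day multiplier."""
    if bmr_w <= 0:
        raise ValueError("BMR must be positive")
    return multiplier_xbmr * bmr_w * WATTS_TO_KJ_PER_DAY


# ---------------------------------------------------------------------------
# Doubly-labeled water
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DlwRecord:
    """Isotope-washout record for one individual."""

    k_d: float                     # deuterium decline rate, day^-1
    k_o: float                     # oxygen-18 decline rate, day^-1
    pool_moles: float              # body water pool N, mol
    diet: Mapping[str, float] = field(
        default_factory=lambda: {"carbohydrate": 0.6, "protein": 0.25, "fat": 0.15}
    )

    def __post_init__(self) -> None:
        if self.pool_moles <= 0:
            raise ValueError("body water pool must be positive")
        total = sum(self.diet.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("diet fractions must sum to 1")


def dlw_decline_rates(
    background: float,
    post_dose: float,
    final: float,
    elapsed_days: float,
) -> float:
    """Daily fractional decline rate of one isotope (log-linear washout).

    Enrichments are background-corrected before taking the log ratio;
    the associated half-life is ``ln 2 / k``.
    """
    if elapsed_days <= 0:
        raise ValueError("elapsed time must be positive")
    initial = post_dose - background
    last = final - background
    if initial <= 0 or last <= 0:
        raise ValueError("background-corrected enrichments must be positive")
    return math.log(initial / last) / elapsed_days


def intercept_pool_size(
    dose_moles_water: float,
    dose_enrichment: float,
    intercept_enrichment: float,
    background: float,
) -> float:
    """Body water pool (mol) by the intercept method: isotope dilution of
    the dose against the zero-time intercept of the washout line."""
    excess = intercept_enrichment - background
    if excess <= 0:
        raise ValueError("intercept enrichment must exceed background")
    return dose_moles_water * (dose_enrichment - intercept_enrichment) / excess


def diet_respiratory_quotient(diet: Mapping[str, float]) -> tuple[float, float]:
    """(RQ, kJ per litre CO2) of a substrate mixture given mass fractions."""
    o2 = sum(f * SUBSTRATES[s].o2_l_per_g for s, f in diet.items())
    co2 = sum(f * SUBSTRATES[s].co2_l_per_g for s, f in diet.items())
    energy = sum(f * SUBSTRATES[s].energy_kj_per_g for s, f in diet.items())
    return co2 / o2, energy / co2


def dlw_co2_and_energy(record: DlwRecord) -> tuple[float, float]:
    """(CO2 production mol/day, energy expenditure kJ/day), one-pool model.

    ``rCO2 = (N / 2.078) (k_o - k_d) - 0.0062 k_d N`` with N the body
    water pool in moles; energy via the diet respiratory quotient and the
    energy equivalent of CO2 for that substrate mixture.
    """
    n = record.pool_moles
    if record.k_o < record.k_d:
        warnings.warn(
            "oxygen turnover below deuterium turnover: negative CO2 production",
            stacklevel=2,
        )
    rco2_mol = (n / ONE_POOL_DIVISOR) * (record.k_o - record.k_d) \
        - ONE_POOL_FRACTIONATION * record.k_d * n
    _, kj_per_l_co2 = diet_respiratory_quotient(record.diet)
    energy_kj = rco2_mol * MOLAR_VOLUME_STP * kj_per_l_co2
    return rco2_mol, energy_kj
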