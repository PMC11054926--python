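"""Protein and leucine modeling for maximal resistance-training hypertrophy.

The requirement side uses the consensus rate of 1.6 g protein per kg body
mass per day. The intake (level) side can come from three places: an
explicit value (e.g. a published modeled level), the protein-energy fraction
of the diet applied to the energy requirement (EER * fraction / 4 kcal/g),
or a protein density row of a scaled profile. The two calculation pathways
need not agree — energy fractions and scaled densities are rounded
differently upstream — so the plan records which source was used.

Leucine is derived from total protein via the leucine share of the protein
source (7.1 % for plant proteins, 8.8 % for animal proteins), split evenly
across meals, and checked against the muscle-protein-synthesis trigger
thresholds of 2 g/meal and 8 g/day (four meals). Threshold comparisons are
inclusive and act on reported (rounded) values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from ._rounding import round_half_away
from .energy import AnthropometricProfile, RoundingPolicy
from .errors import DomainError

__all__ = [
    "ProteinConstants",
    "ProteinPlan",
    "protein_requirement",
    "protein_level_from_energy",
    "relative_protein",
    "leucine_daily",
    "leucine_per_meal",
    "evaluate_protein_thresholds",
    "build_protein_plan",
]

LevelSource = Literal["scaled_profile", "pct_energy", "explicit_value"]


@dataclass(frozen=True)
class ProteinConstants:
    """Requirement rates, leucine shares and MPS trigger thresholds."""

    requirement_rate: float = 1.6          # g protein / kg body mass / day
    protein_kcal_per_g: float = 4.0
    meals_per_day: int = 4                 # admissible 3-6 for off-season athletes
    leucine_fraction_plant: float = 0.071
    leucine_fraction_animal: float = 0.088
    leucine_threshold_per_meal: float = 2.0  # g/meal that maximally triggers MPS
    leucine_threshold_daily: float = 8.0     # g/day = per-meal threshold x 4 meals
    issn_leucine_upper: float = 3.0          # g/meal upper recommendation

    def __post_init__(self) -> None:
        for name in (
            "requirement_rate",
            "protein_kcal_per_g",
            "leucine_fraction_plant",
            "leucine_fraction_animal",
            "leucine_threshold_per_meal",
            "leucine_threshold_daily",
            "issn_leucine_upper",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        if not 3 <= self.meals_per_day <= 6:
            raise DomainError(
                f"meals_per_day must lie in [3, 6], got {self.meals_per_day}"
            )


@dataclass(frozen=True)
class ProteinPlan:
    """Daily protein/leucine quantities plus threshold verdicts."""

    requirement_g_day: float
    level_g_day: float
    relative_g_kg_day: float
    leucine_g_day: float
    leucine_g_meal: float
    meals_per_day: int
    level_source: LevelSource = "explicit_value"
    thresholds_met: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "requirement_g_day",
            "level_g_day",
            "relative_g_kg_day",
            "leucine_g_day",
            "leucine_g_meal",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def all_met(self) -> bool:
        return all(self.thresholds_met.values())


def protein_requirement(
    profile: AnthropometricProfile, constants: ProteinConstants = ProteinConstants()
) -> float:
    """Daily protein requirement in g: rate x body mass, integer-rounded."""
    return round_half_away(profile.body_mass * constants.requirement_rate)


def protein_level_from_energy(
    eer: float,
    protein_energy_fraction: float,
    constants: ProteinConstants = ProteinConstants(),
) -> float:
    """Protein level implied by the diet's protein-energy fraction, g/day.

    eer * fraction gives protein calories; dividing by 4 kcal/g gives grams,
    reported to one decimal.
    """
    if eer <= 0:
        raise DomainError(f"eer must be positive, got {eer}")
    if not 0.0 < protein_energy_fraction < 1.0:
        raise DomainError(
            f"protein_energy_fraction must lie in (0, 1), got {protein_energy_fraction}"
        )
    return round_half_away(eer * protein_energy_fraction / constants.protein_kcal_per_g, 1)


def relative_protein(level_g_day: float, profile: AnthropometricProfile) -> float:
    """Protein level relative to body mass, g/kg/day to one decimal."""
    if level_g_day < 0:
        raise DomainError("level_g_day must be non-negative")
    return round_half_away(level_g_day / profile.body_mass, 1)


def leucine_daily(
    protein_g_day: float,
    leucine_fraction: float = 0.071,
    policy: RoundingPolicy = "report_then_propagate",
) -> float:
    """Daily leucine (g) as a fixed share of total protein."""
    if protein_g_day < 0:
        raise DomainError("protein_g_day must be non-negative")
    if not 0.0 < leucine_fraction < 1.0:
        raise DomainError(f"leucine_fraction must lie in (0, 1), got {leucine_fraction}")
    exact = protein_g_day * leucine_fraction
    return round_half_away(exact) if policy == "report_then_propagate" else exact


def leucine_per_meal(leucine_g_day: float, meals_per_day: int = 4) -> float:
    """Leucine per meal (g, two decimals) under an even meal split."""
    if meals_per_day < 1:
        raise DomainError(f"meals_per_day must be >= 1, got {meals_per_day}")
    if leucine_g_day < 0:
        raise DomainError("leucine_g_day must be non-negative")
    return round_half_away(leucine_g_day / meals_per_day, 2)


def evaluate_protein_thresholds(
    plan: ProteinPlan, constants: ProteinConstants = ProteinConstants()
) -> dict[str, bool]:
    """Inclusive (>=) threshold checks on the plan's reported values."""
    return {
        "level_meets_requirement": plan.level_g_day >= plan.requirement_g_day,
        "relative_meets_rate": plan.relative_g_kg_day >= constants.requirement_rate,
        "leucine_daily_meets_threshold": plan.leucine_g_day
        >= constants.leucine_threshold_daily,
        "leucine_per_meal_meets_threshold": plan.leucine_g_meal
        >= constants.leucine_threshold_per_meal,
    }


def build_protein_plan(
    profile: AnthropometricProfile,
    level_g_day: float,
    constants: ProteinConstants = ProteinConstants(),
    leucine_fraction: float | None = None,
    level_source: LevelSource = "explicit_value",
    policy: RoundingPolicy = "report_then_propagate",
) -> ProteinPlan:
    """Assemble the full plan from a daily protein level, whatever its source."""
    fraction = (
        leucine_fraction if leucine_fraction is not None
        else constants.leucine_fraction_plant
    )
    leu_day = leucine_daily(level_g_day, fraction, policy)
    plan = ProteinPlan(
        requirement_g_day=protein_requirement(profile, constants),
        level_g_day=level_g_day,
        relative_g_kg_day=relative_protein(level_g_day, profile),
        leucine_g_day=leu_day,
        leucine_g_meal=leucine_per_meal(leu_day, constants.meals_per_day),
        meals_per_day=constants.meals_per_day,
        level_source=level_source,
    )
    object.__setattr__(plan, "thresholds_met", evaluate_protein_thresholds(plan, constants))
    return plan
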