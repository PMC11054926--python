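"""Energy-requirement model for hypertrophy-phase (bulking) athletes.

The chain is

    RMR  = slope * body_mass + intercept        (linear, bodybuilder-validated)
    TDEE = RMR * PAL
    ES   = TDEE * surplus_fraction
    EER  = TDEE + ES

with RMR in kcal/day, body mass in kg, PAL a dimensionless activity
multiplier and the surplus the hypercaloric margin that supports muscle
accrual. The default equation is the Tinsley bodybuilder equation
(24.8 * mass + 10), validated in male competitive bodybuilders; other linear
equations can be registered via :class:`LinearRmrEquation`.

Two rounding policies are supported. ``report_then_propagate`` rounds RMR to
integer kcal, derives TDEE and ES from the *rounded* RMR, rounds each, and
sums them — the convention that reproduces a published report chain of
2106 -> 553 -> 4239 kcal/day for an 84.5 kg athlete at PAL 1.75 and a 15 %
surplus. ``full_precision`` carries exact floats, so
EER = RMR * PAL * (1 + surplus) holds identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

from ._rounding import round_half_away
from .errors import DomainError

__all__ = [
    "AnthropometricProfile",
    "ActivityParameters",
    "EnergyRequirement",
    "LinearRmrEquation",
    "TINSLEY_BODYBUILDER",
    "RMR_EQUATIONS",
    "PAL_DEFAULT",
    "PAL_ADMISSIBLE",
    "SURPLUS_DEFAULT",
    "SURPLUS_ADMISSIBLE",
    "compute_rmr",
    "compute_tdee",
    "compute_energy_surplus",
    "compute_eer",
    "energy_requirement",
]

log = logging.getLogger(__name__)

RoundingPolicy = Literal["report_then_propagate", "full_precision"]

#: Study defaults: "active" multiplier and mid-range hypercaloric surplus.
PAL_DEFAULT = 1.75
PAL_ADMISSIBLE = (1.60, 1.89)
SURPLUS_DEFAULT = 0.15
SURPLUS_ADMISSIBLE = (0.10, 0.20)


@dataclass(frozen=True)
class AnthropometricProfile:
    """Body mass (kg), age (y) and sex, with optional plausible ranges."""

    body_mass: float
    age: float
    sex: str = "male"
    body_mass_range: tuple[float, float] | None = None
    age_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise DomainError(f"body_mass must be positive, got {self.body_mass}")
        if self.age <= 0:
            raise DomainError(f"age must be positive, got {self.age}")
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name, rng, value in (
            ("body_mass_range", self.body_mass_range, self.body_mass),
            ("age_range", self.age_range, self.age),
        ):
            if rng is not None:
                low, high = rng
                if not (low <= value <= high):
                    raise DomainError(
                        f"{name} ({low}, {high}) does not bracket the value {value}"
                    )


@dataclass(frozen=True)
class ActivityParameters:
    """Physical activity level and fractional energy surplus."""

    pal: float = PAL_DEFAULT
    surplus_fraction: float = SURPLUS_DEFAULT

    def __post_init__(self) -> None:
        if not 1.0 <= self.pal <= 2.5:
            raise DomainError(f"pal must lie in [1.0, 2.5], got {self.pal}")
        if not 0.0 <= self.surplus_fraction <= 0.5:
            raise DomainError(
                f"surplus_fraction must lie in [0, 0.5], got {self.surplus_fraction}"
            )


@dataclass(frozen=True)
class LinearRmrEquation:
    """RMR = slope * body_mass + intercept, with the sexes it was validated in."""

    slope: float
    intercept: float
    name: str = "custom"
    validated_sexes: tuple[str, ...] = ("male", "female")


#: Bodybuilder-validated equation; the package default.
TINSLEY_BODYBUILDER = LinearRmrEquation(
    slope=24.8, intercept=10.0, name="tinsley_bodybuilder", validated_sexes=("male",)
)

#: Registry of named RMR equations usable by the pipeline config.
RMR_EQUATIONS: dict[str, LinearRmrEquation] = {
    TINSLEY_BODYBUILDER.name: TINSLEY_BODYBUILDER,
}


@dataclass(frozen=True)
class EnergyRequirement:
    """Resolved energy chain: RMR, TDEE, surplus (ES) and requirement (EER)."""

    rmr: float
    tdee: float
    es: float
    eer: float
    rounding_policy: RoundingPolicy = "report_then_propagate"

    def __post_init__(self) -> None:
        for name in ("rmr", "tdee", "es", "eer"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")


def _report(value: float, policy: RoundingPolicy) -> float:
    return round_half_away(value) if policy == "report_then_propagate" else value


def compute_rmr(
    profile: AnthropometricProfile,
    equation: LinearRmrEquation = TINSLEY_BODYBUILDER,
    policy: RoundingPolicy = "report_then_propagate",
) -> float:
    """Resting metabolic rate (kcal/day) from a linear body-mass equation.

    Logs a warning (never errors) when the profile's sex is outside the
    equation's validated population, e.g. a female profile with the
    bodybuilder equation.
    """
    if profile.sex not in equation.validated_sexes:
        log.warning(
            "RMR equation %r was validated in %s subjects only; profile sex is %r",
            equation.name,
            "/".join(equation.validated_sexes),
            profile.sex,
        )
    return _report(equation.slope * profile.body_mass + equation.intercept, policy)


def compute_tdee(
    rmr: float,
    activity: ActivityParameters,
    policy: RoundingPolicy = "report_then_propagate",
) -> float:
    """Total daily energy expenditure: RMR scaled by the activity multiplier."""
    if rmr <= 0:
        raise DomainError(f"rmr must be positive, got {rmr}")
    return _report(rmr * activity.pal, policy)


def compute_energy_surplus(
    rmr: float,
    activity: ActivityParameters,
    policy: RoundingPolicy = "report_then_propagate",
) -> float:
    """Hypercaloric surplus: surplus_fraction of TDEE, in kcal/day."""
    if rmr <= 0:
        raise DomainError(f"rmr must be positive, got {rmr}")
    return _report(rmr * activity.pal * activity.surplus_fraction, policy)


def compute_eer(
    rmr: float,
    activity: ActivityParameters,
    policy: RoundingPolicy = "report_then_propagate",
) -> EnergyRequirement:
    """Estimated energy requirement: TDEE + surplus, under the given policy.

    *rmr* is taken as already reported under the same policy (i.e. already an
    integer under ``report_then_propagate``, as :func:`compute_rmr` returns).
    """
    tdee = compute_tdee(rmr, activity, policy)
    es = compute_energy_surplus(rmr, activity, policy)
    return EnergyRequirement(
        rmr=rmr, tdee=tdee, es=es, eer=tdee + es, rounding_policy=policy
    )


def energy_requirement(
    profile: AnthropometricProfile,
    activity: ActivityParameters | None = None,
    equation: LinearRmrEquation = TINSLEY_BODYBUILDER,
    policy: RoundingPolicy = "report_then_propagate",
) -> EnergyRequirement:
    """Convenience: full chain from anthropometrics to EER."""
    activity = activity if activity is not None else ActivityParameters()
    rmr = compute_rmr(profile, equation, policy)
    return compute_eer(rmr, activity, policy)
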