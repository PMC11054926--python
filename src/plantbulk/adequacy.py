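"""Direction-aware adequacy of a scaled diet against nutrient references.

References come in two directions. *Minima* (RDA — Recommended Dietary
Allowance — and AI — Adequate Intake) are met when the scaled intake is at
least the target. *Limits* are met when intake stays below the target:
strictly below for the Dietary Guidelines saturated-fat limit (printed
"<10 % kcal"), at-or-below for the sodium Chronic Disease Risk Reduction
(CDRR) level. Raising an intake can therefore only help a minimum and only
hurt a limit.

Targets may be energy-relative: the fiber AI is defined as 14 g per
1000 kcal, so its target is recomputed from the energy requirement rather
than read from the table. Comparisons act on reported (precision-rounded)
scaled amounts, and profile/reference units must agree per nutrient.
Profile nutrients without a reference (e.g. a calories row) are untargeted,
not failures; reference nutrients absent from the profile are listed as
missing, not failed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._rounding import round_half_away
from .errors import DomainError, FormatError, UnitMismatchError
from .profiles import VALID_UNITS, ScaledProfile

__all__ = [
    "BASES",
    "NutrientReference",
    "AdequacyRow",
    "AdequacyReport",
    "load_references",
    "packaged_references",
    "fiber_ai_for_energy",
    "evaluate_adequacy",
    "summarize",
]

BASES = frozenset({"RDA", "AI", "CDRR", "DGA_limit"})
_LIMIT_BASES = frozenset({"CDRR", "DGA_limit"})


@dataclass(frozen=True)
class NutrientReference:
    """A single target: value, basis, direction, optional energy-relative rule.

    ``energy_relative_rule`` is grams per 1000 kcal; when set, the effective
    target is recomputed from the energy requirement at evaluation time.
    ``strict`` only matters for limits: True compares with <, False with <=.
    """

    nutrient_id: str
    target_value: float
    unit: str
    basis: str
    direction: str
    strict: bool = False
    energy_relative_rule: float | None = None

    def __post_init__(self) -> None:
        if self.target_value <= 0:
            raise DomainError(f"{self.nutrient_id}: target_value must be positive")
        if self.basis not in BASES:
            raise FormatError(
                f"{self.nutrient_id}: unknown basis {self.basis!r}; "
                f"expected one of {sorted(BASES)}"
            )
        if self.unit not in VALID_UNITS:
            raise FormatError(f"{self.nutrient_id}: unknown unit {self.unit!r}")
        expected = "limit" if self.basis in _LIMIT_BASES else "minimum"
        if self.direction != expected:
            raise FormatError(
                f"{self.nutrient_id}: basis {self.basis} requires direction "
                f"{expected!r}, got {self.direction!r}"
            )


@dataclass(frozen=True)
class AdequacyRow:
    nutrient_id: str
    scaled_amount: float
    unit: str
    target_value: float
    basis: str
    direction: str
    met: bool


@dataclass(frozen=True)
class AdequacyReport:
    """Per-nutrient verdicts plus rollup counts and the failure list."""

    rows: tuple[AdequacyRow, ...]
    missing: tuple[str, ...] = ()

    @property
    def n_met(self) -> int:
        return sum(r.met for r in self.rows)

    @property
    def n_not_met(self) -> int:
        return sum(not r.met for r in self.rows)

    @property
    def failures(self) -> tuple[str, ...]:
        return tuple(sorted(r.nutrient_id for r in self.rows if not r.met))


def load_references(path: str | Path | io.TextIOBase) -> tuple[NutrientReference, ...]:
    """Read a reference table (nutrient_id,target,unit,basis,direction,strict,
    energy_relative_rule); rejects duplicates and unknown bases."""
    try:
        table = pd.read_csv(path, dtype={"nutrient_id": str}, comment="#")
    except pd.errors.EmptyDataError:
        return ()
    required = {"nutrient_id", "target", "unit", "basis", "direction", "strict"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise FormatError(f"reference table lacks columns: {sorted(missing_cols)}")

    refs = []
    seen: set[str] = set()
    for row in table.itertuples(index=False):
        if row.nutrient_id in seen:
            raise FormatError(f"duplicate reference for nutrient {row.nutrient_id!r}")
        seen.add(row.nutrient_id)
        rule = getattr(row, "energy_relative_rule", None)
        if rule is None or (isinstance(rule, float) and math.isnan(rule)):
            rule = None
        else:
            rule = float(rule)
        refs.append(
            NutrientReference(
                nutrient_id=row.nutrient_id,
                target_value=float(row.target),
                unit=str(row.unit),
                basis=str(row.basis),
                direction=str(row.direction),
                strict=_parse_bool(row.strict),
                energy_relative_rule=rule,
            )
        )
    return tuple(refs)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def packaged_references(name: str = "dri_male_19_30") -> tuple[NutrientReference, ...]:
    """Reference fixture shipped with the package (adult males 19-30 y)."""
    text = resources.files("plantbulk.data").joinpath(f"{name}.csv").read_text("utf-8")
    return load_references(io.StringIO(text))


def fiber_ai_for_energy(eer: float) -> float:
    """Fiber Adequate Intake at an energy level: 14 g per 1000 kcal, integer g."""
    if eer <= 0:
        raise DomainError(f"eer must be positive, got {eer}")
    return round_half_away(14.0 * eer / 1000.0)


def _effective_target(ref: NutrientReference, eer: float) -> float:
    if ref.energy_relative_rule is not None:
        return round_half_away(ref.energy_relative_rule * eer / 1000.0)
    return ref.target_value


def _meets(amount: float, target: float, direction: str, strict: bool) -> bool:
    if direction == "minimum":
        return amount >= target
    return amount < target if strict else amount <= target


def evaluate_adequacy(
    scaled: ScaledProfile,
    refs: tuple[NutrientReference, ...],
    eer: float,
) -> AdequacyReport:
    """One verdict row per reference nutrient present in the scaled profile."""
    available = {q.nutrient_id: q for q in scaled.scaled}
    rows, missing = [], []
    for ref in refs:
        quantity = available.get(ref.nutrient_id)
        if quantity is None:
            missing.append(ref.nutrient_id)
            continue
        if quantity.unit != ref.unit:
            raise UnitMismatchError(
                f"{ref.nutrient_id}: profile reports {quantity.unit!r} but the "
                f"reference target is in {ref.unit!r}"
            )
        target = _effective_target(ref, eer)
        rows.append(
            AdequacyRow(
                nutrient_id=ref.nutrient_id,
                scaled_amount=quantity.reported_amount,
                unit=quantity.unit,
                target_value=target,
                basis=ref.basis,
                direction=ref.direction,
                met=_meets(quantity.reported_amount, target, ref.direction, ref.strict),
            )
        )
    return AdequacyReport(rows=tuple(rows), missing=tuple(missing))


def summarize(report: AdequacyReport) -> dict:
    """Counts plus the sorted failure list, as a plain serializable record."""
    return {
        "n_rows": len(report.rows),
        "n_met": report.n_met,
        "n_not_met": report.n_not_met,
        "failures": list(report.failures),
        "missing": sorted(report.missing),
    }
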