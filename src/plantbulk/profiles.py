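"""Per-reference-energy nutrient-density profiles and proportional scaling.

A :class:`DietProfile` expresses a dietary pattern as nutrient densities per
a fixed reference energy (here, per 2000 kcal/day, the convention of the
AHS-2 cohort tables), together with energy-fraction descriptors (protein and
saturated fat as % of calories) and the leucine share of protein.

Scaling a profile to a target energy intake multiplies every mass-unit
density by ``target_energy / reference_energy`` and leaves energy-fraction
(``pct_kcal``) entries untouched — eating proportionally more of the same
diet changes amounts, not composition. Scaled amounts are reported at each
nutrient's display precision with ties rounded away from zero.

Profiles round-trip through a small CSV dialect: ``# key = value`` metadata
lines, then a ``nutrient_id,amount,unit,precision`` table. The packaged
fixture ``ahs2_strict_vegetarian.csv`` carries the strict-vegetarian
(vegan) column of the AHS-2 per-2000-kcal nutrient table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._rounding import round_half_away
from .errors import DomainError, FormatError, NutrientLookupError

__all__ = [
    "VALID_UNITS",
    "NutrientQuantity",
    "DietProfile",
    "ScaledProfile",
    "load_profile",
    "write_profile",
    "packaged_profile",
    "scale_profile",
    "nutrient_level",
]

VALID_UNITS = frozenset({"g", "mg", "mcg", "mcg_RAE", "IU", "pct_kcal"})

#: Metadata keys serialized in the CSV header block.
_META_KEYS = (
    "name",
    "reference_energy",
    "protein_energy_fraction",
    "saturated_fat_energy_fraction",
    "leucine_fraction_of_protein",
)


@dataclass(frozen=True)
class NutrientQuantity:
    """A single nutrient amount with its unit and reporting precision."""

    nutrient_id: str
    amount: float
    unit: str
    display_precision: int = 0

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise DomainError(f"{self.nutrient_id}: amount must be >= 0, got {self.amount}")
        if self.unit not in VALID_UNITS:
            raise FormatError(
                f"{self.nutrient_id}: unknown unit {self.unit!r}; "
                f"expected one of {sorted(VALID_UNITS)}"
            )
        if self.display_precision < 0:
            raise DomainError(f"{self.nutrient_id}: display_precision must be >= 0")

    @property
    def reported_amount(self) -> float:
        """Amount rounded to display precision (half away from zero)."""
        return round_half_away(self.amount, self.display_precision)


@dataclass(frozen=True)
class DietProfile:
    """Nutrient densities per *reference_energy* kcal plus energy fractions."""

    name: str
    reference_energy: float
    densities: tuple[NutrientQuantity, ...]
    protein_energy_fraction: float = 0.145
    saturated_fat_energy_fraction: float = 0.05
    leucine_fraction_of_protein: float = 0.071

    def __post_init__(self) -> None:
        if self.reference_energy <= 0:
            raise DomainError(
                f"reference_energy must be positive, got {self.reference_energy}"
            )
        for fname in (
            "protein_energy_fraction",
            "saturated_fat_energy_fraction",
            "leucine_fraction_of_protein",
        ):
            value = getattr(self, fname)
            if not 0.0 <= value <= 1.0:
                raise DomainError(f"{fname} must lie in [0, 1], got {value}")
        ids = [q.nutrient_id for q in self.densities]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FormatError(f"duplicate nutrient ids: {sorted(dupes)}")
        object.__setattr__(self, "densities", tuple(self.densities))

    def density(self, nutrient_id: str) -> NutrientQuantity:
        for q in self.densities:
            if q.nutrient_id == nutrient_id:
                return q
        raise NutrientLookupError(
            f"nutrient {nutrient_id!r} not in profile {self.name!r}; "
            f"available: {sorted(q.nutrient_id for q in self.densities)}"
        )

    @property
    def nutrient_ids(self) -> tuple[str, ...]:
        return tuple(q.nutrient_id for q in self.densities)

    @property
    def fiber_density(self) -> float:
        """Fiber grams per reference energy (the 'fiber' density row)."""
        return self.density("fiber").amount


@dataclass(frozen=True)
class ScaledProfile:
    """A profile scaled proportionally to *target_energy* kcal/day.

    ``scaled`` holds precision-rounded reported amounts; ``unrounded`` keeps
    the full-precision products for composition/linearity reasoning.
    """

    source: DietProfile
    target_energy: float
    scale_factor: float
    scaled: tuple[NutrientQuantity, ...]
    unrounded: dict[str, float] = field(repr=False, default_factory=dict)

    def amount(self, nutrient_id: str) -> NutrientQuantity:
        for q in self.scaled:
            if q.nutrient_id == nutrient_id:
                return q
        raise NutrientLookupError(
            f"nutrient {nutrient_id!r} not in scaled profile; "
            f"available: {sorted(q.nutrient_id for q in self.scaled)}"
        )


def _parse_metadata(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def load_profile(path: str | Path | io.TextIOBase) -> DietProfile:
    """Read a diet profile from the package's CSV dialect.

    Rejects duplicate nutrient ids, negative amounts and unknown units.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
        label = "<stream>"
    else:
        text = Path(path).read_text(encoding="utf-8")
        label = Path(path).stem
    comment_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_metadata(comment_lines)

    try:
        table = pd.read_csv(io.StringIO(text), comment="#", dtype={"nutrient_id": str})
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=["nutrient_id", "amount", "unit", "precision"])
    missing = {"nutrient_id", "amount", "unit", "precision"} - set(table.columns)
    if missing:
        raise FormatError(f"profile table lacks columns: {sorted(missing)}")

    densities = []
    for row in table.itertuples(index=False):
        if row.amount < 0:
            raise FormatError(
                f"nutrient {row.nutrient_id!r}: negative amount {row.amount}"
            )
        densities.append(
            NutrientQuantity(
                nutrient_id=row.nutrient_id,
                amount=float(row.amount),
                unit=str(row.unit),
                display_precision=int(row.precision),
            )
        )

    kwargs = {}
    if "protein_energy_fraction" in meta:
        kwargs["protein_energy_fraction"] = float(meta["protein_energy_fraction"])
    if "saturated_fat_energy_fraction" in meta:
        kwargs["saturated_fat_energy_fraction"] = float(
            meta["saturated_fat_energy_fraction"]
        )
    if "leucine_fraction_of_protein" in meta:
        kwargs["leucine_fraction_of_protein"] = float(meta["leucine_fraction_of_protein"])
    return DietProfile(
        name=meta.get("name", label),
        reference_energy=float(meta.get("reference_energy", 2000)),
        densities=tuple(densities),
        **kwargs,
    )


def write_profile(profile: DietProfile, path: str | Path) -> Path:
    """Serialize a profile so that ``load_profile`` recovers it field-for-field."""
    path = Path(path)
    values = {
        "name": profile.name,
        "reference_energy": _fmt(profile.reference_energy),
        "protein_energy_fraction": _fmt(profile.protein_energy_fraction),
        "saturated_fat_energy_fraction": _fmt(profile.saturated_fat_energy_fraction),
        "leucine_fraction_of_protein": _fmt(profile.leucine_fraction_of_protein),
    }
    lines = [f"# {key} = {values[key]}" for key in _META_KEYS]
    lines.append("nutrient_id,amount,unit,precision")
    for q in profile.densities:
        lines.append(f"{q.nutrient_id},{_fmt(q.amount)},{q.unit},{q.display_precision}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def packaged_profile(name: str = "ahs2_strict_vegetarian") -> DietProfile:
    """Load a profile fixture shipped with the package."""
    text = resources.files("plantbulk.data").joinpath(f"{name}.csv").read_text("utf-8")
    return load_profile(io.StringIO(text))


def scale_profile(profile: DietProfile, target_energy: float) -> ScaledProfile:
    """Scale all mass-unit densities to *target_energy*; pct_kcal is invariant."""
    if target_energy <= 0:
        raise DomainError(f"target_energy must be positive, got {target_energy}")
    factor = target_energy / profile.reference_energy
    scaled, unrounded = [], {}
    for q in profile.densities:
        if q.unit == "pct_kcal":
            exact = q.amount  # composition fraction: invariant under scaling
        else:
            exact = q.amount * factor
        unrounded[q.nutrient_id] = exact
        scaled.append(
            NutrientQuantity(
                nutrient_id=q.nutrient_id,
                amount=round_half_away(exact, q.display_precision),
                unit=q.unit,
                display_precision=q.display_precision,
            )
        )
    return ScaledProfile(
        source=profile,
        target_energy=target_energy,
        scale_factor=factor,
        scaled=tuple(scaled),
        unrounded=unrounded,
    )


def nutrient_level(scaled: ScaledProfile, nutrient_id: str) -> NutrientQuantity:
    """Reported (precision-rounded) level of one nutrient in a scaled profile."""
    return scaled.amount(nutrient_id)
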