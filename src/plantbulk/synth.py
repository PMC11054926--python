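"""Seeded synthetic cohorts and noisy diet profiles for end-to-end testing.

The anthropometric generator draws body mass and age uniformly over the
ranges observed in competitive male bodybuilders (75-94 kg, 22-35 y);
uniform is the maximum-entropy choice given only a range, and its median
matches the reported 84.5 kg. The profile generator perturbs each nutrient
density with independent multiplicative lognormal noise constructed to have
mean exactly 1 at a chosen coefficient of variation, so large replicate
ensembles recover the base densities; pct_kcal entries are perturbed the
same way then clipped to [0, 100].

One global seed drives everything; per-generator streams are derived from
it deterministically, so cohorts and profiles are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import AnthropometricProfile
from .errors import DomainError
from .profiles import DietProfile, NutrientQuantity, write_profile

__all__ = [
    "CohortSpec",
    "ProfileSpec",
    "generate_cohort",
    "generate_profile",
    "generate_fixture_bundle",
]

# Stream tags keep cohort and profile draws decoupled under one global seed.
_COHORT_STREAM = 1
_PROFILE_STREAM = 2


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, anthropometric ranges and seed."""

    n: int
    body_mass_range: tuple[float, float] = (75.0, 94.0)
    age_range: tuple[float, float] = (22.0, 35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        for name, (low, high) in (
            ("body_mass_range", self.body_mass_range),
            ("age_range", self.age_range),
        ):
            if not low < high:
                raise DomainError(f"{name} must be ordered (low < high)")


@dataclass(frozen=True)
class ProfileSpec:
    """Base profile, multiplicative-noise CV and seed."""

    base_profile: DietProfile
    cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise DomainError(f"cv must be >= 0, got {self.cv}")


def generate_cohort(spec: CohortSpec) -> list[AnthropometricProfile]:
    """Draw *n* profiles with uniform body mass and age over the spec ranges."""
    rng = np.random.default_rng([spec.seed, _COHORT_STREAM])
    masses = rng.uniform(*spec.body_mass_range, size=spec.n)
    ages = rng.uniform(*spec.age_range, size=spec.n)
    return [
        AnthropometricProfile(
            body_mass=float(m),
            age=float(a),
            sex="male",
            body_mass_range=spec.body_mass_range,
            age_range=spec.age_range,
        )
        for m, a in zip(masses, ages)
    ]


def generate_profile(spec: ProfileSpec) -> DietProfile:
    """Perturb each density by lognormal noise with mean 1 and CV = spec.cv.

    With sigma^2 = ln(1 + cv^2) and mu = -sigma^2 / 2 the factor
    exp(N(mu, sigma^2)) has expectation exactly 1, so the generator is
    unbiased on the density scale.
    """
    base = spec.base_profile
    if spec.cv == 0:
        return replace(base, name=f"{base.name}_synthetic")
    rng = np.random.default_rng([spec.seed, _PROFILE_STREAM])
    sigma = math.sqrt(math.log1p(spec.cv**2))
    mu = -(sigma**2) / 2.0
    factors = rng.lognormal(mean=mu, sigma=sigma, size=len(base.densities))
    noisy = []
    for q, f in zip(base.densities, factors):
        amount = q.amount * float(f)
        if q.unit == "pct_kcal":
            amount = min(max(amount, 0.0), 100.0)
        noisy.append(
            NutrientQuantity(q.nutrient_id, amount, q.unit, q.display_precision)
        )
    return replace(base, name=f"{base.name}_synthetic", densities=tuple(noisy))


def generate_fixture_bundle(
    out_dir: str | Path,
    seed: int = 0,
    cohort_n: int = 100,
    cv: float = 0.2,
) -> dict[str, Path]:
    """Write the packaged fixtures plus one seeded synthetic cohort/profile pair.

    Idempotent for a fixed seed: repeated calls produce byte-identical files.
    Returns a name -> path map of everything written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for fixture in ("ahs2_strict_vegetarian", "dri_male_19_30"):
        text = resources.files("plantbulk.data").joinpath(f"{fixture}.csv").read_text("utf-8")
        path = out_dir / f"{fixture}.csv"
        path.write_text(text, encoding="utf-8")
        written[fixture] = path

    cohort = generate_cohort(CohortSpec(n=cohort_n, seed=seed))
    cohort_path = out_dir / "synthetic_cohort.csv"
    pd.DataFrame(
        {
            "body_mass_kg": [p.body_mass for p in cohort],
            "age_y": [p.age for p in cohort],
            "sex": [p.sex for p in cohort],
        }
    ).to_csv(cohort_path, index=False, float_format="%.6f")
    written["synthetic_cohort"] = cohort_path

    from .profiles import packaged_profile  # local import avoids cycle at module load

    noisy = generate_profile(ProfileSpec(packaged_profile(), cv=cv, seed=seed))
    written["synthetic_profile"] = write_profile(noisy, out_dir / "synthetic_profile.csv")
    return written
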