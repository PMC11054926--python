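"""Diet profiles: CSV round-trip, proportional scaling, unit invariance."""

import io
import math

import numpy as np
import pytest

from plantbulk import (
    DietProfile,
    NutrientQuantity,
    load_profile,
    nutrient_level,
    scale_profile,
    write_profile,
)
from plantbulk.errors import DomainError, FormatError, NutrientLookupError


def test_packaged_fixture_loads(vegan_profile):
    assert vegan_profile.reference_energy == 2000
    assert len(vegan_profile.densities) == 18
    assert vegan_profile.protein_energy_fraction == 0.145
    assert vegan_profile.leucine_fraction_of_protein == 0.071
    assert vegan_profile.fiber_density == 46.7


def test_empty_table_is_a_valid_profile():
    text = "# reference_energy = 2000\nnutrient_id,amount,unit,precision\n"
    profile = load_profile(io.StringIO(text))
    assert profile.densities == ()


@pytest.mark.parametrize(
    "bad_rows, match",
    [
        ("iron,-1,mg,0\n", "negative amount"),
        ("iron,1,mg,0\niron,2,mg,0\n", "duplicate"),
        ("iron,1,stone,0\n", "unknown unit"),
    ],
)
def test_malformed_profile_rejected(bad_rows, match):
    text = "# reference_energy = 2000\nnutrient_id,amount,unit,precision\n" + bad_rows
    with pytest.raises((FormatError, DomainError), match=match):
        load_profile(io.StringIO(text))


def test_write_load_round_trip(vegan_profile, tmp_path):
    path = write_profile(vegan_profile, tmp_path / "roundtrip.csv")
    again = load_profile(path)
    assert again == vegan_profile


@pytest.mark.parametrize(
    "nutrient, expected",
    [
        ("sodium", 7484),
        ("folate", 1882),
        ("fiber", 99),
        ("vitamin_b12", 49.4),
        ("omega3_pufa", 4.2),
        ("vitamin_b6", 30.5),
        ("linoleic_acid", 41),
        ("vitamin_a", 2348),
        ("vitamin_c", 1125),
        ("vitamin_e", 214),
        ("calcium", 2450),
        ("magnesium", 1382),
        ("phosphorus", 2906),
    ],
)
def test_scaling_reproduces_reported_levels(study_scaled, nutrient, expected):
    """Per-2000-kcal densities scaled to 4239 kcal match the reported table."""
    assert nutrient_level(study_scaled, nutrient).amount == expected


def test_identity_scaling_preserves_amounts(vegan_profile):
    scaled = scale_profile(vegan_profile, vegan_profile.reference_energy)
    for q in vegan_profile.densities:
        assert scaled.amount(q.nutrient_id).amount == q.reported_amount


def test_pct_kcal_is_scale_invariant(vegan_profile):
    scaled = scale_profile(vegan_profile, 4239)
    assert scaled.amount("saturated_fat").amount == 5
    assert scaled.source.protein_energy_fraction == vegan_profile.protein_energy_fraction


def test_unknown_nutrient_lookup_lists_available(study_scaled):
    with pytest.raises(NutrientLookupError, match="available"):
        nutrient_level(study_scaled, "unobtainium")


def test_nonpositive_target_energy_rejected(vegan_profile):
    with pytest.raises(DomainError, match="target_energy"):
        scale_profile(vegan_profile, 0)


def test_scaling_linearity_and_composition(vegan_profile):
    """Scaling is linear in the energy ratio, and scaling twice (on exact
    amounts) equals scaling once to the final energy."""
    once = scale_profile(vegan_profile, 3000)
    for q in vegan_profile.densities:
        exact = once.unrounded[q.nutrient_id]
        if q.unit == "pct_kcal":
            assert exact == q.amount
        else:
            assert exact == pytest.approx(q.amount * 3000 / 2000, rel=1e-12)

    intermediate = DietProfile(
        name="mid",
        reference_energy=3000,
        densities=tuple(
            NutrientQuantity(q.nutrient_id, once.unrounded[q.nutrient_id], q.unit,
                             q.display_precision)
            for q in vegan_profile.densities
        ),
    )
    composed = scale_profile(intermediate, 4239)
    direct = scale_profile(vegan_profile, 4239)
    for q in vegan_profile.densities:
        assert composed.unrounded[q.nutrient_id] == pytest.approx(
            direct.unrounded[q.nutrient_id], rel=1e-12
        )


def test_scaled_amounts_match_bruteforce_oracle():
    """1000 random profiles: reported scaled amount equals an independently
    rounded amount * factor, to within half a unit at display precision."""
    rng = np.random.default_rng(42)
    units = ["g", "mg", "mcg", "IU"]
    for _ in range(1000):
        n = rng.integers(1, 6)
        densities = tuple(
            NutrientQuantity(
                f"n{i}",
                float(rng.uniform(0, 5000)),
                units[int(rng.integers(0, len(units)))],
                int(rng.integers(0, 3)),
            )
            for i in range(n)
        )
        ref_e = float(rng.uniform(500, 4000))
        target = float(rng.uniform(500, 8000))
        profile = DietProfile(name="rand", reference_energy=ref_e, densities=densities)
        scaled = scale_profile(profile, target)
        for q in densities:
            # independent oracle: plain half-up rounding of amount * factor
            p = q.display_precision
            expected = math.floor(q.amount * target / ref_e * 10**p + 0.5) / 10**p
            got = scaled.amount(q.nutrient_id).amount
            assert abs(got - expected) <= 0.5 * 10**-p + 1e-9
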