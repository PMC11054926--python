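"""Direction-aware adequacy: reference loading, fiber AI, verdicts, oracle."""

import io

import numpy as np
import pytest

from plantbulk import (
    DietProfile,
    NutrientQuantity,
    NutrientReference,
    evaluate_adequacy,
    fiber_ai_for_energy,
    load_references,
    scale_profile,
    summarize,
)
from plantbulk.errors import FormatError, UnitMismatchError

REF_HEADER = "nutrient_id,target,unit,basis,direction,strict,energy_relative_rule\n"


def test_packaged_reference_set(dri_references):
    """17 minimum targets plus the saturated-fat limit, for males 19-30 y."""
    assert len(dri_references) == 18
    directions = {r.nutrient_id: r.direction for r in dri_references}
    assert directions["sodium"] == "limit"
    assert directions["saturated_fat"] == "limit"
    assert sum(d == "minimum" for d in directions.values()) == 16
    fiber = next(r for r in dri_references if r.nutrient_id == "fiber")
    assert fiber.energy_relative_rule == 14


def test_empty_reference_file():
    assert load_references(io.StringIO("")) == ()


def test_direction_basis_coupling_rejected():
    bad = REF_HEADER + "sodium,2300,mg,CDRR,minimum,false,\n"
    with pytest.raises(FormatError, match="direction"):
        load_references(io.StringIO(bad))


def test_unknown_basis_rejected():
    bad = REF_HEADER + "iron,8,mg,XXX,minimum,false,\n"
    with pytest.raises(FormatError, match="basis"):
        load_references(io.StringIO(bad))


def test_duplicate_reference_rejected():
    bad = REF_HEADER + "iron,8,mg,RDA,minimum,false,\niron,9,mg,RDA,minimum,false,\n"
    with pytest.raises(FormatError, match="duplicate"):
        load_references(io.StringIO(bad))


@pytest.mark.parametrize("eer, expected", [(4239, 59), (1000, 14), (2000, 28)])
def test_fiber_ai_tracks_energy(eer, expected):
    assert fiber_ai_for_energy(eer) == expected


def test_study_verdicts(study_scaled, dri_references, study_energy):
    """At 4239 kcal only vitamin D (below its RDA) and sodium (above the
    CDRR) fail; saturated fat passes the strict <10 %kcal limit."""
    report = evaluate_adequacy(study_scaled, dri_references, study_energy.eer)
    assert report.failures == ("sodium", "vitamin_d")
    by_id = {r.nutrient_id: r for r in report.rows}
    assert not by_id["vitamin_d"].met and by_id["vitamin_d"].direction == "minimum"
    assert not by_id["sodium"].met and by_id["sodium"].direction == "limit"
    assert by_id["saturated_fat"].met and by_id["saturated_fat"].scaled_amount == 5
    assert by_id["fiber"].target_value == 59  # recomputed from 14 g / 1000 kcal
    assert report.n_met == 16 and report.n_not_met == 2


def test_summary_counts_and_failures(study_scaled, dri_references, study_energy):
    s = summarize(evaluate_adequacy(study_scaled, dri_references, study_energy.eer))
    assert s["n_met"] + s["n_not_met"] == s["n_rows"] == 18
    assert s["failures"] == ["sodium", "vitamin_d"]
    assert s["missing"] == []


def test_missing_profile_nutrient_listed_not_failed(dri_references, study_energy):
    profile = DietProfile(
        name="iron_only",
        reference_energy=2000,
        densities=(NutrientQuantity("iron", 32, "mg", 0),),
    )
    report = evaluate_adequacy(scale_profile(profile, 4239), dri_references, study_energy.eer)
    assert len(report.rows) == 1
    assert set(report.missing) == {r.nutrient_id for r in dri_references} - {"iron"}
    assert report.failures == ()


def test_unit_mismatch_names_both_units(study_energy):
    profile = DietProfile(
        name="bad_units",
        reference_energy=2000,
        densities=(NutrientQuantity("iron", 32, "mcg", 0),),
    )
    refs = load_references(io.StringIO(REF_HEADER + "iron,8,mg,RDA,minimum,false,\n"))
    with pytest.raises(UnitMismatchError, match="'mcg'.*'mg'"):
        evaluate_adequacy(scale_profile(profile, 4239), refs, study_energy.eer)


def test_all_zero_profile_fails_every_minimum(dri_references, study_energy):
    profile = DietProfile(
        name="zeros",
        reference_energy=2000,
        densities=tuple(
            NutrientQuantity(r.nutrient_id, 0.0, r.unit, 0)
            for r in dri_references
            if r.direction == "minimum"
        ),
    )
    report = evaluate_adequacy(scale_profile(profile, 4239), dri_references, study_energy.eer)
    assert report.n_met == 0 and report.n_not_met == len(report.rows)


def test_raising_intake_never_hurts_a_minimum_nor_helps_a_limit(study_energy):
    """Direction soundness across a grid of intakes around each target."""
    refs = load_references(
        io.StringIO(
            REF_HEADER
            + "iron,8,mg,RDA,minimum,false,\n"
            + "sodium,2300,mg,CDRR,limit,false,\n"
            + "saturated_fat,10,pct_kcal,DGA_limit,limit,true,\n"
        )
    )
    last_met = {r.nutrient_id: None for r in refs}
    for factor in (0.1, 0.5, 0.99, 1.0, 1.01, 2.0, 10.0):
        profile = DietProfile(
            name="grid",
            reference_energy=2000,
            densities=tuple(
                NutrientQuantity(r.nutrient_id, r.target_value * factor, r.unit, 2)
                for r in refs
            ),
        )
        report = evaluate_adequacy(
            scale_profile(profile, 2000), refs, study_energy.eer
        )
        for row in report.rows:
            prev = last_met[row.nutrient_id]
            if prev is not None:
                if row.direction == "minimum":
                    assert row.met >= prev  # once met, stays met as intake rises
                else:
                    assert row.met <= prev  # once exceeded, stays exceeded
            last_met[row.nutrient_id] = row.met


def test_limit_strictness_semantics(study_energy):
    refs = load_references(
        io.StringIO(
            REF_HEADER
            + "saturated_fat,10,pct_kcal,DGA_limit,limit,true,\n"
            + "sodium,2300,mg,CDRR,limit,false,\n"
        )
    )
    profile = DietProfile(
        name="at_limits",
        reference_energy=2000,
        densities=(
            NutrientQuantity("saturated_fat", 10, "pct_kcal", 0),  # == limit: strict fails
            NutrientQuantity("sodium", 2300, "mg", 0),             # == level: non-strict passes
        ),
    )
    report = evaluate_adequacy(scale_profile(profile, 2000), refs, study_energy.eer)
    by_id = {r.nutrient_id: r.met for r in report.rows}
    assert by_id == {"saturated_fat": False, "sodium": True}


def test_flags_match_bruteforce_oracle(study_energy):
    """Random profiles/references: package verdicts equal an independent
    per-row comparison loop."""
    rng = np.random.default_rng(7)
    bases_min = ["RDA", "AI"]
    for _ in range(300):
        n = int(rng.integers(1, 8))
        refs, densities = [], []
        for i in range(n):
            target = float(rng.uniform(1, 1000))
            amount = float(rng.uniform(0, 2000))
            limit = bool(rng.integers(0, 2))
            strict = bool(rng.integers(0, 2))
            refs.append(
                NutrientReference(
                    nutrient_id=f"n{i}",
                    target_value=target,
                    unit="mg",
                    basis=("CDRR" if limit else bases_min[int(rng.integers(0, 2))]),
                    direction=("limit" if limit else "minimum"),
                    strict=strict,
                )
            )
            densities.append(NutrientQuantity(f"n{i}", amount, "mg", 1))
        profile = DietProfile(name="rand", reference_energy=2000, densities=tuple(densities))
        scaled = scale_profile(profile, 2000)
        report = evaluate_adequacy(scaled, tuple(refs), study_energy.eer)
        for ref, row in zip(refs, report.rows):
            amount = scaled.amount(ref.nutrient_id).reported_amount
            if ref.direction == "minimum":
                expected = amount >= ref.target_value
            elif ref.strict:
                expected = amount < ref.target_value
            else:
                expected = amount <= ref.target_value
            assert row.met == expected
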