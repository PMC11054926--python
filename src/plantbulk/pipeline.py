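"""End-to-end orchestration: anthropometrics -> energy -> scaling -> protein
-> adequacy, with config handling and report rendering.

``RunConfig`` defaults are the modeling-study conditions (84.5 kg male, PAL
1.75, 15 % surplus, the packaged strict-vegetarian profile and male-19-30
reference set, 151 g/day explicit protein level, plant leucine share, four
meals), so ``run_model(RunConfig())`` reproduces the headline results.
Stages run in a fixed order; a failure raises :class:`StageError` carrying
the stage name and whatever partial outputs already exist. Reports render
deterministically (sorted JSON keys, no timestamps), so identical configs
give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml

from . import __version__
from .adequacy import (
    AdequacyReport,
    evaluate_adequacy,
    load_references,
    packaged_references,
    summarize,
)
from .energy import (
    ActivityParameters,
    AnthropometricProfile,
    EnergyRequirement,
    RMR_EQUATIONS,
    energy_requirement,
)
from .errors import DomainError, StageError
from .profiles import DietProfile, ScaledProfile, load_profile, packaged_profile, scale_profile
from .protein import (
    ProteinConstants,
    ProteinPlan,
    build_protein_plan,
    protein_level_from_energy,
)

__all__ = ["RunConfig", "ModelRun", "run_model", "render_report"]

log = logging.getLogger(__name__)

ReportFormat = Literal["csv", "json", "text"]


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; defaults reproduce the modeling study."""

    body_mass_kg: float = 84.5
    age_y: float = 28.5
    sex: str = "male"
    pal: float = 1.75
    surplus_fraction: float = 0.15
    rounding_policy: str = "report_then_propagate"
    rmr_equation: str = "tinsley_bodybuilder"
    profile: str | None = None      # path; None -> packaged AHS-2 fixture
    references: str | None = None   # path; None -> packaged DRI fixture
    meals_per_day: int = 4
    leucine_fraction: float | None = None  # None -> profile's plant share
    protein_level_source: str = "explicit_value"
    protein_level_g_day: float = 151.0
    requirement_rate_g_kg: float = 1.6
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load YAML or JSON config; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise DomainError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class ModelRun:
    """All stage outputs of one pipeline execution plus provenance."""

    config: RunConfig
    energy: EnergyRequirement | None = None
    scaled: ScaledProfile | None = None
    plan: ProteinPlan | None = None
    adequacy: AdequacyReport | None = None
    provenance: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        """Plain-data view of the run; stable across identical executions."""
        out: dict = {
            "config": dataclasses.asdict(self.config),
            "provenance": self.provenance,
            "failed_stage": self.failed_stage,
        }
        if self.energy is not None:
            out["energy"] = dataclasses.asdict(self.energy)
        if self.scaled is not None:
            out["scaled_profile"] = {
                "source": self.scaled.source.name,
                "reference_energy": self.scaled.source.reference_energy,
                "target_energy": self.scaled.target_energy,
                "scale_factor": self.scaled.scale_factor,
                "nutrients": [
                    {"nutrient_id": q.nutrient_id, "amount": q.amount, "unit": q.unit}
                    for q in self.scaled.scaled
                ],
            }
        if self.plan is not None:
            out["protein_plan"] = dataclasses.asdict(self.plan)
        if self.adequacy is not None:
            out["adequacy"] = {
                "rows": [dataclasses.asdict(r) for r in self.adequacy.rows],
                "summary": summarize(self.adequacy),
            }
        return out


def _load_inputs(config: RunConfig) -> tuple[DietProfile, tuple]:
    profile = (
        packaged_profile() if config.profile is None else load_profile(config.profile)
    )
    refs = (
        packaged_references()
        if config.references is None
        else load_references(config.references)
    )
    return profile, refs


def run_model(config: RunConfig | None = None) -> ModelRun:
    """Execute every stage in order; deterministic for fixed inputs."""
    config = config if config is not None else RunConfig()
    run = ModelRun(config=config)
    run.provenance = {
        "profile": config.profile or "packaged:ahs2_strict_vegetarian",
        "references": config.references or "packaged:dri_male_19_30",
        "seed": config.seed,
        "version": __version__,
    }

    stage = "inputs"
    try:
        diet, refs = _load_inputs(config)

        stage = "energy"
        log.info(
            "energy stage: body_mass=%.1f kg, pal=%.2f, surplus=%.2f, policy=%s",
            config.body_mass_kg, config.pal, config.surplus_fraction,
            config.rounding_policy,
        )
        profile = AnthropometricProfile(
            body_mass=config.body_mass_kg, age=config.age_y, sex=config.sex
        )
        activity = ActivityParameters(
            pal=config.pal, surplus_fraction=config.surplus_fraction
        )
        run.energy = energy_requirement(
            profile,
            activity,
            equation=RMR_EQUATIONS[config.rmr_equation],
            policy=config.rounding_policy,  # type: ignore[arg-type]
        )

        stage = "scaling"
        log.info("scaling stage: %s -> %.0f kcal", run.provenance["profile"], run.energy.eer)
        run.scaled = scale_profile(diet, run.energy.eer)

        stage = "protein"
        constants = ProteinConstants(
            requirement_rate=config.requirement_rate_g_kg,
            meals_per_day=config.meals_per_day,
        )
        level, source = _protein_level(config, diet, run)
        fraction = (
            config.leucine_fraction
            if config.leucine_fraction is not None
            else diet.leucine_fraction_of_protein
        )
        run.plan = build_protein_plan(
            profile,
            level,
            constants=constants,
            leucine_fraction=fraction,
            level_source=source,  # type: ignore[arg-type]
            policy=config.rounding_policy,  # type: ignore[arg-type]
        )

        if refs:
            stage = "adequacy"
            log.info("adequacy stage: %s", run.provenance["references"])
            run.adequacy = evaluate_adequacy(run.scaled, refs, run.energy.eer)
    except Exception as exc:  # annotate with the failing stage, keep partials
        run.failed_stage = stage
        raise StageError(stage, exc, partial=run) from exc
    return run


def _protein_level(config: RunConfig, diet: DietProfile, run: ModelRun):
    source = config.protein_level_source
    if source == "explicit_value":
        return config.protein_level_g_day, source
    if source == "pct_energy":
        assert run.energy is not None
        return (
            protein_level_from_energy(run.energy.eer, diet.protein_energy_fraction),
            source,
        )
    if source == "scaled_profile":
        assert run.scaled is not None
        return run.scaled.amount("protein").amount, source
    raise DomainError(f"unknown protein_level_source {source!r}")


# ---------------------------------------------------------------------------
# rendering

def render_report(run: ModelRun, fmt: ReportFormat = "text") -> str:
    """Render the run as JSON, CSV or an aligned text report."""
    if fmt == "json":
        return json.dumps(run.to_dict(), indent=2, sort_keys=True) + "\n"
    if fmt == "csv":
        return _render_csv(run)
    if fmt == "text":
        return _render_text(run)
    raise DomainError(f"unknown report format {fmt!r}; use csv, json or text")


def _render_csv(run: ModelRun) -> str:
    lines = ["section,key,value,unit,target,basis,met"]
    if run.energy is not None:
        for key in ("rmr", "tdee", "es", "eer"):
            lines.append(f"energy,{key},{getattr(run.energy, key)},kcal/day,,,")
    if run.plan is not None:
        p = run.plan
        lines.append(f"protein,requirement,{p.requirement_g_day},g/day,,,")
        lines.append(f"protein,level,{p.level_g_day},g/day,,,")
        lines.append(f"protein,relative,{p.relative_g_kg_day},g/kg/day,,,")
        lines.append(f"protein,leucine_daily,{p.leucine_g_day},g/day,,,")
        lines.append(f"protein,leucine_per_meal,{p.leucine_g_meal},g/meal,,,")
    if run.adequacy is not None:
        for r in run.adequacy.rows:
            lines.append(
                f"adequacy,{r.nutrient_id},{r.scaled_amount},{r.unit},"
                f"{r.target_value},{r.basis},{'yes' if r.met else 'no'}"
            )
    return "\n".join(lines) + "\n"


def _render_text(run: ModelRun) -> str:
    out: list[str] = []
    c = run.config
    out.append(f"plantbulk model run (policy: {c.rounding_policy})")
    out.append("")
    if run.energy is not None:
        e = run.energy
        out.append("Energy requirements (kcal/day)")
        out.append(f"  RMR   {e.rmr:>8}")
        out.append(f"  TDEE  {e.tdee:>8}")
        out.append(f"  ES    {e.es:>8}")
        out.append(f"  EER   {e.eer:>8}")
        out.append("")
    if run.plan is not None:
        p = run.plan
        out.append(f"Protein and leucine (level source: {p.level_source})")
        out.append(f"  requirement       {p.requirement_g_day:>7} g/day")
        out.append(f"  level             {p.level_g_day:>7} g/day")
        out.append(f"  relative          {p.relative_g_kg_day:>7} g/kg/day")
        out.append(f"  leucine           {p.leucine_g_day:>7} g/day")
        out.append(f"  leucine per meal  {p.leucine_g_meal:>7} g/meal ({p.meals_per_day} meals)")
        for name, ok in p.thresholds_met.items():
            out.append(f"  [{'x' if ok else ' '}] {name.replace('_', ' ')}")
        out.append("")
    if run.adequacy is not None:
        out.append(f"Nutrient adequacy at {run.scaled.target_energy:.0f} kcal/day")
        header = f"  {'nutrient':<16}{'amount':>10}  {'unit':<8}{'target':>10}  {'basis':<10}{'verdict'}"
        out.append(header)
        for r in run.adequacy.rows:
            verdict = "met" if r.met else "NOT MET"
            out.append(
                f"  {r.nutrient_id:<16}{r.scaled_amount:>10}  {r.unit:<8}"
                f"{r.target_value:>10}  {r.basis:<10}{verdict}"
            )
        s = summarize(run.adequacy)
        out.append(f"  -- {s['n_met']} met, {s['n_not_met']} not met"
                   + (f"; failures: {', '.join(s['failures'])}" if s["failures"] else ""))
        out.append("")
    return "\n".join(out)
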