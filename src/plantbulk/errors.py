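"""Exception types raised across the modeling pipeline."""

from __future__ import annotations

__all__ = [
    "PlantbulkError",
    "DomainError",
    "FormatError",
    "NutrientLookupError",
    "UnitMismatchError",
    "StageError",
]


class PlantbulkError(Exception):
    """Base class for all package errors."""


class DomainError(PlantbulkError, ValueError):
    """A quantity violates a model precondition (names the offending field)."""


class FormatError(PlantbulkError, ValueError):
    """A tabular input file violates the expected schema."""


class NutrientLookupError(PlantbulkError, KeyError):
    """A nutrient id is absent from a profile; message lists available ids."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class UnitMismatchError(PlantbulkError, ValueError):
    """Profile and reference disagree on a nutrient's unit."""


class StageError(PlantbulkError, RuntimeError):
    """A pipeline stage failed; carries the stage name and any partial run."""

    def __init__(self, stage: str, cause: Exception, partial=None):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial = partial
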