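"""Colour proportions -> discrete morph labels and analysis-ready traits.

Morph assignment is presence/absence of above-threshold orange and yellow;
quantitative traits are arcsine-square-root transformed, with yellow in OY
individuals parameterized as the sum of orange and yellow (orange overlays
yellow in the central patch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import pandas as pd

from .pedigree import Individual, Pedigree

__all__ = [
    "ExpressionThresholds",
    "TraitRecord",
    "classify_morph",
    "effective_yellow",
    "arcsin_sqrt",
    "is_expressed",
    "stage_of",
    "prepare_trait_table",
    "trait_table_frame",
]

TRAITS = ("orange", "yellow")
ZERO_POLICIES = ("as_missing", "as_zero", "exclude")


@dataclass(frozen=True)
class ExpressionThresholds:
    """Minimum fractions counting as expressed colour.

    Values strictly below the applicable threshold are scored as absent
    (0 expression); values at or above it count as expressed.
    """

    adult_orange_min: float = 0.02
    adult_yellow_min: float = 0.05
    juvenile_min: float = 0.01

    def __post_init__(self) -> None:
        for name in ("adult_orange_min", "adult_yellow_min", "juvenile_min"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name}={value} outside (0, 1)")
        if self.juvenile_min > min(self.adult_orange_min, self.adult_yellow_min):
            raise ValueError("juvenile_min must not exceed adult thresholds")

    def minimum(self, trait: str, stage: str) -> float:
        if stage == "juvenile":
            return self.juvenile_min
        if trait == "orange":
            return self.adult_orange_min
        return self.adult_yellow_min


@dataclass(frozen=True)
class TraitRecord:
    """One individual x one colour trait, on raw and transformed scales."""

    id: str
    trait: str
    raw_value: float
    effective_value: Optional[float]
    transformed_value: Optional[float]
    expressed: bool


def _check_fraction(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value} outside [0, 1]")


def is_expressed(
    value: float,
    trait: str,
    stage: str = "adult",
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> bool:
    """True when ``value`` reaches the stage/trait expression threshold."""
    _check_fraction(value, trait)
    return value >= thresholds.minimum(trait, stage)


def classify_morph(
    prop_orange: float,
    prop_yellow: float,
    stage: str = "adult",
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> str:
    """Assign O/Y/OY/G from presence/absence of above-threshold colour."""
    _check_fraction(prop_orange, "prop_orange")
    _check_fraction(prop_yellow, "prop_yellow")
    orange = is_expressed(prop_orange, "orange", stage, thresholds)
    yellow = is_expressed(prop_yellow, "yellow", stage, thresholds)
    if orange and yellow:
        return "OY"
    if orange:
        return "O"
    if yellow:
        return "Y"
    return "G"


def effective_yellow(morph: str, prop_orange: float, prop_yellow: float) -> float:
    """Yellow trait value: orange + yellow for OY morphs, yellow otherwise."""
    if morph == "OY":
        return min(1.0, prop_orange + prop_yellow)
    return prop_yellow


def arcsin_sqrt(p: float) -> float:
    """Variance-stabilizing asin(sqrt(p)) transform, radians in [0, pi/2]."""
    _check_fraction(p, "p")
    return math.asin(math.sqrt(p))


def stage_of(individual: Individual) -> str:
    """Life stage used for thresholding: offspring (F1+) scored as juveniles."""
    from .pedigree import _generation_number

    gen = _generation_number(individual.generation)
    if gen is not None and gen >= 1:
        return "juvenile"
    return "adult"


def prepare_trait_table(
    pedigree: Pedigree,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
    zero_policy: str = "as_missing",
) -> List[TraitRecord]:
    """Build per-individual, per-trait records for downstream analyses.

    ``zero_policy`` controls below-threshold values: ``as_missing`` keeps the
    record with missing effective/transformed values (animal-model
    convention), ``as_zero`` sets them to 0, ``exclude`` drops the record
    (regression convention). Individuals with either proportion unmeasured
    are skipped.
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    records: List[TraitRecord] = []
    for ind in pedigree:
        if ind.prop_orange is None or ind.prop_yellow is None:
            continue
        stage = stage_of(ind)
        morph = ind.morph or classify_morph(
            ind.prop_orange, ind.prop_yellow, stage, thresholds
        )
        for trait in TRAITS:
            raw = ind.prop_orange if trait == "orange" else ind.prop_yellow
            expressed = is_expressed(raw, trait, stage, thresholds)
            if not expressed:
                if zero_policy == "exclude":
                    continue
                if zero_policy == "as_missing":
                    records.append(TraitRecord(ind.id, trait, raw, None, None, False))
                else:
                    records.append(TraitRecord(ind.id, trait, raw, 0.0, 0.0, False))
                continue
            if trait == "yellow":
                effective = effective_yellow(morph, ind.prop_orange, ind.prop_yellow)
            else:
                effective = raw
            records.append(
                TraitRecord(
                    ind.id, trait, raw, effective, arcsin_sqrt(effective), True
                )
            )
    return records


def trait_table_frame(records: List[TraitRecord]) -> pd.DataFrame:
    """Serialize trait records to the exported CSV layout."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "trait": r.trait,
                "raw": r.raw_value,
                "effective": r.effective_value,
                "transformed": r.transformed_value,
                "expressed": r.expressed,
            }
            for r in records
        ],
        columns=["id", "trait", "raw", "effective", "transformed", "expressed"],
    )
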