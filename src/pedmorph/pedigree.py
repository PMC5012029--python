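"""Pedigree container, domain types, validation, and CSV I/O.

The canonical on-disk format is a comma-separated table with one row per
individual and a fixed header::

    id,sex,generation,cohort,clutch,sire,dam,prop_orange,prop_yellow,morph

Founders have empty ``sire``/``dam`` cells; any missing value is an empty
cell (configurable token), never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Optional

import pandas as pd

__all__ = [
    "MORPHS",
    "SEXES",
    "Individual",
    "Pedigree",
    "MorphCounts",
    "PedigreeError",
    "PedigreeValidationError",
    "read_pedigree",
    "write_pedigree",
    "morph_counts",
]

#: Fixed morph category order used throughout (orange, yellow, orange+yellow, grey).
MORPHS = ("O", "Y", "OY", "G")
SEXES = ("male", "female", "unknown")

CANONICAL_COLUMNS = (
    "id",
    "sex",
    "generation",
    "cohort",
    "clutch",
    "sire",
    "dam",
    "prop_orange",
    "prop_yellow",
    "morph",
)


class PedigreeError(Exception):
    """Malformed pedigree input (I/O level)."""


class PedigreeValidationError(PedigreeError):
    """Pedigree violates a structural invariant; message lists offenders."""


@dataclass(eq=True)
class Individual:
    """A single animal: identity, links, and measured colour proportions.

    ``prop_orange``/``prop_yellow`` are fractions of throat area in [0, 1]
    (``None`` when unmeasured); ``morph`` is one of :data:`MORPHS` or
    ``None``.
    """

    id: str
    sex: str = "unknown"
    generation: str = "F0"
    cohort: Optional[str] = None
    clutch_id: Optional[str] = None
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    prop_orange: Optional[float] = None
    prop_yellow: Optional[float] = None
    morph: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeValidationError(
                f"individual {self.id!r}: unknown sex code {self.sex!r}"
            )
        for fieldname in ("prop_orange", "prop_yellow"):
            value = getattr(self, fieldname)
            if value is not None and not (0.0 <= value <= 1.0):
                raise PedigreeValidationError(
                    f"individual {self.id!r}: {fieldname}={value} outside [0, 1]"
                )
        if self.morph is not None and self.morph not in MORPHS:
            raise PedigreeValidationError(
                f"individual {self.id!r}: unknown morph {self.morph!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None

    def copy(self) -> "Individual":
        return replace(self)


@dataclass(frozen=True)
class MorphCounts:
    """Counts (or expected counts) per morph category.

    Observed counts are integers; expected counts may be fractional.
    """

    O: float = 0.0
    Y: float = 0.0
    OY: float = 0.0
    G: float = 0.0

    def __post_init__(self) -> None:
        for morph in MORPHS:
            if getattr(self, morph) < 0:
                raise ValueError(f"negative count for morph {morph}")

    @property
    def total(self) -> float:
        return self.O + self.Y + self.OY + self.G

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in MORPHS}

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, m) for m in MORPHS)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "MorphCounts":
        return cls(**{m: float(mapping.get(m, 0.0)) for m in MORPHS})


class Pedigree:
    """Ordered collection of :class:`Individual` keyed by id.

    Invariants enforced by :meth:`validate`: unique ids, parent links refer
    to existing individuals of the correct sex, no cycles, and an
    individual's generation label (``F<k>``) is later than both parents'.
    """

    def __init__(self, individuals: Iterable[Individual] = ()):
        self._individuals: dict = {}
        for ind in individuals:
            self.add(ind)

    # -- container protocol -------------------------------------------------
    def add(self, individual: Individual) -> None:
        if individual.id in self._individuals:
            raise PedigreeValidationError(f"duplicate id {individual.id!r}")
        self._individuals[individual.id] = individual

    def __getitem__(self, key: str) -> Individual:
        return self._individuals[key]

    def __contains__(self, key: str) -> bool:
        return key in self._individuals

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._individuals.values())

    def __len__(self) -> int:
        return len(self._individuals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        if set(self._individuals) != set(other._individuals):
            return False
        return all(self[i] == other[i] for i in self._individuals)

    @property
    def ids(self) -> list:
        return list(self._individuals)

    # -- structure ----------------------------------------------------------
    def founders(self) -> list:
        return [ind for ind in self if ind.is_founder]

    def offspring_of(self, parent_id: str) -> list:
        return [
            ind for ind in self if parent_id in (ind.sire_id, ind.dam_id)
        ]

    def clutches(self) -> dict:
        """Group non-founder ids by (sire_id, dam_id, clutch_id)."""
        groups: dict = {}
        for ind in self:
            if ind.is_founder:
                continue
            key = (ind.sire_id, ind.dam_id, ind.clutch_id)
            groups.setdefault(key, []).append(ind.id)
        return groups

    def families(self) -> dict:
        """Group non-founder ids by (sire_id, dam_id), pooling clutches."""
        groups: dict = {}
        for ind in self:
            if ind.is_founder:
                continue
            groups.setdefault((ind.sire_id, ind.dam_id), []).append(ind.id)
        return groups

    def topological_order(self) -> list:
        """Ids sorted parents-before-offspring; raises on cycles."""
        order: list = []
        state: dict = {}  # 0 unseen, 1 in-progress, 2 done

        for root in self._individuals:
            if state.get(root, 0) == 2:
                continue
            stack = [(root, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 2
                    order.append(node)
                    continue
                if state.get(node, 0) == 2:
                    continue
                if state.get(node, 0) == 1:
                    raise PedigreeValidationError(
                        f"cycle detected through individual {node!r}"
                    )
                state[node] = 1
                stack.append((node, True))
                ind = self._individuals[node]
                for parent in (ind.sire_id, ind.dam_id):
                    if parent is not None and parent in self._individuals:
                        if state.get(parent, 0) == 1:
                            raise PedigreeValidationError(
                                f"cycle detected through individual {parent!r}"
                            )
                        if state.get(parent, 0) == 0:
                            stack.append((parent, False))
        return order

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        problems = []
        for ind in self:
            for role, pid, want_sex in (
                ("sire", ind.sire_id, "male"),
                ("dam", ind.dam_id, "female"),
            ):
                if pid is None:
                    continue
                if pid not in self._individuals:
                    problems.append(
                        f"{ind.id!r}: dangling {role} reference {pid!r}"
                    )
                    continue
                parent = self[pid]
                if parent.sex != want_sex:
                    problems.append(
                        f"{ind.id!r}: {role} {pid!r} has sex {parent.sex!r}, "
                        f"expected {want_sex!r}"
                    )
                gen_child = _generation_number(ind.generation)
                gen_parent = _generation_number(parent.generation)
                if (
                    gen_child is not None
                    and gen_parent is not None
                    and gen_child <= gen_parent
                ):
                    problems.append(
                        f"{ind.id!r} (gen {ind.generation}) not later than "
                        f"parent {pid!r} (gen {parent.generation})"
                    )
            po, py = ind.prop_orange, ind.prop_yellow
            if po is not None and py is not None and po + py > 1.0 + 1e-9:
                problems.append(
                    f"{ind.id!r}: prop_orange + prop_yellow = {po + py:.4f} > 1"
                )
        try:
            self.topological_order()
        except PedigreeValidationError as exc:
            problems.append(str(exc))
        if problems:
            raise PedigreeValidationError(
                "pedigree validation failed:\n  " + "\n  ".join(problems)
            )

    # -- conversion ---------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self:
            rows.append(
                {
                    "id": ind.id,
                    "sex": ind.sex,
                    "generation": ind.generation,
                    "cohort": ind.cohort,
                    "clutch": ind.clutch_id,
                    "sire": ind.sire_id,
                    "dam": ind.dam_id,
                    "prop_orange": ind.prop_orange,
                    "prop_yellow": ind.prop_yellow,
                    "morph": ind.morph,
                }
            )
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _generation_number(label: Optional[str]) -> Optional[int]:
    if label is None:
        return None
    label = label.strip()
    if label.startswith(("F", "f")) and label[1:].isdigit():
        return int(label[1:])
    return None


# ---------------------------------------------------------------------------
# I/O


def _parse_fraction(token, row_id: str, column: str, missing: str):
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    token = str(token).strip()
    if token == missing or token == "":
        return None
    try:
        value = float(token)
    except ValueError as exc:
        raise PedigreeError(
            f"row {row_id!r}, column {column!r}: not a number: {token!r}"
        ) from exc
    if not (0.0 <= value <= 1.0):
        raise PedigreeError(
            f"row {row_id!r}, column {column!r}: proportion {value} outside [0, 1]"
        )
    return value


def _parse_str(token, missing: str):
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    token = str(token).strip()
    if token == missing or token == "":
        return None
    return token


def read_pedigree(path, format_options: Optional[Mapping] = None) -> Pedigree:
    """Read and validate a pedigree CSV.

    ``format_options`` is a flat mapping supporting ``column_aliases``
    (mapping from canonical name to the name used in the file) and
    ``missing`` (the missing-value token, default empty string).
    """
    options = dict(format_options or {})
    aliases = dict(options.get("column_aliases", {}))
    missing = str(options.get("missing", ""))

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {canon: aliases.get(canon, canon) for canon in CANONICAL_COLUMNS}
    required = ("id", "sex", "generation")
    for canon in required:
        if colmap[canon] not in frame.columns:
            raise PedigreeError(
                f"missing required column {colmap[canon]!r} in {path}"
            )

    def cell(row, canon):
        name = colmap[canon]
        return row[name] if name in frame.columns else None

    pedigree = Pedigree()
    for i, row in frame.iterrows():
        row_id = _parse_str(cell(row, "id"), missing)
        if row_id is None:
            raise PedigreeError(f"row {i}: empty id")
        sex = _parse_str(cell(row, "sex"), missing) or "unknown"
        if sex not in SEXES:
            raise PedigreeError(f"row {row_id!r}: unknown sex code {sex!r}")
        try:
            individual = Individual(
                id=row_id,
                sex=sex,
                generation=_parse_str(cell(row, "generation"), missing) or "F0",
                cohort=_parse_str(cell(row, "cohort"), missing),
                clutch_id=_parse_str(cell(row, "clutch"), missing),
                sire_id=_parse_str(cell(row, "sire"), missing),
                dam_id=_parse_str(cell(row, "dam"), missing),
                prop_orange=_parse_fraction(
                    cell(row, "prop_orange"), row_id, "prop_orange", missing
                ),
                prop_yellow=_parse_fraction(
                    cell(row, "prop_yellow"), row_id, "prop_yellow", missing
                ),
                morph=_parse_str(cell(row, "morph"), missing),
            )
        except PedigreeValidationError as exc:
            raise PedigreeError(f"row {row_id!r}: {exc}") from exc
        pedigree.add(individual)

    pedigree.validate()
    return pedigree


def write_pedigree(pedigree: Pedigree, path, missing: str = "") -> None:
    """Write a pedigree to CSV; ``read_pedigree`` round-trips it exactly."""
    frame = pedigree.to_frame()
    frame = frame.astype(object).where(pd.notna(frame), missing)
    frame.to_csv(path, index=False)


def morph_counts(
    pedigree: Pedigree,
    filter: Optional[Callable[[Individual], bool]] = None,
) -> MorphCounts:
    """Tally morph categories over the individuals selected by ``filter``.

    Every selected individual must have a morph assigned.
    """
    tallies = {m: 0 for m in MORPHS}
    for ind in pedigree:
        if filter is not None and not filter(ind):
            continue
        if ind.morph is None:
            raise PedigreeError(
                f"individual {ind.id!r} selected for counting lacks a morph"
            )
        tallies[ind.morph] += 1
    return MorphCounts.from_mapping(tallies)
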