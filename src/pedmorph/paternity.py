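"""Microsatellite paternity exclusion by allele-mismatch counting.

A candidate sire is assigned when, taking the dam as the known mother, his
genotype is compatible with the offspring at all typed loci or mismatches
at a single locus (allowing for mutation). Per-locus summaries (observed/
expected heterozygosity and PIC) support marker quality control.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple
import logging
import re

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTable",
    "PaternityCall",
    "read_genotype_table",
    "read_genepop",
    "mismatch_count",
    "count_typed_loci",
    "assign_paternity",
    "locus_summary",
]

AllelePair = Tuple[int, int]


class GenotypeTable:
    """Per-individual, per-locus unordered allele pairs (0 = missing)."""

    def __init__(self, loci: Sequence[str]):
        self.loci: Tuple[str, ...] = tuple(loci)
        self._data: Dict[str, Dict[str, Optional[AllelePair]]] = {}

    def set(self, individual: str, locus: str, pair: Optional[AllelePair]) -> None:
        if locus not in self.loci:
            raise KeyError(f"unknown locus {locus!r}")
        if pair is not None:
            a, b = pair
            if a <= 0 or b <= 0:
                raise ValueError(
                    f"{individual}/{locus}: allele sizes must be positive"
                )
            pair = (min(a, b), max(a, b))
        self._data.setdefault(individual, {})[locus] = pair

    def get(self, individual: str, locus: str) -> Optional[AllelePair]:
        return self._data.get(individual, {}).get(locus)

    @property
    def individuals(self) -> List[str]:
        return list(self._data)

    def __contains__(self, individual: str) -> bool:
        return individual in self._data


def read_genotype_table(path) -> GenotypeTable:
    """Read a wide CSV: ``id`` column plus two columns per locus.

    Paired columns are recognised by shared stem, e.g. ``Ctde03_a`` and
    ``Ctde03_b`` (suffixes ``_a/_b``, ``_1/_2`` or ``.1/.2``). A zero or
    empty cell means missing; a locus is missing when either allele is.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in frame.columns:
        raise ValueError("genotype table must have an 'id' column")
    stems: Dict[str, List[str]] = {}
    for col in frame.columns:
        if col == "id":
            continue
        stem = re.sub(r"([._](a|b|1|2))$", "", col)
        stems.setdefault(stem, []).append(col)
    loci = [s for s, cols in stems.items() if len(cols) == 2]
    bad = [s for s, cols in stems.items() if len(cols) != 2]
    if bad:
        raise ValueError(f"loci without exactly two allele columns: {bad}")
    table = GenotypeTable(loci)
    for _, row in frame.iterrows():
        ind = row["id"].strip()
        for locus in loci:
            c1, c2 = stems[locus]
            try:
                a = int(row[c1]) if row[c1].strip() else 0
                b = int(row[c2]) if row[c2].strip() else 0
            except ValueError as exc:
                raise ValueError(
                    f"{ind}/{locus}: non-integer allele call"
                ) from exc
            table.set(ind, locus, (a, b) if a > 0 and b > 0 else None)
    return table


def read_genepop(path) -> GenotypeTable:
    """Read the GenePop dialect: title line, locus names, 'Pop' blocks,
    then ``id ,  aaabbb aaabbb ...`` rows with 2- or 3-digit allele codes."""
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    if not lines:
        raise ValueError("empty genepop file")
    body = lines[1:]
    loci: List[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names may be one per line or comma-separated
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    if not loci:
        raise ValueError("no locus names before first 'Pop'")
    table = GenotypeTable(loci)
    for line in body[i:]:
        stripped = line.strip()
        if not stripped or stripped.lower() == "pop":
            continue
        if "," not in stripped:
            raise ValueError(f"malformed genepop row: {line!r}")
        name, rest = stripped.split(",", 1)
        calls = rest.split()
        if len(calls) != len(loci):
            raise ValueError(
                f"{name.strip()}: {len(calls)} genotype fields for "
                f"{len(loci)} loci"
            )
        for locus, call in zip(loci, calls):
            width = len(call) // 2
            a, b = int(call[:width]), int(call[width:])
            table.set(name.strip(), locus, (a, b) if a > 0 and b > 0 else None)
    return table


def _locus_compatible(
    offspring: AllelePair, dam: AllelePair, sire: AllelePair
) -> bool:
    """True iff some assignment of the offspring's alleles to maternal and
    paternal origin is consistent with both parents."""
    o1, o2 = offspring
    for maternal, paternal in ((o1, o2), (o2, o1)):
        if maternal in dam and paternal in sire:
            return True
    return False


def count_typed_loci(
    individual: str, table: GenotypeTable, others: Sequence[str] = ()
) -> int:
    """Loci typed in ``individual`` and every id in ``others``."""
    return sum(
        1
        for locus in table.loci
        if table.get(individual, locus) is not None
        and all(table.get(o, locus) is not None for o in others)
    )


def mismatch_count(
    offspring: str, dam: str, candidate_sire: str, table: GenotypeTable
) -> int:
    """Number of typed loci incompatible with the candidate sire.

    The dam is taken as the true mother; loci with a missing call in any of
    the three individuals are skipped (neither match nor mismatch).
    """
    mismatches = 0
    for locus in table.loci:
        trio = (
            table.get(offspring, locus),
            table.get(dam, locus),
            table.get(candidate_sire, locus),
        )
        if any(g is None for g in trio):
            continue
        if not _locus_compatible(*trio):
            mismatches += 1
    return mismatches


@dataclass(frozen=True)
class PaternityCall:
    offspring: str
    dam: str
    mismatches: Mapping[str, int]
    assigned_sire: Optional[str]
    max_mismatch: int
    reliable: bool
    reason: Optional[str] = None


def assign_paternity(
    offspring: str,
    dam: str,
    candidates: Sequence[str],
    table: GenotypeTable,
    max_mismatch: int = 1,
    min_typed_loci: int = 5,
) -> PaternityCall:
    """Assign the unique candidate within the mismatch allowance.

    Ties among qualifying candidates, or none qualifying, leave the call
    unassigned with a reason; calls on fewer than ``min_typed_loci``
    comparable loci are flagged unreliable.
    """
    if not candidates:
        return PaternityCall(
            offspring, dam, {}, None, max_mismatch, False, "no candidates"
        )
    mismatches = {c: mismatch_count(offspring, dam, c, table) for c in candidates}
    typed = {c: count_typed_loci(offspring, table, (dam, c)) for c in candidates}
    reliable = all(t >= min_typed_loci for t in typed.values())
    qualifying = [c for c in candidates if mismatches[c] <= max_mismatch]
    if not qualifying:
        return PaternityCall(
            offspring, dam, mismatches, None, max_mismatch, reliable,
            "no candidate within mismatch allowance",
        )
    best = min(mismatches[c] for c in qualifying)
    winners = [c for c in qualifying if mismatches[c] == best]
    if len(winners) > 1:
        return PaternityCall(
            offspring, dam, mismatches, None, max_mismatch, reliable,
            f"tie among {sorted(winners)}",
        )
    return PaternityCall(
        offspring, dam, mismatches, winners[0], max_mismatch, reliable
    )


def locus_summary(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus n, observed/expected heterozygosity and PIC.

    He carries the unbiased small-sample correction 2n/(2n-1) on the gene
    count (keeps He <= 1 at any n); monomorphic loci get zeros with a
    logged warning.
    """
    rows = []
    for locus in table.loci:
        pairs = [
            table.get(ind, locus)
            for ind in table.individuals
            if table.get(ind, locus) is not None
        ]
        n = len(pairs)
        if n < 2:
            raise ValueError(f"locus {locus}: fewer than 2 typed individuals")
        counter: Counter = Counter()
        het = 0
        for a, b in pairs:
            counter[a] += 1
            counter[b] += 1
            het += a != b
        freqs = [c / (2 * n) for c in counter.values()]
        if len(freqs) < 2:
            logger.warning("locus %s is monomorphic", locus)
            rows.append({"locus": locus, "n": n, "Ho": 0.0, "He": 0.0, "PIC": 0.0})
            continue
        sum_p2 = sum(p * p for p in freqs)
        he = (2 * n / (2 * n - 1)) * (1.0 - sum_p2)
        pic = 1.0 - sum_p2 - sum(
            2.0 * freqs[i] ** 2 * freqs[j] ** 2
            for i in range(len(freqs))
            for j in range(i + 1, len(freqs))
        )
        rows.append(
            {"locus": locus, "n": n, "Ho": het / n, "He": he, "PIC": pic}
        )
    return pd.DataFrame(rows, columns=["locus", "n", "Ho", "He", "PIC"])
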