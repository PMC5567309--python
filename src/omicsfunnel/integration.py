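"""Merging per-study differential-protein lists into one analysis input.

Studies report genes with a regulation direction (up/down vs. control).
Integration takes the union across studies, keeps one entry per gene, and
removes any gene reported in opposite directions by different studies —
cross-study inconsistency is treated as irresolvable, not voted on.
An optional exclusion list (typically abundant plasma proteins, which may
reflect filtration-barrier leakage rather than tissue biology) can then be
subtracted to form the second analysis arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import io

DIRECTIONS = ("up", "down")


def normalize_symbol(raw: str) -> str:
    """Trim and upper-case a gene symbol; idempotent.

    Raises ValueError for empty / whitespace-only input.
    """
    if raw is None:
        raise ValueError("gene symbol is missing")
    symbol = str(raw).strip().upper()
    if not symbol:
        raise ValueError(f"gene symbol is empty after trimming: {raw!r}")
    return symbol


@dataclass(frozen=True)
class DifferentialProteinRecord:
    """One gene's reported regulation in one study."""

    study_id: str
    gene: str
    direction: str
    fold_change: Optional[float] = None
    p_value: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.fold_change is not None and not self.fold_change > 0:
            raise ValueError(f"fold_change must be positive, got {self.fold_change!r}")
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value!r}")


@dataclass
class IntegratedProteinSet:
    """Non-redundant union of study lists with conflict/exclusion provenance."""

    members: dict[str, str]
    support: dict[str, set[str]]
    conflicts: set[str] = field(default_factory=set)
    excluded: set[str] = field(default_factory=set)

    @property
    def counts(self) -> tuple[int, int, int]:
        n_up = sum(1 for d in self.members.values() if d == "up")
        n_down = len(self.members) - n_up
        return len(self.members), n_up, n_down

    @property
    def genes(self) -> set[str]:
        return set(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, self.members[g], len(self.support.get(g, ())), ",".join(sorted(self.support.get(g, ()))))
            for g in sorted(self.members)
        ]
        return pd.DataFrame(rows, columns=["gene", "direction", "n_studies", "study_ids"])

    def write(self, path, conflicts_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if conflicts_path is not None:
            io.write_gene_list(conflicts_path, self.conflicts)

    @classmethod
    def read(cls, path) -> "IntegratedProteinSet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        members = dict(zip(df["gene"], df["direction"]))
        support = {g: set(s.split(",")) if s else set() for g, s in zip(df["gene"], df["study_ids"])}
        return cls(members=members, support=support)


def records_from_frame(df: pd.DataFrame) -> list[DifferentialProteinRecord]:
    """Build records from a study table (study_id, gene, direction, ...)."""
    records = []
    for row in df.itertuples(index=False):
        fc = getattr(row, "fold_change", None)
        pv = getattr(row, "p_value", None)
        records.append(
            DifferentialProteinRecord(
                study_id=str(row.study_id),
                gene=str(row.gene),
                direction=str(row.direction).strip().lower(),
                fold_change=None if fc is None or pd.isna(fc) else float(fc),
                p_value=None if pv is None or pd.isna(pv) else float(pv),
            )
        )
    return records


def read_study_records(path) -> list[DifferentialProteinRecord]:
    return records_from_frame(io.read_study_table(path))


def integrate(records: Iterable[DifferentialProteinRecord]) -> IntegratedProteinSet:
    """Union study records into one direction-consistent set.

    A gene reported up in any study and down in any other lands in
    ``conflicts`` and is dropped from ``members``.  Duplicate reports of the
    same gene within one study collapse silently when their directions
    agree and raise ValueError when they do not (a malformed study table,
    not a cross-study conflict).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to integrate")

    within: dict[tuple[str, str], str] = {}
    directions: dict[str, set[str]] = {}
    support: dict[str, set[str]] = {}
    for rec in records:
        key = (rec.study_id, rec.gene)
        if key in within and within[key] != rec.direction:
            raise ValueError(
                f"study {rec.study_id!r} reports gene {rec.gene!r} with both directions; malformed study table"
            )
        within[key] = rec.direction
        directions.setdefault(rec.gene, set()).add(rec.direction)
        support.setdefault(rec.gene, set()).add(rec.study_id)

    members = {g: next(iter(ds)) for g, ds in directions.items() if len(ds) == 1}
    conflicts = {g for g, ds in directions.items() if len(ds) > 1}
    return IntegratedProteinSet(
        members=dict(sorted(members.items())),
        support={g: support[g] for g in sorted(members)},
        conflicts=conflicts,
    )


def exclude_genes(s: IntegratedProteinSet, exclusion: set[str]) -> IntegratedProteinSet:
    """Remove listed genes from the set, recording them under ``excluded``."""
    exclusion = {normalize_symbol(g) for g in exclusion}
    hit = set(s.members) & exclusion
    members = {g: d for g, d in s.members.items() if g not in hit}
    return IntegratedProteinSet(
        members=members,
        support={g: set(s.support.get(g, set())) for g in members},
        conflicts=set(s.conflicts),
        excluded=set(s.excluded) | hit,
    )
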