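"""Ternary screening-matrix data model, I/O, and curation filters.

Outcomes are strictly ternary: a recorded ``1`` (active), a recorded ``0``
(inactive), or no record at all (untested).  Promiscuity degree (PD) and
test frequency are derived from this store; curation drops high-hit-rate
assays and compounds carrying interference flags.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

from promidiag.errors import (
    ConfigError,
    ConflictingOutcomeError,
    MalformedRecordError,
    MissingRecordError,
    UnknownCompoundError,
)

ACTIVE = 1
INACTIVE = 0

TRIPLET_HEADER = "compound_id\ttarget_id\toutcome"


class CompoundFlag(str, enum.Enum):
    """Interference-compound alert categories consumed as input flags."""

    PAINS = "PAINS"
    AGGREGATOR = "AGGREGATOR"
    LIABILITY = "LIABILITY"
    FLUC = "FLUC"
    CYTOTOXIC = "CYTOTOXIC"


ALL_FLAGS = frozenset(CompoundFlag)


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound: identifier, optional structure, alert flags."""

    id: str
    smiles: Optional[str] = None
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(CompoundFlag(f) for f in self.flags))


@dataclass(frozen=True)
class AssayFilterConfig:
    """Curation thresholds: assay hit-rate cap and compound flags to exclude."""

    max_hit_rate: float = 0.02
    exclude_flags: frozenset = ALL_FLAGS

    def __post_init__(self) -> None:
        if not (0.0 < self.max_hit_rate <= 1.0):
            raise ConfigError(f"max_hit_rate must be in (0, 1], got {self.max_hit_rate}")
        object.__setattr__(
            self, "exclude_flags", frozenset(CompoundFlag(f) for f in self.exclude_flags)
        )


@dataclass(frozen=True)
class CurationReport:
    """Per-criterion removal tallies; compounds with several flags count once in the final tally."""

    n_original: int
    n_final: int
    n_removed: int
    removed_by_flag: Dict[CompoundFlag, int]

    def __post_init__(self) -> None:
        if self.n_final != self.n_original - self.n_removed:
            raise ValueError("final count must equal original minus the removed union")


class ActivityMatrix:
    """Sparse ternary compound x target outcome store.

    Absent pairs are untested.  Compounds and targets may be registered
    without outcomes (e.g. a compound tested nowhere has PD = 0 and test
    frequency 0 but is still a known identifier).
    """

    def __init__(self) -> None:
        self._by_compound: Dict[str, Dict[str, int]] = {}
        self._by_target: Dict[str, Dict[str, int]] = {}

    # -- construction -------------------------------------------------

    def add_compound(self, compound: str) -> None:
        self._by_compound.setdefault(compound, {})

    def add_target(self, target: str) -> None:
        self._by_target.setdefault(target, {})

    def add(self, compound: str, target: str, outcome: int) -> None:
        if outcome not in (ACTIVE, INACTIVE):
            raise ValueError(f"outcome must be {ACTIVE} or {INACTIVE}, got {outcome!r}")
        row = self._by_compound.setdefault(compound, {})
        existing = row.get(target)
        if existing is not None:
            if existing != outcome:
                raise ConflictingOutcomeError(
                    f"conflicting outcomes for pair ({compound}, {target}): "
                    f"{existing} vs {outcome}"
                )
            return
        row[target] = outcome
        self._by_target.setdefault(target, {})[compound] = outcome

    # -- access -------------------------------------------------------

    @property
    def compounds(self) -> Set[str]:
        return set(self._by_compound)

    @property
    def targets(self) -> Set[str]:
        return set(self._by_target)

    @property
    def n_outcomes(self) -> int:
        return sum(len(row) for row in self._by_compound.values())

    def outcome(self, compound: str, target: str) -> Optional[int]:
        """Recorded outcome for a pair, or ``None`` when untested."""
        return self._by_compound.get(compound, {}).get(target)

    def outcomes_of(self, compound: str) -> Dict[str, int]:
        if compound not in self._by_compound:
            raise UnknownCompoundError(compound)
        return dict(self._by_compound[compound])

    def tested_on(self, target: str) -> Dict[str, int]:
        return dict(self._by_target.get(target, {}))

    def active_on(self, target: str) -> List[str]:
        return sorted(c for c, o in self._by_target.get(target, {}).items() if o == ACTIVE)

    def iter_outcomes(self) -> Iterator[Tuple[str, str, int]]:
        for compound in sorted(self._by_compound):
            row = self._by_compound[compound]
            for target in sorted(row):
                yield compound, target, row[target]

    def promiscuity_degree(self, compound: str) -> int:
        if compound not in self._by_compound:
            raise UnknownCompoundError(compound)
        return sum(1 for o in self._by_compound[compound].values() if o == ACTIVE)

    def test_frequency(self, compound: str) -> int:
        if compound not in self._by_compound:
            raise UnknownCompoundError(compound)
        return len(self._by_compound[compound])

    def active_targets(self, compound: str) -> List[str]:
        """Sorted targets the compound is recorded ACTIVE on."""
        if compound not in self._by_compound:
            raise UnknownCompoundError(compound)
        return sorted(t for t, o in self._by_compound[compound].items() if o == ACTIVE)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivityMatrix):
            return NotImplemented
        return (
            self._by_compound == other._by_compound
            and self.compounds == other.compounds
            and self.targets == other.targets
        )

    def __repr__(self) -> str:
        return (
            f"ActivityMatrix({len(self._by_compound)} compounds, "
            f"{len(self._by_target)} targets, {self.n_outcomes} outcomes)"
        )


def promiscuity_degree(matrix: ActivityMatrix, compound: str) -> int:
    """Number of targets the compound is recorded ACTIVE against."""
    return matrix.promiscuity_degree(compound)


def test_frequency(matrix: ActivityMatrix, compound: str) -> int:
    """Number of targets with any recorded outcome for the compound."""
    return matrix.test_frequency(compound)


def read_activity_triplets(path) -> ActivityMatrix:
    """Read a TSV of (compound_id, target_id, outcome) triplets.

    Outcome tokens are ``1`` (active) and ``0`` (inactive); absent pairs
    remain untested.  Duplicate pairs with conflicting outcomes and
    malformed tokens are hard errors carrying pair / line information.
    """
    path = Path(path)
    matrix = ActivityMatrix()
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header != TRIPLET_HEADER:
            raise MalformedRecordError(
                f"{path}: expected header {TRIPLET_HEADER!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MalformedRecordError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            compound, target, token = parts
            if token not in ("0", "1"):
                raise MalformedRecordError(
                    f"{path}:{lineno}: outcome must be '0' or '1', got {token!r}"
                )
            matrix.add(compound, target, int(token))
    return matrix


def write_activity_triplets(matrix: ActivityMatrix, path) -> None:
    """Write the matrix as a triplet TSV (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(TRIPLET_HEADER + "\n")
        for compound, target, outcome in matrix.iter_outcomes():
            fh.write(f"{compound}\t{target}\t{outcome}\n")


def filter_assays(matrix: ActivityMatrix, config: AssayFilterConfig) -> ActivityMatrix:
    """Drop targets whose hit rate (actives / tested) exceeds ``max_hit_rate``.

    Hit rate is computed over tested compounds only; targets with zero
    tested compounds are dropped (undefined rate).  Compounds left with no
    outcomes are dropped from the result.
    """
    keep_targets = set()
    for target in matrix.targets:
        tested = matrix.tested_on(target)
        if not tested:
            continue
        hit_rate = sum(1 for o in tested.values() if o == ACTIVE) / len(tested)
        if hit_rate <= config.max_hit_rate:
            keep_targets.add(target)
    out = ActivityMatrix()
    for compound, target, outcome in matrix.iter_outcomes():
        if target in keep_targets:
            out.add(compound, target, outcome)
    return out


def remove_flagged_compounds(
    matrix: ActivityMatrix,
    library: Iterable[CompoundRecord],
    config: AssayFilterConfig,
) -> Tuple[ActivityMatrix, CurationReport]:
    """Remove matrix compounds carrying any excluded interference flag.

    Per-criterion tallies count every flagged compound under each of its
    flags, while the final compound count subtracts the *union* of removed
    compounds (a compound with several alerts is removed once).
    """
    records = {r.id: r for r in library}
    missing = sorted(matrix.compounds - set(records))
    if missing:
        raise MissingRecordError(
            f"{len(missing)} matrix compounds lack a library record, e.g. {missing[:3]}"
        )
    removed: Set[str] = set()
    by_flag: Dict[CompoundFlag, int] = {f: 0 for f in sorted(config.exclude_flags, key=lambda f: f.value)}
    for compound in matrix.compounds:
        hit_flags = records[compound].flags & config.exclude_flags
        for f in hit_flags:
            by_flag[f] += 1
        if hit_flags:
            removed.add(compound)
    out = ActivityMatrix()
    for compound in matrix.compounds - removed:
        out.add_compound(compound)
    for compound, target, outcome in matrix.iter_outcomes():
        if compound not in removed:
            out.add(compound, target, outcome)
    report = CurationReport(
        n_original=len(matrix.compounds),
        n_final=len(matrix.compounds) - len(removed),
        n_removed=len(removed),
        removed_by_flag=by_flag,
    )
    return out, report


def read_compound_library(smiles_path=None, flags_path=None) -> List[CompoundRecord]:
    """Read a compound library from a .smi file and/or a flags TSV.

    The .smi dialect is ``SMILES<whitespace>id`` per line; the flags file
    has one ``compound_id<TAB>flag`` row per flag.  Either file may be
    omitted; identifiers are unioned.
    """
    smiles: Dict[str, str] = {}
    flags: Dict[str, Set[CompoundFlag]] = {}
    if smiles_path is not None:
        with Path(smiles_path).open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise MalformedRecordError(
                        f"{smiles_path}:{lineno}: expected 'SMILES id', got {line!r}"
                    )
                smiles[parts[1]] = parts[0]
    if flags_path is not None:
        with Path(flags_path).open("r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n")
            if header != "compound_id\tflag":
                raise MalformedRecordError(
                    f"{flags_path}: expected header 'compound_id\\tflag', got {header!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise MalformedRecordError(f"{flags_path}:{lineno}: expected 2 fields")
                try:
                    flag = CompoundFlag(parts[1])
                except ValueError as exc:
                    raise MalformedRecordError(f"{flags_path}:{lineno}: unknown flag {parts[1]!r}") from exc
                flags.setdefault(parts[0], set()).add(flag)
    ids = sorted(set(smiles) | set(flags))
    return [
        CompoundRecord(id=i, smiles=smiles.get(i), flags=frozenset(flags.get(i, set())))
        for i in ids
    ]
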