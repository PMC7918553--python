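"""Zinc-binding-site families and candidate-site enumeration.

A zinc-binding-site *family* is defined purely by the multiset of liganding
residue types (e.g. C2H2 = two cysteines + two histidines).  It is unrelated
to homologous protein families: the same family arises by convergent
evolution across unrelated folds.  The ten families modelled here cover the
common high-affinity sites, whose ligands are always Cys (C), His (H),
Asp (D) or Glu (E).

Candidate enumeration produces every combination of residues in a sequence
or structure whose types match a family.  In sequence mode combinations are
limited to a maximum first-to-last span; in structure mode they are limited
by a pairwise C-alpha distance cutoff (combinations with any inter-C-alpha
distance above it could not feasibly coordinate a single ion).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .structures import ProteinStructure, Residue

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
LIGAND_RESIDUES = frozenset("CHDE")

#: Default sequence-mode span bound (residues, first to last inclusive).
DEFAULT_MAX_SPAN = 200

#: Default structure-mode feasibility cutoff: no pair of candidate residues
#: may have C-alpha atoms further apart than this (Angstroms).
DEFAULT_MAX_CA_DISTANCE = 30.0

_TOKEN_RE = re.compile(r"([A-Za-z])(\d+)")


class FamilyParseError(ValueError):
    """Raised when a family-name string cannot be parsed."""


@dataclass(frozen=True, order=True)
class FamilySignature:
    """A multiset of liganding residue types, e.g. C2H2.

    Parameters
    ----------
    counts:
        Tuple of ``(one_letter_code, count)`` pairs in alphabetical order.
        Use :meth:`parse` to build one from a name like ``"C2H2"``.
    """

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        for letter, count in self.counts:
            if letter not in AMINO_ACIDS:
                raise FamilyParseError(f"invalid residue code {letter!r}")
            if count < 1:
                raise FamilyParseError(f"count for {letter} must be >= 1, got {count}")
        letters = [letter for letter, _ in self.counts]
        if letters != sorted(letters) or len(set(letters)) != len(letters):
            raise FamilyParseError("residue codes must be unique and alphabetical")

    @classmethod
    def parse(cls, spec: str) -> "FamilySignature":
        """Parse a family name like ``"C2H2"`` into a signature.

        Letter order is irrelevant (``"H2C2"`` canonicalises to ``"C2H2"``);
        repeated letters have their counts summed.
        """
        if not spec or not isinstance(spec, str):
            raise FamilyParseError("family spec must be a non-empty string")
        pos = 0
        counts: dict[str, int] = {}
        for match in _TOKEN_RE.finditer(spec):
            if match.start() != pos:
                raise FamilyParseError(
                    f"malformed family spec {spec!r} at {spec[pos:match.start()]!r}"
                )
            letter = match.group(1).upper()
            count = int(match.group(2))
            if letter not in AMINO_ACIDS:
                raise FamilyParseError(f"invalid residue code {letter!r} in {spec!r}")
            if count < 1:
                raise FamilyParseError(f"count must be positive in token {match.group(0)!r}")
            counts[letter] = counts.get(letter, 0) + count
            pos = match.end()
        if pos != len(spec) or not counts:
            raise FamilyParseError(f"malformed family spec {spec!r} at {spec[pos:]!r}")
        return cls(tuple(sorted(counts.items())))

    @property
    def residue_counts(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def canonical_name(self) -> str:
        return "".join(f"{letter}{count}" for letter, count in self.counts)

    @property
    def site_size(self) -> int:
        return sum(count for _, count in self.counts)

    @property
    def residue_letters(self) -> tuple[str, ...]:
        """The site's residue letters expanded to a sorted tuple (C2H2 -> CCHH)."""
        return tuple(
            letter for letter, count in self.counts for _ in range(count)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical_name


#: The ten modelled families, largest sites first.  Sites with four ligands
#: are the classic structural (zinc-finger-like) sites; the two-residue
#: D1H1/E1H1 families are typically catalytic sites completed by water.
SUPPORTED_FAMILY_NAMES = (
    "C4", "C3H1", "C2H2", "C3", "C2H1", "D1H2", "E1H2", "H3", "D1H1", "E1H1",
)


def supported_families() -> list[FamilySignature]:
    """Return the ten supported family signatures."""
    return [FamilySignature.parse(name) for name in SUPPORTED_FAMILY_NAMES]


def parse_family(spec: str) -> FamilySignature:
    """Parse a family-name string (``"C2H2"``) into a :class:`FamilySignature`."""
    return FamilySignature.parse(spec)


@dataclass(frozen=True)
class SequenceSiteCandidate:
    """An ordered combination of positions in a sequence matching a family.

    Positions are 0-based internally; user-facing reports are 1-based.
    """

    sequence: str
    positions: tuple[int, ...]
    family: FamilySignature
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        if len(self.positions) != self.family.site_size:
            raise ValueError(
                f"{len(self.positions)} positions for site size {self.family.site_size}"
            )
        found = sorted(self.sequence[p] for p in self.positions)
        if tuple(found) != self.family.residue_letters:
            raise ValueError(
                f"residues {''.join(found)} do not match family {self.family.canonical_name}"
            )

    @property
    def residues(self) -> str:
        return "".join(self.sequence[p] for p in self.positions)

    @property
    def span(self) -> int:
        """First-to-last extent in residues, inclusive."""
        return self.positions[-1] - self.positions[0] + 1


@dataclass(frozen=True)
class StructureSiteCandidate:
    """A combination of residues in a structure matching a family.

    Carries the residues' C-alpha/C-beta coordinates plus the parent
    structure's (non-hydrogen) atom cloud for the contrast descriptor.
    """

    residues: tuple[Residue, ...]
    family: FamilySignature
    atom_elements: tuple[str, ...]
    atom_coords: np.ndarray
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        found = sorted(res.res_type for res in self.residues)
        if tuple(found) != self.family.residue_letters:
            raise ValueError(
                f"residues {''.join(found)} do not match family {self.family.canonical_name}"
            )

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([res.ca for res in self.residues], dtype=float)

    @property
    def cb_coords(self) -> np.ndarray:
        coords = []
        for res in self.residues:
            if res.cb is None:
                raise ValueError(f"residue {res.label} has no C-beta coordinate")
            coords.append(res.cb)
        return np.array(coords, dtype=float)

    @property
    def residue_labels(self) -> tuple[str, ...]:
        """1-based chain:number labels, e.g. ``("A:12", "A:15")``."""
        return tuple(res.label for res in self.residues)


def _positions_by_type(sequence: str, family: FamilySignature) -> dict[str, list[int]]:
    wanted = {letter for letter, _ in family.counts}
    out: dict[str, list[int]] = {letter: [] for letter in wanted}
    for i, aa in enumerate(sequence):
        if aa in wanted:
            out[aa].append(i)
    return out


def _combinations(indices_by_type: Mapping[str, Sequence[int]],
                  family: FamilySignature) -> Iterable[tuple[int, ...]]:
    """Yield sorted index tuples matching the family's multiset, lexicographic."""
    per_type = []
    for letter, count in family.counts:
        available = indices_by_type.get(letter, ())
        if len(available) < count:
            return
        per_type.append(list(itertools.combinations(available, count)))
    combos = [
        tuple(sorted(itertools.chain.from_iterable(chosen)))
        for chosen in itertools.product(*per_type)
    ]
    yield from sorted(combos)


def enumerate_sequence_candidates(
    sequence: str,
    family: FamilySignature,
    max_span: int = DEFAULT_MAX_SPAN,
    source_id: Optional[str] = None,
) -> list[SequenceSiteCandidate]:
    """Enumerate every family-matching combination of positions in a sequence.

    Combinations whose first-to-last extent exceeds ``max_span`` residues are
    dropped.  Output order is lexicographic by position tuple.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if max_span < family.site_size:
        raise ValueError(f"max_span {max_span} < site size {family.site_size}")
    sequence = sequence.upper()
    by_type = _positions_by_type(sequence, family)
    out = []
    for positions in _combinations(by_type, family):
        if positions[-1] - positions[0] + 1 <= max_span:
            out.append(SequenceSiteCandidate(sequence, positions, family, source_id))
    return out


def enumerate_structure_candidates(
    structure: ProteinStructure,
    family: FamilySignature,
    max_ca_distance: float = DEFAULT_MAX_CA_DISTANCE,
) -> list[StructureSiteCandidate]:
    """Enumerate feasible family-matching residue combinations in a structure.

    Only combinations with every pairwise inter-C-alpha distance at most
    ``max_ca_distance`` Angstroms are returned (the feasibility rule: more
    distant residues could not coordinate the same ion).  Hetero/modified
    residues and residues lacking a C-alpha atom are never part of a
    candidate.  Order is deterministic (lexicographic in structure residue
    order), independent of chain naming.
    """
    residues = [
        res for res in structure.residues
        if res.res_type in LIGAND_RESIDUES and res.ca is not None
    ]
    by_type: dict[str, list[int]] = {}
    for i, res in enumerate(residues):
        by_type.setdefault(res.res_type, []).append(i)
    out = []
    for index_tuple in _combinations(by_type, family):
        chosen = [residues[i] for i in index_tuple]
        cas = np.array([res.ca for res in chosen], dtype=float)
        diffs = cas[:, None, :] - cas[None, :, :]
        dists = np.sqrt((diffs ** 2).sum(axis=-1))
        if dists.max() <= max_ca_distance:
            out.append(
                StructureSiteCandidate(
                    residues=tuple(chosen),
                    family=family,
                    atom_elements=structure.atom_elements,
                    atom_coords=structure.atom_coords,
                    source_id=structure.id,
                )
            )
    return out
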