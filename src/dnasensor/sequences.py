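"""Sensor sequence model and combinatorial mutant library enumeration.

The sensors are 30-mer ssDNA oligos with fixed hexa-cytosine flanks and an
18-nt central variable region; all engineering happens by substituting bases
inside the variable region.  A round of directed evolution enumerates every
sequence at exact variable-region Hamming distance ``k`` from a parent
(each substituted position takes one of the 3 non-parental bases), which for
``k = 3`` yields C(18,3) * 3**3 = 22,032 candidates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
FLANK = "C" * 6
SEQUENCE_LENGTH = 30
VARIABLE_LENGTH = 18
VARIABLE_START = 6  # 0-based offset of the variable region in the 30-mer

#: Sensor sequences printed in the source study (30-mers, hexa-C flanks).
KNOWN_SENSORS = {
    "original": "CCCCCCAGCCCTTCACCACCAACTCCCCCC",
    "N2-1": "CCCCCCAACCCTACACAACCACCTCCCCCC",
    "L1-14": "CCCCCCAGCACTACACAACCAACTCCCCCC",
}


class SequenceValidationError(ValueError):
    """Base class for sensor sequence validation failures."""


class SequenceLengthError(SequenceValidationError):
    """Sequence is not exactly 30 nt."""


class AlphabetError(SequenceValidationError):
    """Sequence contains a character outside A/C/G/T."""


class FlankError(SequenceValidationError):
    """One of the fixed (C)6 flanks is not all-cytosine."""


@dataclass(frozen=True, order=True)
class SensorSequence:
    """A validated 30-mer sensor sequence with fixed (C)6 flanks.

    Ordering and equality are by the base string, so libraries sort
    deterministically (lexicographically).
    """

    bases: str
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        validate_bases(self.bases)

    @property
    def variable_region(self) -> str:
        """The central 18-nt segment where mutations are allowed."""
        return self.bases[VARIABLE_START : VARIABLE_START + VARIABLE_LENGTH]

    def with_name(self, name: str) -> "SensorSequence":
        return SensorSequence(self.bases, name)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.bases


@dataclass(frozen=True)
class Mutation:
    """One substitution, 1-based position within the variable region."""

    position: int
    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= VARIABLE_LENGTH:
            raise ValueError(f"variable-region position out of range: {self.position}")
        if self.from_base == self.to_base:
            raise ValueError("mutation must change the base")

    def __str__(self) -> str:
        return f"{self.position}:{self.from_base}>{self.to_base}"


@dataclass(frozen=True)
class MutationSpec:
    """Sorted set of substitutions distinguishing two sensor sequences."""

    entries: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.entries]
        if positions != sorted(set(positions)):
            raise ValueError("mutation positions must be unique and ascending")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __str__(self) -> str:
        return ",".join(str(m) for m in self.entries)


@dataclass
class MutantLibrary:
    """Complete exact-k substitution library around a parent sequence."""

    parent: SensorSequence
    k: int
    members: list[SensorSequence]
    round_id: int = 1

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[SensorSequence]:
        return iter(self.members)

    @property
    def expected_size(self) -> int:
        return comb(VARIABLE_LENGTH, self.k) * 3**self.k


def validate_bases(bases: str) -> str:
    """Check length, alphabet and flank constraints; return ``bases``.

    Raises :class:`SequenceLengthError`, :class:`AlphabetError` or
    :class:`FlankError` so callers can tell the failure modes apart.
    """
    if len(bases) != SEQUENCE_LENGTH:
        raise SequenceLengthError(
            f"sensor sequence must be {SEQUENCE_LENGTH} nt, got {len(bases)}"
        )
    bad = set(bases) - set(ALPHABET)
    if bad:
        raise AlphabetError(f"non-ACGT characters: {sorted(bad)}")
    if bases[:6] != FLANK or bases[-6:] != FLANK:
        raise FlankError("both flanks must be CCCCCC")
    return bases


def validate_sequence(bases: str, name: str = "") -> SensorSequence:
    """Validate a raw string and wrap it as a :class:`SensorSequence`."""
    return SensorSequence(validate_bases(bases), name)


def enumerate_k_mutants(
    parent: SensorSequence, k: int, round_id: int = 1
) -> MutantLibrary:
    """Enumerate every sequence at exact variable-region Hamming distance k.

    Each of the k chosen positions is substituted to one of the 3 bases
    different from the parent base, so the library has C(18,k)*3**k members
    (22,032 for k=3).  Output order is lexicographic by sequence string, and
    enumeration is exhaustive, never sampled.
    """
    if not 0 <= k <= VARIABLE_LENGTH:
        raise ValueError(f"k must be in [0, {VARIABLE_LENGTH}], got {k}")
    members = [
        SensorSequence(FLANK + var + FLANK)
        for var in enumerate_k_substitutions(parent.variable_region, k)
    ]
    members.sort()
    return MutantLibrary(parent=parent, k=k, members=members, round_id=round_id)


def enumerate_k_substitutions(parent_var: str, k: int) -> list[str]:
    """All strings at exact Hamming distance k from ``parent_var``.

    Works on a bare variable-region string of any length, which lets tests
    cross-check the combinatorics against brute-force scans of tiny regions.
    """
    out: list[str] = []
    for positions in combinations(range(len(parent_var)), k):
        choices = [[b for b in ALPHABET if b != parent_var[p]] for p in positions]
        for subst in product(*choices):
            mutated = list(parent_var)
            for p, b in zip(positions, subst):
                mutated[p] = b
            out.append("".join(mutated))
    return out


def diff_positions(a: SensorSequence, b: SensorSequence) -> MutationSpec:
    """Variable-region substitutions turning ``a`` into ``b``.

    Positions are 1-based within the 18-nt variable region (full-sequence
    offset +6).  Both inputs are already flank-valid by construction, so the
    flanks can never differ.
    """
    entries = tuple(
        Mutation(i + 1, x, y)
        for i, (x, y) in enumerate(zip(a.variable_region, b.variable_region))
        if x != y
    )
    return MutationSpec(entries)


def _fasta_header(seq: SensorSequence, lib: MutantLibrary) -> str:
    mut = diff_positions(lib.parent, seq)
    name = seq.name or f"mut_{mut}" if len(mut) else (seq.name or "parent")
    return f"{name}|round={lib.round_id}|mut={mut}"


def write_library_fasta(lib: MutantLibrary, path: str | Path) -> None:
    """Write the library as single-line FASTA with provenance headers."""
    records = (
        SeqRecord(Seq(seq.bases), id=_fasta_header(seq, lib), description="")
        for seq in lib.members
    )
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def read_library_fasta(
    path: str | Path, parent: SensorSequence, round_id: int = 1
) -> MutantLibrary:
    """Read a FASTA library back; every record is re-validated.

    ``k`` is inferred from the first member's distance to ``parent`` (0 for an
    empty file).  A record failing validation raises with its FASTA id.
    """
    members: list[SensorSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            name = record.id.split("|")[0]
            members.append(validate_sequence(str(record.seq), name))
        except SequenceValidationError as err:
            raise type(err)(f"record {record.id!r}: {err}") from err
    members.sort()
    k = len(diff_positions(parent, members[0])) if members else 0
    return MutantLibrary(parent=parent, k=k, members=members, round_id=round_id)


def write_library_manifest(lib: MutantLibrary, path: str | Path) -> None:
    """CSV manifest: sequence, name, round_id, hamming_to_parent."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["sequence", "name", "round_id", "hamming_to_parent"])
        for seq in lib.members:
            writer.writerow(
                [seq.bases, seq.name, lib.round_id, len(diff_positions(lib.parent, seq))]
            )


def hamming(a: SensorSequence, b: SensorSequence) -> int:
    """Variable-region Hamming distance."""
    return len(diff_positions(a, b))


def iter_variable_space(length: int) -> Iterable[str]:
    """All 4**length strings over ACGT — brute-force oracle for tiny regions."""
    for tup in product(ALPHABET, repeat=length):
        yield "".join(tup)
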