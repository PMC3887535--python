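"""Genetic-code calculus for start/stop codon sets.

Unidirectional (same-strand, head-to-tail) gene overlaps are created when the
stop codon of an upstream gene or the start codon of a downstream gene is
disrupted by a point mutation and the gene boundary relocates into the
neighbouring gene.  How often that happens, and which overlap lengths are
reachable, is governed by the combinatorics of the start and stop codon sets
of the bacterial/archaeal genetic code (NCBI translation table 11).

This module provides that calculus: redundancy counts and disruption
probabilities of a codon set under uniform single-nucleotide change, the
length <-> reading-frame-phase arithmetic of head-to-tail overlaps, and the
exhaustive enumeration of the short (< 6 nt) stop/start joints that the code
permits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

BASES = ("A", "C", "G", "T")

#: Canonical start codons of translation table 11 used throughout.  ATT is a
#: rare alternative initiator; it is relevant for the combinatorics of short
#: phase-1 overlaps but is excluded from the mutation-accumulation simulations.
DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
ATT = "ATT"
DEFAULT_STOP_CODONS = ("TAA", "TAG", "TGA")


class Role(str, Enum):
    START = "start"
    STOP = "stop"


class SizeClass(str, Enum):
    SHORT = "short"
    LONG = "long"


def _validate_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3:
        raise ValueError(f"codon must be a 3-character string, got {codon!r}")
    codon = codon.upper()
    if any(b not in BASES for b in codon):
        raise ValueError(f"codon {codon!r} contains characters outside ACGT")
    return codon


@dataclass(frozen=True)
class CodonSet:
    """An ordered, duplicate-free set of start or stop codons."""

    role: Role
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(_validate_codon(c) for c in self.members)
        if not members:
            raise ValueError("codon set must be non-empty")
        if len(set(members)) != len(members):
            raise ValueError(f"duplicate codons in set: {members}")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "role", Role(self.role))

    def __contains__(self, codon: str) -> bool:
        return codon in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def start_set(include_att: bool = False) -> CodonSet:
    """The table-11 start codon set, optionally extended with ATT."""
    members = DEFAULT_START_CODONS + ((ATT,) if include_att else ())
    return CodonSet(Role.START, members)


def stop_set() -> CodonSet:
    """The table-11 stop codon set {TAA, TAG, TGA}."""
    return CodonSet(Role.STOP, DEFAULT_STOP_CODONS)


def single_nucleotide_changes(codon: str) -> list[str]:
    """All 9 codons reachable from ``codon`` by one substitution."""
    codon = _validate_codon(codon)
    out = []
    for i, b in enumerate(codon):
        for nb in BASES:
            if nb != b:
                out.append(codon[:i] + nb + codon[i + 1 :])
    return out


def redundant_change_count(codon_set: CodonSet) -> int:
    """Count single-nucleotide changes that map a member onto another member.

    Every member admits 9 single-nucleotide changes (3 positions x 3
    alternative bases), so the total number of changes considered is
    ``9 * len(codon_set)``.  A change is *functionally redundant* if its
    product is again in the set: a start codon mutating into another start
    codon, or a stop into another stop, leaves the gene boundary intact.
    """
    if len(codon_set) == 0:  # pragma: no cover - CodonSet forbids this
        raise ValueError("empty codon set")
    return sum(
        1
        for codon in codon_set
        for product in single_nucleotide_changes(codon)
        if product in codon_set
    )


def disruption_probability(codon_set: CodonSet) -> float:
    """Probability that a uniform single-nucleotide change leaves the set.

    A uniformly chosen member suffers a uniformly chosen substitution; the
    result is a disruption unless the product is itself a member.  Equals
    ``1 - redundant_change_count / (9 * |set|)``.  For table 11 this is
    21/27 for the start set and 23/27 for the stop set: stop codons are the
    less redundant, more fragile signal.
    """
    n = len(codon_set)
    return 1.0 - redundant_change_count(codon_set) / (9.0 * n)


def phase_of_length(length: int) -> int:
    """Reading-frame phase of a head-to-tail overlap of ``length`` nt.

    The two genes are frameshifted by one (phase 1) or two (phase 2)
    nucleotides; in-frame sharing is phase 0.  Because the upstream gene ends
    on a codon boundary, the overlap length determines the phase:
    ``L % 3 == 1`` -> phase 2, ``L % 3 == 2`` -> phase 1, ``L % 3 == 0`` ->
    phase 0.
    """
    if not isinstance(length, int) or isinstance(length, bool) or length < 1:
        raise ValueError(f"overlap length must be a positive integer, got {length!r}")
    return {1: 2, 2: 1, 0: 0}[length % 3]


def classify_length(length: int) -> SizeClass:
    """Short (< 6 nt shared between stop and start) versus long overlap."""
    if not isinstance(length, int) or isinstance(length, bool) or length < 1:
        raise ValueError(f"overlap length must be a positive integer, got {length!r}")
    return SizeClass.SHORT if length < 6 else SizeClass.LONG


@dataclass(frozen=True)
class ShortOverlapJoint:
    """A compatible stop/start codon pair sharing ``length`` (1-5) nt.

    ``joint_sequence`` is the merged nucleotide string spanning both codons;
    e.g. the 4-nt phase-2 joints are ATGA, GTGA and TTGA (start codon followed
    by a stop codon shifted back two positions).
    """

    stop: str
    start: str
    length: int
    phase: int = field(init=False)
    joint_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.length <= 5:
            raise ValueError("short joints share 1-5 nucleotides")
        object.__setattr__(self, "phase", phase_of_length(self.length))
        merged = _merge_joint(self.stop, self.start, self.length)
        if merged is None:
            raise ValueError(
                f"stop {self.stop} and start {self.start} are incompatible at L={self.length}"
            )
        object.__setattr__(self, "joint_sequence", merged)


def _merge_joint(stop: str, start: str, length: int) -> str | None:
    """Merge a stop codon (last 3 nt of gene 1) with a start codon (first 3 nt
    of gene 2) overlapping by ``length`` nt; None if they disagree on any
    shared position.

    Coordinates: gene 1's stop occupies offsets 0..2; gene 2's start occupies
    offsets (3 - length)..(5 - length).
    """
    stop = _validate_codon(stop)
    start = _validate_codon(start)
    s0 = 3 - length  # offset of the start codon's first base
    bases: dict[int, str] = {i: b for i, b in enumerate(stop)}
    for i, b in enumerate(start):
        pos = s0 + i
        if pos in bases and bases[pos] != b:
            return None
        bases[pos] = b
    return "".join(bases[p] for p in sorted(bases))


def enumerate_short_joints(
    phase: int,
    starts: CodonSet | None = None,
    stops: CodonSet | None = None,
) -> list[ShortOverlapJoint]:
    """All short (1-5 nt) stop/start joints of the requested phase.

    Exhausts every (stop, start, L) triple with L in 1..5 and
    ``phase_of_length(L) == phase``, keeping those where the two codons agree
    on every shared position.  With ATT included the genetic code admits 3
    phase-1 joints (ATTAA, ATTAG, ATTGA, all L=5) and 8 phase-2 joints (five
    of L=1 plus ATGA/GTGA/TTGA at L=4); without ATT no short phase-1 joint
    exists at all.
    """
    if phase not in (1, 2):
        raise ValueError("short joints exist only for phases 1 and 2")
    starts = start_set(include_att=True) if starts is None else starts
    stops = stop_set() if stops is None else stops
    if starts.role is not Role.START:
        raise ValueError(f"'starts' must have role start, got {starts.role}")
    if stops.role is not Role.STOP:
        raise ValueError(f"'stops' must have role stop, got {stops.role}")
    joints = []
    for length in range(1, 6):
        if phase_of_length(length) != phase:
            continue
        for stop in stops:
            for start in starts:
                if _merge_joint(stop, start, length) is not None:
                    joints.append(ShortOverlapJoint(stop=stop, start=start, length=length))
    # deterministic order: by length, then merged sequence
    joints.sort(key=lambda j: (j.length, j.joint_sequence, j.stop, j.start))
    return joints


def joints_to_tsv(joints: Iterable[ShortOverlapJoint]) -> str:
    """Render joints as a TSV table (joint_sequence, stop, start, length, phase)."""
    lines = ["joint_sequence\tstop\tstart\tlength\tphase"]
    for j in joints:
        lines.append(f"{j.joint_sequence}\t{j.stop}\t{j.start}\t{j.length}\t{j.phase}")
    return "\n".join(lines) + "\n"
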