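"""Mutation-accumulation simulator of two adjacent same-strand genes.

One replicate holds a forward-strand nucleotide sequence containing the
3'-end of an upstream gene (gene 1, ending in a stop codon), an intergenic
spacer, and the 5'-end of a downstream gene (gene 2, beginning with a start
codon).  Uniform random point mutations are applied one at a time.  Most
are silent with respect to the gene boundaries; a mutation that creates a
premature in-frame stop contracts gene 1, a mutation that disrupts gene 1's
stop elongates it to the next in-frame stop, and a mutation that disrupts
gene 2's start relocates the start to the nearest alternative start codon in
frame (upstream = elongation, downstream = contraction, search order set by
the criterion).  The replicate ends when the two genes overlap; the record
keeps the overlap length, its phase, which gene's elongation caused it, and
how many mutations were tried (a surrogate for evolutionary time).

Three scenarios are supported:

* scenario 1 - fixed geometry: 21 codons per gene end, intergenic distance
  60 + phase nt (sequence length 186 + phase), overlaps capped at 59 nt;
* scenario 2 - gene sizes and intergenic distances drawn from bounded
  empirical-style distributions, no overlap-length cap;
* scenario 3 - as scenario 2 but only overlaps shorter than 60 bp are
  accepted (selection against very long overlaps).

Coordinates are 1-based and inclusive throughout; both reading frames are
fixed for the whole replicate, so gene boundaries only ever move by
multiples of three.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional

from .codon_model import (
    DEFAULT_START_CODONS,
    DEFAULT_STOP_CODONS,
    phase_of_length,
)

STOPS = frozenset(DEFAULT_STOP_CODONS)

#: Empirical start codon usage in prokaryotic genomes (ATG, GTG, TTG).
EMPIRICAL_START_WEIGHTS = (0.80, 0.17, 0.03)

#: Alternative bases for each base, used to draw proposals without self-mutation.
_ALT = {
    "A": ("C", "G", "T"),
    "C": ("A", "G", "T"),
    "G": ("A", "C", "T"),
    "T": ("A", "C", "G"),
}

CAUSE_GENE1 = "gene1_elongation"
CAUSE_GENE2 = "gene2_elongation"

CRITERIA = ("elongation_first", "contraction_first", "both")
SCENARIO1_GENE_CODONS = 21  # per gene end, including the stop / start codon
SCENARIO1_INTERGENIC = 60  # + phase nt
DEFAULT_MAX_OVERLAP = 59  # scenarios 1 and 3

GeneSizeSampler = Callable[[random.Random], int]
IntergenicSampler = Callable[[random.Random, int], int]


@dataclass
class SimConfig:
    """Full parameterization of a simulation batch."""

    scenario: int = 1
    phase: int = 2
    gc_content: float = 0.5
    criterion: str = "both"
    start_usage: str = "empirical"  # "empirical" (0.80/0.17/0.03) or "uniform"
    n_replicates: int = 100_000
    seed: int = 0
    max_overlap_nt: Optional[int] = None
    gene_size_sampler: Optional[GeneSizeSampler] = None
    intergenic_sampler: Optional[IntergenicSampler] = None
    max_proposals: int = 50_000_000  # safety cap per replicate

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError(f"scenario must be 1, 2 or 3, got {self.scenario}")
        if self.phase not in (1, 2):
            raise ValueError(f"phase must be 1 or 2, got {self.phase}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError(f"gc_content must be in [0, 1], got {self.gc_content}")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}, got {self.criterion!r}")
        if self.start_usage not in ("empirical", "uniform"):
            raise ValueError(f"start_usage must be 'empirical' or 'uniform', got {self.start_usage!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_overlap_nt is None and self.scenario in (1, 3):
            self.max_overlap_nt = DEFAULT_MAX_OVERLAP
        if self.scenario == 3 and self.max_overlap_nt != DEFAULT_MAX_OVERLAP:
            raise ValueError("scenario 3 requires max_overlap_nt == 59")

    @property
    def start_codons(self) -> tuple[str, ...]:
        return DEFAULT_START_CODONS

    @property
    def start_weights(self) -> tuple[float, ...]:
        if self.start_usage == "empirical":
            return EMPIRICAL_START_WEIGHTS
        n = len(self.start_codons)
        return tuple(1.0 / n for _ in range(n))


@dataclass
class PairState:
    """Mutable two-gene state of one replicate (1-based coordinates)."""

    sequence: list[str]
    gene1_frame_anchor: int  # a codon-position-1 site of gene 1 (always 1 here)
    gene1_stop_end: int  # last base of gene 1's current stop codon
    gene2_start: int  # first base of gene 2's current start codon
    gene2_region_end: int  # last position available to gene 2
    phase: int

    @property
    def intergenic_distance(self) -> int:
        return self.gene2_start - self.gene1_stop_end - 1

    def seq_str(self) -> str:
        return "".join(self.sequence)


@dataclass(frozen=True)
class MutationProposal:
    position: int  # 1-based index into sequence
    new_base: str


@dataclass(frozen=True)
class OverlapEvent:
    """Terminal record of one replicate."""

    length: int
    phase: int
    cause: str  # CAUSE_GENE1 or CAUSE_GENE2
    mutations_tried: int = 0  # proposals, accepted and rejected
    mutations_accepted: int = 0


@dataclass(frozen=True)
class StepOutcome:
    accepted: bool
    gene1_moved: int = 0  # signed codon offset of gene 1's stop
    gene2_moved: int = 0  # signed codon offset of gene 2's start
    overlap: Optional[OverlapEvent] = None


# singletons for the two dominant outcomes: avoids per-proposal allocation
_ACCEPT_NOMOVE = StepOutcome(accepted=True)
_REJECT = StepOutcome(accepted=False)


def _draw_codon(rng: random.Random, gc: float) -> list[str]:
    return rng.choices("ACGT", ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2), k=3)


def build_initial_state(config: SimConfig, rng: random.Random) -> PairState:
    """Draw the initial non-overlapping two-gene sequence.

    Bases are i.i.d. with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    Gene 1's terminal stop is uniform over {TAA, TAG, TGA}; gene 2's start is
    drawn per the configured usage.  In-frame stop codons inside either coding
    region (other than gene 1's terminal stop) are resampled codon-wise until
    none remain; intergenic bases are unconstrained.
    """
    gc = config.gc_content
    if config.scenario == 1:
        g1_codons = SCENARIO1_GENE_CODONS
        g2_codons = SCENARIO1_GENE_CODONS
        intergenic = SCENARIO1_INTERGENIC + config.phase
    else:
        if config.gene_size_sampler is None or config.intergenic_sampler is None:
            from .synthetic_data import default_gene_size_sampler, default_intergenic_sampler

            size_sampler = config.gene_size_sampler or default_gene_size_sampler
            inter_sampler = config.intergenic_sampler or default_intergenic_sampler
        else:
            size_sampler = config.gene_size_sampler
            inter_sampler = config.intergenic_sampler
        g1_codons = size_sampler(rng)
        g2_codons = size_sampler(rng)
        intergenic = inter_sampler(rng, config.phase)
        if intergenic % 3 != config.phase % 3:
            raise ValueError(
                f"intergenic sampler returned {intergenic} nt, incompatible with phase {config.phase}"
            )

    total = 3 * g1_codons + intergenic + 3 * g2_codons
    seq = rng.choices("ACGT", ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2), k=total)

    stop_start = 3 * g1_codons - 2
    gene2_start = 3 * g1_codons + intergenic + 1

    seq[stop_start - 1 : stop_start + 2] = rng.choice(DEFAULT_STOP_CODONS)
    start = rng.choices(config.start_codons, weights=config.start_weights)[0]
    seq[gene2_start - 1 : gene2_start + 2] = start

    # codon-wise resampling of in-frame stops inside both coding regions
    for cs in range(1, stop_start - 2, 3):
        while "".join(seq[cs - 1 : cs + 2]) in STOPS:
            seq[cs - 1 : cs + 2] = _draw_codon(rng, gc)
    for cs in range(gene2_start + 3, total - 1, 3):
        while "".join(seq[cs - 1 : cs + 2]) in STOPS:
            seq[cs - 1 : cs + 2] = _draw_codon(rng, gc)

    return PairState(
        sequence=seq,
        gene1_frame_anchor=1,
        gene1_stop_end=3 * g1_codons,
        gene2_start=gene2_start,
        gene2_region_end=total,
        phase=config.phase,
    )


def find_first_inframe_stop(state: PairState, frame_anchor: int, from_pos: int) -> Optional[int]:
    """End position of the nearest in-frame stop codon at/after ``from_pos``.

    Scans codons in the frame defined by ``frame_anchor`` to the end of the
    sequence; returns None when no stop exists.
    """
    if (from_pos - frame_anchor) % 3 != 0:
        raise ValueError(
            f"from_pos {from_pos} is not a codon-position-1 site of frame anchored at {frame_anchor}"
        )
    seq = state.sequence
    total = len(seq)
    cs = from_pos
    while cs + 2 <= total:
        if seq[cs - 1] + seq[cs] + seq[cs + 1] in STOPS:
            return cs + 2
        cs += 3
    return None


def find_alternative_start(
    state: PairState,
    disrupted_at: int,
    criterion: str,
    rng: random.Random,
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS,
) -> Optional[int]:
    """Nearest in-frame start codon replacing a disrupted start at ``disrupted_at``.

    Search order: 'elongation_first' scans upstream then downstream,
    'contraction_first' the reverse, 'both' picks a uniformly random direction
    first.  The upstream scan is bounded by position 1; the downstream scan
    keeps at least one codon between the relocated start and the end of gene
    2's region.  Returns the new start position, or None when no start codon
    exists in frame (the triggering mutation is then rejected by the caller).
    """
    seq = state.sequence
    starts = frozenset(start_codons)

    def scan_up() -> Optional[int]:
        q = disrupted_at - 3
        while q >= 1:
            if seq[q - 1] + seq[q] + seq[q + 1] in starts:
                return q
            q -= 3
        return None

    def scan_down() -> Optional[int]:
        q = disrupted_at + 3
        limit = state.gene2_region_end - 5  # keep >= 1 codon after the start
        while q <= limit:
            if seq[q - 1] + seq[q] + seq[q + 1] in starts:
                return q
            q += 3
        return None

    if criterion == "elongation_first":
        order = (scan_up, scan_down)
    elif criterion == "contraction_first":
        order = (scan_down, scan_up)
    elif criterion == "both":
        order = (scan_up, scan_down) if rng.random() < 0.5 else (scan_down, scan_up)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    for scan in order:
        hit = scan()
        if hit is not None:
            return hit
    return None


def step(state: PairState, config: SimConfig, rng: random.Random) -> StepOutcome:
    """Propose one uniform point mutation and resolve its consequences.

    Accept/reject logic (gene 1 effects are resolved before gene 2 effects;
    with non-overlapping genes a single mutation can only touch one of them):

    * premature in-frame stop within gene 1 -> gene 1 contracts to it;
    * gene 1's stop disrupted -> elongate to the next in-frame stop, or
      reject when none exists downstream;
    * gene 2's start disrupted -> relocate via :func:`find_alternative_start`,
      rejecting when no start exists or the relocated gene acquires an
      in-frame premature stop;
    * a mutation creating a premature stop inside gene 2 -> reject;
    * anything else (intergenic, synonymous/nonsynonymous within a gene,
      stop->stop or start->start changes) -> accept with no boundary change.

    A boundary move that makes the genes overlap emits an
    :class:`OverlapEvent`; if a maximum overlap length is configured and the
    resulting overlap would exceed it, the mutation is rejected instead.
    Rejected proposals leave the state bit-identical.
    """
    e = state.gene1_stop_end
    s2 = state.gene2_start
    if e >= s2:
        raise ValueError("step called on a state that already overlaps")

    seq = state.sequence
    total = state.gene2_region_end
    pos = rng.randrange(total) + 1
    old = seq[pos - 1]
    new = _ALT[old][rng.randrange(3)]
    cap = config.max_overlap_nt

    if pos <= e:
        # gene 1 territory (frame anchored at 1)
        cs = pos - (pos - 1) % 3
        i = cs - 1
        if cs == e - 2:
            # the current stop codon was hit
            seq[pos - 1] = new
            codon = seq[i] + seq[i + 1] + seq[i + 2]
            if codon in STOPS:
                return _ACCEPT_NOMOVE  # redundant stop->stop change
            # disrupted: elongate to the next in-frame stop downstream
            q = cs + 3
            new_end = None
            while q + 2 <= total:
                if seq[q - 1] + seq[q] + seq[q + 1] in STOPS:
                    new_end = q + 2
                    break
                q += 3
            if new_end is None:
                seq[pos - 1] = old
                return _REJECT
            if new_end >= s2:
                length = new_end - s2 + 1
                if cap is not None and length > cap:
                    seq[pos - 1] = old
                    return _REJECT
                state.gene1_stop_end = new_end
                event = OverlapEvent(length=length, phase=phase_of_length(length), cause=CAUSE_GENE1)
                return StepOutcome(accepted=True, gene1_moved=(new_end - e) // 3, overlap=event)
            state.gene1_stop_end = new_end
            return StepOutcome(accepted=True, gene1_moved=(new_end - e) // 3)
        # interior codon of gene 1
        codon = (
            (new if i == pos - 1 else seq[i])
            + (new if i + 1 == pos - 1 else seq[i + 1])
            + (new if i + 2 == pos - 1 else seq[i + 2])
        )
        if codon in STOPS:
            if cs < 4:
                return _REJECT  # would contract gene 1 past its one-codon floor
            seq[pos - 1] = new
            moved = (cs + 2 - e) // 3
            state.gene1_stop_end = cs + 2
            return StepOutcome(accepted=True, gene1_moved=moved)
        seq[pos - 1] = new
        return _ACCEPT_NOMOVE

    if pos >= s2:
        off = (pos - s2) % 3
        cs = pos - off
        i = cs - 1
        if cs == s2:
            # the current start codon was hit
            seq[pos - 1] = new
            codon = seq[i] + seq[i + 1] + seq[i + 2]
            if codon in config.start_codons:
                return _ACCEPT_NOMOVE  # redundant start->start change
            ns = find_alternative_start(state, s2, config.criterion, rng, config.start_codons)
            if ns is None:
                seq[pos - 1] = old
                return _REJECT
            if ns < s2:
                # elongation: the region gained upstream (including the old,
                # now internal, start codon) must be free of in-frame stops
                q = ns + 3
                while q <= s2:
                    if seq[q - 1] + seq[q] + seq[q + 1] in STOPS:
                        seq[pos - 1] = old
                        return _REJECT
                    q += 3
            if ns <= e:
                length = e - ns + 1
                if cap is not None and length > cap:
                    seq[pos - 1] = old
                    return _REJECT
                state.gene2_start = ns
                event = OverlapEvent(length=length, phase=phase_of_length(length), cause=CAUSE_GENE2)
                return StepOutcome(accepted=True, gene2_moved=(ns - s2) // 3, overlap=event)
            state.gene2_start = ns
            return StepOutcome(accepted=True, gene2_moved=(ns - s2) // 3)
        if cs + 2 <= total:
            # interior codon of gene 2: premature stops are lethal
            codon = (
                (new if i == pos - 1 else seq[i])
                + (new if i + 1 == pos - 1 else seq[i + 1])
                + (new if i + 2 == pos - 1 else seq[i + 2])
            )
            if codon in STOPS:
                return _REJECT
        seq[pos - 1] = new
        return _ACCEPT_NOMOVE

    # intergenic
    seq[pos - 1] = new
    return _ACCEPT_NOMOVE


def run_replicate(config: SimConfig, rng: random.Random) -> OverlapEvent:
    """Run one replicate to overlap formation.

    ``mutations_tried`` counts every proposal, accepted or rejected (the
    accepted-only count is kept alongside).  Deterministic given the RNG
    state.
    """
    state = build_initial_state(config, rng)
    tried = 0
    accepted = 0
    cap = config.max_proposals
    while True:
        tried += 1
        if tried > cap:
            raise RuntimeError(
                f"replicate exceeded {cap} proposals without overlap formation; "
                "pathological configuration?"
            )
        out = step(state, config, rng)
        if out.accepted:
            accepted += 1
            if out.overlap is not None:
                ev = out.overlap
                return OverlapEvent(
                    length=ev.length,
                    phase=ev.phase,
                    cause=ev.cause,
                    mutations_tried=tried,
                    mutations_accepted=accepted,
                )
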