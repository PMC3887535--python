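"""Synthetic genome annotations and bounded size/distance samplers.

Two jobs live here.  First, the bounded samplers used by simulation
scenarios 2 and 3: gene sizes on 50-1000 codons and intergenic distances on
0-99 (+ phase) nt, by default truncated discretized log-normals chosen to
look like prokaryotic annotations (median gene ~250 codons, median spacer
~30 nt).  Both are injection points — any callable with the same signature
can replace them, e.g. a sampler backed by an empirical histogram.

Second, a generator of fully annotated synthetic genomes (FASTA + GFF3 +
pair-level truth table) with *planted* overlapping gene pairs of chosen
lengths and phases.  These fixtures emulate the structure of prokaryotic
genome annotations — same-strand adjacent gene pairs, controlled GC content,
head-to-tail overlaps — and drive the tests of the annotation-scanning
pipeline: scanning a generated genome must recover exactly the planted truth.
Planted genes carry valid start/stop codons and stop-free interiors in their
own frames, so fixture gene pairs are also usable as simulator micro-states.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

from .codon_model import (
    DEFAULT_START_CODONS,
    DEFAULT_STOP_CODONS,
    classify_length,
    enumerate_short_joints,
    phase_of_length,
    start_set,
    stop_set,
)

GENE_SIZE_BOUNDS = (50, 1000)  # codons
INTERGENIC_BOUNDS = (0, 99)  # nt, before the +phase adjustment
MAX_PLANTED_OVERLAP = 59

_STOPS = frozenset(DEFAULT_STOP_CODONS)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _truncated_lognormal_int(rng: random.Random, mu: float, sigma: float, lo: int, hi: int) -> int:
    """Discretized log-normal draw, rejection-truncated to [lo, hi]."""
    for _ in range(10_000):
        x = int(round(rng.lognormvariate(mu, sigma)))
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated log-normal sampler failed to converge")  # pragma: no cover


def default_gene_size_sampler(rng: random.Random) -> int:
    """Gene size in codons: log-normal, median ~65 codons, bounded 50-1000.

    The default concentrates near the lower bound of the permitted 50-1000
    codon range: under the neutral mutation-accumulation model the expected
    time to overlap formation grows explosively with gene length (the
    contraction rate of the upstream gene scales with its length, trapping
    the boundary walk far from the junction), so short genes keep replicates
    tractable.  Inject a different sampler to study other regimes.
    """
    return _truncated_lognormal_int(rng, math.log(65.0), 0.25, *GENE_SIZE_BOUNDS)


def default_intergenic_sampler(rng: random.Random, phase: int) -> int:
    """Intergenic distance in nt: log-normal median ~30 nt on [0, 99],
    floored to a multiple of 3 and shifted by the phase so the junction has
    the requested frame offset (mirrors the fixed 60 + phase geometry)."""
    base = _truncated_lognormal_int(rng, math.log(30.0), 1.0, *INTERGENIC_BOUNDS)
    return base - base % 3 + phase


@dataclass
class GenomeSpec:
    """Specification of one synthetic annotated genome."""

    n_genes: int = 50
    gc_content: float = 0.5
    strand_policy: float = 0.8  # probability the next gene keeps the previous strand
    planted_overlaps: Sequence[tuple[int, int]] = ()  # (length nt, phase)
    gene_size_distribution: Optional[Callable[[random.Random], int]] = None
    intergenic_distribution: Optional[Callable[[random.Random, int], int]] = None
    seed: int = 0
    contig_id: str = "synthetic_contig_1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.strand_policy <= 1.0:
            raise ValueError("strand_policy must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if 2 * len(self.planted_overlaps) > self.n_genes:
            raise ValueError("each planted overlap consumes two genes; n_genes too small")
        for L, phase in self.planted_overlaps:
            if L < 1 or L > MAX_PLANTED_OVERLAP:
                raise ValueError(f"planted overlap length {L} outside 1..{MAX_PLANTED_OVERLAP}")
            if phase_of_length(L) != phase:
                raise ValueError(
                    f"planted overlap ({L}, {phase}) is inconsistent: "
                    f"length {L} implies phase {phase_of_length(L)}"
                )


@dataclass
class Fixture:
    """A generated genome on disk plus its pair-level ground truth."""

    fasta_path: Path
    gff_path: Path
    truth: pd.DataFrame  # columns: upstream, downstream, kind, length, phase, size_class
    genes: list[dict] = field(repr=False, default_factory=list)


def sample_gene_size(spec: GenomeSpec, rng: random.Random) -> int:
    """Gene size in codons within [50, 1000] per the spec's distribution."""
    sampler = spec.gene_size_distribution or default_gene_size_sampler
    size = sampler(rng)
    lo, hi = GENE_SIZE_BOUNDS
    if not lo <= size <= hi:
        raise ValueError(f"gene size sampler returned {size}, outside {lo}..{hi} codons")
    return size


def sample_intergenic_distance(spec: GenomeSpec, phase: int, rng: random.Random) -> int:
    """Intergenic distance congruent to ``phase`` (mod 3) within the bounds."""
    if phase not in (1, 2):
        raise ValueError("phase must be 1 or 2")
    sampler = spec.intergenic_distribution or default_intergenic_sampler
    d = sampler(rng, phase)
    lo, hi = INTERGENIC_BOUNDS
    if not lo <= d <= hi + phase:
        raise ValueError(f"intergenic sampler returned {d}, outside {lo}..{hi + phase} nt")
    if d % 3 != phase % 3:
        raise ValueError(f"intergenic distance {d} incompatible with phase {phase}")
    return d


def _draw_nonstop_codon(rng: random.Random, gc: float) -> str:
    w = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
    while True:
        codon = "".join(rng.choices("ACGT", w, k=3))
        if codon not in _STOPS:
            return codon


def _build_single_gene(rng: random.Random, gc: float, n_codons: int) -> str:
    """A standalone gene: start codon, stop-free interior, terminal stop."""
    start = rng.choices(DEFAULT_START_CODONS, weights=(0.80, 0.17, 0.03))[0]
    interior = "".join(_draw_nonstop_codon(rng, gc) for _ in range(n_codons - 2))
    return start + interior + rng.choice(DEFAULT_STOP_CODONS)


def _frame_stop_positions(seq: list[str], lo: int, hi: int, anchor: int) -> list[int]:
    """0-based codon starts in [lo, hi) of the frame anchored at ``anchor``
    whose codon is a stop."""
    first = lo + (anchor - lo) % 3
    out = []
    for cs in range(first, hi - 2, 3):
        if "".join(seq[cs : cs + 3]) in _STOPS:
            out.append(cs)
    return out


def _build_overlap_pair(
    rng: random.Random,
    gc: float,
    length: int,
    len1_codons: int,
    len2_codons: int,
    max_attempts: int = 2000,
) -> tuple[str, int, int, int, int]:
    """Forward-sense segment holding two genes sharing ``length`` nt.

    Returns (segment, g1_start, g1_end, g2_start, g2_end) with 0-based
    half-open coordinates converted later.  Gene 1 spans [0, 3*len1); gene 2
    spans [3*len1 - length, seg_len).  Raises when no genetic-code-compatible
    stop/start joint exists for the requested length (short phase-1 overlaps
    other than L=5-with-ATT are unplantable, and ATT is not used here).
    """
    seg_len = 3 * len1_codons + 3 * len2_codons - length
    e1 = 3 * len1_codons  # exclusive end of gene 1
    s2 = e1 - length  # 0-based start of gene 2
    if s2 < 3:
        raise ValueError("overlap would consume gene 1 entirely")

    joint = None
    if length < 6:
        # ATT is admitted here: short phase-1 joints (ATTAA/ATTAG/ATTGA) exist
        # only with it, and planted fixtures exercise the scanner, not the
        # simulator's start-usage model
        joints = [
            j
            for j in enumerate_short_joints(phase_of_length(length), start_set(True), stop_set())
            if j.length == length
        ]
        if not joints:
            raise ValueError(
                f"no stop/start joint of length {length} exists in the genetic code; "
                "pair is unplantable"
            )
        joint = rng.choice(joints)

    w = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
    for _ in range(max_attempts):
        seq = rng.choices("ACGT", w, k=seg_len)
        # forced codons
        seq[0:3] = rng.choices(DEFAULT_START_CODONS, weights=(0.80, 0.17, 0.03))[0]
        seq[seg_len - 3 : seg_len] = rng.choice(DEFAULT_STOP_CODONS)
        forced = set(range(3)) | set(range(seg_len - 3, seg_len))
        if joint is not None:
            # merged stop/start span: from min(stop start, start start) of the joint
            span_start = min(e1 - 3, s2)
            for i, b in enumerate(joint.joint_sequence):
                seq[span_start + i] = b
                forced.add(span_start + i)
        else:
            seq[e1 - 3 : e1] = rng.choice(DEFAULT_STOP_CODONS)
            forced.update(range(e1 - 3, e1))
            seq[s2 : s2 + 3] = rng.choices(DEFAULT_START_CODONS, weights=(0.80, 0.17, 0.03))[0]
            forced.update(range(s2, s2 + 3))

        # iteratively clear in-frame stops from both genes' interiors,
        # resampling only unforced bases (the two frames interact inside the
        # shared window, so passes repeat until clean)
        ok = False
        for _pass in range(200):
            bad = [
                cs
                for cs in _frame_stop_positions(seq, 0, e1 - 3, 0)
            ] + [
                cs
                for cs in _frame_stop_positions(seq, s2 + 3, seg_len - 3, s2)
            ]
            bad = [cs for cs in bad if not set(range(cs, cs + 3)) <= forced]
            if not bad:
                leftover = [
                    cs
                    for cs in _frame_stop_positions(seq, 0, e1 - 3, 0)
                    + _frame_stop_positions(seq, s2 + 3, seg_len - 3, s2)
                ]
                ok = not leftover
                break
            for cs in bad:
                free = [i for i in range(cs, cs + 3) if i not in forced]
                for i in free:
                    seq[i] = rng.choices("ACGT", w)[0]
        if ok:
            return "".join(seq), 0, e1, s2, seg_len
    raise RuntimeError(
        f"failed to realize a planted overlap of length {length} after {max_attempts} attempts"
    )  # pragma: no cover


def _revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def generate_annotated_genome(spec: GenomeSpec, out_dir: str | Path) -> Fixture:
    """Write a synthetic FASTA + GFF3 genome realizing ``spec``.

    Planted overlaps become consecutive same-strand gene pairs sharing
    exactly the requested number of bases; all other adjacencies are
    non-overlapping.  The truth table lists every consecutive same-strand
    pair (real or potential) with its length, phase and size class, derived
    from the layout itself.
    """
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # blocks: planted pairs (2 genes each) and single genes, shuffled
    n_singles = spec.n_genes - 2 * len(spec.planted_overlaps)
    blocks: list[tuple[str, object]] = [("pair", lp) for lp in spec.planted_overlaps]
    blocks += [("single", None)] * n_singles
    rng.shuffle(blocks)

    gc = spec.gc_content
    sequence_parts: list[str] = []
    genes: list[dict] = []  # genomic order
    pair_membership: dict[tuple[str, str], tuple[int, int]] = {}
    cursor = 0  # 0-based length so far
    gene_idx = 0
    strand = "+" if rng.random() < 0.5 else "-"

    for kind, payload in blocks:
        # strand chain: keep previous strand with probability strand_policy
        if genes:
            if rng.random() >= spec.strand_policy:
                strand = "+" if strand == "-" else "-"
        # gap before this block
        if genes:
            gap = rng.randint(*INTERGENIC_BOUNDS)
        else:
            gap = rng.randint(10, 50)
        filler = "".join(
            rng.choices("ACGT", ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2), k=gap)
        )
        sequence_parts.append(filler)
        cursor += gap

        if kind == "single":
            n_codons = sample_gene_size(spec, rng)
            seg = _build_single_gene(rng, gc, n_codons)
            if strand == "-":
                seg = _revcomp(seg)
            gene_id = f"gene_{gene_idx:05d}"
            genes.append(
                {
                    "id": gene_id,
                    "start": cursor + 1,
                    "end": cursor + len(seg),
                    "strand": strand,
                }
            )
            gene_idx += 1
            sequence_parts.append(seg)
            cursor += len(seg)
        else:
            L, phase = payload  # validated by GenomeSpec
            len1 = sample_gene_size(spec, rng)
            len2 = sample_gene_size(spec, rng)
            seg, a0, a1, b0, b1 = _build_overlap_pair(rng, gc, L, len1, len2)
            seg_len = len(seg)
            if strand == "-":
                seg = _revcomp(seg)
                # flip 0-based half-open intervals within the segment
                a0, a1, b0, b1 = seg_len - b1, seg_len - b0, seg_len - a1, seg_len - a0
                # after the flip, interval (a) is the downstream gene 2
                ids = (f"gene_{gene_idx + 1:05d}", f"gene_{gene_idx:05d}")
            else:
                ids = (f"gene_{gene_idx:05d}", f"gene_{gene_idx + 1:05d}")
            genes.append({"id": ids[0], "start": cursor + a0 + 1, "end": cursor + a1, "strand": strand})
            genes.append({"id": ids[1], "start": cursor + b0 + 1, "end": cursor + b1, "strand": strand})
            upstream, downstream = (
                (ids[0], ids[1]) if strand == "+" else (ids[1], ids[0])
            )
            pair_membership[(upstream, downstream)] = (L, phase)
            gene_idx += 2
            sequence_parts.append(seg)
            cursor += seg_len

    # trailing spacer
    tail = rng.randint(10, 50)
    sequence_parts.append(
        "".join(rng.choices("ACGT", ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2), k=tail))
    )
    sequence = "".join(sequence_parts)

    truth = _truth_table(genes, pair_membership)

    fasta_path = out_dir / f"{spec.contig_id}.fasta"
    gff_path = out_dir / f"{spec.contig_id}.gff3"
    _write_fasta(fasta_path, spec.contig_id, sequence)
    _write_gff3(gff_path, spec.contig_id, len(sequence), genes)
    truth.to_csv(out_dir / f"{spec.contig_id}.truth.tsv", sep="\t", index=False)
    return Fixture(fasta_path=fasta_path, gff_path=gff_path, truth=truth, genes=genes)


def _truth_table(genes: list[dict], planted: dict[tuple[str, str], tuple[int, int]]) -> pd.DataFrame:
    """Ground truth for every consecutive same-strand pair, from the layout."""
    rows = []
    for left, right in zip(genes, genes[1:]):
        if left["strand"] != right["strand"]:
            continue
        if left["strand"] == "+":
            upstream, downstream = left, right
        else:
            upstream, downstream = right, left
        key = (upstream["id"], downstream["id"])
        if key in planted:
            L, phase = planted[key]
            rows.append(
                {
                    "upstream": key[0],
                    "downstream": key[1],
                    "kind": "real",
                    "length": L,
                    "phase": phase,
                    "size_class": classify_length(L).value,
                }
            )
        else:
            gap = right["start"] - left["end"] - 1
            if gap < 0:  # pragma: no cover - layout never overlaps across blocks
                raise AssertionError("unplanted adjacency overlaps")
            rows.append(
                {
                    "upstream": key[0],
                    "downstream": key[1],
                    "kind": "potential",
                    "length": 0,
                    "phase": gap % 3,
                    "size_class": "none",
                }
            )
    return pd.DataFrame(rows, columns=["upstream", "downstream", "kind", "length", "phase", "size_class"])


def _write_fasta(path: Path, contig_id: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig_id}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def _write_gff3(path: Path, contig_id: str, contig_len: int, genes: list[dict]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig_id} 1 {contig_len}\n")
        for g in genes:
            fh.write(
                f"{contig_id}\togpkit\tCDS\t{g['start']}\t{g['end']}\t.\t{g['strand']}\t0\t"
                f"ID={g['id']}\n"
            )
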