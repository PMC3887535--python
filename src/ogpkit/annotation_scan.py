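"""Empirical pipeline: overlapping gene pairs from genome annotations.

Given a genome annotation (GFF3 + FASTA, or a GenBank flat file), this module
extracts *unidirectional* gene pairs — consecutive protein-coding genes on
the same strand of the same contig — and classifies each as a real
head-to-tail overlap (the coordinate ranges intersect partially) or a
potential one (adjacent but disjoint).  Real overlaps get a length L (shared
bases), a phase (L mod 3: 1 -> phase 2, 2 -> phase 1, 0 -> phase 0) and a
short/long class (< 6 nt shared vs more); overlaps longer than 59 bp are set
aside as likely misannotations.  Potential pairs get the phase a
boundary-elongation overlap at that junction would have, determined by the
intergenic distance mod 3.

Per-genome summaries feed two comparisons: the per-phase "success ratio"
real/(real + potential), compared between phases 1 and 2 with a one-tailed
two-sample Kolmogorov-Smirnov test, and ordinary least-squares regressions
of overlap-category frequencies on genomic GC content.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import SizeClass, classify_length, phase_of_length

MAX_OVERLAP_NT = 59

KIND_REAL = "real"
KIND_POTENTIAL = "potential"

#: phase of a *potential* pair with intergenic distance d: an upstream-gene
#: elongation to a codon-aligned stop end E yields L = E - s2 + 1 == -d (mod 3),
#: so d % 3 maps 0->phase 0, 1->phase 1, 2->phase 2.
def potential_phase(intergenic_distance: int) -> int:
    if intergenic_distance < 0:
        raise ValueError("potential pairs have non-negative intergenic distance")
    return intergenic_distance % 3


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene (1-based inclusive coordinates)."""

    id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def frame_ok(self) -> bool:
        """Length divisible by 3 — expected of protein-coding records."""
        return self.length % 3 == 0


@dataclass(frozen=True)
class OverlapPair:
    """A unidirectional overlapping (real) or adjacent (potential) gene pair."""

    upstream_gene: str  # 5' gene in transcription order
    downstream_gene: str
    overlap_length: int  # 0 for potential pairs
    phase: int
    size_class: str  # "short" | "long" | "none"
    kind: str  # "real" | "potential"

    def __post_init__(self) -> None:
        if self.kind == KIND_REAL:
            if not 1 <= self.overlap_length <= MAX_OVERLAP_NT:
                raise ValueError(f"real pair length must be 1..{MAX_OVERLAP_NT}")
            if self.phase != phase_of_length(self.overlap_length):
                raise ValueError("real pair phase inconsistent with its length")
        elif self.kind == KIND_POTENTIAL:
            if self.overlap_length != 0:
                raise ValueError("potential pairs have overlap_length 0")
        else:
            raise ValueError(f"kind must be 'real' or 'potential', got {self.kind!r}")


@dataclass
class PairExtraction:
    pairs: list[OverlapPair]
    n_opposite_strand: int = 0
    n_nested: int = 0
    n_too_long: int = 0  # real overlaps > 59 bp, excluded


@dataclass
class GenomeSummary:
    genome_id: str
    gc_content: Optional[float]
    counts: Counter  # keyed by (phase, size_class, kind)

    def success_ratio(self, phase: int) -> Optional[float]:
        """real / (real + potential) for one phase; None when undefined."""
        real = sum(c for (p, _s, k), c in self.counts.items() if p == phase and k == KIND_REAL)
        potential = sum(
            c for (p, _s, k), c in self.counts.items() if p == phase and k == KIND_POTENTIAL
        )
        denom = real + potential
        if denom == 0:
            return None
        return real / denom

    def category_frequency(self, category: str) -> Optional[float]:
        """Frequency of an overlap category among this genome's real overlaps
        (phases 1 and 2 only)."""
        phase, size = _CATEGORIES[category]
        total = sum(
            c for (p, _s, k), c in self.counts.items() if k == KIND_REAL and p in (1, 2)
        )
        if total == 0:
            return None
        hits = sum(
            c
            for (p, s, k), c in self.counts.items()
            if k == KIND_REAL and p == phase and s == size
        )
        return hits / total


_CATEGORIES = {
    "long_phase1": (1, SizeClass.LONG.value),
    "long_phase2": (2, SizeClass.LONG.value),
    "short_phase2": (2, SizeClass.SHORT.value),
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    tails: int
    n: int


def read_gene_models(
    annotation_path: str | Path,
    sequence_path: str | Path | None = None,
    *,
    feature_type: str = "CDS",
    exclude_contig_keywords: Sequence[str] = (),
) -> tuple[list[GeneRecord], Optional[float]]:
    """Load protein-coding gene records plus the genome's GC content.

    ``annotation_path`` may be a GFF3 file (with ``sequence_path`` pointing at
    the matching FASTA) or a GenBank flat file (sequence included).  Records
    are sorted by contig and start.  Contigs whose id or description contains
    any of ``exclude_contig_keywords`` (e.g. "plasmid", "phage") are dropped.
    GC content is computed over all retained contig sequences; when no
    sequence is available it is None.
    """
    annotation_path = Path(annotation_path)
    suffix = annotation_path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        genes, gc = _read_genbank(annotation_path, feature_type, exclude_contig_keywords)
    else:
        genes = _read_gff3(annotation_path, feature_type)
        gc = None
        if sequence_path is not None:
            gc, excluded = _gc_from_fasta(sequence_path, exclude_contig_keywords)
            if excluded:
                genes = [g for g in genes if g.contig not in excluded]
    genes.sort(key=lambda g: (g.contig, g.start, g.end))
    return genes, gc


def _read_gff3(path: Path, feature_type: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feature_types = set(db.featuretypes())
    ftype = feature_type if feature_type in feature_types else "gene"
    if ftype not in feature_types:
        raise ValueError(
            f"annotation {path} contains neither {feature_type!r} nor 'gene' features"
        )
    genes = []
    for i, f in enumerate(db.features_of_type(ftype)):
        fid = f.attributes.get("ID", [f.id or f"feature_{i}"])[0]
        genes.append(
            GeneRecord(id=fid, contig=f.seqid, start=f.start, end=f.end, strand=f.strand)
        )
    return genes


def _read_genbank(
    path: Path, feature_type: str, exclude_keywords: Sequence[str]
) -> tuple[list[GeneRecord], Optional[float]]:
    import warnings

    from Bio import SeqIO
    from Bio.SeqFeature import CompoundLocation

    genes = []
    gc_count = 0
    base_count = 0
    for record in SeqIO.parse(str(path), "genbank"):
        text = f"{record.id} {record.description}".lower()
        if any(kw.lower() in text for kw in exclude_keywords):
            continue
        seq = str(record.seq).upper()
        gc_count += seq.count("G") + seq.count("C")
        base_count += len(seq)
        for i, feat in enumerate(record.features):
            if feat.type != feature_type:
                continue
            if isinstance(feat.location, CompoundLocation):
                warnings.warn(
                    f"skipping compound (join) location for feature {i} in {record.id}"
                )
                continue
            fid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", [f"cds_{i}"]))[0]
            genes.append(
                GeneRecord(
                    id=fid,
                    contig=record.id,
                    # GenBank locations are 0-based half-open in Biopython
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand >= 0 else "-",
                )
            )
    gc = gc_count / base_count if base_count else None
    return genes, gc


def _gc_from_fasta(
    path: str | Path, exclude_keywords: Sequence[str]
) -> tuple[Optional[float], set[str]]:
    from Bio import SeqIO

    gc_count = 0
    base_count = 0
    excluded: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        text = f"{record.id} {record.description}".lower()
        if any(kw.lower() in text for kw in exclude_keywords):
            excluded.add(record.id)
            continue
        seq = str(record.seq).upper()
        gc_count += seq.count("G") + seq.count("C")
        base_count += len(seq)
    return (gc_count / base_count if base_count else None), excluded


def extract_pairs(
    genes: Sequence[GeneRecord], max_overlap_nt: int = MAX_OVERLAP_NT
) -> PairExtraction:
    """Classify every consecutive same-strand gene pair on each contig.

    Pairs whose ranges intersect partially (neither gene nested inside the
    other) are real overlaps with L = number of shared bases; disjoint pairs
    are potential overlaps.  Opposite-strand adjacencies, nested pairs and
    real overlaps longer than ``max_overlap_nt`` are excluded and counted.
    "Upstream" always means the 5' gene in transcription order, so on the
    minus strand the right-hand gene of the pair is upstream.
    """
    result = PairExtraction(pairs=[])
    prev: Optional[GeneRecord] = None
    for gene in genes:
        if prev is not None and gene.contig == prev.contig:
            if gene.start < prev.start:
                raise ValueError("gene records must be sorted by start within each contig")
            _classify_adjacency(prev, gene, max_overlap_nt, result)
        prev = gene
    return result


def _classify_adjacency(
    left: GeneRecord, right: GeneRecord, max_overlap_nt: int, result: PairExtraction
) -> None:
    if left.strand != right.strand:
        result.n_opposite_strand += 1
        return
    # nested: one range contained in the other (includes identical ranges);
    # records arrive sorted by (start, end), so left.start <= right.start
    if right.end <= left.end or right.start == left.start:
        result.n_nested += 1
        return
    if left.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left
    shared = left.end - right.start + 1
    if shared >= 1:
        if shared > max_overlap_nt:
            result.n_too_long += 1
            return
        result.pairs.append(
            OverlapPair(
                upstream_gene=upstream.id,
                downstream_gene=downstream.id,
                overlap_length=shared,
                phase=phase_of_length(shared),
                size_class=classify_length(shared).value,
                kind=KIND_REAL,
            )
        )
    else:
        gap = right.start - left.end - 1
        result.pairs.append(
            OverlapPair(
                upstream_gene=upstream.id,
                downstream_gene=downstream.id,
                overlap_length=0,
                phase=potential_phase(gap),
                size_class="none",
                kind=KIND_POTENTIAL,
            )
        )


def dedupe_pairs(pairs: Iterable[OverlapPair]) -> list[OverlapPair]:
    """Drop exact duplicates on (length, phase, kind, size class).

    A lightweight stand-in for homology-based clustering of near-identical
    pairs: within one genome, repeated identical junction signatures are kept
    once.
    """
    seen = set()
    out = []
    for p in pairs:
        key = (p.overlap_length, p.phase, p.kind, p.size_class)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def summarize_genome(
    pairs: Iterable[OverlapPair], gc: Optional[float], genome_id: str = "genome"
) -> GenomeSummary:
    """Tabulate pair counts by (phase, size class, kind) for one genome.

    Phase-0 real overlaps are not tabulated: in-frame sharing amounts to an
    alternative start site of the same gene, not a genuine overlap.  (No real
    pair can be phase 0 here anyway, since phase is derived from length; the
    guard documents intent for externally built pairs.)  Phase-0 potential
    pairs are kept out of the success-ratio denominators the same way, by
    keying counts on phase.
    """
    counts: Counter = Counter()
    for p in pairs:
        if p.kind == KIND_REAL and p.phase == 0:
            continue
        counts[(p.phase, p.size_class, p.kind)] += 1
    return GenomeSummary(genome_id=genome_id, gc_content=gc, counts=counts)


def compare_phase_success(summaries: Sequence[GenomeSummary]) -> TestResult:
    """One-tailed two-sample KS test: phase-2 success ratios above phase-1.

    The alternative is that the per-genome distribution of phase-2
    real/(real+potential) ratios is stochastically greater than the phase-1
    distribution (its CDF lies below).  Genomes lacking either ratio are
    dropped; at least two complete genomes are required.
    """
    r1, r2 = [], []
    for s in summaries:
        a, b = s.success_ratio(1), s.success_ratio(2)
        if a is not None and b is not None:
            r1.append(a)
            r2.append(b)
    if len(r1) < 2:
        raise ValueError("need >= 2 genomes with both phase ratios defined")
    # alternative='less': CDF of the first sample lies below that of the
    # second, i.e. phase-2 ratios stochastically larger than phase-1 ratios
    ks = stats.ks_2samp(r2, r1, alternative="less")
    return TestResult(statistic=float(ks.statistic), p_value=float(ks.pvalue), tails=1, n=len(r1))


def gc_correlation(
    summaries: Sequence[GenomeSummary], category: str
) -> tuple[float, float, float]:
    """OLS regression of an overlap-category frequency on genomic GC content.

    ``category`` is one of 'long_phase1', 'long_phase2', 'short_phase2'.
    Returns (r_squared, two-sided p-value for the slope, slope).
    """
    if category not in _CATEGORIES:
        raise ValueError(f"category must be one of {sorted(_CATEGORIES)}, got {category!r}")
    xs, ys = [], []
    for s in summaries:
        freq = s.category_frequency(category)
        if s.gc_content is not None and freq is not None:
            xs.append(s.gc_content)
            ys.append(freq)
    if len(xs) < 3:
        raise ValueError("need >= 3 genomes with GC content and category frequencies")
    if math.isclose(float(np.var(xs)), 0.0):
        raise ValueError("zero variance in GC content across genomes")
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue**2), float(fit.pvalue), float(fit.slope)


def pairs_to_frame(pairs: Iterable[OverlapPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "upstream": p.upstream_gene,
                "downstream": p.downstream_gene,
                "length": p.overlap_length,
                "phase": p.phase,
                "size_class": p.size_class,
                "kind": p.kind,
            }
            for p in pairs
        ],
        columns=["upstream", "downstream", "length", "phase", "size_class", "kind"],
    )


def summary_to_frame(summary: GenomeSummary) -> pd.DataFrame:
    rows = [
        {
            "genome": summary.genome_id,
            "gc_content": summary.gc_content,
            "phase": phase,
            "size_class": size,
            "kind": kind,
            "count": count,
        }
        for (phase, size, kind), count in sorted(summary.counts.items(), key=str)
    ]
    return pd.DataFrame(
        rows, columns=["genome", "gc_content", "phase", "size_class", "kind", "count"]
    )


def scan_genome(
    annotation_path: str | Path,
    sequence_path: str | Path | None = None,
    *,
    genome_id: Optional[str] = None,
    max_overlap_nt: int = MAX_OVERLAP_NT,
    exclude_contig_keywords: Sequence[str] = (),
    dedupe: bool = False,
) -> tuple[GenomeSummary, PairExtraction]:
    """End-to-end scan of one genome: read, pair, summarize."""
    genes, gc = read_gene_models(
        annotation_path, sequence_path, exclude_contig_keywords=exclude_contig_keywords
    )
    extraction = extract_pairs(genes, max_overlap_nt=max_overlap_nt)
    pairs = dedupe_pairs(extraction.pairs) if dedupe else extraction.pairs
    gid = genome_id or Path(annotation_path).stem
    return summarize_genome(pairs, gc, genome_id=gid), extraction
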