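"""Annotation scanning: pair extraction, summaries, KS and GC regressions."""

import random

import numpy as np
import pytest

from ogpkit.annotation_scan import (
    GeneRecord,
    GenomeSummary,
    OverlapPair,
    compare_phase_success,
    extract_pairs,
    gc_correlation,
    potential_phase,
    read_gene_models,
    scan_genome,
    summarize_genome,
)
from ogpkit.codon_model import classify_length, phase_of_length
from ogpkit.synthetic_data import GenomeSpec, generate_annotated_genome


def gene(gid, start, end, strand="+", contig="c1"):
    return GeneRecord(id=gid, contig=contig, start=start, end=end, strand=strand)


# -- independent oracle --------------------------------------------------------


def oracle_classify(genes):
    """Brute-force interval arithmetic over consecutive same-strand pairs."""
    out = []
    by_contig = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig_genes in by_contig.values():
        contig_genes = sorted(contig_genes, key=lambda g: (g.start, g.end))
        for a, b in zip(contig_genes, contig_genes[1:]):
            if a.strand != b.strand:
                out.append(("opposite", None, None))
                continue
            inter = min(a.end, b.end) - max(a.start, b.start) + 1
            nested = (b.start >= a.start and b.end <= a.end) or (
                a.start >= b.start and a.end <= b.end
            )
            if nested:
                out.append(("nested", None, None))
            elif inter >= 1:
                if inter > 59:
                    out.append(("too_long", None, None))
                else:
                    out.append(("real", inter, {1: 2, 2: 1, 0: 0}[inter % 3]))
            else:
                gap = b.start - a.end - 1
                out.append(("potential", 0, gap % 3))
    return out


# -- gene records --------------------------------------------------------------


def test_gene_record_validation():
    with pytest.raises(ValueError):
        gene("bad", 100, 50)
    with pytest.raises(ValueError):
        GeneRecord(id="x", contig="c", start=1, end=9, strand="?")
    g = gene("ok", 10, 21)
    assert g.length == 12 and g.frame_ok


# -- pair extraction -----------------------------------------------------------


def test_real_pair_example():
    res = extract_pairs([gene("a", 1, 99), gene("b", 96, 200)])
    (p,) = res.pairs
    assert p.kind == "real" and p.overlap_length == 4
    assert p.phase == 2 and p.size_class == "short"
    assert p.upstream_gene == "a" and p.downstream_gene == "b"


def test_potential_pair_example():
    res = extract_pairs([gene("a", 1, 99), gene("b", 101, 200)])
    (p,) = res.pairs
    assert p.kind == "potential" and p.overlap_length == 0
    assert p.phase == 1  # gap of 1 nt -> hypothetical overlap length = 2 mod 3


def test_nested_pair_excluded():
    res = extract_pairs([gene("a", 1, 300), gene("b", 50, 100)])
    assert res.pairs == [] and res.n_nested == 1


def test_opposite_strand_excluded():
    res = extract_pairs([gene("a", 1, 99), gene("b", 96, 200, strand="-")])
    assert res.pairs == [] and res.n_opposite_strand == 1


def test_long_overlap_excluded():
    res = extract_pairs([gene("a", 1, 99), gene("b", 30, 200)])
    assert res.pairs == [] and res.n_too_long == 1


def test_minus_strand_upstream_normalization():
    # on the minus strand, the right-hand gene is the 5' (upstream) gene
    res = extract_pairs([gene("a", 1, 99, "-"), gene("b", 96, 200, "-")])
    (p,) = res.pairs
    assert p.upstream_gene == "b" and p.downstream_gene == "a"
    assert p.overlap_length == 4 and p.phase == 2


def test_unsorted_input_rejected():
    with pytest.raises(ValueError):
        extract_pairs([gene("a", 100, 200), gene("b", 1, 50)])


def test_extract_pairs_matches_interval_oracle():
    rng = random.Random(42)
    for trial in range(30):
        genes = []
        pos = 1
        for i in range(rng.randint(2, 15)):
            pos += rng.randint(-40, 120)
            pos = max(pos, genes[-1].start + 1 if genes else 1)
            length = rng.randint(9, 150)
            genes.append(
                gene(f"g{trial}_{i}", pos, pos + length - 1, rng.choice("+-"))
            )
        genes.sort(key=lambda g: (g.start, g.end))
        res = extract_pairs(genes)
        oracle = oracle_classify(genes)
        assert res.n_opposite_strand == sum(1 for k, *_ in oracle if k == "opposite")
        assert res.n_nested == sum(1 for k, *_ in oracle if k == "nested")
        assert res.n_too_long == sum(1 for k, *_ in oracle if k == "too_long")
        got = [(p.kind, p.overlap_length, p.phase) for p in res.pairs]
        want = [(k, L, ph) for k, L, ph in oracle if k in ("real", "potential")]
        assert got == want


def test_counts_invariant_under_translation_and_revcomp():
    genes = [
        gene("a", 10, 99),
        gene("b", 96, 200),
        gene("c", 260, 400),
        gene("d", 420, 500, "-"),
        gene("e", 505, 600, "-"),
    ]
    base = extract_pairs(genes)

    shifted = [gene(g.id, g.start + 1000, g.end + 1000, g.strand) for g in genes]
    shift_res = extract_pairs(shifted)

    contig_len = 700
    flipped = sorted(
        (
            gene(
                g.id,
                contig_len - g.end + 1,
                contig_len - g.start + 1,
                "+" if g.strand == "-" else "-",
            )
            for g in genes
        ),
        key=lambda g: g.start,
    )
    flip_res = extract_pairs(flipped)

    def signature(res):
        return sorted((p.kind, p.overlap_length, p.phase) for p in res.pairs)

    assert signature(base) == signature(shift_res) == signature(flip_res)


def test_potential_phase_arithmetic():
    assert [potential_phase(d) for d in (0, 1, 2, 3, 4)] == [0, 1, 2, 0, 1]
    with pytest.raises(ValueError):
        potential_phase(-1)


# -- summaries -----------------------------------------------------------------


def real_pair(L):
    return OverlapPair(
        upstream_gene="u",
        downstream_gene="d",
        overlap_length=L,
        phase=phase_of_length(L),
        size_class=classify_length(L).value,
        kind="real",
    )


def potential_pair(phase):
    return OverlapPair(
        upstream_gene="u",
        downstream_gene="d",
        overlap_length=0,
        phase=phase,
        size_class="none",
        kind="potential",
    )


def test_summarize_genome_success_ratio():
    pairs = [real_pair(4)] * 3 + [potential_pair(2)] * 7
    s = summarize_genome(pairs, gc=0.5, genome_id="g")
    assert s.success_ratio(2) == pytest.approx(0.3)
    assert s.success_ratio(1) is None  # no phase-1 pairs at all


def test_summarize_counts_round_trip():
    pairs = [real_pair(4), real_pair(4), real_pair(8), real_pair(1), potential_pair(1)]
    s = summarize_genome(pairs, gc=0.4)
    assert s.counts[(2, "short", "real")] == 3
    assert s.counts[(1, "long", "real")] == 1  # L=8 -> phase 1, long
    assert s.counts[(1, "none", "potential")] == 1


def make_summary(r1, r2, gc=0.5, gid="g"):
    """Summary with the requested per-phase success ratios (over 20 pairs)."""
    counts = {
        (1, "long", "real"): int(round(20 * r1)),
        (1, "none", "potential"): 20 - int(round(20 * r1)),
        (2, "short", "real"): int(round(20 * r2)),
        (2, "none", "potential"): 20 - int(round(20 * r2)),
    }
    from collections import Counter

    return GenomeSummary(genome_id=gid, gc_content=gc, counts=Counter(counts))


def test_ks_identical_distributions():
    summaries = [make_summary(0.3, 0.3, gid=f"g{i}") for i in range(10)]
    res = compare_phase_success(summaries)
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_ks_phase2_dominates():
    rng = random.Random(0)
    summaries = [
        make_summary(0.05 + 0.2 * rng.random(), 0.6 + 0.35 * rng.random(), gid=f"g{i}")
        for i in range(50)
    ]
    res = compare_phase_success(summaries)
    assert res.p_value < 1e-3
    assert res.tails == 1


def test_ks_requires_two_genomes():
    with pytest.raises(ValueError):
        compare_phase_success([make_summary(0.2, 0.4)])


def test_ks_null_calibration():
    """Under equal phase success the one-tailed p-value should not be
    systematically small."""
    rng = np.random.default_rng(7)
    pvals = []
    for _ in range(20):
        summaries = []
        for i in range(30):
            r = rng.uniform(0.1, 0.9)
            noise = rng.normal(0, 0.05, size=2)
            summaries.append(
                make_summary(
                    float(np.clip(r + noise[0], 0, 1)),
                    float(np.clip(r + noise[1], 0, 1)),
                    gid=f"g{i}",
                )
            )
        pvals.append(compare_phase_success(summaries).p_value)
    assert np.mean(pvals) > 0.2
    assert sum(p < 0.01 for p in pvals) <= 2


# -- GC correlations -----------------------------------------------------------


def category_summary(gc, freq_long1, gid):
    """Summary whose real overlaps are freq_long1 long-phase-1 and the rest
    short phase 2 (100 real pairs)."""
    from collections import Counter

    n1 = int(round(100 * freq_long1))
    counts = Counter({(1, "long", "real"): n1, (2, "short", "real"): 100 - n1})
    return GenomeSummary(genome_id=gid, gc_content=gc, counts=counts)


def test_gc_correlation_collinear():
    summaries = [category_summary(g, 0.9 - g, f"g{g}") for g in (0.3, 0.4, 0.5, 0.6, 0.7)]
    r2, p, slope = gc_correlation(summaries, "long_phase1")
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(-1.0)
    assert p < 0.01


def test_gc_correlation_recovers_planted_negative_trend():
    rng = np.random.default_rng(3)
    summaries = []
    for i in range(100):
        gc = rng.uniform(0.25, 0.75)
        freq = np.clip(0.8 - 0.8 * gc + rng.normal(0, 0.05), 0, 1)
        summaries.append(category_summary(gc, float(freq), f"g{i}"))
    r2, p, slope = gc_correlation(summaries, "long_phase1")
    assert slope < 0 and p < 1e-3 and r2 > 0.5


def test_gc_correlation_null():
    rng = np.random.default_rng(4)
    summaries = [
        category_summary(rng.uniform(0.3, 0.7), float(np.clip(0.4 + rng.normal(0, 0.05), 0, 1)), f"g{i}")
        for i in range(100)
    ]
    r2, p, slope = gc_correlation(summaries, "long_phase1")
    assert r2 < 0.1


def test_gc_correlation_errors():
    with pytest.raises(ValueError):
        gc_correlation([category_summary(0.5, 0.5, "a")] * 5, "no_such_category")
    with pytest.raises(ValueError):
        gc_correlation([category_summary(0.5, 0.5, str(i)) for i in range(5)], "long_phase1")


# -- file round trips ----------------------------------------------------------


def test_read_gene_models_gff_round_trip(tmp_path):
    spec = GenomeSpec(n_genes=10, gc_content=0.42, seed=5)
    fixture = generate_annotated_genome(spec, tmp_path)
    genes, gc = read_gene_models(fixture.gff_path, fixture.fasta_path)
    assert len(genes) == 10
    assert genes == sorted(genes, key=lambda g: (g.contig, g.start, g.end))
    # GC equals the actual base composition of the emitted FASTA
    seq = "".join(
        line.strip() for line in open(fixture.fasta_path) if not line.startswith(">")
    )
    expected_gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert gc == pytest.approx(expected_gc, abs=1e-12)


def test_scan_genome_end_to_end(tmp_path):
    spec = GenomeSpec(n_genes=12, planted_overlaps=[(4, 2), (7, 2)], seed=8)
    fixture = generate_annotated_genome(spec, tmp_path)
    summary, extraction = scan_genome(fixture.gff_path, fixture.fasta_path)
    reals = [p for p in extraction.pairs if p.kind == "real"]
    assert sorted(p.overlap_length for p in reals) == [4, 7]
    assert summary.gc_content is not None


def test_read_genbank(tmp_path):
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    seq = Seq("ATGAAACCCGGGTTTTAAATGCCCAAATAG" + "A" * 30)
    rec = SeqRecord(seq, id="ctg1", description="synthetic test contig")
    rec.annotations["molecule_type"] = "DNA"
    rec.features = [
        SeqFeature(SimpleLocation(0, 30, strand=1), type="CDS", qualifiers={"locus_tag": ["g1"]}),
        SeqFeature(SimpleLocation(35, 50, strand=-1), type="CDS", qualifiers={"locus_tag": ["g2"]}),
        SeqFeature(
            CompoundLocation([SimpleLocation(50, 53, strand=1), SimpleLocation(55, 58, strand=1)]),
            type="CDS",
            qualifiers={"locus_tag": ["join1"]},
        ),
    ]
    path = tmp_path / "test.gbk"
    SeqIO.write([rec], str(path), "genbank")
    with pytest.warns(UserWarning):
        genes, gc = read_gene_models(path)
    assert [g.id for g in genes] == ["g1", "g2"]
    assert genes[0].start == 1 and genes[0].end == 30
    assert genes[1].strand == "-"
    assert gc == pytest.approx((seq.count("G") + seq.count("C")) / len(seq))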