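# ogpkit

Formation and detection of **unidirectional overlapping gene pairs** in
prokaryotic genomes.

Neighbouring genes transcribed in the same direction can come to share
nucleotides head-to-tail: a point mutation disrupts the stop codon of the
upstream gene (gene 1) and its 3′-end extends to the next in-frame stop, or a
mutation disrupts the start codon of the downstream gene (gene 2) and its
5′-end relocates to another start codon upstream.  Which route dominates, and
what overlap lengths result, is largely a property of the genetic code
(NCBI translation table 11):

* the stop set {TAA, TAG, TGA} has only 4 of its 27 possible single-nucleotide
  changes mapping stop→stop, versus 6 of 27 start→start changes for
  {ATG, GTG, TTG} — so the **disruption probability** is 23/27 ≈ 0.85 for
  stops but 21/27 ≈ 0.78 for starts, biasing overlap formation toward
  3′-elongation of gene 1;
* an overlap of length *L* places the two genes in reading-frame **phase**
  *L* mod 3 (1 → phase 2, 2 → phase 1, 0 → phase 0), and the code permits
  eight short (<6 nt) stop/start joints in phase 2 (e.g. A**TGA**, G**TGA**,
  T**TGA** at *L* = 4) but only three in phase 1, all requiring the rare
  initiator ATT — so short overlaps are a phase-2 phenomenon and phase-1
  overlaps are long.

`ogpkit` provides:

* `ogpkit.codon_model` — the codon-set calculus: redundancy counts,
  disruption probabilities, length↔phase arithmetic, exhaustive enumeration
  of short stop/start joints;
* `ogpkit.simulator` — a mutation-accumulation Monte-Carlo of two adjacent
  same-strand genes: uniform point mutations, boundary updates (contraction /
  elongation of either gene), three start-search criteria, three scenarios
  (fixed 21-codon geometry; sampled gene sizes without an overlap cap;
  sampled sizes with overlaps restricted to <60 bp);
* `ogpkit.experiments` — batch execution, cause-of-overlap ratios with an
  exact binomial test, phase-1/phase-2 mutation ratios *r*, and the
  a-posteriori phase weighting *w₁* = 1/(1+*r*), *w₂* = *r*/(1+*r*);
* `ogpkit.annotation_scan` — the empirical pipeline: extract real and
  potential unidirectional gene pairs from GFF3+FASTA or GenBank annotations,
  per-genome success ratios, one-tailed Kolmogorov–Smirnov phase comparison,
  GC-content regressions;
* `ogpkit.synthetic_data` — annotated synthetic genomes with planted overlaps
  (FASTA + GFF3 + truth table) and bounded gene-size/intergenic-distance
  samplers.

## Worked example

```python
from ogpkit import (SimConfig, run_batch, start_set, stop_set,
                    disruption_probability, enumerate_short_joints)
from ogpkit.experiments import cause_ratio, mutation_ratio, weight_phases

print(f"start-set disruption probability: {disruption_probability(start_set()):.3f}")
print(f"stop-set  disruption probability: {disruption_probability(stop_set()):.3f}")
print("short phase-2 joints:",
      ", ".join(j.joint_sequence for j in enumerate_short_joints(2)))

batches = {}
for phase in (1, 2):
    cfg = SimConfig(scenario=1, phase=phase, gc_content=0.5, criterion="both",
                    start_usage="empirical", n_replicates=500, seed=42)
    batches[phase] = run_batch(cfg)
ratio, test = cause_ratio(batches[1], batches[2])
r = mutation_ratio(batches[1], batches[2])
wd = weight_phases(batches[1].length_histogram, batches[2].length_histogram, r)
print(f"gene1/gene2 cause ratio: {ratio:.2f}  (binomial p = {test.p_value:.2e})")
print(f"phase-1/phase-2 mutation ratio r: {r:.2f}")
print(f"phase weights: w1 = {wd.w1:.3f}, w2 = {wd.w2:.3f}")
print(f"weighted modal overlap lengths: {wd.mode_lengths(2)}")
```

prints

```
start-set disruption probability: 0.778
stop-set  disruption probability: 0.852
short phase-2 joints: TAATG, TAATT, TAGTG, TGATG, TGATT, ATGA, GTGA, TTGA
gene1/gene2 cause ratio: 3.67  (binomial p = 2.43e-77)
phase-1/phase-2 mutation ratio r: 1.35
phase weights: w1 = 0.425, w2 = 0.575
weighted modal overlap lengths: [4, 1]
```

Read top to bottom: stop codons are more fragile than start codons, so
overlaps caused by gene-1 elongation outnumber gene-2-caused ones (the
binomial test against a 50/50 split is decisive); phase-1 overlaps need ~1.35×
more mutations to form than phase-2 overlaps, so under equal evolutionary
time phase 1 carries weight w₁ ≈ 0.43; and the combined overlap-length
distribution peaks at 4 nt with a secondary mode at 1 nt — both short
phase-2 joints.

A command-line interface mirrors the library:

```sh
ogpkit simulate --scenario 1 --phase 2 --gc 0.5 --criterion both --n 1000 --seed 7 --out runs/p2
ogpkit scan --gff genome.gff3 --fasta genome.fasta --out scans/genome
ogpkit make-fixture --spec spec.json --out-prefix fixtures/demo
```

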