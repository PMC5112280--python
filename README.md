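# fiberma

Small-RNA sequencing analysis of microRNAs in elongating cotton fibers.

Cotton fiber is a single-cell trichome whose elongation (roughly 5–20 days
post-anthesis, DPA) is shaped by post-transcriptional regulators, among them
miRNAs. `fiberma` is a reusable, tested re-implementation of the standard
desk pipeline for this kind of study: from raw adaptor-ligated small-RNA
reads to annotated read classes, known and novel miRNA calls, normalized
temporal expression profiles, predicted target sites, and the two classic
validation analyses (5′-RACE cleavage mapping and qPCR relative expression).
Because the original sequencing libraries are not redistributable, the
package ships a seeded synthetic-data generator that emulates the study
design — four libraries at 5/10/15/20 DPA with 20–24-nt-dominated size
distributions, embedded miRNA precursors, contaminant classes and
validation data — so every stage runs against known ground truth.

## What the pipeline computes

* **Preprocessing** — 3′-adaptor trimming (≥8-nt overlap, ≤1 mismatch),
  quality/length filtering, collapsing to unique reads with counts, and the
  read-length distribution.
* **Annotation** — classification against rRNA/tRNA/snRNA/snoRNA/repeat
  reference sets (priority order, exact subsequence matching by default) and
  exhaustive genome matching on both strands with a k-mer seed-and-extend
  index (contractually identical to an all-positions scan).
* **Known miRNAs** — assignment to a miRBase-style mature reference with at
  most two substitutions at equal length; ties split counts equally; 3′
  length variants are reported as isomiRs of the same call.
* **Novel miRNAs** — read-stack seeding, RNA folding of two flanking windows
  (ViennaRNA), and the plant-miRNA hairpin criteria: mature within one arm,
  limited mature/star duplex mismatches, at most two asymmetric bulges,
  mature+star read dominance, an MFE ceiling, and the minimal folding free
  energy index

  `MFEI = 100·|MFE| / (length · GC%)`

  recorded for every candidate and flagged at 0.85 (not a hard filter).
* **Expression** — RPTM normalization (`count / clean reads × 10⁷`,
  configurable scale), selection of miRNAs with > 100 RPTM in at least one
  library, log₂ fold change versus the four-library mean, complete-linkage
  hierarchical clustering and temporal classes A (down), B (peak 10 DPA),
  C (peak 10–15 DPA), D (up).
* **Targets** — position-weighted complementarity scoring (match 0, G:U 0.5,
  mismatch 1, gap 2; penalties doubled at miRNA positions 2–13; expectation
  cutoff 3.0) scanned over a transcript set with at most one bulge.
* **Validation** — RACE clone 5′ ends mapped to miRNA-relative cleavage
  positions with per-position fractions and the canonical 9–11 window
  fraction; qPCR 2^−ΔΔCT quantification against a reference gene; Pearson
  correlation between miRNA and target temporal profiles.

## Worked example

```python
from fiberma.pipeline import PipelineConfig, run_all
from fiberma.simulate import SimulationConfig

cfg = PipelineConfig(seed=11)
cfg.sim = SimulationConfig(seed=11, genome_length=100_000, n_known_loci=8,
                           n_novel_loci=6, reads_per_library=10_000,
                           mirna_fraction=0.08)
run_all(cfg, "demo_out")
```

or equivalently `fiberma run-all --seed 11 --out demo_out`. The run
directory then contains, among others, `correlations.tsv`:

```
                 gene    mirna_id       r  anti_correlated
target_of_gar-miR150a gar-miR150a -0.9002             True
target_of_gar-miR150b gar-miR150b -0.9978             True
target_of_gar-miR158a gar-miR158a -0.6904             True
```

— each simulated target gene's 2^−ΔΔCT profile runs against its miRNA's
abundance profile, the signature of miRNA-guided cleavage — and
`hairpin_candidates.tsv`, whose passing rows are the called novel loci:

```
chrom  start   end strand                   mature        mfe  mfei  dominance
 chr1  13162 13453      +    AGAAUCGUAUUCCACCGGGUU -73.800003  0.66      0.900
 chr1  28103 28397      + ACGCGGAAUUGACUGGUCCGUUAG -68.300003  0.62      0.826
```

(`mfe` in kcal/mol; `dominance` is the fraction of precursor-mapped reads
attributable to the mature/star positions.) `table1_class_distribution.tsv`
gives the per-library read-class table with percentages of clean reads, and
`clusters.tsv` the A–D temporal class of every selected miRNA.

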