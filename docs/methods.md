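# Methods

This note documents the models, conventions and numerical choices behind
`fiberma`, and what the synthetic-data generator does and does not emulate.

## Sequence and coordinate conventions

All sequences are held internally in the DNA alphabet (T, not U); report
renderers emit U for miRNA-facing output. Coordinates are 0-based half-open
internally and 1-based closed in GFF3 and reports. Report rounding is
half-up: percentages to two decimals, fractions to three, MFEI to two.

## Synthetic study design

`SimulationConfig` encodes the study conditions: four libraries labelled
5/10/15/20 DPA, 200,000 reads per library, a 2 Mb single-chromosome genome
at 35% GC (plant-genome-like), 30 known and 16 novel embedded miRNA loci.
Smaller configurations used in the test suite and the acceptance script
(150 kb genome, 24 loci, 4 × 30,000 reads) are the package's own choice of
desk-scale problem size; they keep every locus at well above 50 expected
reads, the regime in which locus recovery is a fair ask.

Each precursor is laid down 5′→3′ as mature + loop (15–60 nt) + star, where
the star is the reverse complement of the mature carrying 0–2 substitutions.
With the canonical-overhang option (default on) the star pairs all but the
mature's 3′-terminal dinucleotide and carries two extra 3′ bases, producing
the 2-nt 3′ overhangs of a Dicer duplex: the mature's terminal dinucleotide
is absorbed into the loop and the star's dangles at the hairpin base.

Locus abundance follows four temporal archetypes (relative expectations per
library):

| class | 5 DPA | 10 DPA | 15 DPA | 20 DPA | shape |
|---|---|---|---|---|---|
| A | 1.00 | 0.60 | 0.35 | 0.18 | monotone down |
| B | 0.30 | 1.00 | 0.45 | 0.25 | peak at 10 DPA |
| C | 0.28 | 0.65 | 1.00 | 0.45 | peak at 10–15 DPA |
| D | 0.18 | 0.35 | 0.60 | 1.00 | monotone up |

Counts are negative-binomial around the expected proportions
(var = m + d·m², dispersion d = 0.1 by default, Poisson as d → 0). Reads
from a locus are 80% exact mature, 10% 3′-length isomiRs (±1–2 nt), 2%
single-substitution isomiRs, 5% star reads and 3% other precursor-mapped
reads — rare enough that the mature/star dominance criterion (≥ 0.8) holds
at true loci. Contaminant reads are exact fragments of randomly generated,
class-tagged reference sequences (matching is by subsequence identity, so
biological realism of the references is unnecessary). Background
("no annotation") reads are genome fragments drawn from Dirichlet-weighted
hotspots rather than uniformly: real unannotated sRNAs pile up at
generating loci (mostly 24-nt siRNA clusters), and hotspot structure is
what makes the false-discovery control informative. Insert lengths mix so
that 20–24 nt reads are ≥ 90% of the analysis set with 24 nt modal; mature
lengths and 5′ nucleotides are biased (21 nt and 5′ A/U most frequent) to
match the size/first-nucleotide statistics typical of plant miRNA sets.

All reads are 3′-adaptor-ligated and emitted as fixed-length 36-nt records
with constant Q40 qualities; quality filtering is modelled as a minimum
threshold these always pass. A 2% junk fraction has no adaptor and is
discarded during cleaning. Every output is a pure function of the
configuration; independent numpy Generator streams are derived per
generation step from the seed.

What the generator does **not** emulate: sequencing error models, UMI
structure, multi-chromosome genomes, repetitive-element families, spliced
transcripts, amplification-efficiency variation in qPCR. Passing tests
therefore demonstrate algorithmic correctness and statistical behaviour
under the stated noise model, not robustness to platform artefacts.

## Preprocessing

The 3′ adaptor is located by its longest prefix fitting the read tail, with
a minimum overlap of 8 nt and at most one substitution (common Illumina
practice); the leftmost such position wins. Reads without an adaptor, with
an N, below the quality threshold or outside the length bounds are tallied
by reason. Two length regimes coexist: a broad cleaning window (18–44 nt)
and the analysis window (18–28 nt) used for all downstream miRNA work; the
report distinguishes "cleaned" from "analysis-set" counts.

## Genome matching

The mapper is a k-mer seed-and-extend index reporting *all* occurrences on
both strands up to a substitution budget (0 by default, ≤ 2 supported; no
indels). Pigeonhole seeding — the read split into (mismatches + 1) disjoint
k-mers, k = 18/(mismatches + 1) — guarantees completeness; the contract,
enforced by tests against an exhaustive all-positions oracle, is exact
hit-set equality. Reads with more than 20 hits are flagged multi-mappers:
still genome-matched for the class table, but excluded from novel-locus
seeding. The read-class table is a partition: contaminant classes take
priority (rRNA > tRNA > snRNA > snoRNA > repeat, configurable), then
genome-matched, then no annotation, so per-library counts sum exactly to
clean reads.

## Known-miRNA assignment

A read is assigned to the reference mature with the fewest substitutions
(≤ 2) at equal length; ties split the read's count equally so totals are
conserved. Reads failing equal-length matching are tested as 3′-end length
variants (±1–2 nt, 5′ ends aligned) and reported as isomiRs of the same
call rather than separate miRNAs. Assignment monotonicity holds: lowering
the mismatch budget never adds calls.

## Novel-miRNA criteria

Candidate loci are clusters (merge gap ≤ 10 nt) of uniquely-placed,
unannotated, not-known-assigned reads with a summed count ≥ 5. The cluster's
modal read is the prospective mature; two windows,
`[mature−250, mature_end+20)` and `[mature−20, mature_end+250)`, allow the
mature on either arm. Windows are folded with ViennaRNA (dot-bracket + MFE);
a base-pair-maximisation folder with simple pair scores exists solely for
dependency-free testing and labels itself non-thermodynamic in output
metadata.

The duplex walk runs along the mature between consecutive paired bases. In
each inter-anchor segment with `u_m` unpaired mature bases opposite `u_s`
unpaired star bases, `min(u_m, u_s)` counts as duplex mismatches, and any
segment with `u_m ≠ u_s` counts one asymmetric bulge. Criteria (defaults,
all configurable): mature entirely within one arm with at most 4 unpaired
bases — up to two unpaired bases at each mature terminus are excluded as
canonical 2-nt overhang geometry before counting; duplex mismatches ≤ 4;
asymmetric bulges ≤ 2; mature+star (± 2 nt) read dominance ≥ 0.8 of all
window-overlapping reads; MFE ≤ −18 kcal/mol. MFEI = 100·|MFE|/(length·GC%)
with GC as a percentage (so −42.5 kcal/mol over 100 nt at 50% GC gives
exactly 0.85) is recorded and flagged at ≥ 0.85 but is **not** a hard
filter, since genuine miRNA precursors below 0.85 occur. The star is
inferred from the pair table with the 2-nt 3′ overhang convention. A locus
passing from both windows keeps the lower-MFE precursor. The exact
mature/star mismatch ceiling is not fixed by any published criterion; the
defaults follow the commonly cited plant-annotation ("gold") criteria and
are exposed in configuration.

## Expression

RPTM = count / library clean reads × scale. The scale defaults to 10⁷
(matching the unit's name, "reads per ten million"); 10⁶ is available by
configuration since both conventions circulate, and no analysis in this
package depends on the choice (selection and clustering are applied to
whichever scale is configured, and the shipped thresholds assume 10⁷).
Selection keeps rows exceeding 100 RPTM in at least one library (strict
inequality). Profiles are transformed to log₂((x + 1)/(row mean + 1)) — the
pseudocount of 1 RPTM guards zeros — and clustered with complete linkage on
Euclidean distance (Pearson-correlation distance available). The tree is
cut into k = 4 clusters; each cluster's centroid is labelled A if strictly
decreasing, D if strictly increasing, B if it peaks in library 2, C if it
peaks in library 2–3 and B is taken (first cluster by row order wins B),
otherwise unclassified. An optional |log₂FC| filter exists but is off by
default; the abundance selection alone defines "differentially expressed"
here.

## Target scoring

Expectation is a penalty sum over miRNA positions (counted from the 5′
end): match 0, G:U wobble 0.5 (orientation-aware: miRNA G:target U or
miRNA U:target G), mismatch 1, gap 2, every penalty doubled at positions
2–13 (the seed region). The scanner computes ungapped scores for every
window by vectorised prefix sums and single-gap variants (one bulged base
on either strand) by prefix/suffix decomposition; with gaps disabled it is
exactly the exhaustive per-window rescoring oracle. Hits at expectation
≤ 3.0 are reported; overlapping hits keep the lowest expectation, ties go
to the leftmost. Only cleavage-mode scoring is implemented; site
accessibility (translational-inhibition prediction) is out of scope. The
scheme is declared entirely in configuration because the external servers
it mirrors have varied their defaults over time.

## Validation

Cleavage position p means the clone's 5′ end is the target base paired to
miRNA base p (1-based from the miRNA 5′ end); the canonical fraction sums
positions 9–11. Clones outside the site ± 20 nt are tallied unmapped;
fractions are over mapped clones and sum to 1. For qPCR, technical
replicates are averaged within each biological replicate, ΔCT is taken
against the reference gene per biological replicate, ΔΔCT against the mean
calibrator ΔCT, and 2^−ΔΔCT is summarised as mean ± SD over biological
replicates only. With four time points the miRNA/target correlation is
descriptive; p-values are deliberately suppressed.

## Numerical and degenerate-input choices

Zero library totals raise rather than propagate NaN; zero-variance profiles
make correlation an error, not a warning; empty libraries are an error for
the length distribution. Folding rejects non-ACGU input and sequences over
600 nt. Half-up decimal rounding is used for all reported percentages so
printed tables are reproducible across platforms. Cluster labelling,
hit ordering and all TSV outputs are deterministic given (config, seed);
tie-breaks are by row order, genomic position, then lexicographic sequence.

## Known limitations

Recovery of an embedded locus can fail when the random flank of a folding
window supports a competing minimum-free-energy structure (observed once in
24 loci at one test seed); a production analysis would fold several trimmed
sub-windows. Known-locus star reads can seed a second (minus-strand) call of
the same hairpin; calls are deduplicated per mature placement, not per
overlapping interval. The contaminant matcher is exact-substring by default
and does not model divergent rRNA fragments. The mapper does not support
indels or spliced alignment.
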