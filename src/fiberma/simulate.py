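"""Seeded generator of synthetic sequencing inputs with known ground truth.

Emulates the study design the pipeline targets: four small-RNA libraries from
elongating cotton fibers (5/10/15/20 days post-anthesis), a reference genome
with embedded known and novel miRNA precursors, contaminant reference sets
(rRNA/tRNA/snRNA/snoRNA/repeats), target transcripts carrying complementary
sites, 5'-RACE clone tables concentrated at the canonical cleavage position,
and qPCR Ct tables whose target expression runs against the miRNA's temporal
profile.

Every output is a deterministic function of ``SimulationConfig`` (the seed
fully determines all bytes written).  Expression follows four temporal
archetypes:

* class A — monotone decreasing across the four libraries,
* class B — peak in library 2 (10 DPA),
* class C — peak in library 2 or 3 (10-15 DPA),
* class D — monotone increasing.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError, SizingError
from .seq import revcomp

CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")

# Temporal archetypes: expected relative abundance in the four libraries.
ARCHETYPE_PROFILES: dict[str, tuple[float, ...]] = {
    "A": (1.0, 0.60, 0.35, 0.18),
    "B": (0.30, 1.0, 0.45, 0.25),
    "C": (0.28, 0.65, 1.0, 0.45),
    "D": (0.18, 0.35, 0.60, 1.0),
}

# Insert-length mixture for background genome fragments and contaminants:
# 20-24 nt >= 90% of reads, 24 nt modal, echoing fiber sRNA libraries where
# 24-nt heterochromatic siRNAs dominate.
DEFAULT_LENGTH_MIX: dict[int, float] = {
    18: 0.010, 19: 0.015, 20: 0.070, 21: 0.210, 22: 0.090,
    23: 0.230, 24: 0.320, 25: 0.025, 26: 0.015, 27: 0.010, 28: 0.005,
}

# Mature-length and 5'-nucleotide biases of the embedded miRNA loci
# (21 nt dominant, 24 nt second; 5'-A and 5'-U most frequent).
MATURE_LENGTH_MIX: dict[int, float] = {19: 0.02, 20: 0.05, 21: 0.45, 22: 0.12, 23: 0.04, 24: 0.32}
FIRST_NT_MIX: dict[str, float] = {"A": 0.39, "T": 0.33, "C": 0.13, "G": 0.15}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study-design defaults."""

    seed: int = 0
    genome_length: int = 2_000_000
    gc_content: float = 0.35
    n_known_loci: int = 30
    n_novel_loci: int = 16
    n_contaminant_refs: dict[str, int] = field(
        default_factory=lambda: {"rRNA": 8, "tRNA": 8, "snRNA": 4, "snoRNA": 4, "repeat": 6}
    )
    library_labels: tuple[str, ...] = ("5DPA", "10DPA", "15DPA", "20DPA")
    reads_per_library: int = 200_000
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}
    )
    adaptor_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    adaptor_5p: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    dispersion: float = 0.1  # negative-binomial; ->0 degenerates to Poisson
    mature_len: int = 21  # used when length sampling disabled
    sample_mature_len: bool = True
    loop_len_range: tuple[int, int] = (15, 60)
    max_star_mutations: int = 2
    star_overhang: bool = True  # canonical 2-nt 3' overhang geometry
    mirna_fraction: float = 0.05
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.010, "tRNA": 0.0008, "snRNA": 0.0002,
            "snoRNA": 0.0002, "repeat": 0.0006,
        }
    )
    junk_fraction: float = 0.02
    read_length: int = 36
    quality_char: str = "I"
    # validation-data knobs
    n_validated_mirnas: int = 8
    clones_per_target: int = 30
    p_canonical: float = 0.7
    site_mismatches: int = 0
    site_gu: int = 0
    anticorrelation_strength: float = 0.9
    ct_bio_sd: float = 0.15
    ct_tech_sd: float = 0.05
    window: int = 250  # folding-window allowance used for genome sizing

    def validate(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigurationError("gc_content must be in [0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_mix must sum to 1")
        if any(v < 0 for v in self.class_mix.values()):
            raise ConfigurationError("class_mix fractions must be nonnegative")
        if set(self.class_mix) - set("ABCD"):
            raise ConfigurationError("class_mix keys must be in {A,B,C,D}")
        if len(self.library_labels) != 4:
            raise ConfigurationError("exactly four libraries are modelled")
        footprint = (self.n_known_loci + self.n_novel_loci) * (
            2 * self.window + self.mature_len * 2 + self.loop_len_range[1]
        )
        if self.genome_length < 10 * footprint:
            raise SizingError(
                f"genome_length {self.genome_length} < 10x precursor footprint {footprint}"
            )
        frac = self.mirna_fraction + self.junk_fraction + sum(self.contaminant_fractions.values())
        if frac >= 1.0:
            raise ConfigurationError("read-source fractions exceed 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generation step."""
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class Locus:
    """One embedded miRNA precursor with its ground truth."""

    locus_id: str
    chrom: str
    start: int  # 0-based half-open precursor interval
    end: int
    strand: str
    mature: str
    star: str
    loop: str
    known: bool
    family: str | None
    class_label: str
    weight: float  # relative abundance among miRNA loci
    star_mutations: int

    @property
    def precursor(self) -> str:
        return self.mature + self.loop + self.star

    @property
    def mature_start(self) -> int:
        return self.start

    @property
    def mature_end(self) -> int:
        return self.start + len(self.mature)

    def expected_profile(self) -> tuple[float, ...]:
        return ARCHETYPE_PROFILES[self.class_label]


@dataclass
class TargetTruth:
    transcript_id: str
    mirna_id: str
    mirna_seq: str
    site_start: int  # 0-based half-open on the transcript
    site_end: int
    cleavage_offset: int  # 1-based miRNA position opposite the true cut


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    genome: dict[str, str]
    loci: list[Locus]
    contaminant_refs: dict[str, list[tuple[str, str]]]  # class -> [(id, seq)]
    transcripts: dict[str, str] = field(default_factory=dict)
    targets: list[TargetTruth] = field(default_factory=list)
    race_clones: list[dict] = field(default_factory=list)
    qpcr_rows: list[dict] = field(default_factory=list)
    spikes: dict[str, dict[str, int]] = field(default_factory=dict)  # label -> source counts

    def locus_by_id(self, locus_id: str) -> Locus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise InputError(f"unknown locus {locus_id!r}")

    def mature_reference(self) -> list[tuple[str, str]]:
        """miRBase-style (id, mature) records for the known loci."""
        return [(loc.locus_id, loc.mature) for loc in self.loci if loc.known]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Introduce exactly k substitutions at distinct positions."""
    if k == 0 or not seq:
        return seq
    s = list(seq)
    pos = rng.choice(len(s), size=min(k, len(s)), replace=False)
    for i in pos:
        s[i] = str(rng.choice([c for c in "ACGT" if c != s[i]]))
    return "".join(s)


def _sample_from_mix(rng: np.random.Generator, mix: dict) -> object:
    keys = list(mix)
    p = np.array([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _nb_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + d*m^2; Poisson as d -> 0."""
    means = np.asarray(means, dtype=float)
    if dispersion < 1e-9:
        return rng.poisson(means)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(means, 1e-12))
    return rng.negative_binomial(r, p)


def generate_genome(cfg: SimulationConfig) -> GroundTruth:
    """Random genome with embedded miRNA precursors plus contaminant refs.

    Each precursor is laid down 5'->3' as mature + loop + star, where the star
    arm is the reverse complement of the mature (minus a 2-nt 3' overhang when
    ``star_overhang``) carrying 0-``max_star_mutations`` substitutions, so the
    locus folds into a canonical stem-loop.
    """
    cfg.validate()
    rng = cfg.rng(1)
    chrom = "chr1"
    genome = list(_random_seq(rng, cfg.genome_length, cfg.gc_content))

    n_loci = cfg.n_known_loci + cfg.n_novel_loci
    # Evenly spaced slots with at least one folding window of clearance.
    spacing = cfg.genome_length // (n_loci + 1)
    min_spacing = 2 * cfg.window + 2 * 24 + cfg.loop_len_range[1] + 20
    if spacing < min_spacing:
        raise SizingError("genome too short for the requested number of loci")

    class_labels = list(cfg.class_mix)
    class_p = np.array([cfg.class_mix[c] for c in class_labels])
    # Known loci grouped into families of 1-3 members.
    families: list[str] = []
    fam_no = 150
    while len(families) < cfg.n_known_loci:
        size = int(rng.integers(1, 4))
        fam = f"miR{fam_no}"
        families.extend([fam] * size)
        fam_no += int(rng.integers(1, 9))
    families = families[: cfg.n_known_loci]

    loci: list[Locus] = []
    fam_member: Counter[str] = Counter()
    for i in range(n_loci):
        known = i < cfg.n_known_loci
        if cfg.sample_mature_len:
            mlen = int(_sample_from_mix(rng, MATURE_LENGTH_MIX))
        else:
            mlen = cfg.mature_len
        first = str(_sample_from_mix(rng, FIRST_NT_MIX))
        mature = first + _random_seq(rng, mlen - 1, 0.5)
        loop = _random_seq(rng, int(rng.integers(*cfg.loop_len_range)), 0.5)
        nmut = int(rng.integers(0, cfg.max_star_mutations + 1))
        if cfg.star_overhang:
            # star pairs mature[0:mlen-2]; its own 3' dinucleotide dangles at
            # the hairpin base, mature's 3' dinucleotide joins the loop.
            core = _mutate(rng, revcomp(mature)[2:], nmut)
            star = core + _random_seq(rng, 2, 0.5)
        else:
            star = _mutate(rng, revcomp(mature), nmut)
        precursor = mature + loop + star
        start = spacing * (i + 1)
        genome[start : start + len(precursor)] = list(precursor)
        label = class_labels[int(rng.choice(len(class_labels), p=class_p))]
        weight = float(np.exp(rng.normal(0.0, 0.5)))
        if known:
            fam = families[i]
            fam_member[fam] += 1
            locus_id = f"gar-{fam}{chr(ord('a') + fam_member[fam] - 1)}"
        else:
            fam = None
            locus_id = f"novel-{i - cfg.n_known_loci + 1:03d}"
        loci.append(
            Locus(
                locus_id=locus_id, chrom=chrom, start=start, end=start + len(precursor),
                strand="+", mature=mature, star=star, loop=loop, known=known,
                family=fam, class_label=label, weight=weight, star_mutations=nmut,
            )
        )

    refs: dict[str, list[tuple[str, str]]] = {}
    for cls in CONTAMINANT_CLASSES:
        n_refs = cfg.n_contaminant_refs.get(cls, 0)
        refs[cls] = [
            (f"{cls}_{j + 1}", _random_seq(rng, int(rng.integers(120, 301)), 0.5))
            for j in range(n_refs)
        ]

    return GroundTruth(genome={chrom: "".join(genome)}, loci=loci, contaminant_refs=refs)


def _locus_read(rng: np.random.Generator, loc: Locus) -> str:
    """One read from a locus: mostly exact mature, some isomiRs/star/other."""
    u = rng.random()
    pre = loc.precursor
    if u < 0.80:
        return loc.mature
    if u < 0.90:  # 3'-end length isomiR, +/-1-2 nt
        delta = int(rng.choice([-2, -1, 1, 2]))
        if delta > 0:
            ext = pre[len(loc.mature) : len(loc.mature) + delta]
            return loc.mature + ext if len(ext) == delta else loc.mature
        return loc.mature[:delta]
    if u < 0.92:  # single-substitution isomiR
        return _mutate(rng, loc.mature, 1)
    if u < 0.97:  # star reads
        return loc.star
    # other precursor-mapped reads (loop-overlapping), kept rare so the
    # mature/star dominance criterion holds at the embedded loci
    off = int(rng.integers(0, max(1, len(pre) - 21)))
    return pre[off : off + 21]


def generate_libraries(
    cfg: SimulationConfig, truth: GroundTruth
) -> dict[str, list[tuple[str, str]]]:
    """Raw adaptor-ligated reads per library: {label: [(read_id, seq), ...]}.

    Read sources: miRNA loci (archetype-driven counts), contaminant
    fragments, random genome fragments (the no-annotation background) and a
    small unligated junk fraction.  Exactly ``reads_per_library`` reads are
    emitted per library.
    """
    cfg.validate()
    if not truth.loci:
        raise InputError("ground truth has no loci; run generate_genome first")
    rng = cfg.rng(2)
    chrom = next(iter(truth.genome))
    genome = truth.genome[chrom]
    n_lib = len(cfg.library_labels)

    # Expected per-locus counts: locus weight x archetype profile, scaled so
    # each library's miRNA share is mirna_fraction of reads_per_library.
    profiles = np.array([loc.expected_profile() for loc in truth.loci])
    weights = np.array([loc.weight for loc in truth.loci])
    expected = profiles * weights[:, None]  # loci x libraries
    col_sums = expected.sum(axis=0)
    expected = expected / col_sums * cfg.mirna_fraction * cfg.reads_per_library

    libraries: dict[str, list[tuple[str, str]]] = {}
    truth.spikes = {}
    n_hotspots = max(20, cfg.genome_length // 2000)
    hotspots = rng.integers(0, len(genome) - 60, size=n_hotspots)
    hotspot_w = rng.dirichlet(np.full(n_hotspots, 0.5))
    len_keys = np.array(sorted(DEFAULT_LENGTH_MIX))
    len_p = np.array([DEFAULT_LENGTH_MIX[k] for k in len_keys], dtype=float)
    len_p /= len_p.sum()

    for li, label in enumerate(cfg.library_labels):
        reads: list[str] = []
        counts = _nb_counts(rng, expected[:, li], cfg.dispersion)
        for loc, c in zip(truth.loci, counts):
            for _ in range(int(c)):
                reads.append(_locus_read(rng, loc))
        n_mirna = len(reads)

        spike: dict[str, int] = {"miRNA": n_mirna}
        for cls in CONTAMINANT_CLASSES:
            frac = cfg.contaminant_fractions.get(cls, 0.0)
            refs = truth.contaminant_refs.get(cls, [])
            n_cls = int(_nb_counts(rng, np.array([frac * cfg.reads_per_library]),
                                   cfg.dispersion)[0]) if refs and frac > 0 else 0
            spike[cls] = n_cls
            for _ in range(n_cls):
                _, ref = refs[int(rng.integers(len(refs)))]
                ln = int(len_keys[rng.choice(len(len_keys), p=len_p)])
                off = int(rng.integers(0, max(1, len(ref) - ln)))
                reads.append(ref[off : off + ln])

        n_junk = int(round(cfg.junk_fraction * cfg.reads_per_library))
        n_background = cfg.reads_per_library - len(reads) - n_junk
        if n_background < 0:
            raise ConfigurationError("read-source fractions overflow reads_per_library")
        spike["junk"] = n_junk
        spike["background"] = n_background
        # background reads stack at discrete hotspots (siRNA-like clusters),
        # not uniformly: real no-annotation sRNAs pile up at generating loci
        lens = len_keys[rng.choice(len(len_keys), size=n_background, p=len_p)]
        hs = hotspots[rng.choice(len(hotspots), size=n_background, p=hotspot_w)]
        jit = rng.integers(-2, 3, size=n_background)
        for ln, off, j in zip(lens, hs, jit):
            s = max(0, min(len(genome) - 30, int(off) + int(j)))
            reads.append(genome[s : s + int(ln)])

        records: list[tuple[str, str]] = []
        for j, insert in enumerate(reads):
            raw = (insert + cfg.adaptor_3p)[: cfg.read_length]
            if len(raw) < cfg.read_length:
                raw += _random_seq(rng, cfg.read_length - len(raw), 0.5)
            records.append((f"{label}_{j + 1}", raw))
        for j in range(n_junk):  # unligated junk: no adaptor, discarded in cleaning
            records.append(
                (f"{label}_junk_{j + 1}", _random_seq(rng, cfg.read_length, 0.5))
            )
        perm = rng.permutation(len(records))
        libraries[label] = [records[int(i)] for i in perm]
        truth.spikes[label] = spike
        assert len(libraries[label]) == cfg.reads_per_library
    return libraries


def _site_for(rng: np.random.Generator, cfg: SimulationConfig, mature: str) -> str:
    """A near-perfect complementary target site (5'->3' on the transcript)."""
    site = list(revcomp(mature))
    if cfg.site_gu:
        # G:U wobble: replace a complement C (opposite miRNA G) by T
        cand = [i for i, b in enumerate(site) if b == "C"]
        for i in rng.choice(cand, size=min(cfg.site_gu, len(cand)), replace=False):
            site[int(i)] = "T"
    if cfg.site_mismatches:
        idx = rng.choice(len(site), size=cfg.site_mismatches, replace=False)
        for i in idx:
            site[int(i)] = str(rng.choice([c for c in "ACGT" if c != site[int(i)]]))
    return "".join(site)


def generate_transcripts_and_validation(cfg: SimulationConfig, truth: GroundTruth) -> None:
    """Populate transcripts, RACE clone records and qPCR Ct tables in truth.

    For ``n_validated_mirnas`` loci (preferring class A/D for clear temporal
    signal) a transcript embedding a complementary site is created; RACE clone
    5' ends fall opposite miRNA position 10 with probability ``p_canonical``;
    Ct values encode a latent target expression anti-correlated with the
    locus's archetype profile.
    """
    if not truth.loci:
        raise InputError("ground truth has no loci; run generate_genome first")
    rng = cfg.rng(3)
    ordered = sorted(
        truth.loci, key=lambda loc: (loc.class_label not in ("A", "D"), loc.locus_id)
    )
    chosen = ordered[: cfg.n_validated_mirnas]

    truth.transcripts = {}
    truth.targets = []
    truth.race_clones = []
    truth.qpcr_rows = []

    # reference gene: flat Ct across samples
    ref_gene = "UBQ10"
    ref_ct = 20.0
    for si, sample in enumerate(cfg.library_labels):
        for b in range(1, 4):
            bio = rng.normal(0.0, cfg.ct_bio_sd)
            for t in range(1, 4):
                truth.qpcr_rows.append(
                    {"gene": ref_gene, "sample": sample, "bio_rep": b, "tech_rep": t,
                     "ct": round(ref_ct + bio + rng.normal(0.0, cfg.ct_tech_sd), 3)}
                )

    for k, loc in enumerate(chosen):
        tid = f"TC{600000 + k}"
        up = _random_seq(rng, int(rng.integers(120, 250)), 0.45)
        down = _random_seq(rng, int(rng.integers(120, 250)), 0.45)
        site = _site_for(rng, cfg, loc.mature)
        seq = up + site + down
        truth.transcripts[tid] = seq
        s0, s1 = len(up), len(up) + len(site)
        tt = TargetTruth(
            transcript_id=tid, mirna_id=loc.locus_id, mirna_seq=loc.mature,
            site_start=s0, site_end=s1, cleavage_offset=10,
        )
        truth.targets.append(tt)

        # RACE clones: 5' end opposite miRNA base 10 with prob p_canonical
        canonical_pos0 = s1 - tt.cleavage_offset  # 0-based transcript index
        for c in range(cfg.clones_per_target):
            if rng.random() < cfg.p_canonical:
                pos0 = canonical_pos0
            else:
                pos0 = int(rng.integers(max(0, s0 - 10), min(len(seq), s1 + 10)))
            truth.race_clones.append(
                {"target_id": tid, "clone_id": f"{tid}_cl{c + 1}",
                 "five_prime_pos_1based": pos0 + 1}
            )

        # qPCR: latent target expression anti-correlated with miRNA archetype
        prof = np.array(loc.expected_profile())
        inverted = prof.max() + prof.min() - prof
        s = cfg.anticorrelation_strength
        target_expr = (1 - s) * np.full(4, prof.mean()) + s * inverted
        target_expr = target_expr / target_expr.max()
        gene = f"target_of_{loc.locus_id}"
        for si, sample in enumerate(cfg.library_labels):
            base_ct = ref_ct + 4.0 - np.log2(target_expr[si])
            for b in range(1, 4):
                bio = rng.normal(0.0, cfg.ct_bio_sd)
                for t in range(1, 4):
                    truth.qpcr_rows.append(
                        {"gene": gene, "sample": sample, "bio_rep": b, "tech_rep": t,
                         "ct": round(base_ct + bio + rng.normal(0.0, cfg.ct_tech_sd), 3)}
                    )


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving dinucleotide composition (Eulerian-walk method)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        edges[a] = [edges[a][i] for i in rng.permutation(len(edges[a]))]
    # keep the last edge into the terminal character for walk feasibility
    out = [seq[0]]
    counts = {a: len(v) for a, v in edges.items()}
    cur = seq[0]
    while counts.get(cur, 0) > 0:
        nxt = edges[cur].pop()
        counts[cur] -= 1
        out.append(nxt)
        cur = nxt
    if len(out) != len(seq):  # rare dead-end: fall back to plain shuffle
        arr = list(seq)
        arr = [arr[i] for i in rng.permutation(len(arr))]
        return "".join(arr)
    return "".join(out)


# ---------------------------------------------------------------------------
# file output


def write_fasta(path: Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_outputs(cfg: SimulationConfig, truth: GroundTruth,
                  libraries: dict[str, list[tuple[str, str]]], outdir: str | Path) -> None:
    """Write genome, libraries, references, validation tables and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", sorted(truth.genome.items()))
    write_fasta(out / "mature_ref.fa", truth.mature_reference())
    for cls, refs in truth.contaminant_refs.items():
        write_fasta(out / f"contaminant_{cls}.fa", refs)
    for label, records in libraries.items():
        with open(out / f"lib_{label}.fastq", "w") as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{cfg.quality_char * len(seq)}\n")
    if truth.transcripts:
        write_fasta(out / "transcripts.fa", sorted(truth.transcripts.items()))
    with open(out / "race_clones.tsv", "w") as fh:
        fh.write("target_id\tclone_id\tfive_prime_pos_1based\n")
        for row in truth.race_clones:
            fh.write(f"{row['target_id']}\t{row['clone_id']}\t{row['five_prime_pos_1based']}\n")
    with open(out / "qpcr_ct.tsv", "w") as fh:
        fh.write("gene\tsample\tbio_rep\ttech_rep\tct\n")
        for row in truth.qpcr_rows:
            fh.write(f"{row['gene']}\t{row['sample']}\t{row['bio_rep']}"
                     f"\t{row['tech_rep']}\t{row['ct']}\n")
    payload = {
        "config": dataclasses.asdict(cfg),
        "loci": [dataclasses.asdict(loc) for loc in truth.loci],
        "targets": [dataclasses.asdict(t) for t in truth.targets],
        "spikes": truth.spikes,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_all(cfg: SimulationConfig, outdir: str | Path | None = None):
    """Run all three generation steps; optionally write files.

    Returns (truth, libraries).
    """
    truth = generate_genome(cfg)
    libraries = generate_libraries(cfg, truth)
    generate_transcripts_and_validation(cfg, truth)
    if outdir is not None:
        write_outputs(cfg, truth, libraries, outdir)
    return truth, libraries
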