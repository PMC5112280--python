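"""Benchmark experiments: parameter recovery and oracle-agreement suites.

These functions re-run the pipeline on seeded synthetic studies and measure
how well it recovers the generator's ground truth, and check the fast
implementations against independent exhaustive oracles (vectorised
all-positions genome scan, per-window duplex rescoring, constructed duplex
structures with known bulge counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import AnnotatedLibrary, GenomeHit, GenomeIndex, classify_contaminants, map_to_genome
from .expression import cluster_profiles
from .known import KnownMiRNACall, assign_known
from .novel import HairpinCandidate, _duplex_walk, call_novel
from .folding import pair_table
from .preprocess import ReadLibrary, clean_reads
from .simulate import (
    ARCHETYPE_PROFILES,
    GroundTruth,
    SimulationConfig,
    dinucleotide_shuffle,
    generate_genome,
    generate_libraries,
    simulate_all,
)
from .targets import exhaustive_scan, scan_transcripts, score_duplex
from .seq import revcomp


def recovery_config(seed: int) -> SimulationConfig:
    """Study conditions for the end-to-end recovery experiment.

    Sized for desk-scale compute: a 150 kb genome with 24 embedded loci and
    four libraries of 30k reads, keeping every locus at >= 50 expected reads.
    """
    return SimulationConfig(
        seed=seed,
        genome_length=150_000,
        n_known_loci=12,
        n_novel_loci=12,
        reads_per_library=30_000,
        mirna_fraction=0.06,
    )


@dataclass
class CoreResult:
    truth: GroundTruth
    annotated: list[AnnotatedLibrary]
    known_calls: list[KnownMiRNACall]
    assigned: set[str]
    candidates: list[HairpinCandidate]
    passing: list[HairpinCandidate]


def run_core(cfg: SimulationConfig, genome_override: dict[str, str] | None = None,
             truth_libs=None) -> CoreResult:
    """Simulate (or reuse) a study and run cleaning->annotation->calling."""
    if truth_libs is None:
        truth, libraries = simulate_all(cfg)
    else:
        truth, libraries = truth_libs
    genome = genome_override or truth.genome
    libs = []
    for label in cfg.library_labels:
        triples = ((rid, seq, [40] * len(seq)) for rid, seq in libraries[label])
        libs.append(clean_reads(triples, cfg.adaptor_3p, label=label))
    index = GenomeIndex(genome)
    annotated = [
        map_to_genome(classify_contaminants(lib, truth.contaminant_refs), index)
        for lib in libs
    ]
    known_calls, assigned = assign_known(annotated, truth.mature_reference())
    candidates, passing = call_novel(annotated, genome, assigned)
    return CoreResult(truth, annotated, known_calls, assigned, candidates, passing)


def recovery_metrics(seed: int) -> dict:
    """Recall of embedded loci and surviving-call rate on a shuffled genome."""
    cfg = recovery_config(seed)
    truth, libraries = simulate_all(cfg)
    res = run_core(cfg, truth_libs=(truth, libraries))

    called_known = {c.mirna_id for c in res.known_calls}
    recovered = 0
    for loc in truth.loci:
        if loc.known:
            recovered += loc.locus_id in called_known
        else:
            recovered += any(
                p.chrom == loc.chrom and p.start <= loc.mature_start
                and p.end >= loc.mature_end for p in res.passing
            )
    recall_pct = 100.0 * recovered / len(truth.loci)

    rng = np.random.default_rng([seed, 97])
    shuffled = {c: dinucleotide_shuffle(s, rng) for c, s in truth.genome.items()}
    res_shuf = run_core(cfg, genome_override=shuffled, truth_libs=(truth, libraries))
    shuffled_call_pct = 100.0 * len(res_shuf.passing) / len(truth.loci)
    return {
        "n_loci": len(truth.loci),
        "recall_pct": recall_pct,
        "shuffled_call_pct": shuffled_call_pct,
        "n_passing_real": len(res.passing),
        "n_passing_shuffled": len(res_shuf.passing),
        "core": res,
    }


# ---------------------------------------------------------------------------
# genome-mapper oracle


def vectorized_all_position_hits(genome: str, read: str, max_mismatch: int = 0) -> list[GenomeHit]:
    """Independent exhaustive oracle: scan every position with numpy.

    Hamming distance of the read (and its reverse complement) against every
    genome window, both strands, no seeding heuristics.
    """
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    out: list[GenomeHit] = []
    for query, strand in ((read, "+"), (revcomp(read), "-")):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        L = len(q)
        if L > len(g):
            continue
        win = np.lib.stride_tricks.sliding_window_view(g, L)
        d = (win != q).sum(axis=1)
        for s in np.flatnonzero(d <= max_mismatch):
            out.append(GenomeHit("chr1", int(s), int(s) + L, strand, int(d[s])))
    out.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return out


def mapper_oracle_agreement(seed: int, genome_len: int = 100_000,
                            n_reads: int = 1000) -> dict:
    """Fraction of reads whose hit sets match the exhaustive oracle exactly."""
    rng = np.random.default_rng([seed, 11])
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=genome_len)])
    reads = []
    for _ in range(n_reads // 2):  # genome-derived with 0-2 substitutions
        s = int(rng.integers(0, genome_len - 28))
        L = int(rng.integers(18, 29))
        read = list(genome[s : s + L])
        for _ in range(int(rng.integers(0, 3))):
            read[int(rng.integers(L))] = "ACGT"[int(rng.integers(4))]
        seq = "".join(read)
        reads.append(seq if rng.random() < 0.5 else revcomp(seq))
    for _ in range(n_reads - len(reads)):  # random reads
        L = int(rng.integers(18, 29))
        reads.append("".join("ACGT"[i] for i in rng.integers(0, 4, size=L)))
    agree = 0
    checked = 0
    for mm in (0, 1, 2):
        index = GenomeIndex(genome, mm)
        subset = reads[mm::3]
        for read in subset:
            checked += 1
            agree += index.find(read) == vectorized_all_position_hits(genome, read, mm)
    return {"agreement_pct": 100.0 * agree / checked, "n_checked": checked}


# ---------------------------------------------------------------------------
# duplex-walk (bulge/mismatch) oracle


def random_duplex_with_truth(rng: np.random.Generator):
    """A random two-arm duplex structure with bulge/mismatch counts known
    by construction (segments of paired runs and internal loops)."""
    left, right = ["("], [")"]
    mism = bulges = 0
    for _ in range(int(rng.integers(3, 12))):
        if rng.random() < 0.6:
            left.append("(")
            right.append(")")
        else:
            u_m, u_s = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            if u_m == 0 and u_s == 0:
                u_m = 1
            left.append("." * u_m)
            right.append("." * u_s)
            mism += min(u_m, u_s)
            bulges += u_m != u_s
            left.append("(")
            right.append(")")
    structure = "".join(left) + "...." + "".join(reversed(right))
    mature_len = sum(len(x) for x in left)
    return structure, mature_len, mism, bulges


def bulge_oracle_agreement(seed: int, n_cases: int = 1000) -> dict:
    rng = np.random.default_rng([seed, 13])
    agree = 0
    for _ in range(n_cases):
        structure, mlen, mism, bulges = random_duplex_with_truth(rng)
        got_m, got_b, _ = _duplex_walk(pair_table(structure), 0, mlen)
        agree += (got_m, got_b) == (mism, bulges)
    return {"agreement_pct": 100.0 * agree / n_cases, "n_cases": n_cases}


def mfei_max_error(candidates: list[HairpinCandidate]) -> float:
    """Largest |MFEI - one-line recomputation| over evaluated candidates."""
    err = 0.0
    for c in candidates:
        if c.length and c.gc_percent:
            err = max(err, abs(c.mfei - 100.0 * abs(c.mfe) / (c.length * c.gc_percent)))
    return err


# ---------------------------------------------------------------------------
# target-scanner oracle


def scanner_oracle_agreement(seed: int, transcript_len: int = 5000) -> dict:
    """Gap-free scanner vs exhaustive per-window rescoring on one transcript."""
    rng = np.random.default_rng([seed, 17])
    mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=21))
    transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, size=transcript_len))
    oracle = dict(exhaustive_scan(mirna, transcript))
    hits = scan_transcripts({"m": mirna}, {"t": transcript},
                            max_expectation=18.0, max_gaps=0)
    ok = all(abs(h.expectation - oracle[h.start]) < 1e-9 for h in hits)
    # the oracle's global best window must be among the reported hits
    best_start, best_e = min(oracle.items(), key=lambda kv: (kv[1], kv[0]))
    covered = any(h.start < best_start + 21 and h.end > best_start for h in hits)
    return {"agreement_pct": 100.0 if (ok and covered and hits) else 0.0,
            "n_hits": len(hits)}


def planted_site_recovery(seed: int, n_sites: int = 20) -> dict:
    """Sites with one seed mismatch (expectation 2.0): all found at cutoff 3,
    none at cutoff 1.5."""
    rng = np.random.default_rng([seed, 19])
    mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, size=21))
    transcripts = {}
    for i in range(n_sites):
        site = list(revcomp(mirna))
        j = len(site) - 5  # opposite miRNA position 5, inside the seed
        site[j] = {"A": "C", "C": "A", "G": "A", "T": "C"}[site[j]]
        assert abs(score_duplex(mirna, "".join(site))[0] - 2.0) < 1e-9
        flank1 = "".join("ACG"[k] for k in rng.integers(0, 3, size=120))
        flank2 = "".join("ACG"[k] for k in rng.integers(0, 3, size=120))
        transcripts[f"t{i}"] = flank1 + "".join(site) + flank2
    loose = scan_transcripts({"m": mirna}, transcripts, max_expectation=3.0)
    tight = scan_transcripts({"m": mirna}, transcripts, max_expectation=1.5)
    found = {h.transcript_id for h in loose if abs(h.expectation - 2.0) < 1e-9}
    missed_tight = not any(abs(h.expectation - 2.0) < 1e-9 for h in tight)
    return {
        "recovered_pct": 100.0 * len(found) / n_sites,
        "tight_cutoff_excludes_pct": 100.0 if missed_tight else 0.0,
    }


# ---------------------------------------------------------------------------
# clustering archetype agreement


def clustering_agreement(seed: int, per_class: int = 10) -> dict:
    rng = np.random.default_rng([seed, 23])
    rows, labels_true = [], []
    for c in "ABCD":
        base = np.array(ARCHETYPE_PROFILES[c])
        for _ in range(per_class):
            rows.append(base * rng.uniform(300, 3000) * rng.normal(1.0, 0.07, 4))
            labels_true.append(c)
    ids = [f"m{i}" for i in range(len(rows))]
    m = pd.DataFrame(rows, index=ids, columns=["5DPA", "10DPA", "15DPA", "20DPA"])
    labels, _, _, _ = cluster_profiles(m, k=4)
    agree = sum(labels[i] == t for i, t in zip(ids, labels_true))
    return {"agreement_pct": 100.0 * agree / len(ids), "n_rows": len(ids)}
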