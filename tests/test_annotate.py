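"""Contaminant classification, genome mapping and class-distribution table."""

import numpy as np
import pytest

from fiberma.annotate import (
    GenomeIndex,
    brute_force_hits,
    class_distribution_from_counts,
    class_distribution_table,
    classify_contaminants,
    map_to_genome,
)
from fiberma.errors import ConfigurationError
from fiberma.preprocess import ReadLibrary
from fiberma.seq import revcomp


def _lib(reads):
    return ReadLibrary("t", dict(reads))


def test_priority_order_rrna_wins():
    read = "ACGTACGTACGTACGTACGT"
    refs = {"rRNA": [("r1", "TT" + read + "GG")], "tRNA": [("t1", read + "AAAA")]}
    ann = classify_contaminants(_lib({read: 3}), refs)
    assert ann.annotations[read].annotation_class == "rRNA"


def test_unmatched_read_is_none():
    refs = {"rRNA": [("r1", "G" * 40)]}
    ann = classify_contaminants(_lib({"ACGTACGTACGTACGTAC": 1}), refs)
    assert ann.annotations["ACGTACGTACGTACGTAC"].annotation_class == "none"


def test_empty_reference_class_is_config_error():
    with pytest.raises(ConfigurationError):
        classify_contaminants(_lib({"ACGT" * 5: 1}), {"rRNA": []})


def test_spiked_contaminants_recovered_exactly(pipeline_run):
    """Exact-substring matching recovers the generator's contaminant spikes."""
    cfg, _, state = pipeline_run
    import json

    with open(pipeline_run[1] / "sim" / "truth.json") as fh:
        spikes = json.load(fh)["spikes"]
    for al in state.annotated:
        got = al.class_counts()
        assert got["rRNA"] == spikes[al.label]["rRNA"]


def test_embedded_mature_maps_to_truth_coordinates(sim_small):
    _, truth, _ = sim_small
    index = GenomeIndex(truth.genome)
    loc = truth.loci[0]
    hits = index.find(loc.mature)
    assert any(
        h.chrom == loc.chrom and h.start == loc.mature_start
        and h.end == loc.mature_end and h.strand == "+" for h in hits
    )


def test_minus_strand_hit_has_same_interval(rng):
    genome = "".join(rng.choice(list("ACGT"), size=2000))
    s = 700
    kmer = genome[s : s + 21]
    index = GenomeIndex(genome)
    hits = index.find(revcomp(kmer))
    assert any(h.start == s and h.end == s + 21 and h.strand == "-" for h in hits)


@pytest.mark.parametrize("max_mismatch", [0, 1, 2])
def test_mapper_equals_brute_force_oracle(rng, max_mismatch):
    genome = "".join(rng.choice(list("ACGT"), size=8_000))
    index = GenomeIndex(genome, max_mismatch)
    reads = []
    for _ in range(60):  # genome-derived, with planted substitutions
        s = int(rng.integers(0, len(genome) - 24))
        L = int(rng.integers(18, 25))
        read = list(genome[s : s + L])
        for _ in range(int(rng.integers(0, 3))):
            i = int(rng.integers(L))
            read[i] = str(rng.choice(list("ACGT")))
        seq = "".join(read)
        reads.append(seq if rng.random() < 0.5 else revcomp(seq))
    for _ in range(40):  # random reads, mostly absent
        reads.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 25)))))
    for read in reads:
        assert index.find(read) == brute_force_hits(genome, read, max_mismatch)


def test_multimapper_flagging(rng):
    unit = "ACGTTGCACGGATCCATGCA"
    genome = unit * 30 + "".join(rng.choice(list("ACGT"), size=500))
    ann = map_to_genome(_lib({unit: 5}), genome, max_hits=10)
    a = ann.annotations[unit]
    assert a.multimapper and len(a.genome_hits) >= 30


def test_class_counts_partition_library(pipeline_run):
    _, _, state = pipeline_run
    for al in state.annotated:
        counts = al.class_counts()
        assert sum(counts.values()) == al.library.total_clean_reads


def test_table_percent_arithmetic_matches_printed_cells():
    """Internally consistent published counts reproduce their percents."""
    counts = {"5DPA": {"genome": 2_338_626}, "20DPA": {"rRNA": 162_270}}
    clean = {"5DPA": 7_334_102, "20DPA": 4_877_186}
    df = class_distribution_from_counts(counts, clean).set_index("RNA class")
    assert df.loc["Match to genome", "5DPA percent"] == 31.89
    assert df.loc["rRNA", "20DPA percent"] == 3.33
    assert df.loc["Clean reads", "5DPA percent"] == 100.0


def test_zero_contaminants_give_zero_percent_rows():
    df = class_distribution_from_counts(
        {"L": {"genome": 50, "none": 50}}, {"L": 100}
    ).set_index("RNA class")
    for row in ("rRNA", "tRNA", "snRNA", "snoRNA", "Repeats"):
        assert df.loc[row, "L percent"] == 0.0


def test_pipeline_table_rows_sum_to_clean_totals(pipeline_run):
    _, _, state = pipeline_run
    df = class_distribution_table(state.annotated).set_index("RNA class")
    for al in state.annotated:
        col = f"{al.label} count"
        body = df.loc[[r for r in df.index if r != "Clean reads"], col].sum()
        assert body == df.loc["Clean reads", col]
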