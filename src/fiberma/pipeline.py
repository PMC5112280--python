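"""End-to-end orchestration: simulate -> preprocess -> annotate -> known ->
novel -> quantify -> cluster -> targets -> race -> qpcr -> report.

Each stage writes deterministic TSV/FASTA/GFF3 outputs into the run
directory; the resolved configuration is written beside them.  Stages can be
toggled; a stage whose inputs are missing (because the producing stage was
disabled and its files are absent) raises ``DependencyError`` naming the
missing piece.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import annotate as ann_mod
from . import expression as expr_mod
from . import known as known_mod
from . import novel as novel_mod
from . import targets as tgt_mod
from . import validation as val_mod
from .errors import ConfigurationError, DependencyError
from .folding import default_folder
from .novel import HairpinThresholds
from .preprocess import ReadLibrary, clean_reads, fraction_in_range, length_distribution
from .seq import round_half_up, to_rna
from .simulate import SimulationConfig, simulate_all
from .targets import ScoringScheme

log = logging.getLogger("fiberma")

STAGES = ("simulate", "preprocess", "annotate", "known", "novel",
          "quantify", "cluster", "targets", "race", "qpcr", "report")


@dataclass
class PreprocessParams:
    clean_min_len: int = 18
    clean_max_len: int = 44
    analysis_min_len: int = 18
    analysis_max_len: int = 28
    min_qual: int = 20
    min_overlap: int = 8
    max_adaptor_mismatch: int = 1


@dataclass
class AnnotateParams:
    max_mismatch: int = 0
    max_hits: int = 20


@dataclass
class KnownParams:
    max_mismatch: int = 2


@dataclass
class NovelParams:
    min_stack: int = 5
    window: int = 250
    max_unpaired_mature: int = 4
    max_duplex_mismatches: int = 4
    max_asymmetric_bulges: int = 2
    min_dominance: float = 0.8
    max_mfe: float = -18.0
    mfei_flag: float = 0.85

    def thresholds(self) -> HairpinThresholds:
        return HairpinThresholds(
            self.max_unpaired_mature, self.max_duplex_mismatches,
            self.max_asymmetric_bulges, self.min_dominance,
            self.max_mfe, self.mfei_flag,
        )


@dataclass
class ExpressionParams:
    scale_factor: float = 1e7  # reads per ten million
    min_rptm: float = 100.0
    k: int = 4
    pseudocount: float = 1.0
    metric: str = "euclidean"


@dataclass
class TargetParams:
    max_expectation: float = 3.0
    max_gaps: int = 1
    match: float = 0.0
    gu: float = 0.5
    mismatch: float = 1.0
    gap: float = 2.0
    seed_start: int = 2
    seed_end: int = 13
    seed_multiplier: float = 2.0

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.gu, self.mismatch, self.gap,
                             self.seed_start, self.seed_end, self.seed_multiplier)


@dataclass
class ValidationParams:
    reference_gene: str = "UBQ10"
    calibrator_sample: str = ""  # default: first library label
    flank: int = 20
    correlation: str = "pearson"


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    annotate: AnnotateParams = field(default_factory=AnnotateParams)
    known: KnownParams = field(default_factory=KnownParams)
    novel: NovelParams = field(default_factory=NovelParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    targets: TargetParams = field(default_factory=TargetParams)
    validation: ValidationParams = field(default_factory=ValidationParams)

    def __post_init__(self):
        self.sim.seed = self.seed

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if key == "seed":
                cfg.seed = int(val)
            elif key == "stages":
                unknown = set(val) - set(STAGES)
                if unknown:
                    raise ConfigurationError(f"unknown stages {sorted(unknown)}")
                cfg.stages.update(val)
            elif key in sections and isinstance(val, dict):
                sub = getattr(cfg, key)
                known_fields = {f.name for f in dataclasses.fields(sub)}
                unknown = set(val) - known_fields
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys {sorted(unknown)} in section [{key}]"
                    )
                for k2, v2 in val.items():
                    cur = getattr(sub, k2)
                    if isinstance(cur, tuple):
                        v2 = tuple(v2)
                    setattr(sub, k2, v2)
            else:
                raise ConfigurationError(f"unknown configuration key {key!r}")
        cfg.sim.seed = cfg.seed
        return cfg

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineState:
    """In-memory hand-off between stages within one run."""

    genome: dict[str, str] | None = None
    mature_ref: list[tuple[str, str]] | None = None
    contaminant_refs: dict[str, list[tuple[str, str]]] | None = None
    transcripts: dict[str, str] | None = None
    race_clones: pd.DataFrame | None = None
    qpcr_ct: pd.DataFrame | None = None
    libraries: list[ReadLibrary] | None = None        # analysis-window sets
    clean_libraries: list[ReadLibrary] | None = None  # broad cleaning window
    annotated: list | None = None
    known_calls: list | None = None
    assigned_known: set[str] | None = None
    novel_calls: list | None = None
    all_candidates: list | None = None
    rptm: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    selected: pd.DataFrame | None = None
    class_labels: dict[str, str] | None = None
    target_hits: list | None = None
    labels: tuple[str, ...] = ()


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _require(path: Path, stage: str, what: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} requires {what} at {path}")
    return path


def _setup_logging(outdir: Path, level: str = "INFO") -> None:
    log.setLevel(level.upper())
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(outdir / "run.log", mode="a")):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_all(config: PipelineConfig, outdir: str | Path,
            log_level: str = "INFO") -> Path:
    """Execute all enabled stages in order; returns the output directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, log_level)
    with open(out / "resolved_config.json", "w") as fh:
        json.dump(config.resolved(), fh, indent=1, sort_keys=True, default=str)
    state = PipelineState()
    for stage in STAGES:
        if not config.stages.get(stage, True):
            log.info("stage %s disabled", stage)
            continue
        log.info("stage %s starting", stage)
        _STAGE_FUNCS[stage](config, state, out)
        log.info("stage %s done", stage)
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    sim_dir = out / "sim"
    truth, libraries = simulate_all(cfg.sim, sim_dir)
    state.genome = truth.genome
    state.mature_ref = truth.mature_reference()
    state.contaminant_refs = truth.contaminant_refs
    state.transcripts = dict(truth.transcripts)
    state.race_clones = pd.DataFrame(truth.race_clones)
    state.qpcr_ct = pd.DataFrame(truth.qpcr_rows)
    state.labels = cfg.sim.library_labels
    log.info("simulated %d loci, %d libraries x %d reads",
             len(truth.loci), len(libraries), cfg.sim.reads_per_library)


def _load_sim_inputs(cfg: PipelineConfig, state: PipelineState, out: Path,
                     stage: str) -> None:
    sim_dir = out / "sim"
    if state.genome is None:
        state.genome = dict(_read_fasta(_require(sim_dir / "genome.fa", stage, "genome FASTA")))
    if state.mature_ref is None:
        state.mature_ref = _read_fasta(_require(sim_dir / "mature_ref.fa", stage,
                                                "mature miRNA reference"))
    if state.contaminant_refs is None:
        state.contaminant_refs = {}
        for p in sorted(sim_dir.glob("contaminant_*.fa")):
            state.contaminant_refs[p.stem.removeprefix("contaminant_")] = _read_fasta(p)
    if not state.labels:
        state.labels = cfg.sim.library_labels


def stage_preprocess(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    p = cfg.preprocess
    labels = state.labels or cfg.sim.library_labels
    state.labels = tuple(labels)
    clean_libs, analysis_libs = [], []
    coll = out / "collapsed"
    coll.mkdir(exist_ok=True)
    summary = {}
    for label in labels:
        fq = _require(out / "sim" / f"lib_{label}.fastq", "preprocess",
                      f"raw FASTQ for library {label}")
        lib = clean_reads(
            fq, cfg.sim.adaptor_3p, label=label,
            min_len=p.clean_min_len, max_len=p.clean_max_len,
            min_qual=p.min_qual, min_overlap=p.min_overlap,
            max_adaptor_mismatch=p.max_adaptor_mismatch,
        )
        sub = lib.restrict(p.analysis_min_len, p.analysis_max_len)
        clean_libs.append(lib)
        analysis_libs.append(sub)
        sub.to_frame().to_csv(coll / f"{label}.tsv", sep="\t", index=False)
        ld = length_distribution(sub)
        ld.to_csv(coll / f"{label}_lengths.tsv", sep="\t", index=False)
        summary[label] = {
            "cleaned_reads": lib.total_clean_reads,
            "analysis_reads": sub.total_clean_reads,
            "unique_analysis_reads": sub.n_unique,
            "fraction_20_24": round(fraction_in_range(sub), 4),
            "discards": dict(lib.discards),
        }
        log.info("library %s: %d cleaned, %d in analysis window",
                 label, lib.total_clean_reads, sub.total_clean_reads)
    with open(coll / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    state.clean_libraries = clean_libs
    state.libraries = analysis_libs


def stage_annotate(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.libraries is None:
        raise DependencyError("stage 'annotate' requires preprocessed libraries")
    _load_sim_inputs(cfg, state, out, "annotate")
    a = cfg.annotate
    index = ann_mod.GenomeIndex(state.genome, a.max_mismatch)
    annotated = []
    for lib in state.libraries:
        al = ann_mod.classify_contaminants(lib, state.contaminant_refs)
        al = ann_mod.map_to_genome(al, index, a.max_mismatch, a.max_hits)
        annotated.append(al)
    state.annotated = annotated
    table1 = ann_mod.class_distribution_table(annotated)
    table1.to_csv(out / "table1_class_distribution.tsv", sep="\t", index=False)


def stage_known(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.annotated is None:
        raise DependencyError("stage 'known' requires annotated libraries")
    _load_sim_inputs(cfg, state, out, "known")
    calls, assigned = known_mod.assign_known(
        state.annotated, state.mature_ref, cfg.known.max_mismatch
    )
    state.known_calls = calls
    state.assigned_known = assigned
    labels = list(state.labels)
    known_mod.calls_to_frame(calls, labels).to_csv(
        out / "known_mirnas.tsv", sep="\t", index=False
    )
    known_mod.family_summary(calls).to_csv(
        out / "known_families.tsv", sep="\t", index=False
    )
    log.info("known: %d calls from %d assigned unique reads", len(calls), len(assigned))


def stage_novel(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.annotated is None:
        raise DependencyError("stage 'novel' requires annotated libraries")
    if state.assigned_known is None:
        raise DependencyError("stage 'novel' requires known-miRNA assignment")
    folder = default_folder()
    candidates, passing = novel_mod.call_novel(
        state.annotated, state.genome, state.assigned_known,
        folder=folder, thresholds=cfg.novel.thresholds(),
        min_stack=cfg.novel.min_stack, window=cfg.novel.window,
    )
    state.all_candidates = candidates
    state.novel_calls = passing
    novel_mod.candidates_to_frame(candidates).to_csv(
        out / "hairpin_candidates.tsv", sep="\t", index=False
    )
    _write_novel_outputs(passing, out, folder.name)
    log.info("novel: %d candidate windows, %d passing loci", len(candidates), len(passing))


def _write_novel_outputs(passing, out: Path, folder_name: str) -> None:
    with open(out / "novel_mirnas.gff3", "w") as gff, \
         open(out / "novel_precursors.fa", "w") as fa, \
         open(out / "novel_structures.txt", "w") as st:
        gff.write("##gff-version 3\n")
        st.write(f"# folding backend: {folder_name}\n")
        for i, c in enumerate(sorted(passing, key=lambda c: (c.chrom, c.start)), 1):
            nid = f"novel-mir-{i:03d}"
            gff.write(f"{c.chrom}\tfiberma\tpre_miRNA\t{c.start + 1}\t{c.end}\t.\t"
                      f"{c.strand}\t.\tID={nid};MFE={c.mfe:.1f};MFEI={c.mfei:.2f}\n")
            fa.write(f">{nid} {c.chrom}:{c.start + 1}-{c.end}({c.strand})\n"
                     f"{to_rna(c.precursor_seq)}\n")
            st.write(f">{nid}\n{to_rna(c.precursor_seq)}\n{c.structure} "
                     f"({c.mfe:.2f})\n")


def _counts_matrix(state: PipelineState) -> pd.DataFrame:
    labels = list(state.labels)
    rows: dict[str, dict[str, float]] = {}
    for call in state.known_calls or []:
        rows[call.mirna_id] = call.totals(labels)
    for i, c in enumerate(sorted(state.novel_calls or [],
                                 key=lambda c: (c.chrom, c.start)), 1):
        nid = f"novel-mir-{i:03d}"
        rows[nid] = {lab: float(c.read_support.get(lab, 0)) for lab in labels}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    return df.fillna(0.0).sort_index()


def stage_quantify(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.known_calls is None or state.novel_calls is None:
        raise DependencyError("stage 'quantify' requires known and novel calls")
    if state.libraries is None:
        raise DependencyError("stage 'quantify' requires preprocessed libraries")
    counts = _counts_matrix(state)
    totals = {lib.label: lib.total_clean_reads for lib in state.libraries}
    rptm = expr_mod.normalize_rptm(counts, totals, cfg.expression.scale_factor)
    state.counts, state.rptm = counts, rptm
    rptm.round(3).to_csv(out / "expression_matrix.tsv", sep="\t",
                         index_label="mirna_id")
    log.info("quantify: %d miRNAs x %d libraries (scale %g)",
             *rptm.shape, cfg.expression.scale_factor)


def stage_cluster(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.rptm is None:
        raise DependencyError("stage 'cluster' requires the expression matrix")
    e = cfg.expression
    selected = expr_mod.select_expressed(state.rptm, e.min_rptm)
    state.selected = selected
    if len(selected) < e.k:
        log.warning("cluster: only %d selected rows (< k=%d); skipping clustering",
                    len(selected), e.k)
        state.class_labels = {}
        pd.DataFrame(columns=["mirna_id", "class", "cluster"]).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        return
    labels, assignments, Z, lfc = expr_mod.cluster_profiles(
        selected, e.k, e.pseudocount, e.metric
    )
    state.class_labels = labels
    df = pd.DataFrame(
        {"mirna_id": list(selected.index),
         "class": [labels[i] for i in selected.index],
         "cluster": [assignments[i] for i in selected.index]}
    )
    df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(expr_mod.dendrogram_newick(Z, list(selected.index)) + "\n")
    log.info("cluster: %d selected miRNAs -> classes %s",
             len(selected), dict(pd.Series(list(labels.values())).value_counts()))


def _load_transcripts(state: PipelineState, out: Path, stage: str) -> None:
    if state.transcripts is None:
        fa = _require(out / "sim" / "transcripts.fa", stage, "transcript FASTA")
        state.transcripts = dict(_read_fasta(fa))


def _mirna_seqs(state: PipelineState) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for call in state.known_calls or []:
        seqs[call.mirna_id] = call.canonical_sequence
    for i, c in enumerate(sorted(state.novel_calls or [],
                                 key=lambda c: (c.chrom, c.start)), 1):
        seqs[f"novel-mir-{i:03d}"] = c.mature_seq
    return seqs


def stage_targets(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.known_calls is None and state.novel_calls is None:
        raise DependencyError("stage 'targets' requires miRNA calls")
    _load_transcripts(state, out, "targets")
    t = cfg.targets
    mirnas = _mirna_seqs(state)
    hits = tgt_mod.scan_transcripts(
        mirnas, state.transcripts, t.max_expectation, t.scheme(), t.max_gaps
    )
    state.target_hits = hits
    tgt_mod.hits_to_frame(hits).to_csv(out / "targets.tsv", sep="\t", index=False)
    summ = tgt_mod.target_summary(hits, sorted(mirnas))
    with open(out / "target_summary.json", "w") as fh:
        json.dump(
            {k: (v if not isinstance(v, pd.Series) else v.to_dict())
             for k, v in summ.items()}, fh, indent=1, sort_keys=True)
    log.info("targets: %d hits, %.1f targets/miRNA",
             len(hits), summ["mean_targets_per_mirna"])


def stage_race(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.target_hits is None:
        raise DependencyError("stage 'race' requires target predictions")
    if state.race_clones is None:
        tsv = _require(out / "sim" / "race_clones.tsv", "race", "RACE clone table")
        state.race_clones = pd.read_csv(tsv, sep="\t")
    rows = []
    for tid in sorted(state.race_clones["target_id"].unique()):
        cand = [h for h in state.target_hits if h.transcript_id == tid]
        if not cand:
            continue
        best = min(cand, key=lambda h: (h.expectation, h.start))
        cm = val_mod.map_cleavage(
            state.race_clones, state.transcripts[tid],
            _mirna_seqs(state).get(best.mirna_id, ""), best,
            flank=cfg.validation.flank,
        )
        for p, frac in cm.fractions.items():
            rows.append({"target_id": tid, "mirna_id": best.mirna_id,
                         "position": p, "count": cm.counts[p],
                         "fraction": round_half_up(frac, 3)})
        rows.append({"target_id": tid, "mirna_id": best.mirna_id,
                     "position": "canonical_9_11", "count": cm.n_mapped,
                     "fraction": round_half_up(cm.canonical_fraction, 3)})
    pd.DataFrame(rows).to_csv(out / "cleavage_maps.tsv", sep="\t", index=False)


def stage_qpcr(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    if state.qpcr_ct is None:
        tsv = _require(out / "sim" / "qpcr_ct.tsv", "qpcr", "qPCR Ct table")
        state.qpcr_ct = pd.read_csv(tsv, sep="\t")
    v = cfg.validation
    calibrator = v.calibrator_sample or state.labels[0]
    rel = val_mod.ddct(state.qpcr_ct, v.reference_gene, calibrator)
    rel.to_csv(out / "relative_expression.tsv", sep="\t", index=False)
    if state.rptm is None:
        log.warning("qpcr: no expression matrix; skipping correlation")
        return
    rows = []
    labels = list(state.labels)
    for gene, gdf in rel.groupby("gene"):
        mid = gene.removeprefix("target_of_")
        prof = _match_mirna_profile(state, mid)
        if prof is None:
            continue
        expr = gdf.set_index("sample").reindex(labels)["rel_expr"]
        try:
            r, anti = val_mod.correlate(prof, expr.values, v.correlation)
        except Exception as exc:  # zero-variance profiles in tiny runs
            log.warning("qpcr: correlation undefined for %s (%s)", gene, exc)
            continue
        rows.append({"gene": gene, "mirna_id": mid, "r": round(r, 4),
                     "anti_correlated": anti})
    pd.DataFrame(rows).to_csv(out / "correlations.tsv", sep="\t", index=False)


def _match_mirna_profile(state: PipelineState, mirna_id: str):
    if state.rptm is None:
        return None
    if mirna_id in state.rptm.index:
        return state.rptm.loc[mirna_id].values
    return None


def stage_report(cfg: PipelineConfig, state: PipelineState, out: Path) -> None:
    """Assemble paper-style summary tables from the stage outputs."""
    report = out / "report"
    report.mkdir(exist_ok=True)
    if state.annotated is not None:
        ann_mod.class_distribution_table(state.annotated).to_csv(
            report / "table1_class_distribution.tsv", sep="\t", index=False)
    if state.libraries is not None:
        frames = []
        for lib in state.libraries:
            ld = length_distribution(lib)
            ld.insert(0, "library", lib.label)
            ld["fraction"] = ld["fraction"].map(lambda x: round_half_up(x, 3))
            frames.append(ld)
        pd.concat(frames).to_csv(report / "fig1_length_distribution.tsv",
                                 sep="\t", index=False)
    if state.novel_calls is not None:
        tab2 = novel_mod.novel_summary([c.mature_seq for c in state.novel_calls]) \
            if state.novel_calls else novel_mod.novel_summary([])
        tab2.to_csv(report / "table2_novel_first_nt.tsv", sep="\t")
    if state.class_labels:
        counts = pd.Series(list(state.class_labels.values())).value_counts()
        counts.rename_axis("class").rename("n").to_csv(
            report / "cluster_classes.tsv", sep="\t")
    if state.target_hits is not None:
        summ = tgt_mod.target_summary(state.target_hits, sorted(_mirna_seqs(state)))
        pd.DataFrame(
            [{"non_redundant_pairs": summ["non_redundant_pairs"],
              "non_redundant_transcripts": summ["non_redundant_transcripts"],
              "mirnas_with_hits": summ["mirnas_with_hits"],
              "mean_targets_per_mirna": summ["mean_targets_per_mirna"]}]
        ).to_csv(report / "target_summary.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "annotate": stage_annotate,
    "known": stage_known,
    "novel": stage_novel,
    "quantify": stage_quantify,
    "cluster": stage_cluster,
    "targets": stage_targets,
    "race": stage_race,
    "qpcr": stage_qpcr,
    "report": stage_report,
}
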