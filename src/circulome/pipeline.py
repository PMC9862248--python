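"""End-to-end orchestration of the circulome stages on one config.

Runs simulate -> deconcat -> cluster -> annotate -> biogenesis windows ->
dynamics -> transcript assignment, writing each stage's artifacts as
plain-text standard formats into the output directory so every stage is
independently re-runnable, and returns a RunReport of per-stage record
counts and the consolidated summary tables. Identical (config, seed)
reproduces every output table byte-for-byte; wall time is the only
nondeterministic report field.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import annotate as ann
from . import biogenesis as bio
from . import cluster as clu
from . import dynamics as dyn
from . import io as cio
from . import simulate as sim
from . import transcription as tx
from .deconcat import ConcatemerRead, DeconcatParams, deconcat_reads

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

KNOWN_CONDITIONS = ("D0", "C12", "ST12")


@dataclass
class PipelineConfig:
    """Pipeline parameters; serializes round-trip stable to/from YAML."""

    outdir: str = "circulome_run"
    seed: int = 0
    conditions: tuple[str, ...] = ("D0", "C12", "ST12")
    n_circles: dict = field(default_factory=lambda: {"D0": 120, "C12": 60, "ST12": 60})
    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    window_size: int = 100_000
    n_genes: int = 40
    n_hotspots: int = 1
    # circle population (pipeline-scale defaults trade length for speed)
    mean_length: float = 800.0
    max_length: int = 8_000
    hotspot_enrichment: float = 8.0
    # reads
    pass_range: tuple[float, float] = (2.0, 8.0)
    substitution_rate: float = 0.005
    indel_rate: float = 0.0005
    # stage parameters
    min_passes: float = 2.0
    min_identity: float = 0.85
    cluster_threshold: float = 0.90
    z_min: float = 2.0
    log2fc_lo: float = -2.0
    log2fc_hi: float = 2.0
    pileup_min_depth: int = 10
    pileup_min_fraction: float = 0.9
    n_snps: int = 5
    n_control_sites: int = 10

    def validate(self) -> None:
        unknown = [c for c in self.conditions if c not in KNOWN_CONDITIONS]
        if unknown:
            raise ValueError(f"unknown condition label(s): {unknown}; "
                             f"expected labels among {KNOWN_CONDITIONS}")
        missing = [c for c in self.conditions if c not in self.n_circles]
        if missing:
            raise ValueError(f"n_circles missing for condition(s): {missing}")
        if self.chromosome_length < 2 * self.window_size:
            raise ValueError("chromosome_length must be >= 2 x window_size")
        if not 0 < self.cluster_threshold <= 1:
            raise ValueError("cluster_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if isinstance(cfg.conditions, list):
            cfg.conditions = tuple(cfg.conditions)
        if isinstance(cfg.pass_range, list):
            cfg.pass_range = tuple(cfg.pass_range)
        return cfg

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        data["pass_range"] = list(self.pass_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RunReport:
    """Consolidated pipeline report: stage ledger plus summary tables."""

    stages: list[dict] = field(default_factory=list)
    summary_rows: list[dict] = field(default_factory=list)
    venn_partition: dict = field(default_factory=dict)
    hotspots: list[dict] = field(default_factory=list)
    flagged_genes: list[dict] = field(default_factory=list)
    candidate_transcripts: list[dict] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int, t0: float) -> None:
        self.stages.append(
            {"stage": stage, "n_in": int(n_in), "n_out": int(n_out),
             "seconds": round(time.perf_counter() - t0, 3)}
        )

    def tables(self) -> dict:
        """Deterministic portion of the report (excludes wall time)."""
        return {
            "stages": [{k: v for k, v in s.items() if k != "seconds"} for s in self.stages],
            "summary_rows": self.summary_rows,
            "venn_partition": self.venn_partition,
            "hotspots": self.hotspots,
            "flagged_genes": self.flagged_genes,
            "candidate_transcripts": self.candidate_transcripts,
        }

    def to_json(self, path: str) -> None:
        payload = self.tables()
        payload["stage_seconds"] = {s["stage"]: s["seconds"] for s in self.stages}
        payload["parameters"] = self.parameters
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _truth_circle_of(ecc_id: str) -> str:
    """Map a confirmed-record id back to its truth circle id.

    Deconcat ids are ``ecc|<read_id>`` and simulated read ids are
    ``read#####|<circle_id>``.
    """
    return ecc_id.split("|")[-1]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; artifacts land under ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    report = RunReport(parameters=asdict(config))
    seed = config.seed

    # ---- stage 1: simulate -------------------------------------------------
    t0 = time.perf_counter()
    gconf = sim.GenomeConfig(
        chromosomes=tuple(
            (f"chr{i + 1}", config.chromosome_length) for i in range(config.n_chromosomes)
        ),
        window_size=config.window_size,
        n_genes=config.n_genes,
        n_hotspots=config.n_hotspots,
    )
    genome = sim.build_genome(gconf, seed=seed)
    genome.to_fasta(out("genome.fa"))
    genome.genes_to_gff3(out("genes.gff3"))
    genome.hotspots_to_bed(out("hotspots_truth.bed"))

    circles_by_cond: dict[str, list] = {}
    truth_frames = []
    for cond in config.conditions:
        profile = sim.CONDITION_PROFILES[cond]
        profile = sim.EccProfile(
            condition=cond,
            mean_length=config.mean_length,
            max_length=config.max_length,
            gene_fraction=profile.gene_fraction,
            trna_fraction=profile.trna_fraction,
            ori_fraction=profile.ori_fraction,
            hotspot_enrichment=config.hotspot_enrichment,
            replicates=profile.replicates,
        )
        circles, truth = sim.sample_eccdna(genome, profile, config.n_circles[cond], seed=seed)
        circles_by_cond[cond] = circles
        truth_frames.append(truth.ecc_truth)
    ecc_truth = pd.concat(truth_frames, ignore_index=True)

    # eccDNA-private SNPs on the last condition's gene-bearing circles
    snp_cond = config.conditions[-1]
    pileup = pd.DataFrame()
    if config.n_snps > 0:
        circles_mod, pileup, snp_truth = sim.plant_ecc_snps(
            genome, circles_by_cond[snp_cond],
            ecc_truth[ecc_truth["condition"] == snp_cond], config.n_snps, seed=seed,
            n_control_sites=config.n_control_sites,
        )
        circles_by_cond[snp_cond] = circles_mod
        cio.write_tsv(out("pileup.tsv"), pileup)
        cio.write_tsv(out("snp_truth.tsv"), snp_truth.snp_truth)

    err = sim.ErrorModel(config.substitution_rate, config.indel_rate)
    reads_by_cond = {}
    for cond in config.conditions:
        reads, read_truth = sim.simulate_rca_reads(
            circles_by_cond[cond], config.pass_range, err, seed=seed
        )
        reads_by_cond[cond] = reads
        cio.write_fasta(out(f"reads_{cond}.fa"), reads)
        cio.write_tsv(out(f"read_truth_{cond}.tsv"), read_truth.read_truth)
    cio.write_tsv(out("ecc_truth.tsv"), ecc_truth)

    de_plan = sim.default_de_plan(genome, seed=seed)
    replicates = {c: sim.CONDITION_PROFILES[c].replicates for c in config.conditions}
    counts, de_truth = sim.simulate_rnaseq_counts(genome, de_plan, replicates, seed=seed)
    counts.to_csv(out("rna_counts.tsv"), sep="\t")
    cio.write_tsv(out("de_truth.tsv"), de_truth.de_truth)
    n_reads = sum(len(r) for r in reads_by_cond.values())
    report.record("simulate", sum(config.n_circles.values()), n_reads, t0)

    # ---- stage 2: deconcat -------------------------------------------------
    t0 = time.perf_counter()
    params = DeconcatParams(min_passes=config.min_passes, min_identity=config.min_identity)
    confirmed = {}
    n_rejected = 0
    for cond in config.conditions:
        reads = [ConcatemerRead(rid, seq) for rid, seq in reads_by_cond[cond]]
        records, rejections, metrics = deconcat_reads(reads, params, condition=cond)
        confirmed[cond] = records
        n_rejected += len(rejections)
        cio.write_fasta(out(f"circles_{cond}.fa"), [(r.ecc_id, r.sequence) for r in records])
        cio.write_tsv(out(f"rejections_{cond}.tsv"), rejections)
        cio.write_tsv(out(f"deconcat_metrics_{cond}.tsv"), metrics)
    n_confirmed = sum(len(v) for v in confirmed.values())
    report.record("deconcat", n_reads, n_confirmed, t0)

    # ---- stage 3: cluster --------------------------------------------------
    t0 = time.perf_counter()
    reps = {}
    for cond in config.conditions:
        cset = clu.cluster_sequences(confirmed[cond], threshold=config.cluster_threshold)
        reps[cond] = cset
        cio.write_tsv(out(f"clusters_{cond}.tsv"), cset.to_frame())
        cio.write_fasta(out(f"representatives_{cond}.fa"), cset.representative_records())
    n_reps = sum(c.n_clusters for c in reps.values())
    report.record("cluster", n_confirmed, n_reps, t0)

    # ---- stage 4: annotate -------------------------------------------------
    t0 = time.perf_counter()
    truth_by_id = ecc_truth.set_index("ecc_id")
    summaries = []
    gene_sets: dict[str, set] = {}
    placements_all = []
    for cond in config.conditions:
        cset = reps[cond]
        rep_records = [
            r for r in confirmed[cond]
            if r.ecc_id in {c.representative for c in cset.clusters}
        ]
        placements = []
        for r in rep_records:
            tid = _truth_circle_of(r.ecc_id)
            row = truth_by_id.loc[tid]
            placements.append(
                {"chrom": row["chrom"], "start": int(row["start"]), "end": int(row["end"]),
                 "name": r.ecc_id, "score": 0, "strand": "+"}
            )
        placements = pd.DataFrame(placements)
        placements_all.append(placements.assign(condition=cond))
        cio.write_bed(out(f"placements_{cond}.bed"), placements)

        masked_bp, trna_hits, ori_hits = {}, {}, {}
        for r in rep_records:
            _, intervals = ann.mask_repeats(r.sequence, genome.repeat_library)
            masked_bp[r.ecc_id] = int(intervals["bp"].sum()) if len(intervals) else 0
            trna_hits[r.ecc_id] = len(ann.find_motifs(r.sequence, genome.trna_motifs, 0.90))
            ori_hits[r.ecc_id] = len(ann.find_motifs(r.sequence, genome.ori_motifs, 0.95))
        gene_hits = ann.annotate_genes(placements, genome.gene_models)
        conditions_map = {r.ecc_id: cond for r in rep_records}
        gene_sets.update(ann.gene_sets_by_condition(gene_hits, conditions_map))
        summary = ann.summarize_condition(
            rep_records, masked_bp, gene_hits, trna_hits, ori_hits,
            n_raw=len(confirmed[cond]),
        )
        summaries.append(summary.to_row())
    summary_df = pd.DataFrame(summaries)
    cio.write_tsv(out("condition_summary.tsv"), summary_df)
    report.summary_rows = summaries
    report.record("annotate", n_reps, len(summaries), t0)

    # ---- stage 5: biogenesis windows ----------------------------------------
    t0 = time.perf_counter()
    placements_df = pd.concat(placements_all, ignore_index=True)
    window_counts = bio.assign_windows(
        placements_df, genome.chrom_sizes(), config.window_size
    )
    hotspot_result = bio.call_hotspots(window_counts, z_min=config.z_min)
    cio.write_tsv(out("window_stats.tsv"), hotspot_result.stats)
    cio.write_tsv(out("hotspots.tsv"), hotspot_result.hotspots)
    report.hotspots = hotspot_result.hotspots.to_dict("records")
    report.record("windows", len(placements_df), len(hotspot_result.hotspots), t0)

    # ---- stage 6: dynamics --------------------------------------------------
    t0 = time.perf_counter()
    for cond in config.conditions:
        gene_sets.setdefault(cond, set())
    presence = dyn.presence_matrix(gene_sets)
    report.venn_partition = {str(k): v for k, v in presence.partition.items()}
    d0_cols = [c for c in counts.columns if c.startswith("D0_")]
    de = {}
    for cond in ("C12", "ST12"):
        cols = [c for c in counts.columns if c.startswith(f"{cond}_")]
        if cols and d0_cols:
            de[cond] = dyn.log2fc(counts[d0_cols], counts[cols])
    flagged = dyn.intersect_dynamics(
        presence, de, lo=config.log2fc_lo, hi=config.log2fc_hi
    )
    cio.write_tsv(out("flagged_genes.tsv"), flagged)
    report.flagged_genes = flagged.to_dict("records")
    report.record("dynamics", presence.n_genes, len(flagged), t0)

    # ---- stage 7: transcript assignment -------------------------------------
    t0 = time.perf_counter()
    if len(pileup):
        classified = tx.classify_pileup(
            pileup, min_depth=config.pileup_min_depth,
            min_fraction=config.pileup_min_fraction,
        )
        candidates = tx.scan_transcripts(classified)
        cio.write_tsv(out("classified_sites.tsv"), classified)
        cio.write_tsv(out("candidate_transcripts.tsv"), candidates)
        report.candidate_transcripts = candidates.to_dict("records")
        report.record("transcripts", len(pileup), len(candidates), t0)
    else:
        report.record("transcripts", 0, 0, t0)

    report.to_json(out("report.json"))
    return report
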