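"""Synthetic circulome study generator.

Emulates the study design the downstream analysis expects: a small
reference genome with annotated genes, planted repeat / tRNA / replication
origin motifs and repeat-dense biogenesis hotspots; eccDNA populations
excised from it per condition (Day 0 pooled, Control Day 12,
Lactate-stressed Day 12); rolling-circle concatemer reads over those
circles; negative-binomial RNA-seq counts with planted fold changes; and
eccDNA-private SNPs whose alleles appear in the RNA pileup. Every stage
emits a truth table so downstream recovery can be scored exactly.

All randomness flows from a single integer seed through named generators
(one stream per sub-task), so outputs are byte-stable across runs and
adding one stream never perturbs the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as cio
from ._seq import BASES, random_dna, revcomp, rng_for, rotate
from .deconcat import EccRecord

__all__ = [
    "GenomeConfig",
    "GenomeModel",
    "EccProfile",
    "ErrorModel",
    "TruthTable",
    "CONDITION_PROFILES",
    "build_genome",
    "background_window_weights",
    "sample_eccdna",
    "simulate_rca_reads",
    "simulate_rnaseq_counts",
    "default_de_plan",
    "plant_ecc_snps",
]


class ConfigurationError(ValueError):
    """Invalid generation parameters."""


# ---------------------------------------------------------------------------
# genome model

_REPEAT_CLASS_LENGTHS = {
    # planted motif length per repeat class, loosely mirroring mammalian
    # element sizes (LINEs long, SINEs short, simple repeats as short units)
    "SINE": 300,
    "LINE": 1200,
    "LTR": 500,
    "DNA": 600,
    "satellite": 200,
    "simple": 60,
    "low_complexity": 80,
}


@dataclass(frozen=True)
class GenomeConfig:
    """Parameters for the toy genome.

    Chromosome lengths must be at least twice the hotspot window size so
    that windowed statistics are meaningful.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    window_size: int = 500_000
    n_genes: int = 40
    gene_length: tuple[int, int] = (2_000, 8_000)
    repeats_per_class: int = 2
    copies_per_repeat: int = 6
    n_trna_motifs: int = 4
    trna_length: int = 72
    n_trna_sites: int = 30
    n_ori_motifs: int = 3
    ori_length: int = 120
    n_ori_sites: int = 20
    n_hotspots: int = 1
    hotspot_span: int = 50_000
    hotspot_tandem_copies: int = 8


@dataclass
class GenomeModel:
    """Toy genome with the annotations the analysis consumes.

    Coordinates are 0-based half-open in memory; serialization follows
    each format's own convention (GFF3 1-based inclusive, BED 0-based
    half-open).
    """

    chromosomes: list[tuple[str, str]]
    repeat_library: pd.DataFrame  # name, cls, sequence
    gene_models: pd.DataFrame  # chrom, start, end, strand, gene_id
    trna_motifs: pd.DataFrame  # name, sequence
    ori_motifs: pd.DataFrame  # name, sequence
    trna_sites: pd.DataFrame  # chrom, start, end, motif
    ori_sites: pd.DataFrame  # chrom, start, end, motif
    hotspot_intervals: pd.DataFrame  # chrom, start, end, name
    window_size: int = 500_000

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes}

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(f"unknown chromosome {chrom!r}")

    def n_windows(self, chrom: str) -> int:
        size = self.chrom_sizes()[chrom]
        return -(-size // self.window_size)

    def to_fasta(self, path: str) -> None:
        cio.write_fasta(path, self.chromosomes)

    def genes_to_gff3(self, path: str) -> None:
        cio.write_gff3_genes(path, self.gene_models)

    def hotspots_to_bed(self, path: str) -> None:
        df = self.hotspot_intervals.copy()
        df["name"] = df["name"] if "name" in df else "hotspot"
        cio.write_bed(path, df)


@dataclass
class TruthTable:
    """Ground truth emitted alongside every synthetic artifact."""

    ecc_truth: Optional[pd.DataFrame] = None
    read_truth: Optional[pd.DataFrame] = None
    snp_truth: Optional[pd.DataFrame] = None
    de_truth: Optional[pd.DataFrame] = None

    def validate(self) -> None:
        if self.read_truth is not None and self.ecc_truth is not None:
            known = set(self.ecc_truth["ecc_id"])
            orphans = set(self.read_truth["ecc_id"]) - known
            if orphans:
                raise ValueError(f"read_truth references unknown circles: {sorted(orphans)[:5]}")


def build_genome(config: GenomeConfig = GenomeConfig(), seed: int = 0) -> GenomeModel:
    """Generate the toy genome. Deterministic for a fixed (config, seed).

    Repeat motif copies are dispersed genome-wide; each hotspot interval
    additionally receives a tandem array of one repeat motif plus an
    inverted copy, giving hotspots the repeat-dense, direct+inverted
    architecture the biogenesis stage characterizes.
    """
    for name, length in config.chromosomes:
        if length < 2 * config.window_size:
            raise ConfigurationError(
                f"chromosome {name} length {length} < 2 x window size {config.window_size}"
            )
    names = [n for n, _ in config.chromosomes]
    if len(set(names)) != len(names):
        raise ConfigurationError("chromosome names must be unique")

    rng_bg = rng_for(seed, "genome-background")
    chrom_arrays = {
        name: bytearray(random_dna(rng_bg, length), "ascii")
        for name, length in config.chromosomes
    }
    occupied: dict[str, IntervalTree] = {name: IntervalTree() for name in names}

    def reserve(rng, length, chrom=None, lo=None, hi=None, tries=200):
        """Pick a free interval; greedy rejection against prior placements."""
        for _ in range(tries):
            c = chrom if chrom is not None else names[rng.integers(len(names))]
            size = len(chrom_arrays[c])
            a = lo if lo is not None else 0
            b = (hi if hi is not None else size) - length
            if b <= a:
                continue
            start = int(rng.integers(a, b))
            if not occupied[c].overlap(start, start + length):
                occupied[c].addi(start, start + length)
                return c, start
        raise ConfigurationError("could not place an interval; genome too crowded")

    def write(chrom, start, seq):
        chrom_arrays[chrom][start : start + len(seq)] = seq.encode("ascii")

    # motif libraries
    rng_lib = rng_for(seed, "motif-library")
    repeat_rows = []
    for cls, motif_len in _REPEAT_CLASS_LENGTHS.items():
        for i in range(config.repeats_per_class):
            repeat_rows.append(
                {"name": f"{cls}_{i}", "cls": cls, "sequence": random_dna(rng_lib, motif_len)}
            )
    repeat_library = pd.DataFrame(repeat_rows)
    trna_motifs = pd.DataFrame(
        {
            "name": [f"tRNA_{i}" for i in range(config.n_trna_motifs)],
            "sequence": [random_dna(rng_lib, config.trna_length) for _ in range(config.n_trna_motifs)],
        }
    )
    ori_motifs = pd.DataFrame(
        {
            "name": [f"ORI_{i}" for i in range(config.n_ori_motifs)],
            "sequence": [random_dna(rng_lib, config.ori_length) for _ in range(config.n_ori_motifs)],
        }
    )

    # hotspots first so their tandem arrays claim space
    rng_hot = rng_for(seed, "hotspots")
    hotspot_rows = []
    for h in range(config.n_hotspots):
        chrom = names[h % len(names)]
        n_win = len(chrom_arrays[chrom]) // config.window_size
        win = int(rng_hot.integers(0, n_win))
        w_lo, w_hi = win * config.window_size, (win + 1) * config.window_size
        chrom, start = reserve(rng_hot, config.hotspot_span, chrom, w_lo, w_hi)
        motif = repeat_library.iloc[int(rng_hot.integers(len(repeat_library)))]["sequence"]
        array_seq = motif * config.hotspot_tandem_copies
        pad = int(rng_hot.integers(0, max(1, config.hotspot_span - 2 * len(array_seq) - len(motif))))
        write(chrom, start + pad, array_seq)
        write(chrom, start + pad + len(array_seq) + len(motif) // 2, revcomp(motif))
        hotspot_rows.append(
            {"chrom": chrom, "start": start, "end": start + config.hotspot_span,
             "name": f"hotspot_{h}"}
        )
    hotspots = pd.DataFrame(
        hotspot_rows, columns=["chrom", "start", "end", "name"]
    )

    # genes: evenly slotted so they never overlap one another
    rng_gene = rng_for(seed, "genes")
    gene_rows = []
    total_len = sum(length for _, length in config.chromosomes)
    gid = 0
    for name, length in config.chromosomes:
        n_here = round(config.n_genes * length / total_len)
        slot = length // max(1, n_here)
        for s in range(n_here):
            if gid >= config.n_genes:
                break
            glen = int(rng_gene.integers(config.gene_length[0], config.gene_length[1]))
            margin = slot - glen
            if margin <= 1:
                continue
            start = s * slot + int(rng_gene.integers(0, margin))
            gene_rows.append(
                {"chrom": name, "start": start, "end": start + glen,
                 "strand": "+" if rng_gene.random() < 0.5 else "-",
                 "gene_id": f"gene{gid:04d}"}
            )
            occupied[name].addi(start, start + glen)
            gid += 1
    gene_models = pd.DataFrame(gene_rows)

    # dispersed repeat copies (direct and inverted) outside genes/hotspots
    rng_rep = rng_for(seed, "repeat-copies")
    for row in repeat_library.itertuples(index=False):
        for _ in range(config.copies_per_repeat):
            chrom, start = reserve(rng_rep, len(row.sequence))
            copy = row.sequence if rng_rep.random() < 0.8 else revcomp(row.sequence)
            write(chrom, start, copy)

    # planted tRNA and ORI motif sites
    rng_sites = rng_for(seed, "motif-sites")
    site_rows = {"trna": [], "ori": []}
    for kind, motifs, n_sites in (
        ("trna", trna_motifs, config.n_trna_sites),
        ("ori", ori_motifs, config.n_ori_sites),
    ):
        for _ in range(n_sites):
            motif = motifs.iloc[int(rng_sites.integers(len(motifs)))]
            chrom, start = reserve(rng_sites, len(motif["sequence"]))
            write(chrom, start, motif["sequence"])
            site_rows[kind].append(
                {"chrom": chrom, "start": start,
                 "end": start + len(motif["sequence"]), "motif": motif["name"]}
            )

    chromosomes = [(name, chrom_arrays[name].decode("ascii")) for name in names]
    return GenomeModel(
        chromosomes=chromosomes,
        repeat_library=repeat_library,
        gene_models=gene_models,
        trna_motifs=trna_motifs,
        ori_motifs=ori_motifs,
        trna_sites=pd.DataFrame(site_rows["trna"]),
        ori_sites=pd.DataFrame(site_rows["ori"]),
        hotspot_intervals=hotspots,
        window_size=config.window_size,
    )


# ---------------------------------------------------------------------------
# eccDNA excision

# Per-condition composition profiles emulating the fed-batch study design:
# Day 0 pooled (N=4), Control Day 12 (N=2), Lactate-stressed Day 12 (N=2).
# Length means and gene/tRNA/ORI-bearing fractions follow the observed
# per-condition summaries.


@dataclass(frozen=True)
class EccProfile:
    """Composition targets for one condition's eccDNA population."""

    condition: str = "custom"
    mean_length: float = 4063.0
    sigma_log: float = 0.8  # lognormal shape; resampled into length bounds
    min_length: int = 21
    max_length: int = 24_309
    gene_fraction: float = 0.0335
    trna_fraction: float = 0.0898
    ori_fraction: float = 0.05
    hotspot_enrichment: float = 5.0
    replicates: int = 1


CONDITION_PROFILES: dict[str, EccProfile] = {
    "D0": EccProfile("D0", mean_length=4063, gene_fraction=0.0352,
                     trna_fraction=0.0981, ori_fraction=0.1007, replicates=4),
    "C12": EccProfile("C12", mean_length=3579, gene_fraction=0.0323,
                      trna_fraction=0.0786, ori_fraction=0.0089, replicates=2),
    "ST12": EccProfile("ST12", mean_length=3534, gene_fraction=0.0296,
                       trna_fraction=0.0756, ori_fraction=0.00078, replicates=2),
}


def background_window_weights(genome: GenomeModel, profile: EccProfile) -> pd.DataFrame:
    """Multinomial window weights used for background excisions.

    Windows overlapping a hotspot interval carry ``hotspot_enrichment``
    times the baseline weight. This table is the sampler's own truth for
    enrichment checks.
    """
    rows = []
    hot = {
        (r.chrom, w)
        for r in genome.hotspot_intervals.itertuples(index=False)
        for w in range(r.start // genome.window_size, (r.end - 1) // genome.window_size + 1)
    }
    for chrom, size in genome.chrom_sizes().items():
        for w in range(-(-size // genome.window_size)):
            rows.append(
                {"chrom": chrom, "index": w,
                 "start": w * genome.window_size,
                 "end": min((w + 1) * genome.window_size, size),
                 "weight": profile.hotspot_enrichment if (chrom, w) in hot else 1.0}
            )
    return pd.DataFrame(rows)


def _sample_length(rng: np.random.Generator, profile: EccProfile, floor: int = 0) -> int:
    """Lognormal circle length resampled into [min_length, max_length]."""
    mu = np.log(profile.mean_length) - profile.sigma_log**2 / 2
    lo = max(profile.min_length, floor)
    for _ in range(100):
        x = int(rng.lognormal(mu, profile.sigma_log))
        if lo <= x <= profile.max_length:
            return x
    return int(np.clip(x, lo, profile.max_length))


def sample_eccdna(
    genome: GenomeModel,
    profile: EccProfile,
    n: int,
    seed: int = 0,
) -> tuple[list[EccRecord], TruthTable]:
    """Excise ``n`` circles from the genome per a condition profile.

    Each circle is a contiguous genomic segment read as a circle. Circles
    are drawn from four categories — gene-bearing, tRNA-bearing,
    ORI-bearing and background — with the profile's target fractions;
    non-gene categories reject gene overlaps (and background rejects all
    planted-site overlaps), so composition fractions are exact Bernoulli
    targets rather than incidental. Background starts follow the hotspot
    enrichment weights of :func:`background_window_weights`.
    """
    rng = rng_for(seed, f"ecc-{profile.condition}")
    sizes = genome.chrom_sizes()
    if profile.max_length > max(sizes.values()):
        raise ConfigurationError("requested circle length exceeds chromosome length")
    p = np.array([profile.gene_fraction, profile.trna_fraction, profile.ori_fraction])
    if p.sum() > 1:
        raise ConfigurationError("composition fractions sum to more than 1")
    probs = np.concatenate([p, [1 - p.sum()]])
    categories = rng.choice(4, size=n, p=probs)  # 0 gene, 1 trna, 2 ori, 3 background

    gene_trees = {c: IntervalTree() for c in sizes}
    for g in genome.gene_models.itertuples(index=False):
        gene_trees[g.chrom].addi(g.start, g.end, g.gene_id)
    avoid_trees = {c: IntervalTree() for c in sizes}
    for df in (genome.gene_models, genome.trna_sites, genome.ori_sites):
        for r in df.itertuples(index=False):
            avoid_trees[r.chrom].addi(r.start, r.end)

    weights = background_window_weights(genome, profile)
    wprob = weights["weight"].to_numpy() / weights["weight"].sum()

    def place_over_site(site_row, length):
        chrom = site_row["chrom"]
        size = sizes[chrom]
        lo = max(0, site_row["end"] - length)
        hi = min(size - length, site_row["start"])
        if hi < lo:
            return chrom, max(0, min(site_row["start"], size - length))
        return chrom, int(rng.integers(lo, hi + 1))

    records: list[EccRecord] = []
    truth_rows: list[dict] = []
    rep_labels = [f"{profile.condition}_r{r + 1}" for r in range(max(1, profile.replicates))]
    for i in range(n):
        cat = categories[i]
        if cat == 0 and len(genome.gene_models):
            length = _sample_length(rng, profile)
            g = genome.gene_models.iloc[int(rng.integers(len(genome.gene_models)))]
            chrom, size = g["chrom"], sizes[g["chrom"]]
            lo = max(0, g["start"] - length + 1)
            hi = min(size - length, g["end"] - 1)
            start = int(rng.integers(lo, max(lo, hi) + 1))
            category = "gene"
        elif cat == 1 and len(genome.trna_sites):
            length = _sample_length(rng, profile, floor=genome.trna_motifs["sequence"].str.len().max() + 4)
            site = genome.trna_sites.iloc[int(rng.integers(len(genome.trna_sites)))]
            chrom, start = place_over_site(site, length)
            category = "trna"
        elif cat == 2 and len(genome.ori_sites):
            length = _sample_length(rng, profile, floor=genome.ori_motifs["sequence"].str.len().max() + 4)
            site = genome.ori_sites.iloc[int(rng.integers(len(genome.ori_sites)))]
            chrom, start = place_over_site(site, length)
            category = "ori"
        else:
            length = _sample_length(rng, profile)
            category = "background"
            for _ in range(200):
                w = weights.iloc[int(rng.choice(len(weights), p=wprob))]
                chrom = w["chrom"]
                hi = min(w["end"], sizes[chrom] - length)
                if hi <= w["start"]:
                    continue
                start = int(rng.integers(w["start"], hi))
                if not avoid_trees[chrom].overlap(start, start + length):
                    break
            else:
                raise ConfigurationError("could not place a background circle off annotations")

        # non-gene categories must not touch gene bodies
        if category in ("trna", "ori"):
            for _ in range(200):
                if not gene_trees[chrom].overlap(start, start + length):
                    break
                site_df = genome.trna_sites if category == "trna" else genome.ori_sites
                site = site_df.iloc[int(rng.integers(len(site_df)))]
                chrom, start = place_over_site(site, length)
            # fall through: residual overlap is recorded in truth either way

        end = start + length
        seq = genome.sequence(chrom)[start:end]
        genes = sorted(iv.data for iv in gene_trees[chrom].overlap(start, end))
        ecc_id = f"{profile.condition}_ecc{i:05d}"
        replicate = rep_labels[int(rng.integers(len(rep_labels)))]
        records.append(
            EccRecord(ecc_id=ecc_id, sequence=seq, condition=profile.condition,
                      monomer_support=1, source_read="")
        )
        truth_rows.append(
            {"ecc_id": ecc_id, "condition": profile.condition, "replicate": replicate,
             "chrom": chrom, "start": start, "end": end, "length": length,
             "category": category, "genes": ",".join(genes)}
        )
    truth = TruthTable(ecc_truth=pd.DataFrame(truth_rows))
    return records, truth


def truth_to_bed(ecc_truth: pd.DataFrame) -> pd.DataFrame:
    """Primary genome placements of circles as a BED-shaped frame."""
    return pd.DataFrame(
        {"chrom": ecc_truth["chrom"], "start": ecc_truth["start"],
         "end": ecc_truth["end"], "name": ecc_truth["ecc_id"],
         "score": 0, "strand": "+"}
    )


# ---------------------------------------------------------------------------
# rolling-circle reads


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base read errors, HiFi-like by default.

    Substitutions dominate; 1-bp indels are rare. Rates are per emitted
    base and must lie in [0, 0.2].
    """

    substitution: float = 0.005
    indel: float = 0.0005

    def __post_init__(self):
        for r in (self.substitution, self.indel):
            if not 0 <= r <= 0.2:
                raise ConfigurationError(f"error rate {r} outside [0, 0.2]")


def _apply_errors(seq: str, err: ErrorModel, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = arr.size
    if err.substitution > 0:
        hits = np.flatnonzero(rng.random(n) < err.substitution)
        if hits.size:
            # replace with a uniformly random *different* base
            base_idx = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), arr[hits])
            shift = rng.integers(1, 4, size=hits.size)
            arr[hits] = np.frombuffer(b"ACGT", dtype=np.uint8)[(base_idx + shift) % 4]
    out = arr.tobytes().decode("ascii")
    if err.indel > 0:
        hits = np.flatnonzero(rng.random(len(out)) < err.indel)
        if hits.size:
            chars = list(out)
            for pos in hits[::-1]:
                if rng.random() < 0.5:
                    chars.insert(pos, BASES[rng.integers(4)])
                else:
                    del chars[pos]
            out = "".join(chars)
    return out


def simulate_rca_reads(
    circles: Sequence[EccRecord],
    pass_range: tuple[float, float] = (2.0, 8.0),
    err: ErrorModel = ErrorModel(),
    seed: int = 0,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Rolling-circle concatemer reads, one per circle.

    Each read is the circle repeated from a uniform random phase for a
    fractional pass count drawn uniformly from ``pass_range`` (the
    terminal pass ends mid-circle), then passed through the error model.
    Returns (FASTA-ready (id, sequence) pairs, read truth).
    """
    if pass_range[0] < 1:
        raise ConfigurationError("pass counts must support values >= 1")
    if not circles:
        warnings.warn("simulate_rca_reads called with no circles; empty output")
        return [], TruthTable(read_truth=pd.DataFrame(
            columns=["read_id", "ecc_id", "passes", "phase", "sub_rate", "indel_rate"]))
    rng = rng_for(seed, "rca-reads")
    reads, rows = [], []
    for i, circ in enumerate(circles):
        passes = float(rng.uniform(*pass_range))
        phase = int(rng.integers(0, circ.length))
        total = int(passes * circ.length)
        template = rotate(circ.sequence, phase)
        tiled = (template * (total // circ.length + 2))[:total]
        read_seq = _apply_errors(tiled, err, rng)
        read_id = f"read{i:05d}|{circ.ecc_id}"
        reads.append((read_id, read_seq))
        rows.append(
            {"read_id": read_id, "ecc_id": circ.ecc_id, "passes": passes,
             "phase": phase, "sub_rate": err.substitution, "indel_rate": err.indel}
        )
    return reads, TruthTable(read_truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RNA-seq counts


def default_de_plan(
    genome: GenomeModel,
    seed: int = 0,
    n_loss: int = 13,
    n_gain_c12: int = 2,
    n_gain_st12: int = 4,
    base_mean: float = 1000.0,
    dispersion: float = 0.05,
    effect_range: tuple[float, float] = (2.5, 4.0),
) -> pd.DataFrame:
    """Planted differential-expression plan over the genome's genes.

    Loss genes are down in both Day 12 conditions; gain genes are up in
    exactly one. Planted |log2FC| magnitudes are drawn from
    ``effect_range``, clearly inside the |log2FC| >= 2 flagged class (the
    study's flagged genes also passed significance testing, so planted
    effects sit away from the threshold boundary).
    """
    rng = rng_for(seed, "de-plan")
    genes = list(genome.gene_models["gene_id"])
    need = n_loss + n_gain_c12 + n_gain_st12
    if need > len(genes):
        raise ConfigurationError(f"DE plan needs {need} genes, genome has {len(genes)}")
    chosen = list(rng.choice(genes, size=need, replace=False))
    loss = set(chosen[:n_loss])
    gain_c = set(chosen[n_loss : n_loss + n_gain_c12])
    gain_s = set(chosen[n_loss + n_gain_c12 :])
    rows = []
    for g in genes:
        mag = float(rng.uniform(*effect_range))
        lfc_c = -mag if g in loss else (mag if g in gain_c else 0.0)
        mag = float(rng.uniform(*effect_range))
        lfc_s = -mag if g in loss else (mag if g in gain_s else 0.0)
        rows.append(
            {"gene_id": g, "base_mean": base_mean, "dispersion": dispersion,
             "log2fc_C12": lfc_c, "log2fc_ST12": lfc_s}
        )
    return pd.DataFrame(rows)


def simulate_rnaseq_counts(
    genome: GenomeModel,
    de_plan: pd.DataFrame,
    replicates: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Negative-binomial count matrix (genes x samples) with planted effects.

    ``de_plan`` rows carry base_mean, dispersion and per-condition log2
    fold changes (columns ``log2fc_<cond>``; absent conditions get 0).
    Dispersion is the NB quadratic overdispersion: var = mu + disp * mu^2.
    """
    if replicates is None:
        replicates = {"D0": 4, "C12": 2, "ST12": 2}
    for cond, r in replicates.items():
        if r < 1:
            raise ConfigurationError(f"condition {cond}: replicates must be >= 1")
    if (de_plan["base_mean"] < 0).any():
        raise ConfigurationError("negative baseline means in DE plan")
    rng = rng_for(seed, "rnaseq-counts")
    data = {}
    for cond, nrep in replicates.items():
        lfc_col = f"log2fc_{cond}"
        lfc = de_plan[lfc_col].to_numpy() if lfc_col in de_plan else np.zeros(len(de_plan))
        mu = de_plan["base_mean"].to_numpy() * np.power(2.0, lfc)
        disp = de_plan["dispersion"].to_numpy()
        for r in range(nrep):
            with np.errstate(divide="ignore"):
                nb_n = np.where(disp > 0, 1.0 / np.maximum(disp, 1e-12), np.inf)
            counts = np.where(
                disp > 0,
                rng.negative_binomial(np.where(disp > 0, nb_n, 1.0),
                                      np.where(disp > 0, nb_n / (nb_n + mu), 0.5)),
                rng.poisson(mu),
            )
            data[f"{cond}_r{r + 1}"] = counts.astype(int)
    counts_df = pd.DataFrame(data, index=pd.Index(de_plan["gene_id"], name="gene_id"))
    return counts_df, TruthTable(de_truth=de_plan.copy())


# ---------------------------------------------------------------------------
# eccDNA-private SNPs


def plant_ecc_snps(
    genome: GenomeModel,
    circles: Sequence[EccRecord],
    ecc_truth: pd.DataFrame,
    k: int,
    seed: int = 0,
    ref_depth: int = 71,
    ecc_depth: int = 40,
    rna_depth: int = 60,
    rna_error: float = 0.0,
    n_control_sites: int = 0,
) -> tuple[list[EccRecord], pd.DataFrame, TruthTable]:
    """Plant ``k`` eccDNA-private SNPs inside gene-overlapping circle segments.

    Each planted site flips one circle base away from the genome; the
    emitted RNA pileup carries the circle allele (with optional per-base
    RNA error), the reference-read pileup carries the genome allele, and
    the eccDNA consensus column is the alternate allele at full fraction.
    ``n_control_sites`` adds SNP-free sites where all sources agree, for
    precision checks. Pileup positions are 1-based.
    """
    rng = rng_for(seed, "ecc-snps")
    by_id = {c.ecc_id: i for i, c in enumerate(circles)}
    gene_trees: dict[str, IntervalTree] = {}
    for g in genome.gene_models.itertuples(index=False):
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    # eligible (circle, offset window) segments: circle ∩ gene body
    segments = []
    for row in ecc_truth.itertuples(index=False):
        if row.ecc_id not in by_id:
            continue
        tree = gene_trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            lo, hi = max(row.start, iv.begin), min(row.end, iv.end)
            if hi > lo:
                segments.append((row.ecc_id, row.chrom, row.start, lo, hi, iv.data))
    total_eligible = sum(hi - lo for _, _, _, lo, hi, _ in segments)
    if k > total_eligible:
        raise ValueError(
            f"requested {k} SNPs but only {total_eligible} eligible gene-overlapping bases"
        )

    new_seqs = {c.ecc_id: bytearray(c.sequence, "ascii") for c in circles}
    chosen: set[tuple[str, int]] = set()
    snp_rows, pileup_rows = [], []
    seg_weights = np.array([hi - lo for *_, lo, hi, _ in segments], dtype=float)
    seg_prob = seg_weights / seg_weights.sum() if len(segments) else None

    def pileup_counts(depth, major, error):
        counts = dict.fromkeys(BASES, 0)
        if error <= 0:
            counts[major] = depth
            return counts
        wrong = rng.binomial(depth, error)
        counts[major] = depth - int(wrong)
        for _ in range(int(wrong)):
            counts[BASES[rng.integers(4)]] += 1
        return counts

    planted = 0
    attempts = 0
    while planted < k and attempts < 100 * k + 100:
        attempts += 1
        si = int(rng.choice(len(segments), p=seg_prob))
        ecc_id, chrom, circ_start, lo, hi, gene_id = segments[si]
        gpos = int(rng.integers(lo, hi))
        if (chrom, gpos) in chosen:
            continue
        offset = gpos - circ_start
        ref_base = chr(new_seqs[ecc_id][offset])
        if ref_base not in BASES:
            continue
        alt = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
        new_seqs[ecc_id][offset] = ord(alt)
        chosen.add((chrom, gpos))
        planted += 1
        snp_rows.append(
            {"chrom": chrom, "pos": gpos + 1, "ref_base": ref_base, "ecc_base": alt,
             "ecc_id": ecc_id, "gene_id": gene_id}
        )
        ref_counts = pileup_counts(ref_depth, ref_base, 0.0)
        rna_counts = pileup_counts(rna_depth, alt, rna_error)
        pileup_rows.append(
            {"chrom": chrom, "pos": gpos + 1, "ref_base": ref_base,
             **{f"ref_{b}": ref_counts[b] for b in BASES},
             "ecc_base": alt, "ecc_fraction": 1.0,
             **{f"rna_{b}": rna_counts[b] for b in BASES},
             "gene_id": gene_id}
        )
    if planted < k:
        raise ValueError(f"requested {k} SNPs but placed only {planted} distinct sites")

    for _ in range(n_control_sites):
        if not segments:
            break
        si = int(rng.choice(len(segments), p=seg_prob))
        ecc_id, chrom, circ_start, lo, hi, gene_id = segments[si]
        gpos = int(rng.integers(lo, hi))
        if (chrom, gpos) in chosen:
            continue
        base = chr(new_seqs[ecc_id][gpos - circ_start])
        rna_counts = pileup_counts(rna_depth, base, rna_error)
        pileup_rows.append(
            {"chrom": chrom, "pos": gpos + 1, "ref_base": base,
             **{f"ref_{b}": (ref_depth if b == base else 0) for b in BASES},
             "ecc_base": base, "ecc_fraction": 1.0,
             **{f"rna_{b}": rna_counts[b] for b in BASES},
             "gene_id": gene_id}
        )

    modified = [
        replace(c, sequence=new_seqs[c.ecc_id].decode("ascii")) for c in circles
    ]
    pileup = pd.DataFrame(pileup_rows).sort_values(["chrom", "pos"]).reset_index(drop=True) \
        if pileup_rows else pd.DataFrame(
            columns=["chrom", "pos", "ref_base",
                     *(f"ref_{b}" for b in BASES), "ecc_base", "ecc_fraction",
                     *(f"rna_{b}" for b in BASES), "gene_id"])
    truth = TruthTable(snp_truth=pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "ref_base", "ecc_base", "ecc_id", "gene_id"]))
    return modified, pileup, truth
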