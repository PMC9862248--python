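"""Self-contained recovery studies on synthetic data.

Each function generates a synthetic dataset with a known truth table,
runs the corresponding analysis stage, and scores how well the planted
structure is recovered. These are the package's standard health checks:
they quantify, under the generator's stated conditions, the fidelity of
circle confirmation, cluster recovery, hotspot detection, expression
concordance flagging and transcript assignment.

Problem sizes are chosen so the full battery runs in a few minutes on
one core; every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import transcription as tx
from ._seq import circular_identity, rng_for
from .biogenesis import assign_windows, call_hotspots, window_zscores
from .cluster import cluster_sequences
from .deconcat import ConcatemerRead, DeconcatParams, deconcat_reads
from .simulate import (
    CONDITION_PROFILES,
    EccProfile,
    ErrorModel,
    GenomeConfig,
    build_genome,
    default_de_plan,
    plant_ecc_snps,
    sample_eccdna,
    simulate_rca_reads,
    simulate_rnaseq_counts,
    truth_to_bed,
)

__all__ = [
    "deconcat_recovery",
    "cluster_recovery",
    "hotspot_recovery",
    "dynamics_sensitivity",
    "transcript_recovery",
]


def deconcat_recovery(
    seed: int,
    n_circles: int = 200,
    sub_rate: float = 0.005,
    pass_range: tuple[float, float] = (2.0, 8.0),
    mean_length: float = 1000.0,
    max_length: int = 3000,
) -> dict:
    """Circle-confirmation fidelity under HiFi-like substitution error.

    Simulates one rolling-circle read per circle and deconcatenates it;
    a circle counts as recovered when the accepted consensus length is
    within +/-1 bp of truth and its identity to the truth circle is at
    least 99%. Returns accepted / recovered counts and rates.
    """
    genome = build_genome(GenomeConfig(), seed=seed)
    profile = EccProfile(condition="D0", mean_length=mean_length, max_length=max_length)
    circles, _ = sample_eccdna(genome, profile, n_circles, seed=seed)
    reads, _ = simulate_rca_reads(circles, pass_range, ErrorModel(sub_rate, 0.0), seed=seed)
    records, rejections, _ = deconcat_reads(
        [ConcatemerRead(rid, seq) for rid, seq in reads], DeconcatParams()
    )
    by_id = {x.ecc_id: x.sequence for x in circles}
    recovered = 0
    for rec in records:
        truth_seq = by_id[rec.ecc_id.split("|")[-1]]
        if (
            abs(rec.length - len(truth_seq)) <= 1
            and circular_identity(rec.sequence, truth_seq) >= 0.99
        ):
            recovered += 1
    return {
        "n_circles": n_circles,
        "n_accepted": len(records),
        "n_rejected": len(rejections),
        "n_recovered": recovered,
        "recovery_rate": recovered / len(records) if records else 0.0,
    }


def cluster_recovery(
    seed: int,
    n_clusters: int = 10,
    members: int = 3,
    length: int = 500,
    divergence: float = 0.02,
    threshold: float = 0.90,
) -> dict:
    """Planted-cluster recovery by greedy identity clustering.

    Plants ``n_clusters`` random circles, emits ``members`` rotated,
    strand-flipped copies of each at the given substitution divergence,
    clusters at ``threshold`` and scores exact recovery of the planted
    partition.
    """
    rng = rng_for(seed, "cluster-benchmark")
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    pairs, truth = [], []
    for i in range(n_clusters):
        base = base_bytes[rng.integers(0, 4, size=length)]
        group = set()
        for j in range(members):
            copy = base.copy()
            hits = rng.random(length) < divergence
            copy[hits] = base_bytes[(np.searchsorted(base_bytes, copy[hits])
                                     + rng.integers(1, 4, size=int(hits.sum()))) % 4]
            phase = int(rng.integers(length))
            seq = copy.tobytes().decode("ascii")
            seq = seq[phase:] + seq[:phase]
            if rng.random() < 0.5:
                seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            name = f"c{i}_{j}"
            pairs.append((name, seq))
            group.add(name)
        truth.append(frozenset(group))
    cset = cluster_sequences(pairs, threshold=threshold)
    found = {frozenset(m for m, _ in cl.members) for cl in cset.clusters}
    exact = found == set(truth)
    return {
        "n_sequences": len(pairs),
        "n_clusters_found": cset.n_clusters,
        "n_clusters_planted": n_clusters,
        "exact_recovery": bool(exact),
    }


def hotspot_recovery(
    seed: int,
    n_seeds: int = 20,
    n_placements: int = 2000,
    enrichment: float = 10.0,
) -> dict:
    """Planted-hotspot detection rate across seeds.

    One genome window carries ``enrichment``-fold excision weight; a
    seed succeeds when that window is the top-ranked window AND scores
    z >= 2. Window-count conservation and Z-normalization are asserted
    on every run.
    """
    genome = build_genome(GenomeConfig(), seed=seed)
    hs = genome.hotspot_intervals.iloc[0]
    hot_key = (hs["chrom"], hs["start"] // genome.window_size)
    profile = EccProfile(condition="D0", gene_fraction=0, trna_fraction=0,
                         ori_fraction=0, hotspot_enrichment=enrichment,
                         mean_length=300, max_length=1000)
    detected = 0
    for i in range(n_seeds):
        _, truth = sample_eccdna(genome, profile, n_placements, seed=seed + 1000 + i)
        counts = assign_windows(truth_to_bed(truth.ecc_truth), genome.chrom_sizes(),
                                genome.window_size)
        if counts["count"].sum() != n_placements:
            raise AssertionError("window counts do not conserve placements")
        z = window_zscores(counts["count"].to_numpy())
        if abs(z.mean()) > 1e-9 or abs(z.std() - 1) > 1e-9:
            raise AssertionError("Z vector not normalized")
        result = call_hotspots(counts, z_min=2.0)
        top = result.top.iloc[0]
        if (top["chrom"], top["index"]) == hot_key and top["z"] >= 2.0:
            detected += 1
    return {
        "n_seeds": n_seeds,
        "n_placements": n_placements,
        "n_detected": detected,
        "detection_rate": detected / n_seeds,
    }


def dynamics_sensitivity(
    seed: int,
    n_loss: int = 30,
    n_gain_c12: int = 10,
    n_gain_st12: int = 10,
    base_mean: float = 1000.0,
    dispersion: float = 0.05,
) -> dict:
    """Sensitivity of gain/loss concordance flagging to planted effects.

    Planted loss genes appear only on Day-0 eccDNA and fall in
    expression by Day 12; gain genes appear only on one Day-12
    condition's eccDNA and rise in that condition. Sensitivity is the
    fraction of planted genes flagged with the concordant class at the
    default |log2FC| >= 2 bounds.
    """
    genome = build_genome(GenomeConfig(n_genes=400, gene_length=(1000, 3000)), seed=seed)
    plan = default_de_plan(genome, seed=seed, n_loss=n_loss, n_gain_c12=n_gain_c12,
                           n_gain_st12=n_gain_st12, base_mean=base_mean,
                           dispersion=dispersion)
    counts, truth = simulate_rnaseq_counts(genome, plan, seed=seed)
    de_truth = truth.de_truth.set_index("gene_id")
    loss = set(de_truth.index[de_truth["log2fc_C12"] < 0])
    gain_c = set(de_truth.index[de_truth["log2fc_C12"] > 0])
    gain_s = set(de_truth.index[de_truth["log2fc_ST12"] > 0])
    steady = set(de_truth.index) - loss - gain_c - gain_s
    presence = dyn.presence_matrix(
        {"D0": loss | steady, "C12": gain_c | steady, "ST12": gain_s | steady}
    )
    cols = lambda p: [x for x in counts.columns if x.startswith(p)]
    de = {
        "C12": dyn.log2fc(counts[cols("D0_")], counts[cols("C12_")]),
        "ST12": dyn.log2fc(counts[cols("D0_")], counts[cols("ST12_")]),
    }
    flagged = dyn.intersect_dynamics(presence, de).set_index("gene_id")
    hits = sum(
        1 for g in loss if flagged.loc[g, "flag"] == "loss-correlated"
    ) + sum(
        1 for g in gain_c | gain_s if flagged.loc[g, "flag"] == "gain-correlated"
    )
    planted = len(loss) + len(gain_c) + len(gain_s)
    return {
        "n_planted": planted,
        "n_flagged_concordant": hits,
        "sensitivity": hits / planted,
    }


def transcript_recovery(
    seed: int,
    n_seeds: int = 20,
    k_snps: int = 5,
    rna_error: float = 0.005,
    rna_depth: int = 60,
) -> dict:
    """Recovery of planted eccDNA-private SNP sites from pileups.

    Noise-free precision/recall come from one run with error-free RNA;
    the noisy recall pools planted sites across ``n_seeds`` independent
    replicates at the given RNA error and depth.
    """
    genome = build_genome(GenomeConfig(), seed=seed)
    profile = EccProfile(condition="ST12", gene_fraction=0.6, trna_fraction=0,
                         ori_fraction=0, mean_length=3000, max_length=8000)

    def run(err: float, sub_seed: int):
        circles, truth = sample_eccdna(genome, profile, 30, seed=sub_seed)
        _, pileup, snp_truth = plant_ecc_snps(
            genome, circles, truth.ecc_truth, k_snps, seed=sub_seed,
            rna_depth=rna_depth, rna_error=err, n_control_sites=20,
        )
        classified = tx.classify_pileup(pileup)
        supported = classified[classified["site_class"] == tx.ECC_SUPPORTED]
        called = set(zip(supported["chrom"], supported["pos"]))
        planted = set(zip(snp_truth.snp_truth["chrom"], snp_truth.snp_truth["pos"]))
        return called, planted

    called, planted = run(0.0, seed)
    precision = len(called & planted) / len(called) if called else 0.0
    recall_clean = len(called & planted) / len(planted)

    hit = total = 0
    for i in range(n_seeds):
        called, planted = run(rna_error, seed + 2000 + i)
        hit += len(called & planted)
        total += len(planted)
    return {
        "noise_free_precision": precision,
        "noise_free_recall": recall_clean,
        "noisy_recall": hit / total,
        "n_sites_noisy": total,
        "rna_error": rna_error,
        "rna_depth": rna_depth,
    }
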