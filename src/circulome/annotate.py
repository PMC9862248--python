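"""Per-eccDNA annotation: repeat masking, tRNA/ORI motif hits, gene
content, and Table-style per-condition summaries.

Repeat and motif detection is a seeded alignment scan against small motif
libraries (exact k-mer anchors extended to a full-window identity check).
It stands in for covariance-model tRNA scanning and full repeat-family
masking: the contract — which bases are masked, which sequences carry a
motif at a given identity — is the same, the underlying search is
deliberately simple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import gc_fraction, revcomp, seq_to_array
from .deconcat import EccRecord

__all__ = [
    "mask_repeats",
    "find_motifs",
    "annotate_genes",
    "gene_sets_by_condition",
    "ConditionSummary",
    "summarize_condition",
]

# masking precedence on overlap: interspersed classes outrank tandem/simple
# classes, preventing double-counted bases
REPEAT_CLASS_PRECEDENCE = [
    "SINE", "LINE", "LTR", "DNA", "unclassified",
    "small_RNA", "satellite", "simple", "low_complexity",
]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10**ndigits
    return np.floor(x * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# seeded motif alignment


def _window_identity(seq_arr: np.ndarray, motif_arr: np.ndarray, start: int) -> tuple[int, int, float]:
    """Identity of the motif laid over ``seq`` at ``start``, clipped to bounds.

    Returns (clip_start, clip_end, identity over the clipped window).
    """
    m = motif_arr.size
    lo = max(0, start)
    hi = min(seq_arr.size, start + m)
    if hi <= lo:
        return lo, hi, 0.0
    window = seq_arr[lo:hi]
    motif_part = motif_arr[lo - start : hi - start]
    return lo, hi, float(np.mean(window == motif_part))


def _scan_motif(
    seq: str,
    motif: str,
    min_identity: float,
    min_length: Optional[int] = None,
    k: int = 11,
    circular: bool = False,
) -> list[dict]:
    """Find placements of ``motif`` (both strands) in ``seq``.

    With ``min_length`` set, clipped boundary alignments of at least that
    many bases qualify; otherwise the full motif must fit (full-length
    mode). ``circular`` extends the scan across the origin of a circular
    sequence; hits then start in [0, len(seq)) but may end past it
    (wrapping). Candidates come from exact k-mer anchors, so hits below
    ~70% identity are not expected to seed — acceptable at the 80%+
    thresholds used here.
    """
    seq = seq.upper()
    n = len(seq)
    if circular and n > k:
        seq = seq + seq[: min(n - 1, len(motif) + k)]
    seq_arr = seq_to_array(seq)
    k = min(k, len(motif))
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    hits = []
    for strand, mseq in (("+", motif.upper()), ("-", revcomp(motif.upper()))):
        motif_arr = seq_to_array(mseq)
        m = motif_arr.size
        candidates: set[int] = set()
        step = max(1, k // 2)
        for off in range(0, m - k + 1, step):
            for pos in index.get(mseq[off : off + k], ()):
                candidates.add(pos - off)
        evaluated: set[int] = set()
        for start in sorted(candidates):
            if start in evaluated:
                continue
            # refine +/-1 around the anchor-implied start
            best = None
            for s in (start - 1, start, start + 1):
                lo, hi, ident = _window_identity(seq_arr, motif_arr, s)
                if best is None or ident > best[2]:
                    best = (lo, hi, ident, s)
                evaluated.add(s)
            lo, hi, ident, s = best
            span = hi - lo
            if min_length is None:
                if s < 0 or s + m > len(seq):
                    continue  # full-length mode: motif must fit entirely
            elif span < min_length:
                continue
            if lo >= n:
                continue  # circular duplicate of a hit already seen at lo - n
            if ident >= min_identity:
                hits.append(
                    {"start": lo, "end": hi, "identity": round(ident, 4), "strand": strand}
                )
    return hits


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mask_repeats(
    seq: str,
    repeat_library: pd.DataFrame,
    min_identity: float = 0.80,
    min_length: int = 30,
) -> tuple[str, pd.DataFrame]:
    """Mask repeat-library matches in a sequence.

    A base is masked when a library motif aligns over it at
    >= ``min_identity`` identity across >= ``min_length`` bp. The scan is
    circular (alignments may wrap across the sequence origin). Overlaps
    across classes resolve by :data:`REPEAT_CLASS_PRECEDENCE`, so
    per-class masked-bp totals are additive. Returns the soft-masked
    sequence (masked bases lower-cased) and the interval table
    (cls, start, end, bp).
    """
    if not seq:
        raise ValueError("mask_repeats requires a non-empty sequence")
    seq = seq.upper()
    n = len(seq)
    raw_hits: dict[str, list[tuple[int, int]]] = {}
    for row in repeat_library.itertuples(index=False):
        for hit in _scan_motif(seq, row.sequence, min_identity, min_length=min_length,
                               circular=True):
            raw_hits.setdefault(row.cls, []).append((hit["start"], hit["end"]))

    claimed = np.zeros(n, dtype=bool)
    rows = []
    order = [c for c in REPEAT_CLASS_PRECEDENCE if c in raw_hits] + [
        c for c in raw_hits if c not in REPEAT_CLASS_PRECEDENCE
    ]
    for cls in order:
        for s, e in _merge_intervals(raw_hits[cls]):
            window = np.unique(np.arange(s, e) % n)
            free = window[~claimed[window]]
            if free.size == 0:
                continue
            claimed[free] = True
            # report maximal runs of newly claimed bases
            breaks = np.flatnonzero(np.diff(free) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [free.size - 1]])
            for a, b in zip(starts, ends):
                rows.append(
                    {"cls": cls, "start": int(free[a]), "end": int(free[b]) + 1,
                     "bp": int(free[b]) + 1 - int(free[a])}
                )
    arr = np.array(list(seq))
    arr[claimed] = np.char.lower(arr[claimed])
    intervals = pd.DataFrame(rows, columns=["cls", "start", "end", "bp"])
    return "".join(arr), intervals


def find_motifs(
    seq: str,
    motif_db: pd.DataFrame,
    min_identity: float = 0.95,
) -> pd.DataFrame:
    """Full-length motif hits at or above ``min_identity``, both strands.

    ``motif_db`` needs columns name/sequence. The scan is circular: a hit
    may wrap the sequence origin, in which case its end coordinate
    exceeds the sequence length. The default identity suits
    replication-origin motifs (>= 95% homology over the whole motif);
    tRNA scans conventionally pass 0.90. No hits yields an empty frame.
    """
    rows = []
    for row in motif_db.itertuples(index=False):
        for hit in _scan_motif(seq, row.sequence, min_identity, min_length=None,
                               circular=True):
            rows.append({"motif": row.name, **hit})
    return pd.DataFrame(rows, columns=["motif", "start", "end", "identity", "strand"])


# ---------------------------------------------------------------------------
# gene content


def annotate_genes(
    placements: pd.DataFrame,
    gene_models: pd.DataFrame,
) -> pd.DataFrame:
    """Genes harbored by each placed eccDNA (>= 1 bp gene-body overlap).

    ``placements``: BED-shaped frame (chrom, start, end, name) of one
    primary genome placement per eccDNA. ``gene_models``: chrom, start,
    end, gene_id (0-based half-open). Gene fragments count: any positive
    overlap lists the gene. Unknown chromosomes raise, naming the record.
    """
    trees: dict[str, IntervalTree] = {}
    for g in gene_models.itertuples(index=False):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
    known_chroms = set(trees) | set(gene_models["chrom"])
    rows = []
    for p in placements.itertuples(index=False):
        if p.chrom not in known_chroms:
            raise ValueError(
                f"placement {p.name!r}: unknown chromosome {p.chrom!r} (not in gene models)"
            )
        overlaps = trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
        genes = sorted({iv.data for iv in overlaps})
        rows.append({"ecc_id": p.name, "n_genes": len(genes), "genes": ",".join(genes)})
    return pd.DataFrame(rows, columns=["ecc_id", "n_genes", "genes"])


def gene_sets_by_condition(
    gene_hits: pd.DataFrame, conditions: Mapping[str, str]
) -> dict[str, set[str]]:
    """Per-condition sets of genes observed on >= 1 eccDNA."""
    out: dict[str, set[str]] = {}
    for row in gene_hits.itertuples(index=False):
        cond = conditions.get(row.ecc_id)
        if cond is None or not row.genes:
            continue
        out.setdefault(cond, set()).update(row.genes.split(","))
    return out


# ---------------------------------------------------------------------------
# condition summaries (Table-1 shape)


@dataclass(frozen=True)
class ConditionSummary:
    """One condition's sequence-characteristics row.

    Percentages are recomputable from their numerator/denominator:
    masked % of total bases; gene/tRNA/ORI % of clustered sequence count;
    mean length = total bases / count, rounded half-up to the nearest bp.
    All percentages round half-up to 2 decimals.
    """

    condition: str
    n_sequences: int
    n_clustered: int
    max_length: int
    mean_length: int
    total_bases: int
    masked_bases: int
    masked_pct: float
    gc_pct: float
    n_gene_bearing: int
    gene_pct: float
    n_trna_bearing: int
    n_trna_motifs: int
    trna_pct: float
    n_ori_bearing: int
    ori_pct: float

    @classmethod
    def from_totals(
        cls,
        condition: str,
        n_sequences: int,
        n_clustered: int,
        total_bases: int,
        max_length: int = 0,
        masked_bases: int = 0,
        gc_bases: int = 0,
        n_gene_bearing: int = 0,
        n_trna_bearing: int = 0,
        n_trna_motifs: int = 0,
        n_ori_bearing: int = 0,
    ) -> "ConditionSummary":
        """Build a summary row from raw numerators and denominators."""
        if n_clustered <= 0:
            raise ValueError("summary requires at least one clustered sequence")
        pct = lambda num, den: float(_round_half_up(100.0 * num / den, 2)) if den else 0.0
        return cls(
            condition=condition,
            n_sequences=n_sequences,
            n_clustered=n_clustered,
            max_length=max_length,
            mean_length=int(_round_half_up(total_bases / n_clustered)),
            total_bases=total_bases,
            masked_bases=masked_bases,
            masked_pct=pct(masked_bases, total_bases),
            gc_pct=pct(gc_bases, total_bases),
            n_gene_bearing=n_gene_bearing,
            gene_pct=pct(n_gene_bearing, n_clustered),
            n_trna_bearing=n_trna_bearing,
            n_trna_motifs=n_trna_motifs,
            trna_pct=pct(n_trna_bearing, n_clustered),
            n_ori_bearing=n_ori_bearing,
            ori_pct=pct(n_ori_bearing, n_clustered),
        )

    def to_row(self) -> dict:
        return dict(self.__dict__)


def summarize_condition(
    records: Sequence[EccRecord],
    masked_bp: Mapping[str, int] | None = None,
    gene_hits: Optional[pd.DataFrame] = None,
    trna_hits: Mapping[str, int] | None = None,
    ori_hits: Mapping[str, int] | None = None,
    n_raw: Optional[int] = None,
) -> ConditionSummary:
    """Summarize one condition's clustered records.

    ``masked_bp`` / ``trna_hits`` / ``ori_hits`` map ecc_id to masked base
    count / motif hit count; ``gene_hits`` is the frame from
    :func:`annotate_genes`. GC% is computed over all bases, masked
    included. All records must share one condition label.
    """
    if not records:
        raise ValueError("summarize_condition requires at least one record")
    conditions = {r.condition for r in records}
    if len(conditions) != 1:
        raise ValueError(f"records span multiple conditions: {sorted(conditions)}")
    condition = conditions.pop()
    total_bases = sum(r.length for r in records)
    gc_bases = sum(round(gc_fraction(r.sequence) * r.length) for r in records)
    masked_bp = masked_bp or {}
    trna_hits = trna_hits or {}
    ori_hits = ori_hits or {}
    gene_bearing = 0
    if gene_hits is not None and len(gene_hits):
        gene_bearing = int((gene_hits["n_genes"] > 0).sum())
    return ConditionSummary.from_totals(
        condition=condition,
        n_sequences=n_raw if n_raw is not None else len(records),
        n_clustered=len(records),
        total_bases=total_bases,
        max_length=max(r.length for r in records),
        masked_bases=sum(masked_bp.get(r.ecc_id, 0) for r in records),
        gc_bases=gc_bases,
        n_gene_bearing=gene_bearing,
        n_trna_bearing=sum(1 for r in records if trna_hits.get(r.ecc_id, 0) > 0),
        n_trna_motifs=sum(trna_hits.get(r.ecc_id, 0) for r in records),
        n_ori_bearing=sum(1 for r in records if ori_hits.get(r.ecc_id, 0) > 0),
    )
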