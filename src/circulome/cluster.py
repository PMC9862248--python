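"""Greedy identity clustering of confirmed circles.

Collapses near-duplicate eccDNA sequences per condition at a similarity
threshold (default 90%), longest-first: each sequence joins the first
existing cluster whose representative it matches at or above the
threshold, otherwise it founds a new cluster. Identity is defined over
the best alignment of the shorter sequence against the longer —
denominator the shorter sequence's length — considering both strands and
all rotations of the circular sequences, which reproduces the
nested-fragment semantics of conventional greedy clustering tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from ._seq import circular_identity
from .deconcat import EccRecord

__all__ = ["Cluster", "ClusterSet", "pairwise_identity", "cluster_sequences",
           "summarize_reduction"]


def pairwise_identity(a: str, b: str) -> float:
    """Identity in [0, 1] between two circular sequences.

    Matched fraction of the shorter sequence in its best alignment against
    the longer, maximized over rotations and both strands.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    return circular_identity(a.upper(), b.upper(), both_strands=True)


@dataclass
class Cluster:
    representative: str  # ecc_id of the founding (longest) member
    members: list[tuple[str, float]] = field(default_factory=list)  # (ecc_id, identity)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return sum(c.size for c in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representative_records(self) -> list[tuple[str, str]]:
        return [(c.representative, self.sequences[c.representative]) for c in self.clusters]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"representative": c.representative, "member": m, "identity": round(ident, 4)}
            for c in self.clusters
            for m, ident in c.members
        ]
        return pd.DataFrame(rows, columns=["representative", "member", "identity"])


def cluster_sequences(
    records: Sequence[EccRecord] | Sequence[tuple[str, str]],
    threshold: float = 0.90,
) -> ClusterSet:
    """Greedy longest-first incremental clustering.

    Records are sorted by decreasing length (ties by id); identity at or
    above ``threshold`` joins a cluster. Every input appears in exactly
    one cluster; cluster count never exceeds input count.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not records:
        raise ValueError("cluster_sequences requires at least one record")
    pairs = [
        (r.ecc_id, r.sequence) if isinstance(r, EccRecord) else (r[0], str(r[1]).upper())
        for r in records
    ]
    pairs.sort(key=lambda t: (-len(t[1]), t[0]))
    sequences = dict(pairs)
    clusters: list[Cluster] = []
    for ecc_id, seq in pairs:
        for cl in clusters:
            ident = pairwise_identity(seq, sequences[cl.representative])
            if ident >= threshold:
                cl.members.append((ecc_id, ident))
                break
        else:
            clusters.append(Cluster(representative=ecc_id, members=[(ecc_id, 1.0)]))
    return ClusterSet(clusters=clusters, threshold=threshold, sequences=sequences)


def summarize_reduction(
    before: dict[str, int], after: dict[str, int]
) -> pd.DataFrame:
    """Per-condition and pooled sequence counts before/after clustering."""
    rows = []
    for cond in before:
        b, a = before[cond], after[cond]
        if a > b:
            raise ValueError(f"condition {cond}: clustered count {a} exceeds raw count {b}")
        rows.append({"condition": cond, "sequences": b, "clustered": a, "reduction": b - a})
    pooled = {
        "condition": "pooled",
        "sequences": sum(before.values()),
        "clustered": sum(after.values()),
        "reduction": sum(before.values()) - sum(after.values()),
    }
    return pd.DataFrame(rows + [pooled], columns=["condition", "sequences", "clustered", "reduction"])
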