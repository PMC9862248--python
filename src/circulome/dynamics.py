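"""eccDNA gene-content dynamics across conditions.

Builds the Venn partition of genes observed on eccDNA per condition,
computes expression log2 fold changes (counts-per-million scale with a
pseudocount; significance testing is out of scope and can be imported
from an external differential-expression table), and flags
condition-unique eccDNA genes whose expression shift is concordant with
eccDNA gain or loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = ["GenePresence", "presence_matrix", "log2fc", "intersect_dynamics"]

DAY0 = "D0"


@dataclass
class GenePresence:
    """Boolean gene x condition membership with its Venn partition.

    ``partition`` maps the number of conditions a gene appears in
    (1, 2, 3, ...) to the gene count; values sum to the union size.
    """

    matrix: pd.DataFrame  # bool, genes x conditions
    partition: dict[int, int] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return len(self.matrix)

    def unique_to(self, condition: str) -> set[str]:
        """Genes observed in exactly this condition and no other."""
        m = self.matrix
        mask = m[condition] & (m.sum(axis=1) == 1)
        return set(m.index[mask])

    def shared_day12(self, day12_conditions: tuple[str, ...] = ("C12", "ST12")) -> set[str]:
        """Genes on Day-12 eccDNA in both Day-12 conditions but not Day 0."""
        m = self.matrix
        present = [c for c in day12_conditions if c in m.columns]
        if len(present) < 2:
            return set()
        mask = m[present].all(axis=1)
        if DAY0 in m.columns:
            mask &= ~m[DAY0]
        return set(m.index[mask])


def presence_matrix(gene_lists: Mapping[str, set[str]]) -> GenePresence:
    """Gene presence across conditions (observed on >= 1 eccDNA)."""
    if len(gene_lists) < 2:
        raise ValueError("presence_matrix requires at least 2 conditions")
    union = sorted(set().union(*gene_lists.values()))
    if not union:
        raise ValueError("no genes observed in any condition")
    matrix = pd.DataFrame(
        {cond: [g in genes for g in union] for cond, genes in gene_lists.items()},
        index=pd.Index(union, name="gene_id"),
    )
    n_conditions = matrix.sum(axis=1)
    partition = n_conditions.value_counts().sort_index().to_dict()
    return GenePresence(matrix=matrix, partition={int(k): int(v) for k, v in partition.items()})


def log2fc(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change of group b over group a.

    Each replicate column is scaled to counts-per-million, replicates are
    averaged per group, and
    log2fc = log2((mean_b + pseudocount) / (mean_a + pseudocount)).
    The pseudocount (CPM scale) keeps the ratio finite for unexpressed
    genes. Swapping the groups negates every value exactly.
    """
    for name, df in (("a", counts_a), ("b", counts_b)):
        if df.shape[1] < 1:
            raise ValueError(f"group {name} has no replicate columns")
        zero = df.columns[(df.sum(axis=0) == 0)]
        if len(zero):
            raise ValueError(f"all-zero library in sample(s): {list(zero)}")
    genes = counts_a.index
    if not genes.equals(counts_b.index):
        raise ValueError("count matrices must share the same gene index")
    cpm = lambda df: df / df.sum(axis=0) * 1e6
    mean_a = cpm(counts_a).mean(axis=1)
    mean_b = cpm(counts_b).mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    return pd.DataFrame(
        {"mean_cpm_a": mean_a, "mean_cpm_b": mean_b, "log2fc": lfc}, index=genes
    )


def intersect_dynamics(
    presence: GenePresence,
    de: Mapping[str, pd.DataFrame],
    lo: float = -2.0,
    hi: float = 2.0,
    day12_conditions: tuple[str, ...] = ("C12", "ST12"),
) -> pd.DataFrame:
    """Flag condition-unique eccDNA genes concordant with expression shifts.

    ``de`` maps each Day-12 condition to its Day-12-vs-Day-0 fold-change
    table (a ``log2fc`` column indexed by gene). Day-0-unique genes whose
    expression drops by ``lo`` or more in at least one contrast are
    "loss-correlated"; genes unique to one Day-12 condition whose
    expression in that condition's contrast rises by ``hi`` or more are
    "gain-correlated"; other condition-unique genes are "neutral", and
    genes absent from the expression data are "no-expression-data".
    Genes shared between the two Day-12 conditions (but absent on Day 0)
    are reported with uniqueness class "day12-shared" and flagged by the
    same gain rule using the larger contrast.
    """
    if lo > 0 or hi < 0:
        raise ValueError("expected lo <= 0 <= hi")
    unknown = [c for c in de if c not in presence.conditions]
    if unknown:
        raise ValueError(f"DE contrasts for unknown conditions: {unknown}")

    rows = []

    def flag_gene(gene, uniqueness, contrasts, rule):
        vals = {}
        for cond in contrasts:
            table = de.get(cond)
            if table is not None and gene in table.index:
                vals[cond] = float(table.loc[gene, "log2fc"])
        if not vals:
            return {"gene_id": gene, "uniqueness": uniqueness, "log2fc": np.nan,
                    "flag": "no-expression-data"}
        if rule == "loss":
            best = min(vals.values())
            flag = "loss-correlated" if best <= lo else "neutral"
        else:
            best = max(vals.values())
            flag = "gain-correlated" if best >= hi else "neutral"
        return {"gene_id": gene, "uniqueness": uniqueness, "log2fc": best, "flag": flag}

    if DAY0 in presence.conditions:
        for gene in sorted(presence.unique_to(DAY0)):
            rows.append(flag_gene(gene, f"{DAY0}-unique", list(de), "loss"))
    for cond in day12_conditions:
        if cond not in presence.conditions:
            continue
        for gene in sorted(presence.unique_to(cond)):
            rows.append(flag_gene(gene, f"{cond}-unique", [cond], "gain"))
    for gene in sorted(presence.shared_day12(day12_conditions)):
        rows.append(flag_gene(gene, "day12-shared", list(day12_conditions), "gain"))

    return pd.DataFrame(rows, columns=["gene_id", "uniqueness", "log2fc", "flag"])
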