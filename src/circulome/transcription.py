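"""Assign transcripts to eccDNA templates by allele concordance.

A genomic site supports an eccDNA template when the RNA reads and the
eccDNA consensus agree on an allele that differs from the majority allele
of the reference-aligned DNA reads. Requiring near-fixed
(homozygous-style) allele fractions on both the eccDNA and the RNA side
generalizes the clean 100%-of-reads case to noisy pileups. The
chromosomal allele is defined by the reference-read majority, not the
reference FASTA base alone, so assembly errors at the site do not
masquerade as eccDNA evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._seq import BASES

__all__ = [
    "MajorityCall",
    "PileupSite",
    "majority_allele",
    "classify_site",
    "classify_pileup",
    "scan_transcripts",
]

ECC_SUPPORTED = "eccDNA-supported"
CHROMOSOMAL = "chromosomal"
AMBIGUOUS = "ambiguous"
NO_COVERAGE = "no-coverage"


@dataclass(frozen=True)
class MajorityCall:
    base: str
    fraction: float
    depth: int
    tie: bool = False


def majority_allele(counts: Mapping[str, int]) -> Optional[MajorityCall]:
    """Majority base and its fraction from per-base counts.

    Ties break by fixed base order A < C < G < T and set the ``tie``
    flag. Zero total depth returns None (no coverage).
    """
    total = sum(int(counts.get(b, 0)) for b in BASES)
    if total < 1:
        return None
    best = max(BASES, key=lambda b: int(counts.get(b, 0)))  # first max wins: A<C<G<T
    n_best = int(counts.get(best, 0))
    tie = sum(1 for b in BASES if int(counts.get(b, 0)) == n_best) > 1
    return MajorityCall(base=best, fraction=n_best / total, depth=total, tie=tie)


@dataclass
class PileupSite:
    """Per-site allele evidence from three sources.

    ``ref_counts``: per-base counts of DNA reads aligned to the reference;
    ``ecc_base`` / ``ecc_fraction``: the eccDNA consensus allele and the
    fraction of eccDNA reads supporting it; ``rna_counts``: per-base
    counts of RNA reads. Positions are 1-based.
    """

    chrom: str
    pos: int
    ref_base: str
    ref_counts: dict[str, int]
    ecc_base: str
    ecc_fraction: float
    rna_counts: dict[str, int]
    transcript: Optional[str] = None


def classify_site(
    site: PileupSite,
    min_depth: int = 10,
    min_fraction: float = 0.9,
) -> str:
    """Classify one site given allele-evidence thresholds.

    eccDNA-supported requires all of: RNA majority equals the eccDNA
    consensus allele; both the eccDNA allele fraction and the RNA
    majority fraction reach ``min_fraction``; the eccDNA allele differs
    from the reference-read majority; RNA depth reaches ``min_depth``.
    A site whose RNA majority matches the reference-read majority is
    chromosomal; anything else is ambiguous. Classification is a pure
    function of (counts, thresholds).
    """
    rna = majority_allele(site.rna_counts)
    if rna is None:
        return NO_COVERAGE
    ref = majority_allele(site.ref_counts)
    ref_major = ref.base if ref is not None else site.ref_base
    if (
        rna.base == site.ecc_base
        and site.ecc_fraction >= min_fraction
        and rna.fraction >= min_fraction
        and site.ecc_base != ref_major
        and rna.depth >= min_depth
    ):
        return ECC_SUPPORTED
    if rna.base == ref_major:
        return CHROMOSOMAL
    return AMBIGUOUS


def _sites_from_frame(pileup: pd.DataFrame) -> list[PileupSite]:
    sites = []
    for row in pileup.itertuples(index=False):
        sites.append(
            PileupSite(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_base=row.ref_base,
                ref_counts={b: int(getattr(row, f"ref_{b}", 0)) for b in BASES},
                ecc_base=row.ecc_base,
                ecc_fraction=float(getattr(row, "ecc_fraction", 1.0)),
                rna_counts={b: int(getattr(row, f"rna_{b}", 0)) for b in BASES},
                transcript=str(getattr(row, "gene_id", "")) or None,
            )
        )
    return sites


def classify_pileup(
    pileup: pd.DataFrame,
    min_depth: int = 10,
    min_fraction: float = 0.9,
) -> pd.DataFrame:
    """Classify every row of a pileup table.

    Expects columns chrom / pos / ref_base / ref_A..ref_T / ecc_base /
    ecc_fraction / rna_A..rna_T and optionally gene_id for transcript
    grouping. Returns the table with a ``site_class`` column appended.
    """
    sites = _sites_from_frame(pileup)
    out = pileup.copy()
    out["site_class"] = [classify_site(s, min_depth, min_fraction) for s in sites]
    return out


def scan_transcripts(
    classified: pd.DataFrame,
    group_col: str = "gene_id",
) -> pd.DataFrame:
    """Tabulate candidate eccDNA-templated transcripts.

    Informative sites are those where the eccDNA allele differs from the
    reference base (covered sites only); a transcript with >= 1
    eccDNA-supported site is a candidate. Candidates rank by supported
    site count descending (ties by transcript id).
    """
    if group_col not in classified.columns:
        raise ValueError(f"classified sites lack a {group_col!r} column")
    covered = classified[classified["site_class"] != NO_COVERAGE]
    informative = covered[covered["ecc_base"] != covered["ref_base"]]
    rows = []
    for transcript, grp in informative.groupby(group_col):
        supported = int((grp["site_class"] == ECC_SUPPORTED).sum())
        rows.append(
            {"transcript": transcript, "supported_sites": supported,
             "informative_sites": len(grp)}
        )
    df = pd.DataFrame(rows, columns=["transcript", "supported_sites", "informative_sites"])
    df = df[df["supported_sites"] >= 1]
    df = df.sort_values(
        ["supported_sites", "transcript"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df
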