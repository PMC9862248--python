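"""Readers, writers and structural validation for the plain-text formats
the pipeline exchanges between stages.

Conventions: FASTA via Biopython; BED is 0-based half-open; GFF3 is
1-based inclusive on disk (pyranges converts to 0-based starts on read);
tables are tab-separated with a header row.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
import pyranges
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str) -> list[tuple[str, str]]:
    """Read FASTA as a list of (id, upper-case sequence)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        path,
        "fasta",
    )


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file into columns chrom/start/end[/name/score/strand]."""
    df = pyranges.read_bed(path).df
    rename = {"Chromosome": "chrom", "Start": "start", "End": "end",
              "Name": "name", "Score": "score", "Strand": "strand"}
    df = df.rename(columns=rename)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(path: str, df: pd.DataFrame) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Read gene features from GFF3.

    Returns chrom / start / end (0-based half-open, as pyranges emits) /
    strand / gene_id.
    """
    df = pyranges.read_gff3(path).df
    df = df[df["Feature"] == "gene"].copy()
    gene_id = df["ID"] if "ID" in df.columns else df.index.astype(str)
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str),
            "gene_id": gene_id.astype(str),
        }
    )
    return out.reset_index(drop=True)


def write_gff3_genes(path: str, genes: pd.DataFrame, source: str = "circulome") -> None:
    """Write gene intervals (0-based half-open in memory) as GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id};Name={row.gene_id}\n"
            )


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(path: str, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts(path: str) -> pd.DataFrame:
    """Gene count matrix: first column gene id, one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# structural validation

_VALID_FASTA_ALPHABET = set("ACGTNacgtn")


def validate_formats(paths: dict[str, str]) -> list[str]:
    """Structural checks on pipeline inputs.

    ``paths`` maps a format tag (fasta / gff3 / bed / tsv) to a file path;
    a ``"<tag>:<label>"`` key form allows several files per format.
    Returns a list of line-numbered diagnostics; empty means clean.
    """
    diagnostics: list[str] = []
    for tag, path in paths.items():
        kind = tag.split(":")[0]
        if not os.path.exists(path):
            diagnostics.append(f"{path}: file not found")
            continue
        checker = {
            "fasta": _check_fasta,
            "gff3": _check_gff3,
            "bed": _check_bed,
            "tsv": _check_tsv,
        }.get(kind)
        if checker is None:
            diagnostics.append(f"{path}: unknown format tag '{kind}'")
            continue
        diagnostics.extend(f"{path}:{msg}" for msg in checker(path))
    return diagnostics


def _check_fasta(path: str) -> list[str]:
    out = []
    seen = False
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                seen = True
            elif not set(line) <= _VALID_FASTA_ALPHABET:
                bad = sorted(set(line) - _VALID_FASTA_ALPHABET)
                out.append(f"{i}: invalid sequence characters {bad}")
    if not seen:
        out.append("1: no FASTA header found")
    return out


def _check_bed(path: str) -> list[str]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                out.append(f"{i}: fewer than 3 columns")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                out.append(f"{i}: non-integer coordinates")
                continue
            if start < 0:
                out.append(f"{i}: negative start")
            if end < start:
                out.append(f"{i}: end < start")
    return out


def _check_gff3(path: str) -> list[str]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                out.append(f"{i}: expected 9 columns, found {len(fields)}")
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                out.append(f"{i}: non-integer coordinates")
                continue
            if start < 1:
                out.append(f"{i}: start < 1 violates 1-based GFF3 coordinates")
            if end < start:
                out.append(f"{i}: end < start")
    return out


def _check_tsv(path: str) -> list[str]:
    out = []
    ncols = None
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            n = len(line.rstrip("\n").split("\t"))
            if ncols is None:
                ncols = n
            elif n != ncols:
                out.append(f"{i}: ragged row ({n} columns, expected {ncols})")
    return out
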