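"""Confirm circular DNA from rolling-circle concatemer reads.

Rolling-circle amplification of an eccDNA template yields a long read that
is the circle repeated in tandem, usually ending mid-circle. This module
detects that tandem periodicity by seeded self-matching, splits the read
into monomers, calls a per-column majority consensus, and emits one
confirmed circle per read (or a machine-readable rejection).

Reads are processed independently: a single read either confirms one
circle (two or more full passes of agreeing sequence) or is rejected.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from ._seq import canonical_rotation, revcomp, seq_to_array

__all__ = [
    "ConcatemerRead",
    "EccRecord",
    "PeriodCall",
    "DeconcatParams",
    "Rejection",
    "detect_period",
    "split_monomers",
    "call_consensus",
    "deconcat_read",
    "deconcat_reads",
]

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ConcatemerRead:
    """One raw long read, possibly a rolling-circle concatemer."""

    read_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if not set(seq) <= _ALPHABET:
            bad = sorted(set(seq) - _ALPHABET)
            raise ValueError(f"read {self.read_id}: invalid characters {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EccRecord:
    """One confirmed circular DNA: consensus monomer in canonical rotation."""

    ecc_id: str
    sequence: str
    condition: str = "custom"
    monomer_support: int = 1
    source_read: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeriodCall:
    """Result of tandem-period detection on one read.

    ``period`` is None when no acceptable period exists; ``reason`` then
    explains why. ``identity`` is the self-match identity at the returned
    (or best rejected) shift.
    """

    period: Optional[int]
    passes: Optional[float]
    identity: float
    reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.period is not None


@dataclass(frozen=True)
class DeconcatParams:
    """Acceptance thresholds for circle confirmation.

    min_passes: full tandem passes required to call a circle. One pass
        cannot distinguish a circular from a linear template, so the
        default demands two.
    min_identity: self-match identity required at the detected period.
    min_length / max_length: admissible consensus lengths in bp.
    kmer: seed length for the self-match anchor scan on long reads.
    """

    min_passes: float = 2.0
    min_identity: float = 0.85
    min_length: int = 21
    max_length: int = 30_000
    kmer: int = 13


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


# ---------------------------------------------------------------------------
# period detection


def _shift_identity_hamming(arr: np.ndarray, d: int) -> float:
    """Exact-position self-match identity at shift d (no indel tolerance)."""
    if d <= 0 or d >= arr.size:
        return 0.0
    return float(np.mean(arr[d:] == arr[:-d]))


def _shift_identity_edlib(seq: str, d: int) -> float:
    """Alignment-based self-match identity at shift d (indel tolerant)."""
    overlap = len(seq) - d
    if overlap <= 0:
        return 0.0
    dist = edlib.align(seq[d:], seq[:-d], mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / overlap)


def _candidate_shifts_kmer(seq: str, min_period: int, max_period: int, k: int) -> list[int]:
    """Candidate periods from spacings of repeated k-mers, most-voted first."""
    votes: Counter[int] = Counter()
    last_pos: dict[str, int] = {}
    for i in range(0, len(seq) - k + 1):
        km = seq[i : i + k]
        prev = last_pos.get(km)
        if prev is not None:
            d = i - prev
            if min_period <= d <= max_period:
                votes[d] += 1
        last_pos[km] = i
    return [d for d, _ in votes.most_common(10)]


def detect_period(
    read: ConcatemerRead | str,
    min_period: int = 21,
    max_period: Optional[int] = None,
    min_identity: float = 0.85,
    k: int = 13,
) -> PeriodCall:
    """Detect the tandem repeat period of a concatemer read.

    A period ``p`` is accepted when the read aligns to itself shifted by
    ``p`` with identity >= ``min_identity`` over the overlap; among
    acceptable shifts the smallest is returned (period minimality), then
    refined +/-2 bp to the locally best shift. Returns a PeriodCall with
    ``period=None`` and a reason for aperiodic or too-short reads.
    """
    seq = read.sequence if isinstance(read, ConcatemerRead) else str(read).upper()
    L = len(seq)
    if L < 2 * min_period:
        return PeriodCall(None, None, 0.0, "insufficient length for two passes")
    if max_period is None:
        max_period = L - max(30, min_period)
    max_period = min(max_period, L - 1)
    if max_period < min_period:
        return PeriodCall(None, None, 0.0, "insufficient length for two passes")

    arr = seq_to_array(seq)
    if L <= 2000:
        # short read: exhaustive shift scan is cheap and exact
        idents = np.array(
            [_shift_identity_hamming(arr, d) for d in range(min_period, max_period + 1)]
        )
        order = np.argsort(idents)[::-1]
        passing = [min_period + int(i) for i in np.flatnonzero(idents >= min_identity - 0.10)]
        top = [min_period + int(i) for i in order[:5]]
        candidates = sorted(set(passing) | set(top))
    else:
        candidates = sorted(set(_candidate_shifts_kmer(seq, min_period, max_period, k)))

    best_seen = 0.0
    for d in candidates:
        ident = _shift_identity_edlib(seq, d)
        best_seen = max(best_seen, ident)
        if ident < min_identity:
            continue
        # refine to the locally best shift; ties prefer the smaller period
        lo, hi = max(min_period, d - 2), min(max_period, d + 2)
        scores = [(d2, _shift_identity_hamming(arr, d2)) for d2 in range(lo, hi + 1)]
        d_ref = max(scores, key=lambda t: (t[1], -t[0]))[0]
        ident_ref = _shift_identity_edlib(seq, d_ref)
        if ident_ref < ident:
            d_ref, ident_ref = d, ident
        return PeriodCall(d_ref, L / d_ref, ident_ref, None)
    return PeriodCall(None, None, best_seen, "no tandem periodicity detected")


# ---------------------------------------------------------------------------
# monomer splitting and consensus


def split_monomers(read: ConcatemerRead | str, period: int) -> tuple[list[str], Optional[str]]:
    """Cut a read into consecutive period-length monomers from phase 0.

    Returns (monomers, terminal_fragment); the terminal fragment (shorter
    than one period, possibly None) is kept separately and never counts
    toward monomer support.
    """
    seq = read.sequence if isinstance(read, ConcatemerRead) else str(read).upper()
    if period <= 0:
        raise ValueError(f"period must be positive, got {period}")
    monomers = [seq[i : i + period] for i in range(0, len(seq) - period + 1, period)]
    used = len(monomers) * period
    terminal = seq[used:] or None
    return monomers, terminal


_BASE_ORDER = np.frombuffer(b"ACGT", dtype=np.uint8)


def _best_rotation(monomer: str, reference: str) -> str:
    """Rotation of ``monomer`` best matching the reference prefix."""
    n = len(monomer)
    ref = seq_to_array(reference[:n])
    doubled = seq_to_array(monomer + monomer)
    best_r, best_score = 0, -1
    for r in range(n):
        score = int(np.sum(doubled[r : r + n] == ref))
        if score > best_score:
            best_r, best_score = r, score
    return monomer[best_r:] + monomer[:best_r]


def _vote_columns(votes: np.ndarray, ref_arr: np.ndarray, monomer: str) -> None:
    """Project one monomer's bases onto reference columns and add votes.

    Row layout: 0..3 = A/C/G/T, 4 = deletion relative to the reference.
    A monomer identical in length and content maps 1:1; otherwise an edit
    alignment (edlib) places each base, so an indel in one monomer cannot
    shift its remaining bases out of register.
    """
    arr = seq_to_array(monomer)
    if arr.size == ref_arr.size and np.mean(arr == ref_arr) >= 0.9:
        # gapless fast path: substitution-level divergence only
        for bi, base in enumerate(_BASE_ORDER):
            votes[bi, np.flatnonzero(arr == base)] += 1
        return
    ref = ref_arr.tobytes().decode("ascii")
    cigar = edlib.align(monomer, ref, mode="NW", task="path")["cigar"]
    qpos = tpos = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            seg = arr[qpos : qpos + n]
            cols = np.arange(tpos, tpos + n)
            for bi, base in enumerate(_BASE_ORDER):
                hit = seg == base
                votes[bi, cols[hit]] += 1
            qpos += n
            tpos += n
        elif ch == "I":  # present in monomer, absent from reference: no column
            qpos += n
        elif ch == "D":  # absent from monomer: vote for deleting the column
            votes[4, tpos : tpos + n] += 1
            tpos += n


def call_consensus(monomers: Sequence[str]) -> str:
    """Per-column majority consensus of monomer sequences.

    Monomers are stacked on the first monomer's columns (unequal lengths
    are first anchored to the longest monomer by best-overlap rotation);
    each monomer's bases are placed by edit alignment to the reference,
    which reduces to gapless stacking when monomers differ only by
    substitutions. Ties at a column break by fixed base order
    A < C < G < T; a column is dropped only when deletion votes beat the
    best base; columns with no A/C/G/T votes emit N.
    """
    monomers = [m.upper() for m in monomers if m]
    if not monomers:
        raise ValueError("call_consensus requires at least one monomer")
    if len(monomers) == 1:
        return monomers[0]
    lengths = {len(m) for m in monomers}
    if len(lengths) > 1:
        reference = max(monomers, key=len)
        monomers = [reference] + [
            _best_rotation(m, reference) for m in monomers if m is not reference
        ]
    ref_arr = seq_to_array(monomers[0])
    votes = np.zeros((5, ref_arr.size), dtype=np.int32)
    for m in monomers:
        _vote_columns(votes, ref_arr, m)
    best = np.argmax(votes[:4], axis=0)  # argmax -> first max: A<C<G<T
    best_count = np.take_along_axis(votes[:4], best[None, :], axis=0)[0]
    out = _BASE_ORDER[best].copy()
    out[best_count == 0] = ord("N")
    keep = votes[4] <= best_count  # deletion must strictly win to drop a column
    return out[keep].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# end-to-end per-read confirmation


def deconcat_read(
    read: ConcatemerRead,
    params: DeconcatParams = DeconcatParams(),
    condition: str = "custom",
) -> EccRecord | Rejection:
    """Confirm one circle from one read, or reject with a reason.

    The consensus is reported in canonical (lexicographically minimal)
    rotation so that re-reading the same circle at any phase yields a
    byte-identical record.
    """
    L = read.length
    if L < 2 * params.min_length:
        return Rejection(read.read_id, "insufficient length")
    call = detect_period(
        read,
        min_period=params.min_length,
        max_period=min(params.max_length, L - max(30, params.min_length)),
        min_identity=params.min_identity,
        k=params.kmer,
    )
    if not call.ok:
        return Rejection(read.read_id, call.reason or "no period")
    if call.passes < params.min_passes:
        return Rejection(read.read_id, "insufficient passes")
    monomers, _terminal = split_monomers(read, call.period)
    consensus = canonical_rotation(call_consensus(monomers))
    if not (params.min_length <= len(consensus) <= params.max_length):
        return Rejection(read.read_id, "length out of bounds")
    return EccRecord(
        ecc_id=f"ecc|{read.read_id}",
        sequence=consensus,
        condition=condition,
        monomer_support=int(math.floor(call.passes)),
        source_read=read.read_id,
    )


def deconcat_reads(
    reads: Iterable[ConcatemerRead],
    params: DeconcatParams = DeconcatParams(),
    condition: str = "custom",
) -> tuple[list[EccRecord], pd.DataFrame, pd.DataFrame]:
    """Run deconcatenation over a read set.

    Returns (confirmed records, rejections table, per-read metrics table
    with detected period / passes / identity).
    """
    records: list[EccRecord] = []
    rejections: list[dict] = []
    metrics: list[dict] = []
    for read in reads:
        call = detect_period(
            read,
            min_period=params.min_length,
            max_period=min(params.max_length, read.length - max(30, params.min_length)),
            min_identity=params.min_identity,
            k=params.kmer,
        ) if read.length >= 2 * params.min_length else PeriodCall(
            None, None, 0.0, "insufficient length for two passes"
        )
        metrics.append(
            {
                "read_id": read.read_id,
                "length": read.length,
                "period": call.period if call.ok else pd.NA,
                "passes": round(call.passes, 3) if call.ok else pd.NA,
                "identity": round(call.identity, 4),
            }
        )
        result = deconcat_read(read, params, condition)
        if isinstance(result, Rejection):
            rejections.append({"read_id": result.read_id, "reason": result.reason})
        else:
            records.append(result)
    rej_df = pd.DataFrame(rejections, columns=["read_id", "reason"])
    met_df = pd.DataFrame(metrics, columns=["read_id", "length", "period", "passes", "identity"])
    return records, rej_df, met_df
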