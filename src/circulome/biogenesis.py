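"""eccDNA biogenesis-site statistics over fixed genome windows.

Placed circles are binned into non-overlapping windows (default 500 kbp)
tiling each chromosome; per-window mapping counts are standardized to
Z-scores over the full window population (zero-count windows included),
hotspots are windows at or above a Z threshold, and hotspot repeat
architecture is characterized by an exact-match self-dotplot reporting
direct and inverted repeats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import revcomp

__all__ = [
    "tile_windows",
    "assign_windows",
    "window_zscores",
    "min_count_at_z",
    "call_hotspots",
    "HotspotResult",
    "self_dotplot",
]


def tile_windows(chrom_sizes: Mapping[str, int], window_size: int = 500_000) -> pd.DataFrame:
    """Non-overlapping windows exactly covering each chromosome.

    The terminal window of a chromosome may be shorter than
    ``window_size`` but still counts as a window.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        for i in range(math.ceil(size / window_size)):
            rows.append(
                {"chrom": chrom, "index": i, "start": i * window_size,
                 "end": min((i + 1) * window_size, size)}
            )
    return pd.DataFrame(rows, columns=["chrom", "index", "start", "end"])


def assign_windows(
    placements: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window_size: int = 500_000,
) -> pd.DataFrame:
    """Count eccDNA placements per window (leftmost-window rule).

    Each eccDNA has one primary placement and increments exactly one
    window: the window containing its placement start, which is the
    leftmost window it touches. Placements beyond chromosome bounds or on
    unknown chromosomes raise. Counts sum to the number of placements.
    """
    windows = tile_windows(chrom_sizes, window_size)
    counts = {(r.chrom, r.index): 0 for r in windows.itertuples(index=False)}
    for p in placements.itertuples(index=False):
        if p.chrom not in chrom_sizes:
            raise ValueError(f"placement {getattr(p, 'name', '?')!r}: unknown chromosome {p.chrom!r}")
        if p.start < 0 or p.end > chrom_sizes[p.chrom]:
            raise ValueError(
                f"placement {getattr(p, 'name', '?')!r} [{p.start}, {p.end}) exceeds "
                f"{p.chrom} length {chrom_sizes[p.chrom]}"
            )
        counts[(p.chrom, p.start // window_size)] += 1
    windows["count"] = [counts[(r.chrom, r.index)] for r in windows.itertuples(index=False)]
    return windows


def window_zscores(counts: np.ndarray | pd.Series) -> np.ndarray:
    """Standardize window counts: z = (count - mean) / population SD.

    Mean and SD run over ALL windows, zero-count windows included. A
    degenerate all-equal count vector yields all-zero Z with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("window_zscores requires at least 2 windows")
    mean = counts.mean()
    sd = counts.std()  # population SD (ddof=0): windows are the full bin population
    if sd == 0:
        warnings.warn("all windows have equal counts; Z-scores undefined, returning zeros")
        return np.zeros_like(counts)
    return (counts - mean) / sd


def min_count_at_z(mean: float, sd: float, z: float = 2.0) -> int:
    """Smallest integer count whose Z-score meets the threshold."""
    return int(math.ceil(mean + z * sd))


@dataclass
class HotspotResult:
    stats: pd.DataFrame  # all windows with count and z
    hotspots: pd.DataFrame  # z >= z_min, ranked by count desc
    top: pd.DataFrame  # top_n by count regardless of z
    n_zero_windows: int
    mean: float
    sd: float


def call_hotspots(
    window_counts: pd.DataFrame,
    z_min: float = 2.0,
    top_n: int = 10,
) -> HotspotResult:
    """Call hotspot windows from the output of :func:`assign_windows`.

    Hotspots are windows with Z >= ``z_min``, ranked by count descending
    (ties by chromosome then window index). Also reports the ``top_n``
    most-mapped windows and the count of windows with no eccDNA at all.
    """
    stats = window_counts.copy()
    stats["z"] = window_zscores(stats["count"].to_numpy())
    order = stats.sort_values(
        ["count", "chrom", "index"], ascending=[False, True, True]
    ).reset_index(drop=True)
    hotspots = order[order["z"] >= z_min].reset_index(drop=True)
    counts = stats["count"].to_numpy(dtype=float)
    return HotspotResult(
        stats=stats,
        hotspots=hotspots,
        top=order.head(top_n).reset_index(drop=True),
        n_zero_windows=int((stats["count"] == 0).sum()),
        mean=float(counts.mean()),
        sd=float(counts.std()),
    )


# ---------------------------------------------------------------------------
# self-dotplot


def self_dotplot(region_seq: str, k: int = 15, max_kmer_occurrences: int = 64) -> pd.DataFrame:
    """Exact k-mer self-alignment of a region: direct and inverted repeats.

    Direct matches are maximal chains of shared k-mers on the
    forward x forward comparison off the main diagonal; inverted matches
    chain forward k-mers against the reverse complement. Returns
    x_start/x_end/y_start/y_end/orientation/length sorted by length
    descending. ``k`` below 8 is refused (spurious-match guard); k-mers
    occurring more than ``max_kmer_occurrences`` times are skipped to
    bound the pair count in low-complexity regions.
    """
    if k < 8:
        raise ValueError(f"k must be >= 8 to avoid spurious matches, got {k}")
    seq = region_seq.upper()
    n = len(seq)
    if n < k:
        raise ValueError("region shorter than k")

    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)

    # direct: pairs (i, j), i < j, grouped by diagonal j - i
    diag_pairs: dict[int, list[int]] = {}
    for plist in positions.values():
        if len(plist) > max_kmer_occurrences:
            continue
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                d = plist[b] - plist[a]
                diag_pairs.setdefault(d, []).append(plist[a])

    rows = []
    for d, starts in diag_pairs.items():
        for i0, i1 in _maximal_runs(sorted(set(starts))):
            length = i1 - i0 + k
            rows.append(
                {"x_start": i0, "x_end": i0 + length, "y_start": i0 + d,
                 "y_end": i0 + d + length, "orientation": "direct", "length": length}
            )

    # inverted: k-mer at i matches revcomp of k-mer at j -> antidiagonal i + j
    anti_pairs: dict[int, list[int]] = {}
    for kmer, plist in positions.items():
        if len(plist) > max_kmer_occurrences:
            continue
        rc = revcomp(kmer)
        if rc not in positions or len(positions[rc]) > max_kmer_occurrences:
            continue
        for i in plist:
            for j in positions[rc]:
                if j <= i:  # keep one orientation of the symmetric pair
                    continue
                anti_pairs.setdefault(i + j, []).append(i)
    for s, starts in anti_pairs.items():
        for i0, i1 in _maximal_runs(sorted(set(starts))):
            length = i1 - i0 + k
            j_last = s - i1  # y interval runs backwards as x advances
            rows.append(
                {"x_start": i0, "x_end": i0 + length, "y_start": j_last,
                 "y_end": j_last + length, "orientation": "inverted", "length": length}
            )

    df = pd.DataFrame(
        rows, columns=["x_start", "x_end", "y_start", "y_end", "orientation", "length"]
    )
    return df.sort_values(["length", "x_start"], ascending=[False, True]).reset_index(drop=True)


def _maximal_runs(sorted_starts: list[int]) -> list[tuple[int, int]]:
    """Collapse sorted k-mer start positions into maximal contiguous runs."""
    runs = []
    lo = prev = sorted_starts[0]
    for x in sorted_starts[1:]:
        if x == prev + 1:
            prev = x
        else:
            runs.append((lo, prev))
            lo = prev = x
    runs.append((lo, prev))
    return runs
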