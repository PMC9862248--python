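"""Low-level sequence helpers shared across the package.

Sequences are plain upper-case strings over {A, C, G, T, N}. Numpy byte
arrays are used internally where columnwise arithmetic is needed.
"""

from __future__ import annotations

import zlib

import edlib
import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    return gc / len(s) if s else 0.0


def hamming_identity(a: str, b: str) -> float:
    """Fraction of equal positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    if not a:
        raise ValueError("empty sequence")
    return float(np.mean(seq_to_array(a) == seq_to_array(b)))


def least_rotation(s: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm), O(n)."""
    if not s:
        return s
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]


def canonical_rotation(s: str) -> str:
    """Canonical form of a circular sequence: minimal rotation."""
    return least_rotation(s.upper())


def rotate(s: str, phase: int) -> str:
    """Rotate a circular sequence so it starts at ``phase``."""
    phase %= len(s)
    return s[phase:] + s[:phase]


def circular_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Identity between two circular sequences.

    The shorter sequence is aligned (edit distance, edlib) against the
    doubled longer sequence in infix mode, which scores every rotation;
    identity is matched fraction of the shorter sequence's length. With
    ``both_strands`` the reverse complement of the shorter sequence is
    also tried and the better strand wins.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)

    def one_way(query: str, subject: str) -> int:
        target = subject + subject
        d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
        if both_strands:
            d_rc = edlib.align(revcomp(query), target, mode="HW", task="distance")[
                "editDistance"
            ]
            d = min(d, d_rc)
        return d

    best = one_way(short, long_)
    if len(short) == len(long_):
        # gapped alignment against a doubled target is not symmetric in
        # its arguments; for equal lengths take the better direction so
        # identity(a, b) == identity(b, a)
        best = min(best, one_way(long_, short))
    return max(0.0, (len(short) - best) / len(short))


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named child generator: one master seed, one stream per sub-task.

    Adding a new named stream never perturbs existing ones, and streams
    are stable across platforms (crc32 of the name, not ``hash``).
    """
    child = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, child]))
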