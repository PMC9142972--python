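"""Shared sequence utilities: alphabet handling, encoding, approximate search.

All pipeline stages compare sequences in DNA space (``ACGT``) and report
miRNA sequences in RNA space (``ACGU``); these helpers centralise the
conversions plus the small numeric primitives used by several modules.
Internal coordinates are 0-based half-open; reports are 1-based inclusive.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

#: fixed byte codes for A/C/G/T used by the vectorised window scans
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def to_dna(seq: str) -> str:
    """Uppercase and rewrite U->T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and rewrite T->U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content as a percentage of sequence length."""
    s = to_dna(seq)
    if not s:
        return 0.0
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0 C=1 G=2 T=3, other=255)."""
    return _ENC[np.frombuffer(to_dna(seq).encode(), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def approx_occurrences(pattern: str, text: str, max_mismatch: int) -> list[int]:
    """All 0-based start positions where *pattern* occurs in *text* as a
    full-length substring with at most ``max_mismatch`` substitutions.

    Vectorised over every window of ``text``; suitable for scanning a few
    short patterns against megabase-scale transcript sets.
    """
    m, n = len(pattern), len(text)
    if m == 0 or n < m:
        return []
    t = encode(text)
    p = encode(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mm = (windows != p).sum(axis=1)
    return np.flatnonzero(mm <= max_mismatch).tolist()


class ApproxMembershipIndex:
    """Seed-and-verify index answering "does this read occur inside any of
    these sequences (either strand) with at most k substitutions?".

    Pigeonhole seeding: with ``max_mismatch`` substitutions, a read of
    length L split into ``max_mismatch + 1`` disjoint seeds of length
    ``L // (max_mismatch + 1)`` must contain at least one exact seed, so
    every true occurrence is recovered by exact seed lookup plus
    verification.  Used for blacklist screening of collapsed reads.
    """

    def __init__(self, sequences: dict[str, str], seed_len: int = 9):
        self.seed_len = seed_len
        self._seqs: list[tuple[str, str]] = []
        self._index: dict[str, list[tuple[int, int]]] = {}
        for name, seq in sequences.items():
            for label, s in ((name, to_dna(seq)), (name + "/rc", revcomp(seq))):
                sid = len(self._seqs)
                self._seqs.append((label, s))
                for pos in range(len(s) - seed_len + 1):
                    self._index.setdefault(s[pos : pos + seed_len], []).append((sid, pos))

    def find(self, read: str, max_mismatch: int = 1) -> tuple[str, int] | None:
        """Return ``(sequence name, 0-based position)`` of one occurrence of
        *read* with <= max_mismatch substitutions, or None."""
        read = to_dna(read)
        k = self.seed_len
        n_seeds = max_mismatch + 1
        if len(read) < k * n_seeds:
            # read too short for pigeonhole at this seed length: fall back
            # to exhaustive scan (rare; reads are >= 18 nt in the pipeline)
            for label, s in self._seqs:
                for pos in range(len(s) - len(read) + 1):
                    if hamming(read, s[pos : pos + len(read)]) <= max_mismatch:
                        return label, pos
            return None
        seen: set[tuple[int, int]] = set()
        for i in range(n_seeds):
            off = i * k
            for sid, pos in self._index.get(read[off : off + k], ()):
                start = pos - off
                cand = (sid, start)
                if start < 0 or cand in seen:
                    continue
                seen.add(cand)
                label, s = self._seqs[sid]
                if start + len(read) > len(s):
                    continue
                if hamming(read, s[start : start + len(read)]) <= max_mismatch:
                    return label, start
        return None

    def __contains__(self, read: str) -> bool:
        return self.find(read) is not None
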