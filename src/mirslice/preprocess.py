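"""Read preprocessing: adapter removal, 3' quality trimming, length
selection, collapsing identical reads across libraries, and per-library
length/complexity profiles.

The stage mirrors a standard small-RNA cleanup: 3' adapter ligation means
every informative read is ``insert + adapter[ + filler]``; the insert is
recovered by locating the leftmost adapter prefix.  Quality trimming uses
a mean-Phred sliding window (threshold 15, window 6 by default).  Retained
inserts are 18-28 nt, the size range containing plant miRNAs (21 nt) and
heterochromatic siRNAs (24 nt).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable, Sequence

from .types import CollapsedRead, LibraryProfile


def trim_adapter(seq: str, qual: str, adapter: str, min_overlap: int = 8) -> tuple[str, str] | None:
    """Remove the leftmost adapter occurrence and everything 3' of it.

    A hit is an exact occurrence of a >= ``min_overlap``-nt adapter
    prefix anywhere in the read (the usual case when the insert plus
    adapter overruns the read length), or the full adapter with one
    mismatch tolerated (adapters >= 12 nt).  Restricting mismatch
    tolerance to full-length matches keeps trimming idempotent: once the
    leftmost hit is removed, the remainder can contain no hit.  Returns
    the trimmed ``(sequence, qualities)``, the input unchanged when no
    adapter is found, or ``None`` when nothing remains 5' of the adapter.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    n, m = len(seq), len(adapter)
    prefix = adapter[:min_overlap]
    best = None
    for start in range(n - min_overlap + 1):
        if seq[start : start + min_overlap] == prefix:
            best = start
            break
        if n - start >= m:
            allowed = 1 if m >= 12 else 0
            mm = 0
            for a, b in zip(seq[start : start + m], adapter):
                if a != b:
                    mm += 1
                    if mm > allowed:
                        break
            else:
                best = start
                break
    if best is None:
        return seq, qual
    if best == 0:
        return None
    return seq[:best], qual[:best]


def quality_trim(seq: str, qual: str, threshold: int = 15, window: int = 6) -> tuple[str, str]:
    """Truncate the read so the retained 5' prefix contains no length-
    ``window`` stretch whose mean Phred quality falls below ``threshold``.

    Scans windows from the 3' end toward the 5' end, cutting at each
    failing window; a single backward pass reaches the fixed point, which
    makes the operation idempotent.  Reads shorter than the window are
    kept iff their overall mean quality passes the threshold.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    phred = [ord(c) - 33 for c in qual]
    if len(seq) < window:
        if seq and sum(phred) / len(phred) < threshold:
            return "", ""
        return seq, qual
    cut = len(seq)
    for start in range(len(seq) - window, -1, -1):
        if start + window > cut:
            continue
        if sum(phred[start : start + window]) / window < threshold:
            cut = start
    if 0 < cut < window and sum(phred[:cut]) / cut < threshold:
        cut = 0  # sub-window remnant held to the same mean rule
    return seq[:cut], qual[:cut]


def length_filter(reads: Iterable[str], min_len: int = 18, max_len: int = 28) -> list[str]:
    """Keep reads with ``min_len <= length <= max_len`` (defaults keep the
    18-28 nt small-RNA window; 29-nt and longer reads are discarded)."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    return [r for r in reads if min_len <= len(r) <= max_len]


def clean_library(
    reads: Iterable[tuple[str, str, str]],
    adapter: str,
    min_len: int = 18,
    max_len: int = 28,
    quality_threshold: int = 15,
    quality_window: int = 6,
) -> list[str]:
    """Full per-library cleanup: adapter trim -> quality trim -> length
    selection.  Input is ``(id, sequence, quality)`` triplets; output is the
    clean insert sequences."""
    out = []
    for _name, seq, qual in reads:
        trimmed = trim_adapter(seq, qual, adapter)
        if trimmed is None:
            continue
        s, q = quality_trim(*trimmed, threshold=quality_threshold, window=quality_window)
        if min_len <= len(s) <= max_len:
            out.append(s)
    return out


def collapse(per_library_reads: dict[str, Sequence[str]]) -> list[CollapsedRead]:
    """Collapse identical sequences across libraries into one record each,
    preserving per-library counts.  Library order follows the input dict;
    records are sorted by descending total then sequence for determinism."""
    libs = list(per_library_reads)
    counts: dict[str, list[int]] = defaultdict(lambda: [0] * len(libs))
    for i, lib in enumerate(libs):
        for seq in per_library_reads[lib]:
            counts[seq][i] += 1
    records = [CollapsedRead(seq, tuple(c)) for seq, c in counts.items()]
    records.sort(key=lambda r: (-r.total, r.sequence))
    return records


def profile_library(reads: Sequence[str], library: str = "") -> LibraryProfile:
    """Length profile of one clean library.

    ``rpm`` is reads of that length per million clean reads;
    ``complexity_index(L)`` is distinct sequences of length L divided by
    total reads of length L (1.0 = every read unique, ->0 = redundant).
    """
    redundant = Counter(len(r) for r in reads)
    nonredundant = Counter(len(s) for s in set(reads))
    total = len(reads)
    rpm = {L: 1e6 * c / total for L, c in redundant.items()} if total else {}
    complexity = {L: nonredundant[L] / redundant[L] for L in redundant}
    return LibraryProfile(
        library=library,
        redundant_counts=dict(sorted(redundant.items())),
        nonredundant_counts=dict(sorted(nonredundant.items())),
        rpm=dict(sorted(rpm.items())),
        complexity_index=dict(sorted(complexity.items())),
        total_reads=total,
    )
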