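"""Known-miRNA annotation by homology to a reference mature set.

Collapsed reads are compared to reference matures by ungapped sliding
alignment: a hit needs an overlap of at least 18 nt with at most 2
substitutions (the 89.9%-identity / 18-nt-minimum setting of the study's
aligner), the best hit has the fewest mismatches, tie-broken by longest
overlap and then lexicographically smallest reference name.  Annotated
reads are then kept only when expressed with >= 5 reads in >= 3 of the 4
libraries, which is the multi-library support rule that controls false
positives when libraries are treated as biological replicates.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Sequence

from .types import CollapsedRead, MiRNAAnnotation
from .util import to_dna

_FAMILY_RE = re.compile(
    r"^(?:[a-z]{3,4}-)?"          # optional species prefix, e.g. osa-
    r"(mir|miR|MIR)(\d+)",        # family stem + number
)


class ReferenceIndex:
    """Exact-seed index over a reference mature set for fast best-hit
    lookup.  Seeding is sound for the default thresholds: an 18-nt overlap
    with <= 2 substitutions always contains an exact 6-mer aligned between
    read and reference (pigeonhole), so exact 6-mer lookups enumerate a
    superset of the true candidate (reference, offset) diagonals, which are
    then verified exactly."""

    seed_len = 6

    def __init__(self, reference: dict[str, str]):
        if not reference:
            raise ValueError("empty reference set")
        self.names = sorted(reference)
        self.seqs = {name: to_dna(reference[name]) for name in self.names}
        self._index: dict[str, list[tuple[str, int]]] = {}
        k = self.seed_len
        for name in self.names:
            seq = self.seqs[name]
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((name, pos))

    def candidate_diagonals(self, read: str) -> set[tuple[str, int]]:
        """(reference name, read_offset_minus_ref_offset) pairs worth
        verifying.  Offset is the read position minus the reference position
        of the aligned seed."""
        k = self.seed_len
        out: set[tuple[str, int]] = set()
        for q in range(len(read) - k + 1):
            for name, p in self._index.get(read[q : q + k], ()):
                out.add((name, q - p))
        return out


def _overlap_mismatches(read: str, ref: str, offset: int) -> tuple[int, int]:
    """Overlap length and substitution count for an ungapped alignment in
    which read position ``offset + i`` faces reference position ``i``."""
    start_r = max(0, offset)
    end_r = min(len(read), offset + len(ref))
    overlap = end_r - start_r
    if overlap <= 0:
        return 0, 0
    mm = 0
    for i in range(start_r, end_r):
        if read[i] != ref[i - offset]:
            mm += 1
    return overlap, mm


def align_to_reference(
    read: str | CollapsedRead,
    reference: dict[str, str] | ReferenceIndex,
    max_mismatch: int = 2,
    min_len: int = 18,
) -> MiRNAAnnotation | None:
    """Best ungapped assignment of a read to a reference mature, or None.

    Both sequences are compared in DNA space (U/T normalised).  The search
    is deterministic: fewest mismatches, then longest overlap, then
    lexicographically smallest reference name.
    """
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    seq = to_dna(read.sequence if isinstance(read, CollapsedRead) else read)
    # Seeding is sound when a minimal hit must contain an exact 6-mer;
    # otherwise (permissive thresholds) enumerate every diagonal.
    guaranteed_run = -(-(min_len - max_mismatch) // (max_mismatch + 1))
    if guaranteed_run >= index.seed_len:
        diagonals: Iterable[tuple[str, int]] = index.candidate_diagonals(seq)
    else:
        diagonals = (
            (name, off)
            for name in index.names
            for off in range(min_len - len(index.seqs[name]), len(seq) - min_len + 1)
        )
    best: tuple[int, int, str] | None = None  # (mismatches, -overlap, name)
    for name, offset in diagonals:
        ref = index.seqs[name]
        overlap, mm = _overlap_mismatches(seq, ref, offset)
        if overlap < min_len or mm > max_mismatch:
            continue
        key = (mm, -overlap, name)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    mm, neg_overlap, name = best
    counts = read.counts if isinstance(read, CollapsedRead) else ()
    return MiRNAAnnotation(
        sequence=seq,
        ref_name=name,
        family=assign_family(name),
        mismatches=mm,
        overlap=-neg_overlap,
        counts=tuple(counts),
    )


def annotate_reads(
    reads: Sequence[CollapsedRead],
    reference: dict[str, str],
    max_mismatch: int = 2,
    min_len: int = 18,
) -> tuple[list[MiRNAAnnotation], list[CollapsedRead]]:
    """Annotate every collapsed read; returns (annotations, unannotated
    reads).  Unannotated reads are the input to novel-miRNA discovery."""
    index = ReferenceIndex(reference)
    annotated, leftover = [], []
    for rec in reads:
        hit = align_to_reference(rec, index, max_mismatch=max_mismatch, min_len=min_len)
        if hit is None:
            leftover.append(rec)
        else:
            annotated.append(hit)
    return annotated, leftover


def library_support_filter(
    annotations: Iterable[MiRNAAnnotation],
    min_libraries: int = 3,
    min_reads: int = 5,
) -> list[MiRNAAnnotation]:
    """Retain annotations expressed with >= min_reads in >= min_libraries
    libraries; fills ``supporting_library_count``."""
    kept = []
    for a in annotations:
        support = sum(c >= min_reads for c in a.counts)
        a.supporting_library_count = support
        if support >= min_libraries:
            kept.append(a)
    return kept


def assign_family(name: str) -> str:
    """Canonical family of a miRBase-style name: strip the species prefix,
    the letter/number variant and the arm suffix -> ``miR<number>``.
    Unparseable names are returned whole (with a warning)."""
    m = _FAMILY_RE.match(name)
    if m is None:
        warnings.warn(f"cannot parse miRNA family from {name!r}", stacklevel=2)
        return name
    return "miR" + m.group(2)


def compute_tpm(count: int, library_total_clean: int) -> float:
    """Transcripts per million: reads of this sequence per million clean
    reads of the library."""
    if library_total_clean <= 0:
        raise ValueError("library total must be positive")
    return 1e6 * count / library_total_clean


def attach_tpm(annotations: Iterable[MiRNAAnnotation], library_totals: Sequence[int]) -> None:
    """Fill per-library TPM on each annotation, in place."""
    for a in annotations:
        a.tpm = tuple(
            compute_tpm(c, t) if t > 0 else 0.0 for c, t in zip(a.counts, library_totals)
        )
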