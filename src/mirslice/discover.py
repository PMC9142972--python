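"""Novel miRNA candidate discovery from reads unassigned by homology.

Stages: (1) remove reads matching blacklisted non-miRNA classes (rRNA,
tRNA, snoRNA, chloroplast) by approximate substring membership on either
strand; (2) size-select (default: shorter than 24 nt, keeping the
21-22 nt miRNA range and excluding 24-nt heterochromatic siRNAs);
(3) greedy CD-HIT-style clustering (word size 5, 85% identity over the
shorter read) to fold isomiR redundancy; (4) require cluster-summed
expression in at least 3 libraries with at least 5 reads, then demand a
valid hairpin precursor in the transcriptome.  A candidate whose predicted
star sequence is itself observed in the collapsed reads is promoted to the
"high-confidence" tier, matching current plant-miRNA annotation criteria
(star evidence is the strongest sign of genuine Dicer processing).
"""

from __future__ import annotations

import warnings
from typing import Sequence

from .annotate import library_support_filter
from .fold import FoldingEngine
from .precursor import extract_and_validate, find_pri_locations, identify_star
from .types import CollapsedRead, MiRNAAnnotation, NovelCandidate
from .util import ApproxMembershipIndex


def blacklist_filter(
    reads: Sequence[CollapsedRead],
    blacklists: dict[str, str],
    max_mismatch: int = 1,
) -> list[CollapsedRead]:
    """Drop reads occurring within any blacklist sequence (either strand)
    with at most ``max_mismatch`` substitutions.  An empty blacklist set
    passes everything through with a warning."""
    if not blacklists:
        warnings.warn("empty blacklist set: no contaminant screening applied", stacklevel=2)
        return list(reads)
    index = ApproxMembershipIndex(blacklists)
    return [r for r in reads if index.find(r.sequence, max_mismatch) is None]


def size_select(
    reads: Sequence[CollapsedRead],
    max_len_exclusive: int = 24,
    min_len: int = 18,
) -> list[CollapsedRead]:
    """Keep reads with ``min_len <= length < max_len_exclusive`` (the
    discovery stage excludes 24-nt reads, unlike the known-miRNA stage)."""
    return [r for r in reads if min_len <= len(r.sequence) < max_len_exclusive]


class Cluster:
    def __init__(self, representative: CollapsedRead):
        self.representative = representative
        self.members: list[CollapsedRead] = [representative]
        self._words = _words(representative.sequence)

    @property
    def counts(self) -> tuple[int, ...]:
        n = len(self.representative.counts)
        out = [0] * n
        for m in self.members:
            for i, c in enumerate(m.counts):
                out[i] += c
        return tuple(out)


def _words(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _identity(short: str, long: str) -> float:
    """Best ungapped identity of the shorter sequence over its full length
    at any offset within the longer sequence."""
    best = 0
    for off in range(len(long) - len(short) + 1):
        matches = sum(a == b for a, b in zip(short, long[off : off + len(short)]))
        best = max(best, matches)
    return best / len(short) if short else 0.0


def cluster_reads(
    reads: Sequence[CollapsedRead],
    identity: float = 0.85,
    word: int = 5,
) -> list[Cluster]:
    """Greedy incremental clustering in CD-HIT's longest-first style.

    Reads sorted by length (desc), abundance (desc), then sequence; each
    read joins the first existing cluster whose representative shares at
    least one length-``word`` substring and aligns ungapped (full overlap
    of the shorter read) at >= ``identity``; otherwise it founds a new
    cluster.  Deterministic given the sort order.
    """
    ordered = sorted(reads, key=lambda r: (-len(r.sequence), -r.total, r.sequence))
    clusters: list[Cluster] = []
    word_map: dict[str, list[int]] = {}
    for rec in ordered:
        seq = rec.sequence
        candidates: set[int] = set()
        for w in _words(seq, word):
            candidates.update(word_map.get(w, ()))
        joined = False
        for ci in sorted(candidates):
            rep = clusters[ci].representative.sequence
            short, long_ = (seq, rep) if len(seq) <= len(rep) else (rep, seq)
            if _identity(short, long_) >= identity:
                clusters[ci].members.append(rec)
                joined = True
                break
        if not joined:
            ci = len(clusters)
            clusters.append(Cluster(rec))
            for w in _words(seq, word):
                word_map.setdefault(w, []).append(ci)
    return clusters


def validate_candidates(
    clusters: Sequence[Cluster],
    transcriptome: dict[str, str],
    collapsed_reads: Sequence[CollapsedRead],
    engine: FoldingEngine,
    min_libraries: int = 3,
    min_reads: int = 5,
    max_mismatch: int = 2,
    **precursor_kwargs,
) -> list[NovelCandidate]:
    """Validate supported clusters as novel miRNA candidates.

    The cluster representative must locate in the transcriptome and yield
    a valid hairpin precursor; candidates resolving to the same precursor
    interval are merged (first kept).  Tier is "high-confidence" when the
    predicted star is observed among the collapsed reads at any count.
    """
    totals = {r.sequence: r.total for r in collapsed_reads}
    observed = set(totals)
    # reuse the annotation-stage support rule on cluster-summed counts
    supported = []
    for cl in clusters:
        proxy = MiRNAAnnotation(
            sequence=cl.representative.sequence, ref_name="", family="",
            mismatches=0, overlap=0, counts=cl.counts,
        )
        if library_support_filter([proxy], min_libraries, min_reads):
            supported.append(cl)
    candidates: list[NovelCandidate] = []
    seen_intervals: set[tuple[str, int, int]] = set()
    for cl in supported:
        rep = cl.representative.sequence
        best = None
        for loc in find_pri_locations(rep, transcriptome, max_mismatch=max_mismatch):
            rec = extract_and_validate(
                loc.transcript_id, transcriptome[loc.transcript_id],
                (loc.start, loc.end), engine, **precursor_kwargs,
            )
            if rec is None:
                continue
            rec = identify_star(rec, totals)
            if best is None or rec.mfei < best.mfei:
                best = rec
        if best is None:
            continue
        key = (best.transcript_id, best.start, best.end)
        if key in seen_intervals:
            continue
        seen_intervals.add(key)
        star_seen = best.star_sequence is not None and best.star_sequence in observed
        candidates.append(
            NovelCandidate(
                representative=rep,
                members=tuple(m.sequence for m in cl.members),
                counts=cl.counts,
                precursor=best,
                star_observed=star_seen,
                tier="high-confidence" if star_seen else "candidate",
            )
        )
    return candidates
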