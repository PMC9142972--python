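"""Hairpin precursor location, validation and polycistronic clusters.

Without a genome, pri-miRNAs are searched directly in the assembled
transcriptome: every full-length occurrence of a mature sequence with at
most two substitutions (either strand) is a potential hairpin host.
Around each occurrence, candidate precursor windows of 60-300 nt are
folded and accepted when they look like a canonical plant pre-miRNA:

(a) the mature sits on one arm of a stem-loop (it does not span the
    terminal loop),
(b) at most 4 mature bases are unpaired,
(c) no bulge larger than 3 nt inside the mature:star duplex,
(d) MFEI <= -0.85 (the empirical boundary separating miRNA hairpins from
    tRNA/rRNA/mRNA folds),
(e) precursor length <= 300 nt.

Among accepted windows the minimal-MFEI (then shortest) one is returned.
The star strand is read off the dot-bracket pair table with the canonical
2-nt 3' overhang geometry, and of the two duplex strands the one with the
lower summed read count keeps the "star" label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .fold import FoldingEngine, pair_table
from .types import CollapsedRead, PrecursorRecord
from .util import approx_occurrences, gc_percent, revcomp, to_dna

DEFAULT_WINDOWS = tuple(range(60, 301, 20))


@dataclass(frozen=True)
class PriLocation:
    transcript_id: str
    start: int          # 0-based half-open, transcript orientation
    end: int
    orientation: str    # "+" if the mature matches the transcript as given
    mismatches: int


def find_pri_locations(
    mature: str,
    transcriptome: dict[str, str],
    max_mismatch: int = 2,
) -> list[PriLocation]:
    """All full-length occurrences of a mature sequence in the
    transcriptome, allowing substitutions, on both the given strand and
    its reverse complement (assembled transcripts may be antisense).
    Intervals are reported on the transcript's stated orientation."""
    mat = to_dna(mature)
    rc = revcomp(mat)
    hits = []
    for tid, seq in transcriptome.items():
        for pat, orient in ((mat, "+"), (rc, "-")):
            for pos in approx_occurrences(pat, seq, max_mismatch):
                window = seq[pos : pos + len(pat)]
                mm = sum(a != b for a, b in zip(window, pat))
                hits.append(PriLocation(tid, pos, pos + len(pat), orient, mm))
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.orientation))
    return hits


def compute_amfe_mfei(mfe: float, length: int, gc_pct: float) -> tuple[float, float]:
    """AMFE = MFE per 100 nt; MFEI = AMFE / GC%.

    Both are negative for any structured RNA; MFEI below about -0.85
    separates miRNA hairpins from tRNA (-0.64), rRNA (-0.59) and mRNA
    (+0.62..0.66) folds."""
    if length <= 0:
        raise ValueError("length must be positive")
    if mfe == 0:
        return 0.0, 0.0
    if gc_pct <= 0:
        raise ValueError("GC percentage must be positive")
    amfe = mfe / length * 100.0
    return amfe, amfe / gc_pct


def _mature_arm(structure: str, ms: int, me: int) -> str | None:
    """Arm of the mature in the hairpin, or None when paired mature bases
    fall on both sides (mature spans the terminal loop)."""
    pt = pair_table(structure)
    partners = [pt[i] for i in range(ms, me) if pt[i] >= 0]
    if not partners:
        return None
    if all(p >= me for p in partners):
        return "5p"
    if all(p < ms for p in partners):
        return "3p"
    return None


def _max_duplex_bulge(structure: str, ms: int, me: int) -> int:
    """Largest asymmetric interruption between consecutive paired mature
    bases, measured on both duplex strands."""
    pt = pair_table(structure)
    paired = [i for i in range(ms, me) if pt[i] >= 0]
    worst = 0
    for a, b in zip(paired, paired[1:]):
        gap_m = b - a - 1
        gap_s = abs(pt[a] - pt[b]) - 1
        worst = max(worst, gap_m, gap_s)
    return worst


def extract_and_validate(
    transcript_id: str,
    transcript: str,
    mature_interval: tuple[int, int],
    engine: FoldingEngine,
    windows: Sequence[int] = DEFAULT_WINDOWS,
    mfei_threshold: float = -0.85,
    max_unpaired_mature: int = 4,
    max_bulge: int = 3,
    max_length: int = 300,
    flank: int = 10,
) -> PrecursorRecord | None:
    """Fold candidate windows around a located mature and return the best
    accepted precursor (minimal MFEI, then shortest), or None.

    For each window size two placements are tried, putting the mature near
    the window's 5' end (5p arm) or near its 3' end (3p arm), offset by
    ``flank`` nt of context.
    """
    seq = to_dna(transcript)
    ms, me = mature_interval
    if not (0 <= ms < me <= len(seq)):
        raise ValueError("mature interval outside transcript")
    accepted: list[PrecursorRecord] = []
    seen_windows: set[tuple[int, int]] = set()
    for w in windows:
        if w > max_length or w < (me - ms):
            continue
        starts = (ms - flank, me + flank - w)
        for start in starts:
            start = max(0, min(start, len(seq) - w))
            end = start + w
            if end > len(seq) or (start, end) in seen_windows:
                continue
            if not (start <= ms and me <= end):
                continue
            seen_windows.add((start, end))
            sub = seq[start:end]
            structure, mfe = engine.fold(sub)
            rec = _validate_window(
                transcript_id, sub, structure, mfe, start, end, ms - start, me - start,
                mfei_threshold, max_unpaired_mature, max_bulge,
            )
            if rec is None:
                continue
            trimmed = _trim_to_hairpin(rec, engine, mfei_threshold,
                                       max_unpaired_mature, max_bulge)
            accepted.append(trimmed if trimmed is not None else rec)
    if not accepted:
        return None
    accepted.sort(key=lambda r: (r.mfei, r.length, r.start))
    return accepted[0]


def _validate_window(
    tid: str,
    sub: str,
    structure: str,
    mfe: float,
    start: int,
    end: int,
    ms: int,
    me: int,
    mfei_threshold: float,
    max_unpaired_mature: int,
    max_bulge: int,
) -> PrecursorRecord | None:
    reasons = []
    pt = pair_table(structure)
    unpaired = sum(1 for i in range(ms, me) if pt[i] < 0)
    arm = _mature_arm(structure, ms, me)
    if arm is None:
        reasons.append("mature_spans_loop_or_unpaired")
    if unpaired > max_unpaired_mature:
        reasons.append("too_many_unpaired_mature_bases")
    if arm is not None and _max_duplex_bulge(structure, ms, me) > max_bulge:
        reasons.append("duplex_bulge_too_large")
    gc = gc_percent(sub)
    if gc <= 0 or mfe >= 0:
        reasons.append("no_stable_fold")
        return None
    amfe, mfei = compute_amfe_mfei(mfe, len(sub), gc)
    if mfei > mfei_threshold:
        reasons.append("mfei_above_threshold")
    if reasons:
        return None
    rec = PrecursorRecord(
        transcript_id=tid, start=start, end=end, sequence=sub, structure=structure,
        mfe=mfe, amfe=amfe, mfei=mfei, gc_percent=gc, arm=arm,
        mature_start=ms, mature_end=me,
    )
    star = predict_star(rec)
    if star is not None:
        s0, s1 = star
        rec = replace(rec, star_start=s0, star_end=s1, star_sequence=sub[s0:s1])
    return rec


def _trim_to_hairpin(
    rec: PrecursorRecord,
    engine: FoldingEngine,
    mfei_threshold: float,
    max_unpaired_mature: int,
    max_bulge: int,
    min_length: int = 60,
) -> PrecursorRecord | None:
    """Trim an accepted window to the stem-loop actually containing the
    mature (the span between the mature's outermost partners), refold and
    revalidate.  Returns None when the trimmed sequence no longer passes,
    in which case the caller keeps the untrimmed window."""
    pt = pair_table(rec.structure)
    ms, me = rec.mature_start, rec.mature_end
    anchors = [i for i in range(ms, me) if pt[i] >= 0]
    if not anchors:
        return None
    lo = min(ms, min(min(i, pt[i]) for i in anchors))
    hi = max(me, max(max(i, pt[i]) for i in anchors) + 1)
    if hi - lo < min_length:  # pad up to the length floor, keeping the mature
        pad = min_length - (hi - lo)
        lo = max(0, lo - pad // 2)
        hi = min(len(rec.sequence), lo + min_length)
        lo = max(0, hi - min_length)
        lo, hi = min(lo, ms), max(hi, me)
    if (lo, hi) == (0, len(rec.sequence)):
        return rec
    sub = rec.sequence[lo:hi]
    structure, mfe = engine.fold(sub)
    return _validate_window(
        rec.transcript_id, sub, structure, mfe, rec.start + lo, rec.start + hi,
        ms - lo, me - lo, mfei_threshold, max_unpaired_mature, max_bulge,
    )


def predict_star(record: PrecursorRecord) -> tuple[int, int] | None:
    """Star interval on the precursor from the pair table, placed so both
    duplex strands carry 2-nt 3' overhangs: the star's 3' end pairs with
    mature position 3 and the mature's 3' end pairs with star position 3.
    Returns None when the duplex cannot be resolved from the structure."""
    pt = pair_table(record.structure)
    ms, me = record.mature_start, record.mature_end
    # Anchor on (or next to) mature position 3: its partner is the star's
    # 3'-most paired base, and the star extends 0 further (the 2-nt mature
    # 5' overhang of the star is already inside positions 1-2's partners).
    anchor5 = next((i for i in (ms + 2, ms + 1, ms + 3, ms, ms + 4) if ms <= i < me and pt[i] >= 0), None)
    anchor3 = next((i for i in (me - 1, me - 2, me - 3, me - 4) if ms <= i < me and pt[i] >= 0), None)
    if anchor5 is None or anchor3 is None:
        return None
    # extrapolate along the helix to the exact anchor positions
    star_end = pt[anchor5] + (anchor5 - (ms + 2)) + 1
    star_start = pt[anchor3] - ((me - 1) - anchor3) - 2
    star_start = max(0, star_start)
    star_end = min(len(record.sequence), star_end)
    if star_end - star_start < (me - ms) - 4:
        return None
    return star_start, star_end


def identify_star(
    record: PrecursorRecord,
    collapsed_reads: Sequence[CollapsedRead] | dict[str, int],
) -> PrecursorRecord:
    """Attach observed counts to the predicted star and enforce the
    abundance rule: of the two duplex strands the lower-count one is the
    star.  Equal counts keep the 5' arm as mature (documented tie-break).
    Accepts either collapsed reads or a precomputed sequence->total map;
    returns a (possibly strand-swapped) copy of the record."""
    if record.star_sequence is None:
        return record
    by_seq = (
        collapsed_reads
        if isinstance(collapsed_reads, dict)
        else {r.sequence: r.total for r in collapsed_reads}
    )
    mature_n = by_seq.get(record.mature_sequence, 0)
    star_n = by_seq.get(record.star_sequence, 0)
    rec = replace(record, star_predicted_only=star_n == 0)
    if star_n > mature_n:
        # swap labels: the more abundant strand is the mature
        rec = replace(
            rec,
            mature_start=rec.star_start, mature_end=rec.star_end,
            star_start=rec.mature_start, star_end=rec.mature_end,
            star_sequence=rec.sequence[rec.mature_start : rec.mature_end],
            arm="3p" if rec.arm == "5p" else "5p",
            star_predicted_only=mature_n == 0,
        )
    return rec


@dataclass
class PrecursorCluster:
    """Two or more precursors on one transcript (polycistronic pri-miRNA)."""

    transcript_id: str
    records: list[PrecursorRecord]
    spacers: list[int]        # gap in nt between consecutive precursor intervals
    has_overlap: bool = False


def detect_clusters(records: Sequence[PrecursorRecord]) -> list[PrecursorCluster]:
    """Group precursors per transcript and report pairwise spacer lengths
    between consecutive intervals.  Overlapping precursors are merged into
    the same cluster with a negative spacer and flagged."""
    by_tid: dict[str, list[PrecursorRecord]] = {}
    for r in records:
        by_tid.setdefault(r.transcript_id, []).append(r)
    clusters = []
    for tid in sorted(by_tid):
        recs = sorted(by_tid[tid], key=lambda r: (r.start, r.end))
        if len(recs) < 2:
            continue
        spacers = [b.start - a.end for a, b in zip(recs, recs[1:])]
        clusters.append(
            PrecursorCluster(tid, recs, spacers, has_overlap=any(s < 0 for s in spacers))
        )
    return clusters


def write_vienna(path, records: Sequence[PrecursorRecord]) -> None:
    """Dot-bracket output in Vienna format: header, sequence line, then the
    structure line with the MFE in parentheses."""
    from .util import to_rna

    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.transcript_id}:{r.start + 1}-{r.end}\n")
            fh.write(to_rna(r.sequence) + "\n")
            fh.write(f"{r.structure} ({r.mfe:.2f})\n")
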