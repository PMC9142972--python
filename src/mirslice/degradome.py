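"""Degradome (PARE) analysis: 5'-end profiles, slice-site prediction,
category assignment and empirical p-values.

AGO-guided cleavage leaves an uncapped 3' fragment whose 5' end lies
between the target bases pairing miRNA nucleotides 10 and 11; degradome
sequencing reads start exactly at such remnant 5' ends.  The stage maps
each read's first 20 nt to the transcriptome by exact match, builds a
per-transcript position->count profile, scans each annotated miRNA
against every transcript window with an Allen-style penalty score
(mismatch 1, G:U wobble 0.5, doubled at miRNA positions 2-13, cutoff 7)
and emits a site whenever the predicted slice position carries degradome
reads.  Sites are ranked into five evidence categories:

  0  count > 1, equal to the transcript maximum, unique maximum position
  1  count > 1, equal to the maximum, several positions at the maximum
  2  count > 1, below the maximum but above the average depth
  3  count > 1, below or equal to the average depth
  4  exactly one read

and given an empirical p-value from mononucleotide shuffles of the miRNA.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import DegradomeProfile, TargetSite
from .util import encode, revcomp, to_dna

#: penalty lookup: row = (miRNA base, target base) -> base penalty
_MATCH = {("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")}
_WOBBLE = {("G", "T"), ("T", "G")}


def build_profiles(
    degradome_reads: Iterable[tuple[str, str, str]] | Iterable[str],
    transcriptome: dict[str, str],
    read_prefix_len: int = 20,
) -> tuple[dict[str, DegradomeProfile], dict[str, float]]:
    """Map degradome reads by exact ``read_prefix_len``-nt prefix (sense
    strand) and accumulate 5'-end counts per transcript position (1-based).
    Multi-mapping prefixes increment every location.  Returns the profiles
    plus mapping statistics (total, mapped, too-short counts and the
    mapping rate)."""
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in transcriptome.items():
        s = to_dna(seq)
        for pos in range(len(s) - read_prefix_len + 1):
            index.setdefault(s[pos : pos + read_prefix_len], []).append((tid, pos))
    counts: dict[str, dict[int, int]] = {}
    total = mapped = short = 0
    for item in degradome_reads:
        seq = to_dna(item[1] if isinstance(item, tuple) else item)
        total += 1
        if len(seq) < read_prefix_len:
            short += 1
            continue
        hits = index.get(seq[:read_prefix_len])
        if not hits:
            continue
        mapped += 1
        for tid, pos in hits:
            counts.setdefault(tid, {})[pos + 1] = counts.setdefault(tid, {}).get(pos + 1, 0) + 1
    profiles = {
        tid: DegradomeProfile(tid, dict(sorted(c.items())), transcript_length=len(transcriptome[tid]))
        for tid, c in counts.items()
    }
    stats = {
        "total_reads": float(total),
        "mapped_reads": float(mapped),
        "too_short": float(short),
        "mapping_rate": mapped / total if total else 0.0,
    }
    return profiles, stats


def _base_penalty(mir_base: str, target_base: str) -> float:
    if (mir_base, target_base) in _MATCH:
        return 0.0
    if (mir_base, target_base) in _WOBBLE:
        return 0.5
    return 1.0


def score_duplex(mirna: str, window: str) -> tuple[float, str]:
    """Allen-style penalty of an antiparallel miRNA:target duplex.

    miRNA nucleotide i (1-based, 5'->3') faces target base ``window[n-i]``.
    Penalties per miRNA position: mismatch 1.0, G:U wobble 0.5, doubled at
    positions 2-13 (the seed-plus-central region where pairing matters for
    slicing).  Returns (score, three-line alignment string).
    """
    mir = to_dna(mirna)
    win = to_dna(window)
    if len(mir) != len(win):
        raise ValueError("window length must equal miRNA length (ungapped mode)")
    if set(mir + win) - set("ACGT"):
        raise ValueError("sequences must be A/C/G/U/T")
    n = len(mir)
    score = 0.0
    marks = []
    for i in range(1, n + 1):
        t = win[n - i]
        p = _base_penalty(mir[i - 1], t)
        if 2 <= i <= 13:
            p *= 2.0
        score += p
        marks.append("|" if (mir[i - 1], t) in _MATCH else ("o" if (mir[i - 1], t) in _WOBBLE else " "))
    # alignment drawn 5'->3' along the target window
    target_line = f"5' {win} 3' target"
    mark_line = "   " + "".join(reversed(marks))
    mir_line = f"3' {mir[::-1]} 5' miRNA"
    return score, "\n".join((target_line, mark_line, mir_line))


def _penalty_matrix(mirna: str) -> np.ndarray:
    """(window position j, target base code) -> penalty, for vectorised
    window scans.  Window position j faces miRNA nucleotide i = n - j."""
    mir = to_dna(mirna)
    n = len(mir)
    mat = np.zeros((n, 4), dtype=np.float64)
    for j in range(n):
        i = n - j  # 1-based miRNA position
        weight = 2.0 if 2 <= i <= 13 else 1.0
        for code, base in enumerate("ACGT"):
            mat[j, code] = weight * _base_penalty(mir[i - 1], base)
    return mat


def scores_at(transcript: str, starts: Sequence[int], mirna: str) -> np.ndarray:
    """Duplex scores of the windows beginning at ``starts`` (0-based) on a
    transcript, vectorised; windows running off the transcript score inf."""
    t = encode(transcript)
    n = len(to_dna(mirna))
    mat = _penalty_matrix(mirna)
    starts_arr = np.asarray(starts, dtype=np.int64)
    out = np.full(len(starts_arr), np.inf)
    ok = (starts_arr >= 0) & (starts_arr + n <= len(t))
    if ok.any():
        s = starts_arr[ok]
        acc = np.zeros(len(s))
        valid = np.ones(len(s), dtype=bool)
        for j in range(n):
            codes = t[s + j]
            valid &= codes < 4
            acc += mat[j, np.minimum(codes, 3)]
        acc[~valid] = np.inf
        out[ok] = acc
    return out


def slice_position_1based(window_start: int, mirna_len: int) -> int:
    """Transcript coordinate (1-based) of the remnant 5' end for a window
    beginning at ``window_start`` (0-based): the base pairing miRNA
    nucleotide 10."""
    return window_start + mirna_len - 10 + 1


def find_sites(
    mirna_name: str,
    mirna: str,
    transcriptome: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    max_score: float = 7.0,
    multi_site: bool = False,
    all_positions_average: bool = False,
) -> list[TargetSite]:
    """Degradome-supported slice sites for one miRNA.

    Every transcript window is scanned (equivalently: every profiled
    position is tested as a candidate slice site, since a site requires at
    least one degradome read exactly at the predicted slice position).  In
    the default single-site mode only the best site per miRNA-transcript
    pair survives (lowest category, then highest count, then lowest
    score); ``multi_site`` reports them all.
    """
    mir = to_dna(mirna)
    n = len(mir)
    sites: list[TargetSite] = []
    for tid, profile in sorted(profiles.items()):
        seq = transcriptome.get(tid)
        if seq is None:
            continue
        positions = sorted(profile.counts)
        starts = [p - 1 - (n - 10) for p in positions]
        scores = scores_at(seq, starts, mir)
        per_transcript = []
        for pos, start, score in zip(positions, starts, scores):
            if score > max_score:
                continue
            window = to_dna(seq)[start : start + n]
            cat = categorize_site(profile, pos, all_positions_average=all_positions_average)
            _, alignment = score_duplex(mir, window)
            per_transcript.append(
                TargetSite(
                    mirna_name=mirna_name, mirna_sequence=mir, transcript_id=tid,
                    slice_pos_1based=pos, score=float(score), alignment=alignment,
                    count=profile.counts[pos], category=cat,
                )
            )
        if not per_transcript:
            continue
        if multi_site:
            sites.extend(sorted(per_transcript, key=lambda s: s.slice_pos_1based))
        else:
            per_transcript.sort(key=lambda s: (s.category, -s.count, s.score, s.slice_pos_1based))
            sites.append(per_transcript[0])
    return sites


def categorize_site(
    profile: DegradomeProfile,
    position: int,
    all_positions_average: bool = False,
) -> int:
    """Evidence category 0-4 of a profiled position (see module docstring).

    ``all_positions_average`` switches the category-2/3 boundary to the
    mean over every transcript position rather than the default mean over
    positions with at least one read.
    """
    c = profile.counts.get(position, 0)
    if c < 1:
        raise ValueError("no degradome read at the requested position")
    if c == 1:
        return 4
    max_count = profile.max_count
    if c == max_count:
        return 0 if len(profile.positions_at_max) == 1 else 1
    if all_positions_average and profile.transcript_length:
        avg = profile.total / profile.transcript_length
    else:
        avg = profile.average_depth
    return 2 if c > avg else 3


def site_pvalue(
    site: TargetSite,
    transcriptome: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    n_shuffles: int = 100,
    seed: int = 0,
    max_score: float = 7.0,
) -> float:
    """Empirical p-value of a site from mononucleotide shuffles of the
    miRNA: the add-one fraction of shuffles that produce at least one site
    anywhere with category <= the observed category and score <= the
    observed score.  Deterministic for a fixed seed; bounded below by
    1/(n_shuffles + 1)."""
    rng = np.random.default_rng(seed)
    mir = list(site.mirna_sequence)
    threshold = min(max_score, site.score)
    successes = 0
    for _ in range(n_shuffles):
        shuffled = "".join(rng.permutation(mir))
        if _any_site_at_least(shuffled, transcriptome, profiles, threshold, site.category):
            successes += 1
    return (1 + successes) / (1 + n_shuffles)


def _any_site_at_least(
    mirna: str,
    transcriptome: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    max_score: float,
    max_category: int,
) -> bool:
    n = len(mirna)
    for tid, profile in profiles.items():
        seq = transcriptome.get(tid)
        if seq is None:
            continue
        positions = sorted(profile.counts)
        starts = [p - 1 - (n - 10) for p in positions]
        scores = scores_at(seq, starts, mirna)
        for pos, score in zip(positions, scores):
            if score <= max_score and categorize_site(profile, pos) <= max_category:
                return True
    return False


def tplot_table(
    profile: DegradomeProfile,
    site: TargetSite | None = None,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Serialise a degradome profile as a (position, count, is_slice_site)
    table, optionally restricted to a 1-based inclusive position window —
    the tabular form of a t-plot."""
    rows = []
    for pos in sorted(profile.counts):
        if window is not None and not (window[0] <= pos <= window[1]):
            continue
        rows.append(
            {
                "position": pos,
                "count": profile.counts[pos],
                "is_slice_site": site is not None and pos == site.slice_pos_1based,
            }
        )
    return pd.DataFrame(rows, columns=["position", "count", "is_slice_site"])


def sites_table(sites: Sequence[TargetSite], annotations: dict[str, str] | None = None) -> pd.DataFrame:
    """Target-site report table (miRNA, target, annotation passthrough from
    the transcriptome FASTA headers, category, p-value, score, position)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "mirna": s.mirna_name,
                "target_id": s.transcript_id,
                "annotation": (annotations or {}).get(s.transcript_id, "n/a"),
                "slice_position": s.slice_pos_1based,
                "degradome_count": s.count,
                "score": s.score,
                "category": s.category,
                "p_value": s.pvalue,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mirna", "target_id", "annotation", "slice_position",
                 "degradome_count", "score", "category", "p_value"],
    )
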