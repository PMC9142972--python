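"""Descriptive statistics of a miRNA catalogue: base composition,
positional nucleotide distributions (the 5' end and the positions facing
the slice site, 10 and 11), length histograms, family-member counts and
precursor summary ranges."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .types import MiRNAAnnotation, PrecursorRecord
from .util import to_rna

_BASES = ("A", "U", "G", "C")


def _round_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percentages to 2 decimals via largest-remainder rounding, so each
    table sums to exactly 100.00."""
    total = sum(counts[b] for b in _BASES)
    raw = {b: 10000.0 * counts[b] / total for b in _BASES}
    floored = {b: int(raw[b]) for b in _BASES}
    short = 10000 - sum(floored.values())
    for b in sorted(_BASES, key=lambda b: raw[b] - floored[b], reverse=True)[:short]:
        floored[b] += 1
    return {b: floored[b] / 100.0 for b in _BASES}


@dataclass
class CompositionReport:
    base_percent: dict[str, float]      # pooled over all positions, 2 dp
    gc_percent: float
    positional: dict[int, dict[str, float]]
    length_histogram: dict[int, int]
    n_sequences: int


def base_composition(sequences: list[str], positions: tuple[int, ...] = (1, 10, 11)) -> CompositionReport:
    """Pooled single-nucleotide composition of a mature set (RNA alphabet),
    GC%, the length histogram and positional distributions at the requested
    1-based positions.  Percentages are reported to two decimals."""
    if not sequences:
        raise ValueError("empty sequence set")
    seqs = [to_rna(s) for s in sequences]
    pooled = Counter()
    for s in seqs:
        pooled.update(s)
    total = sum(pooled[b] for b in _BASES)
    pct = _round_percentages(pooled)
    gc = round(100.0 * (pooled["G"] + pooled["C"]) / total, 2)
    return CompositionReport(
        base_percent=pct,
        gc_percent=gc,
        positional={
            p: positional_distribution(seqs, p)
            for p in positions
            if any(len(s) >= p for s in seqs)
        },
        length_histogram=dict(sorted(Counter(len(s) for s in seqs).items())),
        n_sequences=len(seqs),
    )


def positional_distribution(sequences: list[str], position: int) -> dict[str, float]:
    """Base frequencies (percent) at a 1-based position, over the sequences
    long enough to have that position."""
    if position < 1:
        raise ValueError("position is 1-based")
    bases = [to_rna(s)[position - 1] for s in sequences if len(s) >= position]
    if not bases:
        raise ValueError(f"no sequence of length >= {position}")
    return _round_percentages(Counter(bases))


def family_member_counts(annotations: list[MiRNAAnnotation]) -> pd.DataFrame:
    """Distinct retained mature sequences per family, sorted by descending
    member count then family name."""
    members: dict[str, set[str]] = {}
    for a in annotations:
        members.setdefault(a.family, set()).add(a.sequence)
    rows = [{"family": f, "members": len(s)} for f, s in members.items()]
    frame = pd.DataFrame(rows, columns=["family", "members"])
    return frame.sort_values(["members", "family"], ascending=[False, True]).reset_index(drop=True)


@dataclass
class PrecursorSummary:
    n: int
    length_min: int
    length_max: int
    length_mean: int          # rounded to integer nt for reporting
    mfe_min: float
    mfe_max: float
    mfei_min: float
    mfei_max: float


def precursor_summary(records: list[PrecursorRecord]) -> PrecursorSummary:
    """Length/MFE/MFEI summary of a validated precursor set."""
    if not records:
        raise ValueError("empty precursor set")
    lengths = [r.length for r in records]
    mfes = [r.mfe for r in records]
    mfeis = [r.mfei for r in records]
    return PrecursorSummary(
        n=len(records),
        length_min=min(lengths),
        length_max=max(lengths),
        length_mean=math.floor(sum(lengths) / len(lengths) + 0.5),  # half rounds up
        mfe_min=min(mfes),
        mfe_max=max(mfes),
        mfei_min=min(mfeis),
        mfei_max=max(mfeis),
    )
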