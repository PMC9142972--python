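"""Domain record types shared across pipeline stages.

Coordinate convention: in-memory intervals are 0-based half-open
(``start``/``end``); anything labelled ``*_1based`` or written to a report
is 1-based inclusive, which is how positions are quoted in the small-RNA
literature and in the TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .util import to_rna


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct small-RNA sequence with its per-library read counts."""

    sequence: str                 # DNA space, uppercase
    counts: tuple[int, ...]       # one entry per library, fixed order

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("empty collapsed read")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative library count")

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)


@dataclass
class LibraryProfile:
    """Per-library length profile: redundant/non-redundant histograms,
    reads-per-million and the complexity index (distinct/total per length)."""

    library: str
    redundant_counts: dict[int, int]
    nonredundant_counts: dict[int, int]
    rpm: dict[int, float]
    complexity_index: dict[int, float]
    total_reads: int


@dataclass
class MiRNAAnnotation:
    """A collapsed read annotated by homology to a reference mature miRNA."""

    sequence: str                 # DNA space
    ref_name: str                 # e.g. osa-miR395a-5p
    family: str                   # e.g. miR395
    mismatches: int
    overlap: int
    counts: tuple[int, ...]
    tpm: tuple[float, ...] = ()
    supporting_library_count: int = 0

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)


@dataclass
class PrecursorRecord:
    """A validated hairpin precursor located on a host transcript."""

    transcript_id: str
    start: int                    # 0-based half-open on the transcript
    end: int
    sequence: str
    structure: str                # dot-bracket, same length as sequence
    mfe: float                    # kcal/mol
    amfe: float                   # kcal/mol per 100 nt
    mfei: float                   # AMFE / GC%
    gc_percent: float
    arm: str                      # "5p" | "3p"
    mature_start: int             # 0-based on the precursor
    mature_end: int
    star_sequence: str | None = None
    star_start: int | None = None # 0-based on the precursor
    star_end: int | None = None
    star_predicted_only: bool = True
    valid: bool = True
    reasons: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start : self.mature_end]


@dataclass
class NovelCandidate:
    """A cluster of unannotated reads validated as a candidate novel miRNA."""

    representative: str           # DNA space
    members: tuple[str, ...]
    counts: tuple[int, ...]       # cluster-summed per library
    precursor: PrecursorRecord
    star_observed: bool
    tier: str                     # "candidate" | "high-confidence"


@dataclass
class DegradomeProfile:
    """Per-transcript map of degradome-read 5' ends (1-based positions)."""

    transcript_id: str
    counts: dict[int, int]
    transcript_length: int | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    @property
    def positions_at_max(self) -> list[int]:
        m = self.max_count
        return sorted(p for p, c in self.counts.items() if c == m) if self.counts else []

    @property
    def average_depth(self) -> float:
        """Mean count over positions with at least one read."""
        return self.total / len(self.counts) if self.counts else 0.0


@dataclass
class TargetSite:
    """A degradome-supported miRNA slice site on a transcript."""

    mirna_name: str
    mirna_sequence: str           # DNA space
    transcript_id: str
    slice_pos_1based: int         # 5' end of the downstream cleavage remnant
    score: float                  # duplex penalty score
    alignment: str
    count: int                    # degradome reads at the slice position
    category: int                 # 0..4
    pvalue: float | None = None


@dataclass
class PlantedMiRNA:
    """Ground truth for one simulated hairpin locus (coordinates 1-based
    inclusive, matching the truth TSV)."""

    name: str
    family: str
    mature: str                   # DNA space
    star: str
    transcript_id: str
    hairpin_start: int
    hairpin_end: int
    arm: str
    is_novel: bool
    cluster_id: int | None = None


@dataclass
class PlantedTarget:
    """Ground truth for one simulated degradome slice site."""

    mirna_name: str
    mature: str
    transcript_id: str
    slice_pos_1based: int
    intended_category: int


@dataclass
class TruthTable:
    """Everything the generator planted, for downstream scoring."""

    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_decoys: list[str] = field(default_factory=list)   # abundant non-hairpin reads
    read_classes: dict[str, list[str]] = field(default_factory=dict)  # library -> per-read label
    library_expression: dict[str, dict[str, float]] = field(default_factory=dict)
    # ^ sequence-role key ("mature:<name>" / "star:<name>") -> library -> expected reads

    def known_matures(self) -> list[PlantedMiRNA]:
        return [p for p in self.planted_mirnas if not p.is_novel]

    def novel_matures(self) -> list[PlantedMiRNA]:
        return [p for p in self.planted_mirnas if p.is_novel]
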