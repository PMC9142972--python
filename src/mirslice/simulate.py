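"""Synthetic study generator: transcriptome with planted miRNA hairpins,
multi-library small-RNA FASTQs, blacklist contaminants and a degradome
with peaks at known slice sites.

The generator emulates the study design the pipeline is built for: four
nutrient-treatment libraries ("C", "P", "Na", "NaP") treated as
biological replicates, a 24-nt-dominant read-length profile with a 21-nt
secondary peak, planted hairpin loci in transcripts (including one
polycistronic cluster whose two precursors sit 94 nt apart), rRNA/tRNA/
chloroplast contaminant reads, and degradome 5'-end peaks placed exactly
at the slice positions of planted targets.  Every planted feature is
recorded in a :class:`~mirslice.types.TruthTable` so downstream stages can
be scored without external data.

Planted hairpins are verified with the folding engine at generation time
(the embedded locus must validate as a precursor in its transcript
context), and planted decoys are verified *not* to validate, so the truth
labels are correct by construction.  Fixed seeds give byte-identical
FASTA/FASTQ outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fold import FoldingEngine, ViennaEngine
from .precursor import extract_and_validate, predict_star
from .types import PlantedMiRNA, PlantedTarget, PrecursorRecord, TruthTable
from .util import revcomp, to_dna

_DEFAULT_SIZE_PROFILE = {
    18: 0.04, 19: 0.05, 20: 0.07, 21: 0.13, 22: 0.07, 23: 0.06,
    24: 0.33, 25: 0.09, 26: 0.07, 27: 0.05, 28: 0.04,
}  # 24-nt dominant, 21-nt secondary peak; 66% of mass in 20-24 nt;
#    miRNA/star reads add to the 21-nt class on top of this background


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults reproduce the emulated
    design (4 libraries, 24>21-nt profile, one 94-nt-spacer cluster)."""

    n_transcripts: int = 200
    transcript_length_range: tuple[int, int] = (400, 2500)
    gc_fraction: float = 0.45
    n_planted_mirnas: int = 20
    novel_fraction: float = 0.25          # planted matures kept out of the reference
    n_decoy_reference: int = 10           # reference matures with no planted locus
    n_decoy_reads: int = 5                # abundant non-hairpin reads (discovery negatives)
    n_libraries: int = 4
    library_names: tuple[str, ...] = ("C", "P", "Na", "NaP")
    depth_per_library: int = 50_000
    size_profile: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_SIZE_PROFILE))
    contaminant_fraction: float = 0.10
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 50
    mirna_star_ratio: float = 10.0
    mean_mirna_reads_per_library: float = 300.0
    # ^ abundant miRNAs make the 21-nt class about twice as redundant as
    #   the 24-nt class (complexity index ratio ~0.5), the pattern of
    #   real monocot libraries; implied top TPM ~10^4 at default depth
    mean_decoy_reads_per_library: float = 100.0
    degradome_depth: int = 100_000
    peak_fraction: float = 0.30
    degradome_unmapped_fraction: float = 0.0
    degradome_read_len: int = 20
    n_planted_targets: int = 10
    n_cat4_targets: int = 2
    double_site: bool = True              # give one miRNA two sites on one transcript
    cluster_spacer: int = 94
    mature_len: int = 21
    loop_len_range: tuple[int, int] = (18, 150)
    # ^ per-hairpin loop draw: precursors span ~60-192 nt (mean ~126),
    #   the realistic plant pre-miRNA size spread; the 18-nt floor keeps
    #   the smallest hairpin at the 60-nt precursor minimum
    low_quality_tail: bool = False
    max_fold_retries: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        if self.n_planted_mirnas > self.n_transcripts and self.n_transcripts > 0:
            raise ValueError("more planted miRNAs than transcripts")
        if self.depth_per_library < 0 or self.degradome_depth < 0:
            raise ValueError("depth must be >= 0")
        if abs(sum(self.size_profile.values()) - 1.0) > 1e-9:
            raise ValueError("size_profile probabilities must sum to 1")
        if len(self.library_names) != self.n_libraries:
            raise ValueError("library_names must match n_libraries")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant_fraction must be a proportion")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=p))


def _draw_lengths(rng: np.random.Generator, profile: dict[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(profile))
    probs = np.array([profile[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def generate_transcriptome(
    config: SimulationConfig,
    engine: FoldingEngine | None = None,
) -> tuple[dict[str, str], TruthTable]:
    """Random transcripts with planted, fold-verified miRNA hairpins.

    The first two planted miRNAs share one host transcript, their hairpin
    intervals separated by ``config.cluster_spacer`` nt (the polycistronic
    cluster); every other planted miRNA gets its own host.  Raises
    ``RuntimeError`` when a hairpin cannot be made to fold within
    ``max_fold_retries`` redraws.
    """
    config.validate()
    engine = engine or ViennaEngine()
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    if config.n_transcripts == 0:
        return {}, truth

    lo, hi = config.transcript_length_range
    max_hairpin = 2 * config.mature_len + config.loop_len_range[1]
    min_host = 2 * max_hairpin + config.cluster_spacer + 240
    transcripts: dict[str, str] = {}
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    lengths[0] = max(lengths[0], min_host)  # the cluster host must fit two hairpins
    for i in range(config.n_transcripts):
        transcripts[f"TR{i + 1}"] = _random_seq(rng, int(lengths[i]), config.gc_fraction)

    n_novel = int(round(config.n_planted_mirnas * config.novel_fraction))
    cluster_pairs = 2 if config.n_planted_mirnas >= 2 else config.n_planted_mirnas
    cluster_end_1b = 0
    for i in range(config.n_planted_mirnas):
        if i < cluster_pairs:
            tid = "TR1"
            offset = 60 if i == 0 else cluster_end_1b + config.cluster_spacer
        else:
            tid = f"TR{i}"  # TR2.. host one hairpin each (TR1 holds the cluster)
            offset = 60
        is_novel = i >= config.n_planted_mirnas - n_novel
        planted = _plant_hairpin(rng, config, engine, transcripts, tid, offset, i, is_novel)
        planted.cluster_id = 1 if i < cluster_pairs and cluster_pairs == 2 else None
        if i < cluster_pairs:
            cluster_end_1b = planted.hairpin_end
        truth.planted_mirnas.append(planted)

    _plant_targets(rng, config, transcripts, truth)
    _plant_decoys(rng, config, engine, transcripts, truth)
    _draw_expression(rng, config, truth)
    return transcripts, truth


def _plant_hairpin(
    rng: np.random.Generator,
    config: SimulationConfig,
    engine: FoldingEngine,
    transcripts: dict[str, str],
    tid: str,
    offset: int,
    index: int,
    is_novel: bool,
) -> PlantedMiRNA:
    n = config.mature_len
    host = transcripts[tid]
    for _attempt in range(config.max_fold_retries):
        loop_len = int(rng.integers(config.loop_len_range[0], config.loop_len_range[1] + 1))
        hairpin_len = 2 * n + loop_len
        if offset + hairpin_len > len(host):
            raise ValueError(f"host transcript {tid} too short for hairpin at {offset}")
        # G/C at both mature ends keeps the terminal stem pairs from
        # fraying, so the folded hairpin spans the full planted interval
        mature = (
            "GC"[int(rng.integers(2))]
            + _random_seq(rng, n - 2, 0.5)
            + "GC"[int(rng.integers(2))]
        )
        loop = _random_seq(rng, loop_len, 0.4)
        hairpin = mature + loop + revcomp(mature)
        candidate = host[:offset] + hairpin + host[offset + hairpin_len :]
        rec = extract_and_validate(tid, candidate, (offset, offset + n), engine)
        if rec is None or rec.star_sequence is None:
            continue
        transcripts[tid] = candidate
        if is_novel:
            name = f"miRC{1000 + index}"
            family = name
        else:
            name = f"ado-miR{150 + index}a-5p"
            family = f"miR{150 + index}"
        return PlantedMiRNA(
            name=name, family=family, mature=mature,
            star=_truth_star(engine, hairpin, n),
            transcript_id=tid,
            hairpin_start=offset + 1, hairpin_end=offset + hairpin_len,
            arm="5p", is_novel=is_novel,
        )
    raise RuntimeError(
        "hairpin retry cap exceeded: arm/loop parameters incompatible with folding"
    )


def _truth_star(engine: FoldingEngine, hairpin: str, mature_len: int) -> str:
    """Star sequence implied by the folded hairpin and the 2-nt 3'
    overhang geometry (same rule the precursor stage applies)."""
    structure, mfe = engine.fold(hairpin)
    rec = PrecursorRecord(
        transcript_id="hairpin", start=0, end=len(hairpin), sequence=to_dna(hairpin),
        structure=structure, mfe=mfe, amfe=0.0, mfei=0.0, gc_percent=50.0,
        arm="5p", mature_start=0, mature_end=mature_len,
    )
    star = predict_star(rec)
    if star is None:
        return revcomp(hairpin[:mature_len])
    return to_dna(hairpin)[star[0] : star[1]]


def _plant_targets(
    rng: np.random.Generator,
    config: SimulationConfig,
    transcripts: dict[str, str],
    truth: TruthTable,
) -> None:
    """Embed perfect complementary sites of planted matures in non-hairpin
    transcripts and record the implied slice positions."""
    if config.n_planted_targets == 0:
        return
    hosts = {p.transcript_id for p in truth.planted_mirnas}
    free = [t for t in transcripts if t not in hosts]
    if len(free) < config.n_planted_targets:
        raise ValueError("not enough transcripts to host targets")
    matures = truth.planted_mirnas
    n = config.mature_len
    for j in range(config.n_planted_targets):
        planted = matures[j % len(matures)]
        tid = free[j]
        seq = transcripts[tid]
        cat = 4 if j >= config.n_planted_targets - config.n_cat4_targets else 0
        positions = [_target_pos(rng, len(seq), n, config.degradome_read_len)]
        if j == 0 and config.double_site:
            positions.append(positions[0] + n + 120)
        for w0 in positions:
            site_seq = revcomp(planted.mature)
            transcripts[tid] = transcripts[tid][:w0] + site_seq + transcripts[tid][w0 + n :]
            truth.planted_targets.append(
                PlantedTarget(
                    mirna_name=planted.name, mature=planted.mature, transcript_id=tid,
                    slice_pos_1based=w0 + n - 10 + 1, intended_category=cat,
                )
            )


def _target_pos(rng: np.random.Generator, tlen: int, n: int, read_len: int) -> int:
    # the remnant read must fit downstream of the slice position
    hi = tlen - (n + 120) - (read_len + 20)
    lo = 50
    if hi <= lo:
        raise ValueError("transcript too short for a target site")
    return int(rng.integers(lo, hi))


def _plant_decoys(
    rng: np.random.Generator,
    config: SimulationConfig,
    engine: FoldingEngine,
    transcripts: dict[str, str],
    truth: TruthTable,
) -> None:
    """Abundant reads from non-hairpin transcript regions, verified not to
    validate as precursors so the decoy truth label is correct."""
    hosts = {p.transcript_id for p in truth.planted_mirnas}
    targeted = {t.transcript_id for t in truth.planted_targets}
    free = [t for t in transcripts if t not in hosts and t not in targeted]
    n = config.mature_len
    made = 0
    attempts = 0
    while made < config.n_decoy_reads and attempts < 50 * max(1, config.n_decoy_reads):
        attempts += 1
        tid = free[int(rng.integers(len(free)))]
        seq = transcripts[tid]
        if len(seq) < n + 40:
            continue
        pos = int(rng.integers(20, len(seq) - n - 20))
        read = seq[pos : pos + n]
        if extract_and_validate(tid, seq, (pos, pos + n), engine) is None:
            truth.planted_decoys.append(read)
            made += 1
    if made < config.n_decoy_reads:
        raise RuntimeError("could not place the requested number of decoy reads")


def _draw_expression(rng: np.random.Generator, config: SimulationConfig, truth: TruthTable) -> None:
    for planted in truth.planted_mirnas:
        m = {}
        s = {}
        for lib in config.library_names:
            factor = rng.uniform(0.6, 1.4)
            m[lib] = config.mean_mirna_reads_per_library * factor
            s[lib] = m[lib] / config.mirna_star_ratio
        truth.library_expression[f"mature:{planted.name}"] = m
        truth.library_expression[f"star:{planted.name}"] = s
    for i, _read in enumerate(truth.planted_decoys):
        truth.library_expression[f"decoy:{i}"] = {
            lib: config.mean_decoy_reads_per_library * rng.uniform(0.6, 1.4)
            for lib in config.library_names
        }


def make_reference(
    truth: TruthTable,
    config: SimulationConfig,
) -> dict[str, str]:
    """Reference mature set (miRBase-style names): the planted known
    matures plus random decoy reference entries that have no locus or
    expression in the simulated study."""
    rng = np.random.default_rng(config.seed + 101)
    reference = {p.name: p.mature for p in truth.known_matures()}
    for i in range(config.n_decoy_reference):
        reference[f"osa-miR{900 + i}-5p"] = _random_seq(rng, config.mature_len, 0.5)
    return reference


def make_blacklists(config: SimulationConfig) -> dict[str, str]:
    """Synthetic rRNA/tRNA/snoRNA/chloroplast stand-in sequences used both
    as contaminant read sources and as the discovery-stage blacklist."""
    rng = np.random.default_rng(config.seed + 202)
    out = {}
    for name, length in (
        ("rRNA_1", 1800), ("rRNA_2", 1200), ("tRNA_1", 80), ("tRNA_2", 76),
        ("snoRNA_1", 120), ("chloroplast_1", 2500),
    ):
        out[name] = _random_seq(rng, length, 0.52)
    return out


def simulate_srna_libraries(
    truth: TruthTable,
    config: SimulationConfig,
    transcripts: dict[str, str],
    blacklists: dict[str, str],
) -> dict[str, list[tuple[str, str, str]]]:
    """One FASTQ-ready read list per library.

    Per library a single multinomial of size ``depth_per_library`` is
    drawn over channels: each planted mature and star (expected counts
    from ``truth.library_expression``), each decoy read, a contaminant
    channel and a background channel; read class labels are recorded in
    ``truth.read_classes``.  Reads are insert + 3' adapter, truncated to
    the read length, with constant high quality (optionally a low-quality
    3' tail to exercise quality trimming).
    """
    if len(config.adapter) < 8:
        raise ValueError("adapter shorter than 8 nt is untrimmable")
    rng = np.random.default_rng(config.seed + 303)
    depth = config.depth_per_library
    tids = sorted(transcripts)
    tlens = np.array([len(transcripts[t]) for t in tids], dtype=float)
    tprobs = tlens / tlens.sum() if tlens.sum() else None
    bl_names = sorted(blacklists)
    decoys = list(truth.planted_decoys)

    channels: list[tuple[str, str | None]] = []  # (label, fixed sequence or None)
    probs: list[float] = []
    for planted in truth.planted_mirnas:
        for role, seq in (("mature", planted.mature), ("star", planted.star)):
            channels.append((f"{role}:{planted.name}", seq))
    for i, read in enumerate(decoys):
        channels.append((f"decoy:{i}", read))
    channels.append(("contaminant", None))
    channels.append(("background", None))

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    for lib in config.library_names:
        probs = []
        for label, _seq in channels:
            if label == "contaminant":
                probs.append(config.contaminant_fraction * depth)
            elif label == "background":
                probs.append(0.0)  # remainder, set below
            else:
                probs.append(truth.library_expression[label][lib])
        probs = np.array(probs, dtype=float)
        remainder = max(0.0, depth - probs.sum())
        probs[-1] = remainder
        if probs.sum() == 0:
            libraries[lib] = []
            truth.read_classes[lib] = []
            continue
        counts = rng.multinomial(depth, probs / probs.sum())
        reads: list[tuple[str, str, str]] = []
        labels: list[str] = []
        for (label, seq), k in zip(channels, counts):
            if k == 0:
                continue
            if seq is not None:
                inserts = [seq] * int(k)
            elif label == "contaminant":
                inserts = _fragment_reads(rng, config, [blacklists[b] for b in bl_names], int(k))
            else:
                inserts = _fragment_reads(rng, config, [transcripts[t] for t in tids], int(k), tprobs)
            for ins in inserts:
                reads.append(_make_read(config, lib, len(reads), ins))
                labels.append(label)
        # shuffle read order so class labels are not positionally encoded
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
        labels = [labels[i] for i in order]
        reads = [(f"{lib}_{i + 1}", s, q) for i, (_n, s, q) in enumerate(reads)]
        libraries[lib] = reads
        truth.read_classes[lib] = labels
    return libraries


def _fragment_reads(
    rng: np.random.Generator,
    config: SimulationConfig,
    sources: list[str],
    n: int,
    probs: np.ndarray | None = None,
) -> list[str]:
    lens = _draw_lengths(rng, config.size_profile, n)
    idx = rng.choice(len(sources), size=n, p=probs)
    out = []
    for i in range(n):
        src = sources[int(idx[i])]
        L = int(lens[i])
        if len(src) <= L:
            out.append(src)
            continue
        pos = int(rng.integers(0, len(src) - L + 1))
        out.append(src[pos : pos + L])
    return out


def _make_read(config: SimulationConfig, lib: str, i: int, insert: str) -> tuple[str, str, str]:
    seq = (insert + config.adapter)[: config.read_length]
    qual = "I" * len(seq)
    if config.low_quality_tail and len(seq) >= 6:
        qual = qual[:-6] + "#" * 6
    return f"{lib}_{i}", seq, qual


def simulate_degradome(
    truth: TruthTable,
    config: SimulationConfig,
    transcripts: dict[str, str],
) -> list[tuple[str, str, str]]:
    """Degradome reads: exact transcript subsequences of fixed length
    starting at 5'-remnant positions.

    A ``peak_fraction`` share of reads starts exactly at planted slice
    positions (category-4 targets receive exactly one read; the rest of
    the peak mass is split across category-0 targets); the remaining reads
    start at uniform random transcript positions, plus an optional
    unmappable fraction of random sequence.  Targets whose slice position
    leaves no room for a full read are skipped with a warning.
    """
    import warnings

    if not truth.planted_targets and config.peak_fraction > 0:
        raise ValueError("peak_fraction > 0 requires planted targets")
    rng = np.random.default_rng(config.seed + 404)
    D = config.degradome_depth
    L = config.degradome_read_len
    reads: list[str] = []

    usable: list[PlantedTarget] = []
    for t in truth.planted_targets:
        seq = transcripts[t.transcript_id]
        if t.slice_pos_1based - 1 + L > len(seq):
            warnings.warn(f"slice position too close to 3' end on {t.transcript_id}; skipped")
            continue
        usable.append(t)

    n_junk = rng.binomial(D, config.degradome_unmapped_fraction) if D else 0
    n_peak = rng.binomial(D - n_junk, config.peak_fraction) if D else 0
    cat0 = [t for t in usable if t.intended_category == 0]
    cat4 = [t for t in usable if t.intended_category != 0]
    for t in cat4[: max(0, n_peak)]:
        reads.append(transcripts[t.transcript_id][t.slice_pos_1based - 1 :][:L])
    n_left = n_peak - len(cat4[: max(0, n_peak)])
    if cat0 and n_left > 0:
        alloc = rng.multinomial(n_left, np.full(len(cat0), 1.0 / len(cat0)))
        for t, k in zip(cat0, alloc):
            frag = transcripts[t.transcript_id][t.slice_pos_1based - 1 :][:L]
            reads.extend([frag] * int(k))
    n_bg = D - n_junk - n_peak
    if n_bg > 0:
        tids = sorted(transcripts)
        weights = np.array([max(0, len(transcripts[t]) - L + 1) for t in tids], dtype=float)
        idx = rng.choice(len(tids), size=n_bg, p=weights / weights.sum())
        for i in idx:
            seq = transcripts[tids[int(i)]]
            pos = int(rng.integers(0, len(seq) - L + 1))
            reads.append(seq[pos : pos + L])
    if n_junk:
        block = rng.choice(np.array(["A", "C", "G", "T"]), size=(n_junk, L))
        reads.extend("".join(row) for row in block)
    order = rng.permutation(len(reads))
    return [(f"deg_{i + 1}", reads[j], "I" * len(reads[j])) for i, j in enumerate(order)]


@dataclass
class SimulatedStudy:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    transcripts: dict[str, str]
    truth: TruthTable
    reference: dict[str, str]
    blacklists: dict[str, str]
    libraries: dict[str, list[tuple[str, str, str]]]
    degradome: list[tuple[str, str, str]]


def simulate_study(
    config: SimulationConfig | None = None,
    engine: FoldingEngine | None = None,
    outdir: str | Path | None = None,
) -> SimulatedStudy:
    """Run the full generator; optionally write all artifacts under
    ``outdir`` (transcriptome/reference/blacklist FASTA, per-library and
    degradome FASTQ, truth TSVs)."""
    from . import io as mio

    config = config or SimulationConfig()
    engine = engine or ViennaEngine()
    transcripts, truth = generate_transcriptome(config, engine)
    reference = make_reference(truth, config)
    blacklists = make_blacklists(config)
    libraries = simulate_srna_libraries(truth, config, transcripts, blacklists)
    degradome = (
        simulate_degradome(truth, config, transcripts) if config.degradome_depth else []
    )
    study = SimulatedStudy(config, transcripts, truth, reference, blacklists, libraries, degradome)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_fasta(outdir / "transcriptome.fasta", sorted(transcripts.items()))
        mio.write_mirbase_fasta(outdir / "reference_matures.fasta", reference)
        mio.write_fasta(outdir / "blacklist.fasta", sorted(blacklists.items()))
        for lib, reads in libraries.items():
            mio.write_fastq(outdir / f"library_{lib}.fastq", reads)
        mio.write_fastq(outdir / "degradome.fastq", degradome)
        write_truth(outdir, truth)
    return study


def write_truth(outdir: str | Path, truth: TruthTable) -> None:
    """Truth tables as TSV (1-based inclusive coordinates)."""
    outdir = Path(outdir)
    pd.DataFrame(
        [
            {
                "name": p.name, "family": p.family, "mature": p.mature, "star": p.star,
                "transcript_id": p.transcript_id, "hairpin_start": p.hairpin_start,
                "hairpin_end": p.hairpin_end, "arm": p.arm, "is_novel": p.is_novel,
                "cluster_id": p.cluster_id,
            }
            for p in truth.planted_mirnas
        ]
    ).to_csv(outdir / "truth_mirnas.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mirna_name": t.mirna_name, "mature": t.mature,
                "transcript_id": t.transcript_id, "slice_pos": t.slice_pos_1based,
                "intended_category": t.intended_category,
            }
            for t in truth.planted_targets
        ]
    ).to_csv(outdir / "truth_targets.tsv", sep="\t", index=False)
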