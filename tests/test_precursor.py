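"""Hairpin location, validation, MFEI algebra, star geometry, clusters."""

import numpy as np
import pytest

from mirslice.fold import ViennaEngine, pair_table
from mirslice.precursor import (
    PrecursorRecord, compute_amfe_mfei, detect_clusters, extract_and_validate,
    find_pri_locations, identify_star, predict_star,
)
from mirslice.types import CollapsedRead
from mirslice.util import gc_percent, revcomp


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPriLocation:
    def test_verbatim_planted_mature_found_at_exact_interval(self):
        rng = np.random.default_rng(31)
        mature = random_seq(rng, 21)
        t = random_seq(rng, 500) + mature + random_seq(rng, 300)
        hits = find_pri_locations(mature, {"TR1": t})
        exact = [h for h in hits if h.mismatches == 0 and h.orientation == "+"]
        assert any(h.start == 500 and h.end == 521 for h in exact)
        # 1-based inclusive report: [501, 521]
        assert any((h.start + 1, h.end) == (501, 521) for h in exact)

    def test_absent_mature_yields_empty(self):
        rng = np.random.default_rng(32)
        assert find_pri_locations(random_seq(rng, 21), {"TR1": random_seq(rng, 400)}) == []

    def test_matches_brute_force_sliding_window(self):
        rng = np.random.default_rng(33)
        transcriptome = {f"TR{i}": random_seq(rng, 300) for i in range(5)}
        for _ in range(50):
            mature = random_seq(rng, 20)
            hits = find_pri_locations(mature, transcriptome, max_mismatch=2)
            expected = set()
            for tid, seq in transcriptome.items():
                for pat, orient in ((mature, "+"), (revcomp(mature), "-")):
                    for i in range(len(seq) - len(pat) + 1):
                        mm = sum(a != b for a, b in zip(seq[i : i + len(pat)], pat))
                        if mm <= 2:
                            expected.add((tid, i, orient))
            assert {(h.transcript_id, h.start, h.orientation) for h in hits} == expected


class TestAmfeMfei:
    def test_arithmetic(self):
        amfe, mfei = compute_amfe_mfei(-45.0, 100, 50.0)
        assert amfe == pytest.approx(-45.0)
        assert mfei == pytest.approx(-0.90)

    def test_zero_mfe(self):
        assert compute_amfe_mfei(0.0, 80, 40.0) == (0.0, 0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_amfe_mfei(-10.0, 0, 50.0)
        with pytest.raises(ValueError):
            compute_amfe_mfei(-10.0, 100, 0.0)

    @pytest.mark.parametrize(
        "trna",
        [
            # canonical cloverleaf controls (cytosolic tRNAs)
            "GCGGAUUUAGCUCAGUUGGGAGAGCGCCAGACUGAAGAUCUGGAGGUCCUGUGUUCGAUCCACAGAAUUCGCACCA",
            "GGGGCUAUAGCUCAGCUGGGAGAGCGCCUGCUUUGCACGCAGGAGGUCUGCGGUUCGAUCCCGCAUAGCUCCACCA",
        ],
    )
    def test_trna_control_near_benchmark(self, vienna, trna):
        """tRNA folds sit near the published MFEI benchmark of -0.64,
        well above the -0.85 hairpin acceptance bound."""
        structure, mfe = vienna.fold(trna)
        _, mfei = compute_amfe_mfei(mfe, len(trna), gc_percent(trna))
        assert mfei == pytest.approx(-0.64, abs=0.15)
        assert mfei > -0.85


class TestValidation:
    def test_planted_hairpins_validate_and_contain_planted_interval(self, study, vienna):
        recovered = 0
        for p in study.truth.planted_mirnas:
            t = study.transcripts[p.transcript_id]
            ms = t.index(p.mature)
            rec = extract_and_validate(p.transcript_id, t, (ms, ms + len(p.mature)), vienna)
            if rec is None:
                continue
            recovered += 1
            assert rec.mfei <= -0.85
            assert rec.start <= ms and ms + len(p.mature) <= rec.end
        assert recovered >= 0.9 * len(study.truth.planted_mirnas)

    def test_dinucleotide_shuffled_context_rarely_validates(self, study, vienna):
        """Shuffle-null: the hairpin context loses its precursor signal in
        at least 95% of dinucleotide-preserving shuffles."""
        p = study.truth.planted_mirnas[2]
        t = study.transcripts[p.transcript_id]
        rng = np.random.default_rng(71)
        accepted = 0
        n_shuffles = 100
        for _ in range(n_shuffles):
            shuffled = dinucleotide_shuffle(t, rng)
            ms = int(rng.integers(60, len(shuffled) - 90))
            rec = extract_and_validate("shuf", shuffled, (ms, ms + 21), vienna)
            accepted += rec is not None
        assert accepted <= 0.05 * n_shuffles

    def test_validated_records_satisfy_structure_constraints(self, result):
        assert result.precursors, "pipeline validated no precursors"
        for rec in result.precursors:
            assert 60 <= rec.length <= 300
            assert rec.mfe < 0
            assert len(rec.structure) == len(rec.sequence)
            amfe, mfei = compute_amfe_mfei(rec.mfe, rec.length, rec.gc_percent)
            assert amfe == pytest.approx(rec.amfe)
            assert mfei == pytest.approx(rec.mfei)
            assert rec.mfei <= -0.85


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Altschul-Erikson-style shuffle preserving dinucleotide counts,
    via a random walk over the dinucleotide multigraph."""
    edges = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        perm = rng.permutation(len(edges[a]))
        edges[a] = [edges[a][i] for i in perm]
    # random walk consuming edges; restart greedily on dead ends
    out = [seq[0]]
    counts = {a: 0 for a in edges}
    for _ in range(len(seq) - 1):
        a = out[-1]
        if counts.get(a, 0) >= len(edges.get(a, [])):
            # dead end: fall back to any unused edge source (rare)
            a = next(x for x in edges if counts[x] < len(edges[x]))
        out.append(edges[a][counts[a]])
        counts[a] += 1
    return "".join(out)


class TestStar:
    def _perfect_record(self, vienna):
        rng = np.random.default_rng(41)
        mature = random_seq(rng, 22)
        hairpin = "GATCG" + mature + "CAGAATTCAGAACAG" + revcomp(mature) + "CGATC"
        structure, mfe = vienna.fold(hairpin)
        ms = 5
        return PrecursorRecord(
            transcript_id="t", start=0, end=len(hairpin), sequence=hairpin,
            structure=structure, mfe=mfe, amfe=-40, mfei=-1.0, gc_percent=50,
            arm="5p", mature_start=ms, mature_end=ms + 22,
        )

    def test_perfect_stem_star_is_offset_reverse_complement(self, vienna):
        rec = self._perfect_record(vienna)
        star = predict_star(rec)
        assert star is not None
        s0, s1 = star
        mature = rec.mature_sequence
        star_seq = rec.sequence[s0:s1]
        # reverse complement shifted by 2 nt at each 3' end: the star's
        # last 20 nt pair mature positions 3.., and its first 2 nt are the
        # loop-side 3' overhang counterpart
        assert len(star_seq) == len(mature)
        assert star_seq[2:] == revcomp(mature[2:])

    def test_two_nt_overhang_geometry_on_accepted_duplexes(self, result):
        """Both duplex strands carry 2-nt 3' overhangs: the star's 3' end
        pairs with mature position 3 and vice versa."""
        checked = 0
        for rec in result.precursors:
            if rec.star_sequence is None or rec.star_start in (None, 0):
                continue
            pt = pair_table(rec.structure)
            ms, me = rec.mature_start, rec.mature_end
            s0, s1 = rec.star_start, rec.star_end
            if pt[s1 - 1] >= 0:
                assert pt[s1 - 1] == ms + 2
                checked += 1
            if pt[me - 1] >= 0:
                assert pt[me - 1] == s0 + 2
                checked += 1
        assert checked > 0

    def test_lower_count_strand_is_star(self, vienna):
        rec = self._perfect_record(vienna)
        star = predict_star(rec)
        from dataclasses import replace

        rec = replace(rec, star_start=star[0], star_end=star[1],
                      star_sequence=rec.sequence[star[0] : star[1]])
        reads = [
            CollapsedRead(rec.mature_sequence, (10, 0)),
            CollapsedRead(rec.star_sequence, (1, 0)),
        ]
        out = identify_star(rec, reads)
        assert out.mature_sequence == rec.mature_sequence  # 10:1 keeps labels
        assert not out.star_predicted_only
        # reversed abundance swaps the labels
        reads = [
            CollapsedRead(rec.mature_sequence, (1, 0)),
            CollapsedRead(rec.star_sequence, (10, 0)),
        ]
        swapped = identify_star(rec, reads)
        assert swapped.mature_sequence == rec.star_sequence

    def test_equal_counts_keep_five_prime_arm_mature(self, vienna):
        rec = self._perfect_record(vienna)
        star = predict_star(rec)
        from dataclasses import replace

        rec = replace(rec, star_start=star[0], star_end=star[1],
                      star_sequence=rec.sequence[star[0] : star[1]])
        reads = [
            CollapsedRead(rec.mature_sequence, (3, 0)),
            CollapsedRead(rec.star_sequence, (3, 0)),
        ]
        out = identify_star(rec, reads)
        assert out.arm == "5p"
        assert out.mature_sequence == rec.mature_sequence


def _rec(tid, start, end):
    n = end - start
    return PrecursorRecord(
        transcript_id=tid, start=start, end=end, sequence="A" * n,
        structure="." * n, mfe=-10, amfe=-10, mfei=-1, gc_percent=50,
        arm="5p", mature_start=0, mature_end=min(21, n),
    )


class TestClusters:
    def test_spacer_94(self):
        # 1-based intervals [100,200] and [295,400] -> 94-nt spacer
        clusters = detect_clusters([_rec("t", 99, 200), _rec("t", 294, 400)])
        assert len(clusters) == 1
        assert clusters[0].spacers == [94]
        assert not clusters[0].has_overlap

    def test_distinct_transcripts_no_cluster(self):
        assert detect_clusters([_rec("a", 0, 100), _rec("b", 0, 100)]) == []

    def test_overlapping_records_flagged_negative_spacer(self):
        clusters = detect_clusters([_rec("t", 0, 120), _rec("t", 100, 220)])
        assert clusters[0].has_overlap
        assert clusters[0].spacers == [-20]

    def test_pipeline_recovers_planted_cluster(self, study, result):
        clustered = [p for p in study.truth.planted_mirnas if p.cluster_id is not None]
        tid = clustered[0].transcript_id
        found = [c for c in result.clusters if c.transcript_id == tid]
        assert found, "planted polycistronic cluster not detected"
        assert len(found[0].records) >= 2
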