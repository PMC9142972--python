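"""Degradome analysis: profiles, duplex scoring, site finding, categories
and empirical p-values."""

import numpy as np
import pytest

from mirslice.degradome import (
    build_profiles, categorize_site, find_sites, score_duplex, site_pvalue,
    slice_position_1based, tplot_table,
)
from mirslice.types import DegradomeProfile, TargetSite
from mirslice.util import revcomp


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestProfiles:
    def test_single_read_at_position(self):
        rng = np.random.default_rng(61)
        t = random_seq(rng, 2000)
        read = t[1519:1539]  # 5' end at 1-based position 1520
        profiles, stats = build_profiles([read], {"TR1": t})
        assert profiles["TR1"].counts == {1520: 1}
        assert stats["mapping_rate"] == 1.0

    def test_multimapping_read_increments_both(self):
        rng = np.random.default_rng(62)
        core = random_seq(rng, 30)
        t1 = random_seq(rng, 100) + core + random_seq(rng, 50)
        t2 = random_seq(rng, 40) + core + random_seq(rng, 60)
        read = core[:20]
        profiles, _ = build_profiles([read], {"A": t1, "B": t2})
        assert profiles["A"].counts == {101: 1}
        assert profiles["B"].counts == {41: 1}

    def test_too_short_reads_skipped(self):
        profiles, stats = build_profiles(["ACGT"], {"TR1": "ACGT" * 30})
        assert profiles == {}
        assert stats["too_short"] == 1

    def test_simulated_counts_match_planted_allocation(self, study):
        profiles, _ = build_profiles(
            study.degradome, study.transcripts, study.config.degradome_read_len
        )
        # independent counting oracle over raw degradome reads
        from collections import Counter

        oracle = Counter()
        for _n, seq, _q in study.degradome:
            for tid, t in study.transcripts.items():
                start = 0
                while True:
                    i = t.find(seq[:20], start)
                    if i < 0:
                        break
                    oracle[(tid, i + 1)] += 1
                    start = i + 1
        got = {
            (tid, pos): c
            for tid, p in profiles.items()
            for pos, c in p.counts.items()
        }
        assert got == dict(oracle)


class TestDuplexScore:
    def test_perfect_complement_scores_zero(self):
        rng = np.random.default_rng(63)
        mir = random_seq(rng, 21)
        score, _ = score_duplex(mir, revcomp(mir))
        assert score == 0.0

    def test_wobble_penalty_position_dependent(self):
        mir = "T" + "A" * 20  # position 1 = U
        window = list(revcomp(mir))
        # target base facing miRNA position 1 is window[-1]
        window[-1] = "G"  # U:G wobble at position 1 -> 0.5
        assert score_duplex(mir, "".join(window))[0] == 0.5
        mir5 = "A" * 4 + "T" + "A" * 16  # position 5 = U
        window = list(revcomp(mir5))
        window[len(mir5) - 5] = "G"  # wobble at position 5 -> doubled
        assert score_duplex(mir5, "".join(window))[0] == 1.0

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(64)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(100):
            n = int(rng.integers(19, 25))
            mir, win = random_seq(rng, n), random_seq(rng, n)
            expected = 0.0
            for i in range(1, n + 1):
                t = win[n - i]
                if comp[mir[i - 1]] == t:
                    p = 0.0
                elif (mir[i - 1], t) in {("G", "T"), ("T", "G")}:
                    p = 0.5
                else:
                    p = 1.0
                expected += p * (2.0 if 2 <= i <= 13 else 1.0)
            assert score_duplex(mir, win)[0] == pytest.approx(expected)

    def test_length_mismatch_and_alphabet_errors(self):
        with pytest.raises(ValueError):
            score_duplex("ACGT" * 5, "ACGT" * 4)
        with pytest.raises(ValueError):
            score_duplex("ACGX" + "A" * 17, "ACGT" * 5 + "A")


class TestCategories:
    def test_hand_derived_table(self):
        p = DegradomeProfile("t", {50: 10, 300: 6, 450: 1, 451: 1})  # avg 4.5
        assert categorize_site(p, 50) == 0
        assert categorize_site(p, 300) == 2
        assert categorize_site(p, 450) == 4

    def test_two_positions_at_max_is_category_one(self):
        p = DegradomeProfile("t", {50: 10, 120: 10, 300: 2})
        assert categorize_site(p, 50) == 1

    def test_at_or_below_average_is_category_three(self):
        p = DegradomeProfile("t", {100: 2, 200: 5, 300: 5})  # avg 4
        assert categorize_site(p, 100) == 3

    def test_no_read_is_an_error(self):
        with pytest.raises(ValueError):
            categorize_site(DegradomeProfile("t", {10: 2}), 11)

    def test_adding_reads_at_slice_never_raises_category(self):
        rng = np.random.default_rng(65)
        base = {int(p): int(c) for p, c in zip(rng.integers(1, 500, 12), rng.integers(1, 8, 12))}
        pos = max(base)  # any profiled position
        prev = categorize_site(DegradomeProfile("t", dict(base)), pos)
        for _ in range(15):
            base[pos] += 1
            cat = categorize_site(DegradomeProfile("t", dict(base)), pos)
            assert cat <= prev
            prev = cat


class TestFindSites:
    def test_supported_site_emitted_at_exact_coordinate(self, study, result):
        from mirslice.pipeline import score_targets

        scores = score_targets(result, study.truth)
        assert scores["cat0_recovery"] == 1.0

    def test_good_score_without_degradome_reads_is_silent(self):
        rng = np.random.default_rng(66)
        mir = random_seq(rng, 21)
        t = random_seq(rng, 200) + revcomp(mir) + random_seq(rng, 100)
        # profile exists for the transcript but not at the slice position
        profiles = {"TR1": DegradomeProfile("TR1", {5: 3})}
        sites = find_sites("m", mir, {"TR1": t}, profiles)
        assert all(s.slice_pos_1based == 5 or s.count > 0 for s in sites)
        assert not any(s.slice_pos_1based == slice_position_1based(200, 21) for s in sites)

    def test_equals_exhaustive_window_enumeration(self):
        """Site finding over profiled positions equals a brute-force scan
        of every window on a small transcriptome."""
        rng = np.random.default_rng(67)
        transcriptome = {f"TR{i}": random_seq(rng, 400) for i in range(6)}
        mir = random_seq(rng, 21)
        # plant a perfect site and a near-site
        t = transcriptome["TR0"]
        transcriptome["TR0"] = t[:100] + revcomp(mir) + t[121:]
        profiles = {}
        for tid, t in transcriptome.items():
            counts = {int(p): int(c) for p, c in zip(rng.integers(1, 380, 30), rng.integers(1, 6, 30))}
            counts[slice_position_1based(100, 21)] = 9  # cover the planted site
            profiles[tid] = DegradomeProfile(tid, dict(sorted(counts.items())))
        got = find_sites("m", mir, transcriptome, profiles, max_score=7.0, multi_site=True)
        expected = []
        for tid, t in sorted(transcriptome.items()):
            for w0 in range(len(t) - 21 + 1):
                score = score_duplex(mir, t[w0 : w0 + 21])[0]
                if score > 7.0:
                    continue
                pos = slice_position_1based(w0, 21)
                if pos in profiles[tid].counts:
                    expected.append((tid, pos, score))
        assert [(s.transcript_id, s.slice_pos_1based, s.score) for s in got] == sorted(expected)

    def test_multi_site_mode_reports_double_site(self, study):
        from mirslice import degradome as deg

        double = {}
        for t in study.truth.planted_targets:
            double.setdefault((t.mature, t.transcript_id), []).append(t.slice_pos_1based)
        (pair, positions), = [x for x in double.items() if len(x[1]) == 2]
        mature, tid = pair
        profiles, _ = deg.build_profiles(
            study.degradome, study.transcripts, study.config.degradome_read_len
        )
        multi = deg.find_sites("m", mature, study.transcripts, profiles, multi_site=True)
        on_target = [s for s in multi if s.transcript_id == tid]
        assert {s.slice_pos_1based for s in on_target} >= set(positions)
        single = deg.find_sites("m", mature, study.transcripts, profiles, multi_site=False)
        assert len([s for s in single if s.transcript_id == tid]) == 1


class TestPvalue:
    def test_planted_site_significant(self, study, result):
        cat0 = [
            s for s in result.sites
            if s.category == 0 and any(
                t.transcript_id == s.transcript_id
                and t.slice_pos_1based == s.slice_pos_1based
                for t in study.truth.planted_targets
            )
        ]
        assert cat0
        p = site_pvalue(cat0[0], study.transcripts, result.degradome_profiles,
                        n_shuffles=100, seed=9)
        assert p <= 0.05

    def test_estimator_floor_and_determinism(self, study, result):
        site = result.sites[0]
        p1 = site_pvalue(site, study.transcripts, result.degradome_profiles,
                         n_shuffles=20, seed=4)
        p2 = site_pvalue(site, study.transcripts, result.degradome_profiles,
                         n_shuffles=20, seed=4)
        assert p1 == p2
        assert p1 >= 1 / 21


class TestTplot:
    def test_single_flagged_row(self):
        p = DegradomeProfile("t", {1520: 3})
        site = TargetSite("m", "A" * 21, "t", 1520, 0.0, "", 3, 0)
        table = tplot_table(p, site)
        assert len(table) == 1
        assert bool(table.iloc[0].is_slice_site)

    def test_window_filters_rows(self):
        p = DegradomeProfile("t", {100: 1, 1550: 2, 1700: 1})
        table = tplot_table(p, None, window=(1500, 1600))
        assert list(table.position) == [1550]
        empty = tplot_table(p, None, window=(2000, 2100))
        assert empty.empty
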