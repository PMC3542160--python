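import numpy as np
import pytest

from smallrna._seq import revcomp
from smallrna.degradome import (
    build_tplot,
    call_targets,
    categorize_cleavage,
    map_degradome_tags,
    profile_to_frame,
    scan_transcriptome,
    score_target_site,
)
from smallrna.synthetic_data import build_scenario, generate_degradome, random_seq

MIRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


def perfect_site(mirna: str) -> str:
    return revcomp(mirna)


def site_with_mismatch(mirna: str, position: int) -> str:
    """Flip the site base opposite 1-based miRNA ``position`` to a
    non-pairing, non-wobble base."""
    site = list(revcomp(mirna))
    idx = len(mirna) - position
    no_pair = {"A": "A", "C": "C", "G": "A", "T": "C"}
    site[idx] = no_pair[mirna[position - 1]]
    return "".join(site)


def site_with_wobble(mirna: str, position: int) -> str:
    site = list(revcomp(mirna))
    base = mirna[position - 1]
    assert base in "GT", "wobble requires G or U at the miRNA position"
    site[len(mirna) - position] = "T" if base == "G" else "G"
    return "".join(site)


class TestScoreTargetSite:
    def test_perfect_complement_scores_zero(self):
        assert score_target_site(MIRNA, perfect_site(MIRNA)).score == 0.0

    def test_single_mismatch_outside_core(self):
        assert score_target_site(MIRNA, site_with_mismatch(MIRNA, 15)).score == 1.0

    def test_wobble_in_core_doubled(self):
        # miRNA position 5 is G -> G:U wobble, 0.5 doubled in the 2-13 core
        assert MIRNA[4] == "G"
        assert score_target_site(MIRNA, site_with_wobble(MIRNA, 5)).score == 1.0

    def test_mismatch_in_core_doubled(self):
        assert score_target_site(MIRNA, site_with_mismatch(MIRNA, 5)).score == 2.0

    def test_wobble_outside_core(self):
        assert MIRNA[0] == "T"
        assert score_target_site(MIRNA, site_with_wobble(MIRNA, 1)).score == 0.5

    def test_site_bulge_costs_two(self):
        site = perfect_site(MIRNA)
        bulged = site[:3] + "A" + site[3:]  # extra transcript nt, non-core side
        score = score_target_site(MIRNA, bulged).score
        assert score in (2.0, 4.0)

    def test_window_length_out_of_range(self):
        with pytest.raises(ValueError):
            score_target_site(MIRNA, perfect_site(MIRNA)[:-2])

    def test_cleavage_position_opposite_position_10(self):
        aln = score_target_site(
            MIRNA, perfect_site(MIRNA), transcript_id="t", site_start=101
        )
        assert aln.site_end == 101 + len(MIRNA) - 1
        assert aln.cleavage_position == aln.site_end - 9


class TestScanTranscriptome:
    def test_planted_perfect_site_found(self, rng):
        transcript = random_seq(rng, 300) + perfect_site(MIRNA) + random_seq(rng, 300)
        hits = scan_transcriptome(MIRNA, {"t1": transcript}, 4.5)
        assert any(a.score == 0.0 and a.site_start == 301 for a in hits)

    def test_threshold_edge(self):
        site = list(perfect_site(MIRNA))
        # five 1.0-penalty mismatches outside the core -> score 5.0
        for pos in (15, 16, 17, 18, 19):
            site[len(MIRNA) - pos] = site_with_mismatch(MIRNA, pos)[len(MIRNA) - pos]
        transcript = "C" * 50 + "".join(site) + "C" * 50
        assert score_target_site(MIRNA, "".join(site)).score == 5.0
        at_5 = scan_transcriptome(MIRNA, {"t": transcript}, 5.0)
        at_45 = scan_transcriptome(MIRNA, {"t": transcript}, 4.5)
        assert any(a.site_start == 51 and a.score == 5.0 for a in at_5)
        assert not any(a.site_start == 51 and a.score == 5.0 for a in at_45)

    def test_matches_exhaustive_oracle(self, rng):
        def oracle(mirna, transcripts, threshold):
            found = set()
            for tid, seq in transcripts.items():
                for wlen in (len(mirna) - 1, len(mirna), len(mirna) + 1):
                    for start in range(len(seq) - wlen + 1):
                        aln = score_target_site(
                            mirna, seq[start : start + wlen],
                            transcript_id=tid, site_start=start + 1,
                        )
                        if aln.score <= threshold:
                            found.add((tid, start + 1, wlen, aln.score))
            return found

        mirna = random_seq(rng, 21)
        transcripts = {
            "t1": random_seq(rng, 400) + perfect_site(mirna) + random_seq(rng, 100),
            "t2": random_seq(rng, 500),
        }
        got = {
            (a.transcript_id, a.site_start, a.site_end - a.site_start + 1, a.score)
            for a in scan_transcriptome(mirna, transcripts, 7.5)
        }
        assert got == oracle(mirna, transcripts, 7.5)

    def test_sorted_output(self, rng):
        transcript = random_seq(rng, 200) + perfect_site(MIRNA) + random_seq(rng, 200)
        hits = scan_transcriptome(MIRNA, {"t": transcript}, 8.0)
        keys = [(a.score, a.transcript_id, a.site_start) for a in hits]
        assert keys == sorted(keys)


class TestTplot:
    def test_point_mass(self):
        profile = build_tplot("t", 200, {100: 10}, 10)
        assert profile.raw[99] == 10
        assert profile.tpb_at(100) == pytest.approx(1e9)

    def test_empty_coverage(self):
        profile = build_tplot("t", 50, {}, 10)
        assert profile.raw.sum() == 0

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            build_tplot("t", 50, {}, 0)

    def test_synthetic_profile_matches_generator_truth(self):
        scenario = build_scenario(5, n_mirnas=4, n_tas=1, n_targets=3, n_known=1)
        tags, truth = generate_degradome(scenario, 5, background_tag_rate=0.05)
        counts, total = map_degradome_tags(tags, scenario.transcripts)
        assert total >= truth["count"].sum()  # multi-mapping tags may add placements
        for tid, group in truth.groupby("transcript"):
            profile = build_tplot(
                tid, len(scenario.transcripts[tid]), counts.get(tid, {}), total
            )
            for row in group.itertuples():
                assert profile.raw[row.position - 1] >= row.count

    def test_tpb_conservation(self):
        scenario = build_scenario(5, n_mirnas=4, n_tas=1, n_targets=3, n_known=1)
        tags, _ = generate_degradome(scenario, 5, background_tag_rate=0.05)
        counts, total = map_degradome_tags(tags, scenario.transcripts)
        acc = 0.0
        for tid, pc in counts.items():
            profile = build_tplot(tid, len(scenario.transcripts[tid]), pc, total)
            acc += profile.tpb.sum()
        assert acc == pytest.approx(1e9)


class TestCategories:
    def _profile(self, counts, length=300):
        return build_tplot("t", length, counts, max(1, sum(counts.values())))

    def test_unique_max_is_category_0(self):
        assert categorize_cleavage(self._profile({100: 5}), 100) == 0

    def test_tied_max_is_category_1(self):
        profile = self._profile({100: 5, 200: 5})
        assert categorize_cleavage(profile, 100) == 1
        assert categorize_cleavage(profile, 200) == 1

    def test_single_read_is_category_4(self):
        profile = self._profile({100: 1, 200: 7})
        assert categorize_cleavage(profile, 100) == 4

    def test_above_median_below_max_is_category_2(self):
        profile = self._profile({50: 2, 100: 5, 150: 9, 200: 2})
        assert categorize_cleavage(profile, 100) == 2

    def test_at_or_below_median_is_category_3(self):
        profile = self._profile({50: 4, 100: 4, 150: 9, 200: 9, 250: 2})
        assert categorize_cleavage(profile, 100) == 3

    def test_no_tags_means_no_call(self):
        assert categorize_cleavage(self._profile({100: 5}), 150) is None

    def test_position_bounds(self):
        with pytest.raises(ValueError):
            categorize_cleavage(self._profile({10: 2}, length=50), 60)

    def test_total_and_exclusive_over_random_profiles(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 12))
            positions = rng.choice(np.arange(1, 200), size=n, replace=False)
            counts = {int(p): int(rng.integers(1, 20)) for p in positions}
            profile = self._profile(counts)
            for pos in counts:
                category = categorize_cleavage(profile, pos)
                assert category in (0, 1, 2, 3, 4)


class TestCallTargets:
    def test_planted_clean_signal_is_category_0(self, rng):
        mirna = random_seq(rng, 21)
        transcript = random_seq(rng, 150) + perfect_site(mirna) + random_seq(rng, 150)
        alns = scan_transcriptome(mirna, {"t": transcript}, 4.5, mirna_id="m")
        pos = alns[0].cleavage_position
        profile = build_tplot("t", len(transcript), {pos: 50}, 50)
        calls = call_targets(alns, {"t": profile})
        assert len(calls) == 1
        assert calls[0].category == 0 and calls[0].raw == 50

    def test_site_without_tags_produces_no_call(self, rng):
        mirna = random_seq(rng, 21)
        transcript = random_seq(rng, 100) + perfect_site(mirna) + random_seq(rng, 100)
        alns = scan_transcriptome(mirna, {"t": transcript}, 4.5, mirna_id="m")
        profile = build_tplot("t", len(transcript), {5: 3}, 3)
        calls = call_targets(alns, {"t": profile})
        assert all(c.alignment.site_start != 101 for c in calls)

    def test_one_row_per_mirna_transcript_cut(self, rng):
        mirna = random_seq(rng, 21)
        transcript = random_seq(rng, 100) + perfect_site(mirna) + random_seq(rng, 100)
        alns = scan_transcriptome(mirna, {"t": transcript}, 6.0, mirna_id="m")
        pos = next(a for a in alns if a.score == 0.0).cleavage_position
        profile = build_tplot("t", len(transcript), {pos: 30}, 30)
        calls = call_targets(alns, {"t": profile})
        keys = [(c.alignment.mirna_id, c.alignment.transcript_id, c.cleavage_position) for c in calls]
        assert len(keys) == len(set(keys))
        best = next(c for c in calls if c.cleavage_position == pos)
        assert best.alignment.score == 0.0


def test_profile_frame_roundtrip():
    profile = build_tplot("t", 10, {3: 4, 7: 1}, 5)
    frame = profile_to_frame(profile)
    assert frame.shape[0] == 10
    assert frame.loc[frame["position"] == 3, "raw"].iloc[0] == 4
    assert frame["tpb"].sum() == pytest.approx(1e9)
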