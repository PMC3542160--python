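import numpy as np
import pytest

from smallrna._seq import as_dna, revcomp
from smallrna.config import Thresholds
from smallrna.fold import fold
from smallrna.hairpin_discovery import (
    LocusCall,
    discover,
    evaluate_hairpin,
    extract_windows,
    locus_support,
    star_detection,
)
from smallrna.read_processing import GenomeHit, UniqueTag, collapse, map_tags
from smallrna.synthetic_data import (
    LibrarySpec,
    build_precursor,
    build_scenario,
    generate_srna_libraries,
    random_seq,
)


class TestExtractWindows:
    def test_three_windows_contain_tag(self, rng):
        genome = {"s1": "".join(rng.choice(list("ACGT"), size=2000))}
        tag = genome["s1"][1000:1021]
        hit = GenomeHit(tag, "s1", 1000, "+")
        windows = extract_windows(hit, genome, 150)
        assert len(windows) == 3
        for w in windows:
            assert w.sequence[w.tag_offset : w.tag_offset + 21] == tag

    def test_minus_strand_window_reverse_complemented(self, rng):
        genome = {"s1": "".join(rng.choice(list("ACGT"), size=2000))}
        tag = revcomp(genome["s1"][1000:1021])
        hit = GenomeHit(tag, "s1", 1000, "-")
        for w in extract_windows(hit, genome, 150):
            assert w.sequence[w.tag_offset : w.tag_offset + 21] == tag

    def test_clipped_near_scaffold_start(self, rng):
        genome = {"s1": "".join(rng.choice(list("ACGT"), size=600))}
        tag = genome["s1"][10:31]
        hit = GenomeHit(tag, "s1", 10, "+")
        for w in extract_windows(hit, genome, 150):
            assert w.start >= 0 and w.end <= 600
            assert w.sequence[w.tag_offset : w.tag_offset + 21] == tag

    def test_window_cap_respected(self, rng):
        genome = {"s1": "".join(rng.choice(list("ACGT"), size=3000))}
        hit = GenomeHit(genome["s1"][1500:1521], "s1", 1500, "+")
        for w in extract_windows(hit, genome, 300, window_cap=400):
            assert w.end - w.start <= 400

    def test_flank_too_small(self, rng):
        genome = {"s1": "A" * 500}
        hit = GenomeHit("A" * 21, "s1", 100, "+")
        with pytest.raises(ValueError, match="flank"):
            extract_windows(hit, genome, 10)

    def test_hit_outside_scaffold_is_error(self):
        genome = {"s1": "A" * 100}
        with pytest.raises(ValueError, match="outside"):
            extract_windows(GenomeHit("A" * 21, "s1", 95, "+"), genome, 150)

    def test_planted_precursor_inside_a_window(self, small_scenario):
        mirna = small_scenario.novel_mirnas[0]
        hit = GenomeHit(
            mirna.mature_seq,
            mirna.scaffold,
            mirna.mature_genome_start - 1,
            mirna.strand,
        )
        windows = extract_windows(hit, small_scenario.genome, 150)
        assert any(mirna.precursor_seq in w.sequence for w in windows)


class TestEvaluateHairpin:
    def test_perfect_stem_accepts_with_zero_stats(self, rng):
        mature = random_seq(rng, 21)
        precursor, offset, star, _ = build_precursor(rng, mature, mismatches=0)
        ev = evaluate_hairpin(fold(precursor), offset, 21)
        assert ev.accepted
        assert ev.mismatches <= 1  # fold noise may cost at most an edge position
        assert ev.bulges <= 1

    def test_catalog_duplex_accepts(self):
        # a published mature/star duplex pair: the duplex carries real
        # mismatches and a bulge but must stay within the 4/1 limits
        mature = as_dna("ACCUGGCUCUGAUACCAUAAC")
        star = as_dna("CGUGGUAUCAGAGUCAUGUUA")
        precursor = mature + "GAGAGAGAGAGAGAG" + star
        ev = evaluate_hairpin(fold(precursor), 0, len(mature))
        assert ev.accepted
        assert ev.arm == "5p"

    def test_planted_negative_controls_fail(self, small_scenario):
        thresholds = Thresholds()
        for mirna in small_scenario.mirnas:
            if not mirna.negative_control:
                continue
            hit = GenomeHit(
                mirna.mature_seq,
                mirna.scaffold,
                mirna.mature_genome_start - 1,
                mirna.strand,
            )
            for w in extract_windows(hit, small_scenario.genome, thresholds.flank):
                ev = evaluate_hairpin(fold(w.sequence), w.tag_offset, w.tag_length)
                assert not ev.accepted

    def test_unstructured_window_rejected(self):
        ev = evaluate_hairpin(fold("A" * 120), 50, 21)
        assert not ev.accepted
        assert ev.reason == "mature unpaired"

    def test_mature_interval_bounds_checked(self):
        with pytest.raises(ValueError):
            evaluate_hairpin(fold("ACGU" * 10), 30, 21)


class TestStarDetection:
    def _locus(self):
        return LocusCall(
            scaffold="s1",
            start=0,
            end=120,
            strand="+",
            mature_start=0,
            arm="5p",
            star_sequence="G" * 21,
            star_five_prime=60,
        )

    def test_exact_star_observed(self):
        reads = [GenomeHit("G" * 21, "s1", 60, "+")]
        observed, count, seq = star_detection(self._locus(), reads, {"G" * 21: 1})
        assert observed and count == 1 and seq == "G" * 21

    def test_no_star_reads(self):
        observed, count, _ = star_detection(self._locus(), [], {})
        assert not observed and count == 0

    def test_three_nt_offset_not_star_evidence(self):
        reads = [GenomeHit("G" * 21, "s1", 63, "+")]
        observed, _, _ = star_detection(self._locus(), reads, {"G" * 21: 5})
        assert not observed

    def test_one_nt_offset_is_star_evidence(self):
        reads = [GenomeHit("G" * 21, "s1", 61, "+")]
        observed, _, _ = star_detection(self._locus(), reads, {"G" * 21: 5})
        assert observed


class TestLocusSupport:
    def _reads(self, spec):
        return [GenomeHit(seq, "s1", i, "+") for i, seq in enumerate(spec)]

    def test_only_mature_reads(self):
        reads = self._reads(["M" * 21])
        pair, uniq = locus_support(reads, {"M" * 21: 10}, "M" * 21, set(), {"M" * 21})
        assert pair == 1.0 and uniq == 1.0

    def test_pair_fraction_passes_at_080(self):
        reads = self._reads(["M" * 21, "S" * 21, "O" * 21])
        counts = {"M" * 21: 60, "S" * 21: 20, "O" * 21: 20}
        pair, _ = locus_support(reads, counts, "M" * 21, {"S" * 21}, set())
        assert pair == pytest.approx(0.8)

    def test_pair_fraction_070_fails_rule(self):
        reads = self._reads(["M" * 21, "O" * 21])
        counts = {"M" * 21: 70, "O" * 21: 30}
        pair, _ = locus_support(reads, counts, "M" * 21, set(), set())
        assert pair == pytest.approx(0.70)
        assert not pair > Thresholds().pair_fraction

    def test_zero_reads_is_error(self):
        with pytest.raises(ValueError):
            locus_support([], {}, "M" * 21, set(), set())


@pytest.fixture(scope="module")
def clean_run():
    scenario = build_scenario(
        31, n_mirnas=6, n_tas=0, n_targets=0, n_negative=1, n_known=0
    )
    specs = [
        LibrarySpec(lib, depth=20_000, background_fraction=0.5)
        for lib in scenario.libraries
    ]
    reads, _ = generate_srna_libraries(scenario, specs, 31)
    tags = collapse(reads)
    hits = map_tags(tags, scenario.genome)
    calls = discover(tags, hits, scenario.genome)
    return scenario, tags, hits, calls


class TestDiscover:
    def test_all_planted_called_novel(self, clean_run):
        scenario, _, _, calls = clean_run
        planted = {m.mature_seq for m in scenario.novel_mirnas}
        novel = {c.mature for c in calls if c.klass == "novel"}
        assert planted <= novel

    def test_no_background_or_negative_calls(self, clean_run):
        scenario, _, _, calls = clean_run
        planted = {m.mature_seq for m in scenario.novel_mirnas}
        assert {c.mature for c in calls} == planted

    def test_classification_is_a_partition(self, clean_run):
        _, _, _, calls = clean_run
        assert all(c.klass in ("novel", "candidate") for c in calls)
        assert all((c.klass == "novel") == c.star_observed for c in calls)

    def test_star_suppressed_scenario_yields_candidates(self):
        scenario = build_scenario(
            32, n_mirnas=4, n_tas=0, n_targets=0, n_negative=0, n_known=0
        )
        for m in scenario.mirnas:
            m.star_fraction = 0.0
        specs = [
            LibrarySpec(lib, depth=20_000, background_fraction=0.4)
            for lib in scenario.libraries
        ]
        reads, _ = generate_srna_libraries(scenario, specs, 32)
        tags = collapse(reads)
        hits = map_tags(tags, scenario.genome)
        calls = discover(tags, hits, scenario.genome)
        planted = {m.mature_seq for m in scenario.novel_mirnas}
        called = {c.mature: c for c in calls}
        assert planted <= set(called)
        for seq in planted:
            assert called[seq].klass == "candidate"
            assert not called[seq].star_observed

    def test_low_pair_fraction_rejected(self, clean_run):
        scenario, tags, hits, _ = clean_run
        mirna = scenario.novel_mirnas[0]
        # flood the locus with a competing read inside the precursor span
        competitor = mirna.precursor_seq[24:45]
        extra = UniqueTag(competitor, {"root": 3 * sum(
            t.total for t in tags if t.sequence == mirna.mature_seq
        )})
        tags2 = list(tags) + [extra]
        hits2 = map_tags(tags2, scenario.genome)
        calls = discover(tags2, hits2, scenario.genome)
        assert mirna.mature_seq not in {c.mature for c in calls}
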