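import numpy as np
import pandas as pd
import pytest

from smallrna._seq import revcomp
from smallrna.config import Thresholds
from smallrna.fold import fold
from smallrna.hairpin_discovery import evaluate_hairpin
from smallrna.synthetic_data import (
    LibrarySpec,
    PlantedMirna,
    ToyGenomeSpec,
    build_precursor,
    build_scenario,
    generate_degradome,
    generate_genome,
    generate_srna_libraries,
    random_seq,
)


class TestSpecs:
    def test_scaffold_length_floor(self):
        with pytest.raises(ValueError):
            ToyGenomeSpec(scaffold_length=500)

    def test_gc_fraction_bounds(self):
        with pytest.raises(ValueError):
            ToyGenomeSpec(gc_fraction=1.5)

    def test_library_depth_floor(self):
        with pytest.raises(ValueError):
            LibrarySpec("x", depth=500)

    def test_background_fraction_bounds(self):
        with pytest.raises(ValueError):
            LibrarySpec("x", background_fraction=1.5)


class TestDeterminism:
    def test_identical_seed_identical_genome(self):
        a = build_scenario(21, n_mirnas=3, n_tas=1, n_targets=2, n_known=1)
        b = build_scenario(21, n_mirnas=3, n_tas=1, n_targets=2, n_known=1)
        assert a.genome == b.genome
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.transcripts == b.transcripts

    def test_identical_seed_identical_reads(self):
        scenario = build_scenario(22, n_mirnas=2, n_tas=0, n_targets=0, n_known=0)
        specs = [LibrarySpec(lib, depth=2000, background_fraction=0.5) for lib in scenario.libraries]
        r1, c1 = generate_srna_libraries(scenario, specs, 5)
        r2, c2 = generate_srna_libraries(scenario, specs, 5)
        assert r1 == r2
        pd.testing.assert_frame_equal(c1, c2)

    def test_identical_seed_identical_degradome(self):
        scenario = build_scenario(22, n_mirnas=2, n_tas=1, n_targets=2, n_known=1)
        t1, d1 = generate_degradome(scenario, 9, background_tag_rate=0.03)
        t2, d2 = generate_degradome(scenario, 9, background_tag_rate=0.03)
        assert t1 == t2
        pd.testing.assert_frame_equal(d1, d2)


class TestGenerateGenome:
    def test_truth_rows_and_reextraction(self, small_scenario):
        truth = small_scenario.truth
        assert len(truth) == len(small_scenario.mirnas) + len(small_scenario.tas_loci)
        for row in truth.itertuples():
            embedded = small_scenario.genome[row.scaffold][row.start - 1 : row.end]
            expected = row.sequence if row.strand == "+" else revcomp(row.sequence)
            assert embedded == expected

    def test_overlap_error_names_both_features(self, rng):
        mature = random_seq(rng, 21)
        precursor, offset, star, loop = build_precursor(rng, mature)
        def planted(name, start):
            return PlantedMirna(
                name=name, mature_seq=mature, star_seq=star, loop_seq=loop,
                precursor_seq=precursor, mature_offset=offset,
                duplex_mismatches=0, bulges=0, arm="5p",
                tissue_profile={}, scaffold="scaffold_1", start=start,
            )
        with pytest.raises(ValueError, match="mirA.*mirB|mirB.*mirA"):
            generate_genome(
                ToyGenomeSpec(seed=3),
                [planted("mirA", 2000), planted("mirB", 2030)],
            )

    def test_feature_must_fit_scaffold(self, rng):
        mature = random_seq(rng, 21)
        precursor, offset, star, loop = build_precursor(rng, mature)
        feature = PlantedMirna(
            name="m", mature_seq=mature, star_seq=star, loop_seq=loop,
            precursor_seq=precursor, mature_offset=offset,
            duplex_mismatches=0, bulges=0, arm="5p",
            tissue_profile={}, scaffold="scaffold_1", start=24_990,
        )
        with pytest.raises(ValueError, match="fit"):
            generate_genome(ToyGenomeSpec(seed=3), [feature])


class TestPlantedHairpins:
    def test_every_planted_mirna_passes_evaluation(self, small_scenario):
        from smallrna.synthetic_data import _evaluate_in_context

        thresholds = Thresholds()
        for mirna in small_scenario.mirnas:
            accepted, star_ok = _evaluate_in_context(
                mirna, small_scenario.genome, thresholds
            )
            if mirna.negative_control:
                assert not accepted
            else:
                assert accepted and star_ok

    def test_bare_precursor_duplex(self, rng):
        for mm in (0, 1, 2):
            mature = random_seq(rng, 21)
            precursor, offset, _, _ = build_precursor(rng, mature, mismatches=mm)
            ev = evaluate_hairpin(fold(precursor), offset, 21)
            # fold noise may add a stray mismatch or bulge; the planted
            # configuration must stay within the acceptance limits
            assert ev.mismatches <= mm + 2
            assert ev.bulges <= 1

    def test_mature_too_short_for_mismatches(self, rng):
        with pytest.raises(ValueError, match="too short"):
            build_precursor(rng, random_seq(rng, 20), mismatches=8)


class TestLibraries:
    def test_count_conservation(self, small_reads):
        reads, counts = small_reads
        for lib, lib_reads in reads.items():
            assert counts[counts["library"] == lib]["count"].sum() == len(lib_reads)

    def test_background_zero_maps_to_planted_only(self):
        scenario = build_scenario(23, n_mirnas=2, n_tas=0, n_targets=0, n_known=0)
        specs = [LibrarySpec(lib, depth=2000, background_fraction=0.0) for lib in scenario.libraries]
        reads, counts = generate_srna_libraries(scenario, specs, 23)
        feature_seqs = set()
        for m in scenario.mirnas:
            feature_seqs.update({m.mature_seq, m.star_seq})
        for lib_reads in reads.values():
            assert set(lib_reads) <= feature_seqs

    def test_length_mode_is_24(self, small_reads):
        reads, _ = small_reads
        lengths = pd.Series([len(r) for lib in reads.values() for r in lib])
        assert lengths.value_counts().idxmax() == 24

    def test_planted_counts_within_3_sigma(self):
        scenario = build_scenario(24, n_mirnas=6, n_tas=0, n_targets=0, n_known=0)
        depth = 50_000
        specs = [LibrarySpec(lib, depth=depth, background_fraction=0.3) for lib in scenario.libraries]
        _, counts = generate_srna_libraries(scenario, specs, 24)
        mature = counts[counts["kind"] == "mature"]
        for m in scenario.mirnas:
            observed = mature[mature["feature"] == m.name]["count"].sum()
            lam = sum(m.tissue_profile.values()) * depth / 1e6
            assert abs(observed - lam) <= 3 * np.sqrt(lam) + 1

    def test_adapter_appended_in_full(self):
        scenario = build_scenario(25, n_mirnas=2, n_tas=0, n_targets=0, n_known=0)
        specs = [LibrarySpec(lib, depth=1500, background_fraction=0.2) for lib in scenario.libraries]
        reads, _ = generate_srna_libraries(scenario, specs, 25, adapter="TGGAATTCTCGGGTG")
        for lib_reads in reads.values():
            assert all(r.endswith("TGGAATTCTCGGGTG") for r in lib_reads)


class TestDegradome:
    def test_no_background_all_tags_at_cleavage_positions(self):
        scenario = build_scenario(26, n_mirnas=3, n_tas=0, n_targets=2, n_known=0)
        tags, truth = generate_degradome(scenario, 26, background_tag_rate=0.0)
        assert set(truth["kind"]) == {"cleavage"}
        planted_positions = {
            (t.transcript_id, t.cleavage_pos) for t in scenario.targets
        }
        assert {(r.transcript, r.position) for r in truth.itertuples()} == planted_positions

    def test_tas_pileup_at_cleavage_pos(self):
        scenario = build_scenario(26, n_mirnas=3, n_tas=1, n_targets=0, n_known=1)
        _, truth = generate_degradome(scenario, 26, background_tag_rate=0.0)
        tas = scenario.tas_loci[0]
        row = truth[(truth["transcript"] == tas.name)]
        assert list(row["position"]) == [tas.cleavage_pos]
        assert row["count"].iloc[0] == tas.trigger_tag_count

    def test_depth_below_planted_total_is_error(self):
        scenario = build_scenario(26, n_mirnas=3, n_tas=0, n_targets=2, n_known=0)
        planted = sum(t.degradome_tag_count for t in scenario.targets)
        with pytest.raises(ValueError, match="depth"):
            generate_degradome(scenario, 26, depth=planted - 1)

    def test_no_planted_features_is_error(self):
        scenario = build_scenario(27, n_mirnas=2, n_tas=0, n_targets=0, n_known=0)
        with pytest.raises(ValueError, match="no planted"):
            generate_degradome(scenario, 27)

    def test_target_sites_respect_intended_scores(self):
        scenario = build_scenario(28, n_mirnas=4, n_tas=0, n_targets=5, n_known=0)
        for target in scenario.targets:
            assert target.achieved_align_score <= 5.0
            assert target.achieved_align_score == pytest.approx(
                target.intended_align_score, abs=0.51
            )
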