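import numpy as np
import pytest

from smallrna.config import PipelineConfig
from smallrna.read_processing import collapse, library_totals, map_tags
from smallrna.synthetic_data import (
    DEFAULT_ADAPTER,
    LibrarySpec,
    build_scenario,
    generate_degradome,
    generate_srna_libraries,
    mirna_references,
    write_degradome_fasta,
    write_fasta,
    write_reads_fasta,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_scenario():
    """A compact scenario shared across the suite (deterministic)."""
    return build_scenario(
        11, n_mirnas=6, n_tas=1, n_targets=4, n_negative=1, n_known=1
    )


@pytest.fixture(scope="session")
def small_library_specs(small_scenario):
    return [
        LibrarySpec(lib, depth=12_000, background_fraction=0.5)
        for lib in small_scenario.libraries
    ]


@pytest.fixture(scope="session")
def small_reads(small_scenario, small_library_specs):
    reads, counts = generate_srna_libraries(
        small_scenario, small_library_specs, seed=11
    )
    return reads, counts


@pytest.fixture(scope="session")
def small_mapping(small_scenario, small_reads):
    reads, _ = small_reads
    tags = collapse(reads)
    hits = map_tags(tags, small_scenario.genome)
    totals = library_totals(tags, hits)
    return tags, hits, totals


@pytest.fixture(scope="session")
def e2e_dataset(tmp_path_factory):
    """A small on-disk dataset plus its pipeline config."""
    out = tmp_path_factory.mktemp("e2e")
    scenario = build_scenario(
        7, n_mirnas=5, n_tas=1, n_targets=4, n_negative=1, n_known=1
    )
    specs = [
        LibrarySpec(lib, depth=8_000, background_fraction=0.5)
        for lib in scenario.libraries
    ]
    reads, counts = generate_srna_libraries(
        scenario, specs, seed=7, adapter=DEFAULT_ADAPTER
    )
    deg_tags, deg_truth = generate_degradome(scenario, 7, background_tag_rate=0.02)

    write_fasta(scenario.genome, out / "genome.fasta")
    write_fasta(scenario.transcripts, out / "transcripts.fasta")
    write_fasta(mirna_references(scenario.known_mirnas), out / "mirna_refs.fasta")
    write_degradome_fasta(deg_tags, out / "degradome.fasta")
    libraries = {}
    for lib, lib_reads in reads.items():
        path = out / f"{lib}.fasta"
        write_reads_fasta(lib_reads, path)
        libraries[lib] = str(path)
    config = PipelineConfig(
        genome=str(out / "genome.fasta"),
        libraries=libraries,
        mirna_reference=str(out / "mirna_refs.fasta"),
        transcriptome=str(out / "transcripts.fasta"),
        degradome=str(out / "degradome.fasta"),
        adapter=DEFAULT_ADAPTER,
        seed=7,
        outdir=str(out / "results"),
    )
    return {
        "scenario": scenario,
        "reads": reads,
        "counts": counts,
        "degradome_truth": deg_truth,
        "config": config,
        "dir": out,
    }


@pytest.fixture(scope="session")
def e2e_result(e2e_dataset):
    from smallrna.pipeline import run_pipeline

    return run_pipeline(e2e_dataset["config"])
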