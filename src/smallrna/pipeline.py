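"""End-to-end orchestration: preprocessing, known-family annotation,
hairpin discovery, degradome validation, phasing and processing stats,
with a run manifest and summary tallies.

Stages degrade gracefully: missing optional inputs (degradome,
intensities) skip their stages and are noted in the manifest; a stage
failure aborts with the stage name and a machine-readable error code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from ._seq import as_dna
from .config import PipelineConfig
from .degradome import (
    TranscriptProfile,
    build_tplot,
    call_targets,
    calls_to_table as target_calls_to_table,
    map_degradome_tags,
    profile_to_frame,
    scan_transcriptome,
)
from .hairpin_discovery import MirnaLocusCall, calls_to_gff3, calls_to_table, discover
from .known_annotation import annotate_tags, family_expression_table, load_references
from .phasing import PhasedRead, assign_registers, tissue_accumulation
from .phasing import profile_to_frame as register_profile_to_frame
from .processing_stats import processing_report, read_intensity_table
from .read_processing import (
    collapse,
    expand_collapsed,
    hits_to_bed,
    length_distribution,
    library_totals,
    load_genome,
    map_tags,
    normalize_rpm,
    preprocess_libraries,
    read_sequences,
)


class StageError(RuntimeError):
    """A pipeline stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineResult:
    stats: dict
    totals: dict[str, int]
    length_dist: pd.DataFrame
    family_table: pd.DataFrame | None
    mirna_calls: list[MirnaLocusCall]
    mirna_table: pd.DataFrame
    target_table: pd.DataFrame | None
    register_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    tissue_table: pd.DataFrame | None = None
    ape_table: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _load_reads(path: str) -> list[str]:
    return list(expand_collapsed(read_sequences(path)))


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage the configured inputs allow and write the result
    bundle under ``outdir`` (defaults to ``config.outdir``)."""
    config.validate()
    thr = config.thresholds
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
        "skipped": [],
    }

    # -- preprocessing -------------------------------------------------
    try:
        genome = load_genome(config.genome)
        raw = {lib: _load_reads(path) for lib, path in sorted(config.libraries.items())}
        adapter = config.adapter or None
        inserts, stats = preprocess_libraries(
            raw,
            adapter,
            min_overlap=thr.adapter_min_overlap,
            min_len=thr.min_len,
            max_len=thr.max_len,
        )
        tags = collapse(inserts)
        hits = map_tags(tags, genome)
        totals = library_totals(tags, hits)
        dist = length_distribution(tags, hits, min_len=thr.min_len, max_len=thr.max_len)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - surfaced with stage context
        raise StageError("preprocess", "input_error", str(exc)) from exc
    if not totals or all(v == 0 for v in totals.values()):
        raise StageError("preprocess", "no_genome_matched_reads", "rpm denominator is zero")
    libraries = sorted(raw)
    manifest["stages"]["preprocess"] = {
        "libraries": len(libraries),
        "unique_tags": len(tags),
        "mapped_tags": len(hits),
        "genome_matched_reads": {k: int(v) for k, v in sorted(totals.items())},
    }
    stats_payload = {lib: s.to_dict() for lib, s in stats.items()}
    (out / "library_stats.json").write_text(json.dumps(stats_payload, indent=2, sort_keys=True))
    dist.to_csv(out / "length_distribution.tsv", sep="\t", index=False)
    hits_to_bed(hits).to_csv(out / "genome_hits.bed", sep="\t", index=False, header=False)

    rpm = {
        t.sequence: {
            lib: normalize_rpm(t.counts.get(lib, 0), totals[lib]) for lib in libraries
        }
        for t in tags
        if t.sequence in hits
    }

    # -- known annotation ----------------------------------------------
    family_table = None
    exclude: set[str] = set()
    if config.mirna_reference or config.ncrna_reference:
        mirna_refs = load_references(config.mirna_reference) if config.mirna_reference else []
        ncrna_refs = load_references(config.ncrna_reference) if config.ncrna_reference else []
        assignments, removed, _ = annotate_tags(
            (t.sequence for t in tags if t.sequence in hits),
            ncrna_refs,
            mirna_refs,
            max_mismatches=thr.known_mismatches,
        )
        family_table = family_expression_table(assignments, rpm)
        family_table.to_csv(out / "known_families.tsv", sep="\t")
        exclude = set(assignments) | removed
        manifest["stages"]["annotate_known"] = {
            "assigned_tags": len(assignments),
            "removed_ncrna_tags": len(removed),
            "families": int(family_table.shape[0]),
        }
    else:
        manifest["skipped"].append("annotate_known")

    # -- hairpin discovery ---------------------------------------------
    calls = discover(tags, hits, genome, exclude=exclude, thresholds=thr)
    mirna_table = calls_to_table(calls, totals, libraries)
    mirna_table.to_csv(out / "mirna_calls.tsv", sep="\t", index=False)
    calls_to_table(calls, totals, libraries, round_rpm=False).to_csv(
        out / "mirna_calls_full_precision.tsv", sep="\t", index=False
    )
    calls_to_gff3(calls, out / "mirna_loci.gff3")
    manifest["stages"]["discover"] = {
        "calls": len(calls),
        "novel": sum(c.klass == "novel" for c in calls),
        "candidate": sum(c.klass == "candidate" for c in calls),
        "loci": sum(len(c.loci) for c in calls),
    }

    # -- degradome -----------------------------------------------------
    target_table = None
    register_tables: dict[str, pd.DataFrame] = {}
    tissue_table = None
    profiles: dict[str, TranscriptProfile] = {}
    if config.transcriptome and config.degradome:
        transcripts = {
            tid: as_dna(seq) for tid, seq in read_sequences(config.transcriptome)
        }
        deg_tags: dict[str, int] = {}
        for name, seq in read_sequences(config.degradome):
            mult = 1
            if "_x" in name and name.rsplit("_x", 1)[1].isdigit():
                mult = int(name.rsplit("_x", 1)[1])
            deg_tags[seq] = deg_tags.get(seq, 0) + mult
        position_counts, total_mapped = map_degradome_tags(deg_tags.items(), transcripts)
        if total_mapped == 0:
            raise StageError("degradome", "no_mapped_tags", "no degradome tag matched the transcriptome")
        profiles = {
            tid: build_tplot(tid, len(transcripts[tid]), position_counts.get(tid, {}), total_mapped)
            for tid in transcripts
        }
        queries: list[tuple[str, str, float]] = [
            (f"mir{i}", call.mature, thr.align_score_novel)
            for i, call in enumerate(calls, 1)
        ]
        if config.mirna_reference:
            queries.extend(
                (ref.name, ref.sequence, thr.align_score_known)
                for ref in load_references(config.mirna_reference)
            )
        alignments = []
        for mirna_id, seq, threshold in queries:
            alignments.extend(
                scan_transcriptome(seq, transcripts, threshold, mirna_id=mirna_id)
            )
        cleavage_calls = call_targets(alignments, profiles)
        target_table = target_calls_to_table(cleavage_calls)
        target_table.to_csv(out / "target_calls.tsv", sep="\t", index=False)
        tplot_dir = out / "tplots"
        tplot_dir.mkdir(exist_ok=True)
        for tid, profile in profiles.items():
            profile_to_frame(profile).to_csv(tplot_dir / f"{tid}.tsv", sep="\t", index=False)
        manifest["stages"]["degradome"] = {
            "transcripts": len(transcripts),
            "mapped_tag_total": int(total_mapped),
            "alignments": len(alignments),
            "cleavage_calls": len(cleavage_calls),
        }

        # -- phasing anchored at validated cleavage sites --------------
        tag21 = [t for t in tags if len(t.sequence) == 21]
        placed: dict[str, list[PhasedRead]] = {tid: [] for tid in transcripts}
        for tag in tag21:
            for tid, seq in transcripts.items():
                start = seq.find(tag.sequence)
                while start >= 0:
                    placed[tid].append(PhasedRead(start + 1, 21, tag.counts))
                    start = seq.find(tag.sequence, start + 1)
        reg_profiles = {}
        for call in cleavage_calls:
            tid = call.alignment.transcript_id
            # the tag pile-up position is the first nt of the 3' fragment,
            # i.e. the first nt of the first phased siRNA
            anchor = call.cleavage_position
            key = f"{tid}@{anchor}"
            if key in reg_profiles or not placed.get(tid):
                continue
            profile = assign_registers(placed[tid], anchor)
            if profile.total == 0:
                continue
            reg_profiles[key] = profile
            register_tables[key] = register_profile_to_frame(profile)
        if reg_profiles:
            tissue_table = tissue_accumulation(reg_profiles)
            tissue_table.to_csv(out / "phasing_tissue_accumulation.tsv", sep="\t", index=False)
            reg_dir = out / "register_profiles"
            reg_dir.mkdir(exist_ok=True)
            for key, frame in register_tables.items():
                frame.to_csv(reg_dir / f"{key.replace('@', '_')}.tsv", sep="\t", index=False)
        manifest["stages"]["phasing"] = {"anchors": len(reg_profiles)}
    else:
        manifest["skipped"].extend(["degradome", "phasing"])

    # -- processing statistics -----------------------------------------
    ape_table = None
    if config.intensities:
        records = read_intensity_table(config.intensities)
        ape_table, summary = processing_report(records)
        ape_table.to_csv(out / "processing_efficiency.tsv", sep="\t", index=False)
        manifest["stages"]["processing_stats"] = {"samples": len(records), **summary}
    else:
        manifest["skipped"].append("processing_stats")

    summary = summarize_counts(mirna_table, target_table)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_yaml(out / "config.yaml")

    return PipelineResult(
        stats=stats_payload,
        totals=totals,
        length_dist=dist,
        family_table=family_table,
        mirna_calls=calls,
        mirna_table=mirna_table,
        target_table=target_table,
        register_tables=register_tables,
        tissue_table=tissue_table,
        ape_table=ape_table,
        manifest=manifest,
    )


# ----------------------------------------------------------------------
# Summary tallies
# ----------------------------------------------------------------------

NO_STAR = "None detected"


def summarize_mirna_table(table: pd.DataFrame) -> dict:
    """Tallies over a catalog-style miRNA table.

    Star detection is read from the ``star_sequence`` column (the string
    ``"None detected"`` means no star); sequence lengths are measured
    from the printed sequence, not trusted from a length column. Tissue
    rpm columns are those named ``rpm_<library>`` (``rpm_total``
    excluded); per-row totals are their sums.
    """
    if table.empty:
        return {
            "entries": 0, "novel": 0, "candidate": 0,
            "length_counts": {}, "star_detected": 0, "loci": 0, "row_totals": {},
        }
    star = table["star_sequence"].fillna(NO_STAR).astype(str) != NO_STAR
    lengths = table["sequence"].astype(str).str.len()
    rpm_cols = [
        c for c in table.columns if c.startswith("rpm_") and c != "rpm_total"
    ]
    row_totals = table[rpm_cols].sum(axis=1) if rpm_cols else pd.Series(dtype=float)
    loci = (
        int(table["n_loci"].sum()) if "n_loci" in table.columns else int(table.shape[0])
    )
    return {
        "entries": int(table.shape[0]),
        "novel": int(star.sum()),
        "candidate": int((~star).sum()),
        "star_detected": int(star.sum()),
        "length_counts": {
            int(k): int(v) for k, v in lengths.value_counts().sort_index().items()
        },
        "loci": loci,
        "row_totals": {
            str(m): float(t) for m, t in zip(table["mirna"], row_totals)
        },
    }


def summarize_target_table(table: pd.DataFrame | None) -> dict:
    if table is None or table.empty:
        return {"rows": 0, "distinct_targets": 0, "distinct_mirnas": 0, "category_counts": {}}
    return {
        "rows": int(table.shape[0]),
        "distinct_targets": int(table["target_gene"].nunique()),
        "distinct_mirnas": int(table["mirna"].nunique()),
        "category_counts": {
            int(k): int(v)
            for k, v in table["category"].value_counts().sort_index().items()
        },
    }


def summarize_counts(
    mirna_table: pd.DataFrame, target_table: pd.DataFrame | None = None
) -> dict:
    """Summary JSON over the result tables (class tallies, per-length
    counts, star detection, loci, target counts)."""
    return {
        "mirna": summarize_mirna_table(mirna_table),
        "targets": summarize_target_table(target_table),
    }
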