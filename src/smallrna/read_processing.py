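"""Read preprocessing: adapter trimming, collapsing, exact genome mapping,
reads-per-million normalisation and length-distribution profiling.

The mapping contract is exactness: a tag is reported at all and only the
genomic positions where it (or its reverse complement, for minus-strand
hits) occurs as a perfect full-length substring. Reads that never match
the genome are kept in the tag set but excluded from the rpm denominator,
which is the per-library total of perfectly genome-matched redundant
reads.

Coordinates are 0-based half-open internally; emitted tables are 1-based
inclusive. Minus-strand hits report the start of the match on the forward
strand.
"""

from __future__ import annotations

import gzip
import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import as_dna, has_degenerate, revcomp

MIN_TAG_LEN = 15
MAX_TAG_LEN = 31


class TrimStatus(Enum):
    OK = "ok"
    NO_ADAPTER = "no_adapter"
    TOO_SHORT = "too_short"
    TOO_LONG = "too_long"


@dataclass(frozen=True)
class TrimResult:
    status: TrimStatus
    insert: str | None = None


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeHit:
    """One exact full-length genomic occurrence of a tag.

    ``start`` is the 0-based forward-strand start of the matched interval
    regardless of strand; the matched interval is [start, start+len).
    """

    tag: str
    scaffold: str
    start: int
    strand: str

    @property
    def end(self) -> int:
        return self.start + len(self.tag)

    @property
    def five_prime(self) -> int:
        """0-based forward-strand coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class LibraryStats:
    library: str
    raw_reads: int = 0
    adapter_found: int = 0
    length_filtered: int = 0
    genome_matched: int = 0  # rpm denominator (redundant reads)

    def to_dict(self) -> dict:
        return {
            "library": self.library,
            "raw_reads": self.raw_reads,
            "adapter_found": self.adapter_found,
            "length_filtered": self.length_filtered,
            "genome_matched": self.genome_matched,
        }


# ----------------------------------------------------------------------
# FASTA / FASTQ input
# ----------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[tuple[str, str]]:
    """Yield (read id, DNA sequence) from FASTA or FASTQ, plain or gzip.

    Collapsed-count headers of the form ``name_xCOUNT`` are recognised by
    :func:`expand_collapsed`; this function yields records verbatim.
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, as_dna(str(record.seq))


def expand_collapsed(records: Iterable[tuple[str, str]]) -> Iterator[str]:
    """Expand ``..._xCOUNT`` collapsed headers into redundant reads."""
    for name, seq in records:
        mult = 1
        if "_x" in name:
            tail = name.rsplit("_x", 1)[1]
            if tail.isdigit():
                mult = int(tail)
        for _ in range(mult):
            yield seq


def write_collapsed_fasta(tags: Sequence[UniqueTag], path: str | Path) -> None:
    """Write tags as collapsed FASTA (``>tag_N_xCOUNT`` headers, total counts)."""
    with open(path, "w") as out:
        for i, tag in enumerate(sorted(tags, key=lambda t: (-t.total, t.sequence)), 1):
            out.write(f">tag_{i}_x{tag.total}\n{tag.sequence}\n")


# ----------------------------------------------------------------------
# Trimming and collapsing
# ----------------------------------------------------------------------

def trim_adapter(
    read: str,
    adapter: str,
    *,
    min_overlap: int = 6,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> TrimResult:
    """Cut the insert preceding the leftmost 3' adapter occurrence.

    A full adapter match anywhere wins; otherwise a suffix of the read
    matching a prefix of the adapter of at least ``min_overlap`` nt counts
    as adapter evidence at the read end. Reads without adapter evidence
    are rejected (status ``NO_ADAPTER``); inserts outside
    [min_len, max_len] are rejected with a length status.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = as_dna(read)
    adapter = as_dna(adapter)
    idx = read.find(adapter)
    if idx < 0:
        idx = -1
        for k in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
            if read.endswith(adapter[:k]):
                idx = len(read) - k
                break
        if idx < 0:
            return TrimResult(TrimStatus.NO_ADAPTER)
    insert = read[:idx]
    if len(insert) < min_len:
        return TrimResult(TrimStatus.TOO_SHORT)
    if len(insert) > max_len:
        return TrimResult(TrimStatus.TOO_LONG)
    return TrimResult(TrimStatus.OK, insert)


def collapse(reads_by_library: Mapping[str, Iterable[str]]) -> list[UniqueTag]:
    """Collapse redundant reads into unique tags with per-library counts."""
    counts: dict[str, Counter] = defaultdict(Counter)
    for library, reads in reads_by_library.items():
        for read in reads:
            counts[as_dna(read)][library] += 1
    return [UniqueTag(seq, dict(c)) for seq, c in sorted(counts.items())]


# ----------------------------------------------------------------------
# Exact genome mapping
# ----------------------------------------------------------------------

def load_genome(path: str | Path) -> dict[str, str]:
    with _open_text(path) as handle:
        return {r.id: as_dna(str(r.seq)) for r in SeqIO.parse(handle, "fasta")}


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    start = haystack.find(needle)
    while start >= 0:
        yield start
        start = haystack.find(needle, start + 1)


_SEED_LEN = 14  # <= minimum tag length, used for the lookup index


def _build_seed_index(genome: Mapping[str, str]) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for scaffold, ref in genome.items():
        for pos in range(len(ref) - _SEED_LEN + 1):
            index[ref[pos : pos + _SEED_LEN]].append((scaffold, pos))
    return index


def map_tags(
    tags: Sequence[UniqueTag | str], genome: Mapping[str, str]
) -> dict[str, list[GenomeHit]]:
    """Report every exact full-length occurrence of each tag, both strands.

    Returns a mapping ``tag sequence -> hits`` containing only tags with at
    least one hit. Tags containing degenerate bases are skipped with a
    warning. Matching is seed-and-verify over a 14-mer index; tags
    shorter than the seed fall back to a direct scan.
    """
    index = _build_seed_index(genome)
    hits: dict[str, list[GenomeHit]] = {}
    for tag in tags:
        seq = tag if isinstance(tag, str) else tag.sequence
        if has_degenerate(seq):
            warnings.warn(f"skipping degenerate tag {seq}", stacklevel=2)
            continue
        found: list[GenomeHit] = []
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            if strand == "-" and query == seq:
                # palindromic tag: forward matches cover both strands
                found.extend(
                    [GenomeHit(seq, h.scaffold, h.start, "-") for h in found]
                )
                break
            if len(query) >= _SEED_LEN:
                for scaffold, pos in index.get(query[:_SEED_LEN], ()):
                    ref = genome[scaffold]
                    if ref[pos : pos + len(query)] == query:
                        found.append(GenomeHit(seq, scaffold, pos, strand))
            else:
                for scaffold, ref in genome.items():
                    for pos in _find_all(ref, query):
                        found.append(GenomeHit(seq, scaffold, pos, strand))
        if found:
            hits[seq] = sorted(found, key=lambda h: (h.scaffold, h.start, h.strand))
    return hits


# ----------------------------------------------------------------------
# Normalisation and profiling
# ----------------------------------------------------------------------

def normalize_rpm(count: float, genome_matched_total: int) -> float:
    """Reads per million: count * 1e6 / library genome-matched total."""
    if genome_matched_total <= 0:
        raise ValueError("genome-matched total must be positive")
    return count * 1_000_000 / genome_matched_total


def library_totals(
    tags: Sequence[UniqueTag], hits: Mapping[str, list[GenomeHit]]
) -> dict[str, int]:
    """Per-library genome-matched redundant read totals (rpm denominators)."""
    totals: Counter = Counter()
    for tag in tags:
        if tag.sequence in hits:
            totals.update(tag.counts)
    return dict(totals)


def length_distribution(
    tags: Sequence[UniqueTag],
    hits: Mapping[str, list[GenomeHit]],
    *,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> pd.DataFrame:
    """Per-length redundant/unique counts split by genome-matched status.

    Returns a tidy frame with one row per (library, length, matched) and
    columns ``redundant`` / ``unique``.
    """
    rows: dict[tuple[str, int, bool], list[int]] = defaultdict(lambda: [0, 0])
    for tag in tags:
        matched = tag.sequence in hits
        for library, count in tag.counts.items():
            cell = rows[(library, len(tag.sequence), matched)]
            cell[0] += count
            cell[1] += 1
    records = [
        {"library": lib, "length": ln, "matched": m, "redundant": red, "unique": uniq}
        for (lib, ln, m), (red, uniq) in sorted(rows.items())
        if min_len <= ln <= max_len
    ]
    return pd.DataFrame(
        records, columns=["library", "length", "matched", "redundant", "unique"]
    )


def length_percentages(dist: pd.DataFrame, column: str = "redundant") -> pd.DataFrame:
    """Per-library percentage of each length class; sums to 100 per library."""
    total = dist.groupby("library")[column].transform("sum")
    out = dist[["library", "length", "matched"]].copy()
    out["percent"] = dist[column] * 100.0 / total
    return out


# ----------------------------------------------------------------------
# End-to-end library preprocessing
# ----------------------------------------------------------------------

def preprocess_libraries(
    raw_reads: Mapping[str, Iterable[str]],
    adapter: str | None,
    *,
    min_overlap: int = 6,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> tuple[dict[str, list[str]], dict[str, LibraryStats]]:
    """Trim and length-filter every library; pass ``adapter=None`` for
    pre-trimmed input (length filter still applies)."""
    inserts: dict[str, list[str]] = {}
    stats: dict[str, LibraryStats] = {}
    for library, reads in raw_reads.items():
        st = LibraryStats(library)
        kept: list[str] = []
        for read in reads:
            st.raw_reads += 1
            if adapter is None:
                read = as_dna(read)
                st.adapter_found += 1
                if min_len <= len(read) <= max_len:
                    st.length_filtered += 1
                    kept.append(read)
                continue
            result = trim_adapter(
                read, adapter, min_overlap=min_overlap, min_len=min_len, max_len=max_len
            )
            if result.status is not TrimStatus.NO_ADAPTER:
                st.adapter_found += 1
            if result.status is TrimStatus.OK:
                st.length_filtered += 1
                kept.append(result.insert)
        inserts[library] = kept
        stats[library] = st
    return inserts, stats


def hits_to_bed(hits: Mapping[str, list[GenomeHit]]) -> pd.DataFrame:
    """All hits as a BED-like frame (0-based half-open)."""
    rows = [
        {
            "chrom": h.scaffold,
            "start": h.start,
            "end": h.end,
            "name": h.tag,
            "score": 0,
            "strand": h.strand,
        }
        for hitlist in hits.values()
        for h in hitlist
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def write_stats_json(stats: Mapping[str, LibraryStats], totals: Mapping[str, int], path: str | Path) -> None:
    payload = {
        lib: {**st.to_dict(), "genome_matched": int(totals.get(lib, 0))}
        for lib, st in stats.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
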