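"""miRNA target prediction by complementarity scoring and degradome
validation with per-transcript t-plots and category 0-4 calls.

Scoring follows the classic plant target-prediction scheme: the miRNA is
aligned 5'->3' against the reverse-complement sense of the site, each
mismatch costs 1, each G:U wobble 0.5 and each bulged nucleotide 2 (at
most one bulge per site), with penalties doubled inside the 5' core
(miRNA positions 2-13, position 1 being the miRNA 5' end). Degradome
tags are 5' ends of cleaved transcripts; the call for an alignment is
made at the transcript nucleotide pairing miRNA position 10 (slicing
between positions 10 and 11) and classified against the transcript-wide
tag distribution:

    no tags at the site      -> no call
    exactly one tag          -> category 4
    site is the unique max   -> category 0
    site ties the max        -> category 1
    above the median of
    covered positions        -> category 2
    otherwise                -> category 3
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import as_dna, pairs_wobble, revcomp

#: 1-based miRNA core positions with doubled penalties
CORE_START, CORE_END = 2, 13

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0


@dataclass(frozen=True)
class TargetAlignment:
    mirna: str  # miRNA sequence (DNA alphabet)
    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based, inclusive
    site_end: int
    score: float
    alignment: str  # pairing string, miRNA 5'->3': '|' pair, 'o' wobble, '.' mismatch, '-' gap

    @property
    def cleavage_position(self) -> int:
        """1-based transcript coordinate opposite miRNA position 10."""
        # walk the alignment from the miRNA 5' end (= site 3' end)
        pos = self.site_end
        mirna_pos = 0
        for symbol in self.alignment:
            if symbol == "-":
                pos -= 1  # bulged transcript nucleotide
                continue
            mirna_pos += 1
            if symbol == "+":
                continue  # bulged miRNA nucleotide consumes no site base
            if mirna_pos == 10:
                return pos
            pos -= 1
        raise ValueError("alignment shorter than 10 miRNA positions")


@dataclass
class TranscriptProfile:
    """Per-position degradome tag counts for one transcript."""

    transcript_id: str
    raw: np.ndarray  # 1-based positions stored at index pos-1
    total_mapped: int  # library-wide mapped-tag denominator

    @property
    def tpb(self) -> np.ndarray:
        if self.total_mapped <= 0:
            raise ValueError("zero mapped degradome tags")
        return self.raw * 1e9 / self.total_mapped

    def tpb_at(self, position: int) -> float:
        return float(self.raw[position - 1]) * 1e9 / self.total_mapped


@dataclass(frozen=True)
class CleavageCall:
    alignment: TargetAlignment
    cleavage_position: int
    raw: int
    tpb: float
    category: int


# ----------------------------------------------------------------------
# Complementarity scoring
# ----------------------------------------------------------------------

def _position_weight(mirna_pos: int) -> float:
    return 2.0 if CORE_START <= mirna_pos <= CORE_END else 1.0


def _align_no_gap(mirna: str, site_rc: str) -> tuple[float, str]:
    score = 0.0
    symbols = []
    for i, (m, t) in enumerate(zip(mirna, site_rc), start=1):
        if m == t:
            symbols.append("|")
            continue
        if pairs_wobble(m, revcomp(t)):
            score += WOBBLE_PENALTY * _position_weight(i)
            symbols.append("o")
        else:
            score += MISMATCH_PENALTY * _position_weight(i)
            symbols.append(".")
    return score, "".join(symbols)


def _align_site_bulge(mirna: str, site_rc: str) -> tuple[float, str]:
    """Site one nt longer than the miRNA: one bulged transcript base."""
    best, best_sym = float("inf"), ""
    n = len(mirna)
    for gap in range(n + 1):  # bulge after miRNA position `gap`
        reduced = site_rc[:gap] + site_rc[gap + 1 :]
        score, sym = _align_no_gap(mirna, reduced)
        weight = _position_weight(min(max(gap, 1), n))
        score += GAP_PENALTY * weight
        if score < best:
            best = score
            best_sym = sym[:gap] + "-" + sym[gap:]
    return best, best_sym


def _align_mirna_bulge(mirna: str, site_rc: str) -> tuple[float, str]:
    """Site one nt shorter than the miRNA: one bulged miRNA base."""
    best, best_sym = float("inf"), ""
    for gap in range(len(mirna)):
        reduced = mirna[:gap] + mirna[gap + 1 :]
        score, sym = _align_no_gap(reduced, site_rc)
        score += GAP_PENALTY * _position_weight(gap + 1)
        if score < best:
            best = score
            best_sym = sym[:gap] + "+" + sym[gap:]
    return best, best_sym


def score_target_site(
    mirna: str,
    window: str,
    *,
    mirna_id: str = "",
    transcript_id: str = "",
    site_start: int = 1,
) -> TargetAlignment:
    """Score a miRNA against one transcript window.

    The window length must be within one nt of the miRNA length; the
    length difference decides whether a single bulge (penalty 2, doubled
    in the core) is placed on the transcript or the miRNA side.
    """
    mirna = as_dna(mirna)
    window = as_dna(window)
    delta = len(window) - len(mirna)
    if abs(delta) > 1:
        raise ValueError("window length must be within 1 nt of the miRNA length")
    site_rc = revcomp(window)
    if delta == 0:
        score, sym = _align_no_gap(mirna, site_rc)
    elif delta == 1:
        score, sym = _align_site_bulge(mirna, site_rc)
    else:
        score, sym = _align_mirna_bulge(mirna, site_rc)
    return TargetAlignment(
        mirna,
        mirna_id,
        transcript_id,
        site_start,
        site_start + len(window) - 1,
        score,
        sym,
    )


def scan_transcriptome(
    mirna: str,
    transcripts: Mapping[str, str],
    threshold: float,
    *,
    mirna_id: str = "",
) -> list[TargetAlignment]:
    """All windows scoring at or below ``threshold``, ties kept.

    Windows of miRNA length and of length +/- 1 nt (one bulge) are
    scanned at every transcript position; results are sorted by
    (score, transcript id, position).
    """
    mirna = as_dna(mirna)
    out: list[TargetAlignment] = []
    for tid in sorted(transcripts):
        seq = as_dna(transcripts[tid])
        for wlen in (len(mirna) - 1, len(mirna), len(mirna) + 1):
            if wlen < 1:
                continue
            for start in range(len(seq) - wlen + 1):
                aln = score_target_site(
                    mirna,
                    seq[start : start + wlen],
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    site_start=start + 1,
                )
                if aln.score <= threshold:
                    out.append(aln)
    out.sort(key=lambda a: (a.score, a.transcript_id, a.site_start))
    return out


# ----------------------------------------------------------------------
# Degradome t-plots
# ----------------------------------------------------------------------

def map_degradome_tags(
    tags: Iterable[tuple[str, int]], transcripts: Mapping[str, str]
) -> tuple[dict[str, Counter], int]:
    """Map degradome tags to transcripts by exact prefix match.

    ``tags`` yields (sequence, count). A tag's 5' end marks the first
    transcript nucleotide of the cleaved fragment; every exact occurrence
    receives the full count. Returns per-transcript position counts
    (1-based) and the total placed count (the tpb denominator).
    """
    seqs = {tid: as_dna(seq) for tid, seq in transcripts.items()}
    counts: dict[str, Counter] = defaultdict(Counter)
    total = 0
    for tag, n in tags:
        tag = as_dna(tag)
        for tid, seq in seqs.items():
            start = seq.find(tag)
            while start >= 0:
                counts[tid][start + 1] += n
                total += n
                start = seq.find(tag, start + 1)
    return counts, total


def build_tplot(
    transcript_id: str,
    length: int,
    position_counts: Mapping[int, int],
    total_mapped: int,
) -> TranscriptProfile:
    """Per-position degradome profile for one transcript.

    ``position_counts`` maps 1-based 5'-end positions to raw tag counts;
    ``total_mapped`` is the library-wide mapped total used for tpb.
    """
    if total_mapped <= 0:
        raise ValueError("zero mapped degradome tags")
    raw = np.zeros(length, dtype=np.int64)
    for pos, n in position_counts.items():
        if not 1 <= pos <= length:
            raise ValueError(f"position {pos} outside transcript {transcript_id}")
        raw[pos - 1] = n
    return TranscriptProfile(transcript_id, raw, total_mapped)


def categorize_cleavage(profile: TranscriptProfile, position: int) -> int | None:
    """Category 0-4 for the signal at ``position``; None when untagged."""
    if not 1 <= position <= profile.raw.shape[0]:
        raise ValueError("cleavage position outside transcript")
    r = int(profile.raw[position - 1])
    if r == 0:
        return None
    if r == 1:
        return 4
    covered = profile.raw[profile.raw > 0]
    maximum = int(covered.max())
    median = float(np.median(covered))
    if r == maximum:
        return 0 if int((profile.raw == maximum).sum()) == 1 else 1
    if r > median:
        return 2
    return 3


def call_targets(
    alignments: Sequence[TargetAlignment],
    profiles: Mapping[str, TranscriptProfile],
) -> list[CleavageCall]:
    """Emit a cleavage call for every alignment with degradome evidence.

    The cleavage position is the transcript nucleotide opposite miRNA
    position 10; alignments with no tag there produce no call
    (prediction-only sites stay in the alignment list). Overlapping
    windows pointing at the same cut site collapse to the best-scoring
    alignment, so the output has one row per (miRNA, transcript, cut).
    """
    best: dict[tuple[str, str, int], CleavageCall] = {}
    for aln in alignments:
        profile = profiles.get(aln.transcript_id)
        if profile is None:
            continue
        pos = aln.cleavage_position
        category = categorize_cleavage(profile, pos)
        if category is None:
            continue
        call = CleavageCall(
            aln, pos, int(profile.raw[pos - 1]), profile.tpb_at(pos), category
        )
        key = (aln.mirna_id, aln.transcript_id, pos)
        held = best.get(key)
        if held is None or aln.score < held.alignment.score:
            best[key] = call
    return sorted(
        best.values(),
        key=lambda c: (c.alignment.mirna_id, c.alignment.transcript_id, c.cleavage_position),
    )


def calls_to_table(calls: Sequence[CleavageCall], annotations: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Target-table-style frame: miRNA, target gene, align score, tpb,
    category, annotation passthrough."""
    annotations = annotations or {}
    rows = [
        {
            "mirna": c.alignment.mirna_id,
            "target_gene": c.alignment.transcript_id,
            "align_score": c.alignment.score,
            "cleavage_position": c.cleavage_position,
            "tpb": round(c.tpb, 1),
            "category": c.category,
            "annotation": annotations.get(c.alignment.transcript_id, ""),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "target_gene",
            "align_score",
            "cleavage_position",
            "tpb",
            "category",
            "annotation",
        ],
    )


def profile_to_frame(profile: TranscriptProfile) -> pd.DataFrame:
    """Serialisable t-plot data: position, raw count, tpb."""
    positions = np.arange(1, profile.raw.shape[0] + 1)
    return pd.DataFrame(
        {"position": positions, "raw": profile.raw, "tpb": profile.tpb}
    )
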