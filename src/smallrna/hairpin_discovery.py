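"""Novel / candidate miRNA locus calling from hairpin structure and read
support.

A 20-22 nt tag that was not assigned to a known reference is anchored at
each of its exact genomic hits, flanking windows are folded with the
maximum-base-pair folder, and the mature/star duplex is evaluated on the
fold: the locus survives when the duplex shows at most four mismatched
mature positions and at most one asymmetric bulge, the mature plus star
reads account for more than 75% of the reads in the precursor span, and
more than 75% of those reads come from tags mapping nowhere outside the
locus family. A surviving locus is classed ``novel`` when a star read is
observed (5' end within 1 nt of the predicted star 5' end, length within
2 nt) and ``candidate`` otherwise.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import as_rna, encode, revcomp
from .config import Thresholds
from .fold import FoldResult, fold
from .read_processing import GenomeHit, UniqueTag, normalize_rpm

#: slack added around the tag on its near side when building windows
_NEAR_PAD = 10
#: slack added around the predicted precursor span when collecting reads
_SPAN_PAD = 3
#: free unpaired allowance at the mature 3' end (duplex 3' overhang)
_OVERHANG_ALLOWANCE = 2
#: largest register shift a single asymmetric bulge may cause
_MAX_BULGE_SHIFT = 4
#: minimum mature positions the fold must pair into the star arm
_MIN_FOLD_SUPPORT = 6

# base-pairability lookup over codes A=0, C=1, G=2, T=3 (WC + G-U wobble)
_PAIRABLE = np.zeros((4, 4), dtype=bool)
for _x, _y in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRABLE[_x, _y] = True


@dataclass(frozen=True)
class PrecursorWindow:
    """A genomic window oriented 5'->3' along the locus strand.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``sequence`` is reverse-complemented for minus-strand loci.
    ``tag_offset`` locates the anchor tag inside ``sequence``.
    """

    scaffold: str
    start: int
    end: int
    strand: str
    sequence: str
    tag_offset: int
    tag_length: int

    def to_genome(self, window_pos: int) -> int:
        """Forward-strand coordinate of an oriented window position."""
        if self.strand == "+":
            return self.start + window_pos
        return self.end - 1 - window_pos


@dataclass(frozen=True)
class DuplexEvaluation:
    accepted: bool
    reason: str
    arm: str = ""  # '5p' or '3p'
    star_start: int = -1  # oriented window coords, inclusive
    star_end: int = -1
    mismatches: int = 0
    bulges: int = 0


@dataclass
class LocusCall:
    """One accepted precursor locus for a mature tag."""

    scaffold: str
    start: int  # precursor span, 0-based half-open, forward strand
    end: int
    strand: str
    mature_start: int  # forward-strand start of the mature match
    arm: str
    star_sequence: str  # predicted star (oriented 5'->3')
    star_five_prime: int  # forward-strand coord of the star 5' end
    star_observed: bool = False
    star_reads: int = 0
    observed_star_sequence: str = ""
    pair_fraction: float = 0.0
    uniqueness_fraction: float = 0.0
    mismatches: int = 0
    bulges: int = 0


@dataclass
class MirnaLocusCall:
    """A called miRNA: one mature tag with one or more accepted loci."""

    mature: str
    star_sequence: str
    star_observed: bool
    loci: list[LocusCall] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def klass(self) -> str:
        return "novel" if self.star_observed else "candidate"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ----------------------------------------------------------------------
# Windows
# ----------------------------------------------------------------------

def extract_windows(
    hit: GenomeHit,
    genome: Mapping[str, str],
    flank: int = 150,
    *,
    window_cap: int = 400,
) -> list[PrecursorWindow]:
    """Three candidate precursor windows around a hit.

    A centred window plus one with the tag near the locus 5' end (flank
    mostly 3') and one with the tag near the 3' end, clipped at scaffold
    boundaries. Minus-strand windows are reverse-complemented.
    """
    if flank < 50:
        raise ValueError("flank must be >= 50")
    ref = genome[hit.scaffold]
    if not (0 <= hit.start and hit.end <= len(ref)):
        raise ValueError(f"hit outside scaffold: {hit}")
    # (upstream, downstream) extension pairs in locus orientation
    shapes = [(flank, flank), (_NEAR_PAD, 2 * flank), (2 * flank, _NEAR_PAD)]
    windows = []
    for up, down in shapes:
        left, right = (up, down) if hit.strand == "+" else (down, up)
        start = max(0, hit.start - left)
        end = min(len(ref), hit.end + right)
        if end - start > window_cap:
            # trim the far edge first, keeping the tag inside
            if hit.strand == "+":
                end = min(end, start + window_cap)
                start = max(start, end - window_cap)
            else:
                start = max(start, end - window_cap)
                end = min(end, start + window_cap)
        seq = ref[start:end]
        if hit.strand == "-":
            seq = revcomp(seq)
            offset = end - hit.end
        else:
            offset = hit.start - start
        windows.append(
            PrecursorWindow(
                hit.scaffold, start, end, hit.strand, seq, offset, len(hit.tag)
            )
        )
    return windows


# ----------------------------------------------------------------------
# Duplex evaluation
# ----------------------------------------------------------------------

def evaluate_hairpin(
    fold_result: FoldResult,
    mature_start: int,
    mature_length: int,
    *,
    max_mismatches: int = 4,
    max_bulges: int = 1,
) -> DuplexEvaluation:
    """Evaluate the mature/star duplex implied by a fold.

    The mature interval must lie wholly on one arm: pairing partners all
    on one side of it, with at most a couple of stray internal or
    opposite-side pairs (tolerated as mismatches, since maximum-pairing
    folds opportunistically pair loop and overhang bases). The duplex is
    read off the fold's pairing registers (register of position ``i`` =
    ``i + partner(i)``): a clean duplex keeps one register, a single
    asymmetric bulge shifts it once by up to ``_MAX_BULGE_SHIFT`` nt.
    The best one- or two-register coverage of the mature is found;
    uncovered mature positions inside the duplex count as mismatches
    (symmetric internal loops keep the register, so each such position
    is a mismatch and never a bulge), a register shift counts as one
    bulge, and up to 2 nt at the mature 3' end are free (the duplex 3'
    overhang). The star interval is the covered partner interval
    extended 2 nt past the partner of the mature 5' end.
    """
    a, b = mature_start, mature_start + mature_length
    seq = fold_result.sequence
    if a < 0 or b > len(seq):
        raise ValueError("mature interval outside the folded window")
    partners = fold_result.pairs[a:b]
    paired = np.nonzero(partners >= 0)[0]
    if paired.size == 0:
        return DuplexEvaluation(False, "mature unpaired")
    pvals = partners[paired]
    internal = (pvals >= a) & (pvals < b)
    if int(internal.sum()) > 2:
        return DuplexEvaluation(False, "mature pairs with itself")
    paired, pvals = paired[~internal], pvals[~internal]
    if paired.size == 0:
        return DuplexEvaluation(False, "mature unpaired")
    n_right = int((pvals >= b).sum())
    n_left = paired.size - n_right
    if min(n_right, n_left) > 2:
        return DuplexEvaluation(False, "mature spans both arms")
    arm = "5p" if n_right >= n_left else "3p"
    keep = pvals >= b if arm == "5p" else pvals < a
    paired, pvals = paired[keep], pvals[keep]
    if paired.size < _MIN_FOLD_SUPPORT:
        return DuplexEvaluation(False, "insufficient hairpin pairing", arm)

    # Candidate duplex registers come from the fold (register of mature
    # position i = i + partner(i), constant along a clean stem). Duplex
    # quality is then measured by direct base pairability along the
    # registers, because the maximum-pairing fold reroutes bases around
    # planted mismatches and would otherwise overstate them.
    fold_registers = sorted({int(d) for d in paired + a + pvals})

    codes = encode(seq)
    # the mature 3'-overhang dinucleotide is outside the duplex by
    # definition; excluding it pins the star boundary at the partner of
    # the last duplex position instead of letting chance background
    # pairing extend the star
    duplex_length = mature_length - _OVERHANG_ALLOWANCE
    mcodes = codes[a : a + duplex_length]
    positions = np.arange(duplex_length)
    abs_pos = positions + a
    if arm == "5p":
        q_lo, q_hi = b + 3, len(seq)
    else:
        q_lo, q_hi = 0, a - 3
    if q_hi <= q_lo:
        return DuplexEvaluation(False, "no room for a star arm", arm)

    def pairable(d: int) -> np.ndarray:
        q = d - abs_pos
        valid = (q >= q_lo) & (q < q_hi)
        out = np.zeros(duplex_length, dtype=bool)
        idx = np.nonzero(valid)[0]
        if idx.size:
            out[idx] = _PAIRABLE[mcodes[idx], codes[q[idx]]]
        return out

    cache: dict[int, np.ndarray] = {}

    def vec(d: int) -> np.ndarray:
        if d not in cache:
            cache[d] = pairable(d)
        return cache[d]

    # candidate registers: fold-observed ones plus the best-covered
    # anti-diagonals of the direct pairability matrix over the whole arm
    # (the maximum-pairing fold may pair the mature off the true star)
    pair_rows = _PAIRABLE[mcodes][:, codes[q_lo:q_hi]]
    acc = np.zeros(q_hi - q_lo + duplex_length, dtype=np.int32)
    for i in range(duplex_length):
        acc[i : i + q_hi - q_lo] += pair_rows[i]
    top = np.argsort(acc)[::-1][:12]
    coverage_registers = [int(t) + q_lo for t in top if acc[t] >= duplex_length // 2]
    candidate_registers = sorted(set(fold_registers) | set(coverage_registers))

    def score_mask(mask: np.ndarray, shift: int, k: int):
        covered = int(mask.sum())
        if covered == 0:
            return None
        idx = np.nonzero(mask)[0]
        lead = int(idx[0])
        trail = duplex_length - 1 - int(idx[-1])
        interior = int(idx[-1]) - int(idx[0]) + 1 - covered
        mismatches = lead + trail + interior
        bulges = 1 if shift and idx[0] < k <= idx[-1] else 0
        return (covered, -mismatches, -bulges), mask, mismatches, bulges

    best = None
    for d1 in candidate_registers:
        v1 = vec(d1)
        for shift in range(-_MAX_BULGE_SHIFT, _MAX_BULGE_SHIFT + 1):
            if shift == 0:
                entry = score_mask(v1, 0, duplex_length)
                if entry and (best is None or entry[0] > best[0]):
                    best = (*entry, d1, d1, duplex_length)
                continue
            v2 = vec(d1 + shift)
            if not v2.any():
                continue
            # best split by coverage, then detailed scoring at the optima
            prefix1 = np.concatenate(([0], np.cumsum(v1)))
            suffix2 = np.concatenate((np.cumsum(v2[::-1])[::-1], [0]))
            coverage = prefix1 + suffix2
            for k in np.nonzero(coverage == coverage.max())[0]:
                mask = np.where(positions < k, v1, v2)
                entry = score_mask(mask, shift, int(k))
                if entry and (best is None or entry[0] > best[0]):
                    best = (*entry, d1, d1 + shift, int(k))
    if best is None:
        return DuplexEvaluation(False, "no duplex register", arm)
    _, mask, mismatches, bulges, d1, d2, k = best
    idx = np.nonzero(mask)[0]
    qs = [(d1 if i < k else d2) - (a + int(i)) for i in idx]
    star_start = min(qs)
    star_end = min(max(qs) + 2, len(seq) - 1)

    accepted = mismatches <= max_mismatches and bulges <= max_bulges
    reason = "" if accepted else "duplex exceeds mismatch/bulge limits"
    return DuplexEvaluation(
        accepted, reason, arm, star_start, star_end, mismatches, bulges
    )


# ----------------------------------------------------------------------
# Read support
# ----------------------------------------------------------------------

class _ReadIndex:
    """Hits grouped by (scaffold, strand), sorted by start, for range scans."""

    def __init__(self, hits: Mapping[str, list[GenomeHit]]):
        grouped: dict[tuple[str, str], list[GenomeHit]] = defaultdict(list)
        for hitlist in hits.values():
            for h in hitlist:
                grouped[(h.scaffold, h.strand)].append(h)
        self._groups = {}
        for key, hs in grouped.items():
            hs.sort(key=lambda h: h.start)
            self._groups[key] = ([h.start for h in hs], hs)

    def within(self, scaffold: str, strand: str, start: int, end: int) -> list[GenomeHit]:
        """Hits fully contained in [start, end) on the given strand."""
        group = self._groups.get((scaffold, strand))
        if group is None:
            return []
        starts, hs = group
        lo = bisect_left(starts, start)
        hi = bisect_right(starts, end)
        return [h for h in hs[lo:hi] if h.end <= end]


def star_detection(
    locus: LocusCall,
    reads: Sequence[GenomeHit],
    counts: Mapping[str, int],
    *,
    position_tolerance: int = 1,
    length_tolerance: int = 2,
) -> tuple[bool, int, str]:
    """Detect star reads among the reads of a locus.

    A read is star evidence when its 5' end lies within
    ``position_tolerance`` nt of the predicted star 5' end and its length
    is within ``length_tolerance`` nt of the predicted star length.
    Returns (observed, star read count, best observed star sequence).
    """
    star_len = len(locus.star_sequence)
    best_seq, best_count, total = "", 0, 0
    for read in reads:
        if abs(read.five_prime - locus.star_five_prime) > position_tolerance:
            continue
        if abs(len(read.tag) - star_len) > length_tolerance:
            continue
        n = counts.get(read.tag, 0)
        total += n
        if n > best_count:
            best_count, best_seq = n, read.tag
    return total > 0, total, best_seq


def locus_support(
    reads: Sequence[GenomeHit],
    counts: Mapping[str, int],
    mature: str,
    star_reads: set[str],
    unique_tags: set[str],
) -> tuple[float, float]:
    """(pair fraction, uniqueness fraction) over the reads of one locus."""
    total = sum(counts.get(r.tag, 0) for r in reads)
    if total == 0:
        raise ValueError("no reads in the precursor span")
    pair = sum(
        counts.get(r.tag, 0) for r in reads if r.tag == mature or r.tag in star_reads
    )
    unique = sum(counts.get(r.tag, 0) for r in reads if r.tag in unique_tags)
    return pair / total, unique / total


# ----------------------------------------------------------------------
# Locus calling
# ----------------------------------------------------------------------

def _evaluate_hit(
    hit: GenomeHit,
    genome: Mapping[str, str],
    thresholds: Thresholds,
) -> LocusCall | None:
    """Fold candidate windows for one hit; return the locus of the first
    window whose duplex evaluation accepts, or None."""
    for window in extract_windows(
        hit, genome, thresholds.flank, window_cap=thresholds.window_cap
    ):
        result = fold(window.sequence, max_len=thresholds.window_cap)
        ev = evaluate_hairpin(
            result,
            window.tag_offset,
            window.tag_length,
            max_mismatches=thresholds.duplex_mismatches,
            max_bulges=thresholds.duplex_bulges,
        )
        if not ev.accepted:
            continue
        star_seq = window.sequence[ev.star_start : ev.star_end + 1]
        lo = min(window.tag_offset, ev.star_start)
        hi = max(window.tag_offset + window.tag_length - 1, ev.star_end)
        g1, g2 = window.to_genome(lo), window.to_genome(hi)
        # pad so reads barely overhanging the predicted duplex still count
        span_start = max(0, min(g1, g2) - _SPAN_PAD)
        span_end = max(g1, g2) + 1 + _SPAN_PAD
        return LocusCall(
            scaffold=hit.scaffold,
            start=span_start,
            end=span_end,
            strand=hit.strand,
            mature_start=hit.start,
            arm=ev.arm,
            star_sequence=star_seq,
            star_five_prime=window.to_genome(ev.star_start),
            mismatches=ev.mismatches,
            bulges=ev.bulges,
        )
    return None


def discover(
    tags: Sequence[UniqueTag],
    hits: Mapping[str, list[GenomeHit]],
    genome: Mapping[str, str],
    *,
    exclude: set[str] = frozenset(),
    thresholds: Thresholds | None = None,
) -> list[MirnaLocusCall]:
    """Call novel and candidate miRNA loci from unassigned tags.

    ``exclude`` holds tag sequences already attributed to known miRNAs or
    ncRNAs. Tags shorter than 20 or longer than 22 nt, tags below the
    read-support floor, and tags with too many genomic loci are skipped.
    Read counts of multi-locus tags are attributed fully to each locus.
    """
    thresholds = thresholds or Thresholds()
    counts = {t.sequence: t.total for t in tags}
    per_lib = {t.sequence: t.counts for t in tags}
    index = _ReadIndex(hits)

    calls: list[MirnaLocusCall] = []
    for seq in sorted(hits):
        if seq in exclude or not 20 <= len(seq) <= 22:
            continue
        if counts.get(seq, 0) < thresholds.min_discovery_reads:
            continue
        tag_hits = hits[seq]
        if len(tag_hits) > thresholds.max_discovery_loci:
            continue
        loci = [
            locus
            for hit in tag_hits
            if (locus := _evaluate_hit(hit, genome, thresholds)) is not None
        ]
        if not loci:
            continue

        spans = [(l.scaffold, l.strand, l.start, l.end) for l in loci]

        def _unique_to_family(tag: str) -> bool:
            return all(
                any(
                    h.scaffold == sc and h.strand == st and h.start >= s and h.end <= e
                    for sc, st, s, e in spans
                )
                for h in hits.get(tag, [])
            )

        passing: list[LocusCall] = []
        star_observed_any = False
        observed_star = ""
        for locus in loci:
            reads = index.within(locus.scaffold, locus.strand, locus.start, locus.end)
            observed, star_count, star_seq = star_detection(locus, reads, counts)
            locus.star_observed = observed
            locus.star_reads = star_count
            locus.observed_star_sequence = star_seq
            star_tags = {
                r.tag
                for r in reads
                if abs(r.five_prime - locus.star_five_prime) <= 1
                and abs(len(r.tag) - len(locus.star_sequence)) <= 2
            }
            unique_tags = {r.tag for r in reads if _unique_to_family(r.tag)}
            pair, uniq = locus_support(reads, counts, seq, star_tags, unique_tags)
            locus.pair_fraction = pair
            locus.uniqueness_fraction = uniq
            if pair > thresholds.pair_fraction and uniq > thresholds.uniqueness_fraction:
                passing.append(locus)
                if observed:
                    star_observed_any = True
                    observed_star = observed_star or star_seq
        if not passing:
            continue
        star = observed_star if star_observed_any else passing[0].star_sequence
        calls.append(
            MirnaLocusCall(
                mature=seq,
                star_sequence=star,
                star_observed=star_observed_any,
                loci=passing,
                counts=dict(per_lib.get(seq, {})),
            )
        )
    calls = _drop_star_strand_calls(calls, hits)
    calls.sort(key=lambda c: (-c.total, c.mature))
    return calls


def _drop_star_strand_calls(
    calls: list[MirnaLocusCall], hits: Mapping[str, list[GenomeHit]]
) -> list[MirnaLocusCall]:
    """Keep one call per duplex: when a called tag is star evidence of a
    more abundant call at the same locus, it is the star strand, not an
    independent miRNA."""
    drop: set[str] = set()
    for a in calls:
        for b in calls:
            if a is b or b.mature in drop or a.mature in drop:
                continue
            if (b.total, b.mature) >= (a.total, a.mature):
                continue
            for locus in a.loci:
                b_hits = [
                    h
                    for h in hits.get(b.mature, [])
                    if h.scaffold == locus.scaffold and h.strand == locus.strand
                ]
                if any(
                    abs(h.five_prime - locus.star_five_prime) <= 1
                    and abs(len(h.tag) - len(locus.star_sequence)) <= 2
                    for h in b_hits
                ):
                    drop.add(b.mature)
                    break
    return [c for c in calls if c.mature not in drop]


# ----------------------------------------------------------------------
# Output
# ----------------------------------------------------------------------

def calls_to_table(
    calls: Sequence[MirnaLocusCall],
    totals: Mapping[str, int],
    libraries: Sequence[str],
    *,
    name_prefix: str = "mir",
    round_rpm: bool = True,
) -> pd.DataFrame:
    """Catalog-style table: one row per called miRNA, rpm per library.

    rpm values are rounded to integers when ``round_rpm`` (report style);
    pass ``False`` to keep full precision.
    """
    rows = []
    for i, call in enumerate(calls, 1):
        locus = call.loci[0]
        rpms = {
            lib: normalize_rpm(call.counts.get(lib, 0), totals[lib])
            for lib in libraries
        }
        if round_rpm:
            rpms = {lib: int(round(v)) for lib, v in rpms.items()}
        rows.append(
            {
                "mirna": f"{name_prefix}{i}",
                "sequence": as_rna(call.mature),
                "length": len(call.mature),
                "scaffold": locus.scaffold,
                "match_site": locus.mature_start + 1,
                "strand": locus.strand,
                **{f"rpm_{lib}": rpms[lib] for lib in libraries},
                "rpm_total": sum(rpms.values()),
                "n_loci": len(call.loci),
                "class": call.klass,
                "star_sequence": as_rna(call.star_sequence)
                if call.star_observed
                else "None detected",
            }
        )
    return pd.DataFrame(rows)


def calls_to_gff3(calls: Sequence[MirnaLocusCall], path: str | Path, *, name_prefix: str = "mir") -> None:
    """Write accepted loci as GFF3 (primary transcript + mature miRNA)."""
    lines = ["##gff-version 3"]
    for i, call in enumerate(calls, 1):
        name = f"{name_prefix}{i}"
        for j, locus in enumerate(call.loci, 1):
            pid = f"{name}.pre{j}"
            lines.append(
                "\t".join(
                    [
                        locus.scaffold,
                        "smallrna",
                        "miRNA_primary_transcript",
                        str(locus.start + 1),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={pid};Name={name}",
                    ]
                )
            )
            lines.append(
                "\t".join(
                    [
                        locus.scaffold,
                        "smallrna",
                        "miRNA",
                        str(locus.mature_start + 1),
                        str(locus.mature_start + len(call.mature)),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={pid}.mature;Parent={pid};class={call.klass}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
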