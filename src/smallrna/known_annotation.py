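"""Screening against non-coding RNA references and assignment of tags to
known miRNA families with a bounded-mismatch ungapped alignment.

Alignments are ungapped and slid over a small offset range; positions of
the tag that hang off a reference end (at most two per end) are not
counted as mismatches. A tag that matches both an ncRNA and a known
miRNA within the mismatch bound is attributed to whichever reference it
matches with fewer mismatches, ties going to the miRNA, so genuine
miRNAs shadowed by ncRNA look-alikes are not discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import as_dna

CONSERVATION_CLASSES = ("conserved", "less-conserved")

#: maximum number of tag bases allowed to overhang each reference end
MAX_OVERHANG = 2


@dataclass(frozen=True)
class ReferenceMature:
    """A known mature miRNA (or ncRNA) reference sequence."""

    name: str
    family: str
    sequence: str
    conservation: str = "conserved"

    def __post_init__(self):
        if not self.family:
            raise ValueError("family must be non-empty")
        if self.conservation not in CONSERVATION_CLASSES:
            raise ValueError(f"unknown conservation class {self.conservation!r}")


@dataclass(frozen=True)
class FamilyAssignment:
    tag: str
    reference: str
    family: str
    mismatches: int
    conservation: str


def load_references(path: str | Path) -> list[ReferenceMature]:
    """Load a reference FASTA with ``name|family|class`` headers.

    Missing fields default to family = name and class = conserved.
    """
    refs = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        name = parts[0]
        family = parts[1] if len(parts) > 1 and parts[1] else name
        conservation = parts[2] if len(parts) > 2 else "conserved"
        refs.append(ReferenceMature(name, family, as_dna(str(record.seq)), conservation))
    return refs


def _best_ungapped_mismatches(tag: str, ref: str, max_overhang: int = MAX_OVERHANG) -> int:
    """Minimum mismatch count of ``tag`` slid along ``ref``.

    All offsets are considered for which the tag overhangs each reference
    end by at most ``max_overhang`` bases; overhanging tag bases are free.
    Returns ``len(tag)`` when no admissible offset exists.
    """
    best = len(tag)
    lo = -max_overhang
    hi = len(ref) - len(tag) + max_overhang
    for offset in range(lo, hi + 1):
        start = max(0, -offset)  # first tag index on the reference
        stop = min(len(tag), len(ref) - offset)
        if stop <= start:
            continue
        mm = sum(1 for i in range(start, stop) if tag[i] != ref[offset + i])
        if mm < best:
            best = mm
    return best


def screen_ncrna(
    tag: str,
    ncrna_refs: Sequence[ReferenceMature],
    *,
    max_mismatches: int = 2,
) -> bool:
    """True if the tag should be removed as an ncRNA look-alike."""
    if not ncrna_refs:
        warnings.warn("empty ncRNA reference set; all tags kept", stacklevel=2)
        return False
    tag = as_dna(tag)
    return any(
        _best_ungapped_mismatches(tag, ref.sequence) <= max_mismatches
        for ref in ncrna_refs
    )


def assign_known(
    tag: str,
    references: Sequence[ReferenceMature],
    *,
    max_mismatches: int = 2,
    max_length_diff: int = 2,
) -> FamilyAssignment | None:
    """Best known-miRNA assignment for a tag, or None.

    Candidates are references whose length is within ``max_length_diff``
    nt of the tag; the winner minimises (mismatches, |length difference|,
    reference name). Returns None if the minimum exceeds
    ``max_mismatches``.
    """
    tag = as_dna(tag)
    best: tuple[int, int, str] | None = None
    best_ref: ReferenceMature | None = None
    best_mm = max_mismatches + 1
    for ref in references:
        if abs(len(ref.sequence) - len(tag)) > max_length_diff:
            continue
        mm = _best_ungapped_mismatches(tag, ref.sequence)
        key = (mm, abs(len(ref.sequence) - len(tag)), ref.name)
        if best is None or key < best:
            best = key
            best_ref = ref
            best_mm = mm
    if best_ref is None or best_mm > max_mismatches:
        return None
    return FamilyAssignment(
        tag, best_ref.name, best_ref.family, best_mm, best_ref.conservation
    )


def annotate_tags(
    tags: Iterable[str],
    ncrna_refs: Sequence[ReferenceMature],
    mirna_refs: Sequence[ReferenceMature],
    *,
    max_mismatches: int = 2,
) -> tuple[dict[str, FamilyAssignment], set[str], set[str]]:
    """Partition tags into (known-miRNA assignments, removed ncRNA, unassigned).

    Precedence: a tag within the mismatch bound of both reference sets is
    given to the set it matches with fewer mismatches; ties favour the
    miRNA assignment.
    """
    assignments: dict[str, FamilyAssignment] = {}
    removed: set[str] = set()
    unassigned: set[str] = set()
    for tag in tags:
        tag = as_dna(tag)
        assignment = (
            assign_known(tag, mirna_refs, max_mismatches=max_mismatches)
            if 20 <= len(tag) <= 22
            else None
        )
        nc_mm = min(
            (_best_ungapped_mismatches(tag, r.sequence) for r in ncrna_refs),
            default=len(tag),
        )
        nc_hit = nc_mm <= max_mismatches
        if assignment is not None and (not nc_hit or assignment.mismatches <= nc_mm):
            assignments[tag] = assignment
        elif nc_hit:
            removed.add(tag)
        else:
            unassigned.add(tag)
    return assignments, removed, unassigned


def family_expression_table(
    assignments: Mapping[str, FamilyAssignment],
    rpm: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Sum member-tag rpm per family and library.

    ``rpm`` maps tag sequence -> {library: rpm}. Each tag belongs to
    exactly one family, so the per-library grand total equals the summed
    rpm of all assigned tags.
    """
    rows: dict[str, dict[str, float]] = {}
    conservation: dict[str, str] = {}
    for tag, assignment in assignments.items():
        fam = rows.setdefault(assignment.family, {})
        conservation[assignment.family] = assignment.conservation
        for library, value in rpm.get(tag, {}).items():
            fam[library] = fam.get(library, 0.0) + value
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
    table.index.name = "family"
    table["conservation"] = [conservation[f] for f in table.index]
    return table
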