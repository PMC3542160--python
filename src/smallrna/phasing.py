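"""21-nt phasing-register analysis downstream of a miRNA cleavage site.

Reads are binned into 21 registers by the residue of (read 5' position -
anchor) modulo 21, where the anchor is the first nucleotide of the first
phased siRNA (the nucleotide 3' of the guided cut). Register 0 is the
in-phase register. The optional enrichment statistic (upper-tail
binomial test of the dominant register against p = 1/21, Bonferroni
corrected for register selection) is an extension beyond the radial-plot
output and is off by default in report mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_REGISTERS = 21
PHASE_LENGTH = 21
#: default analysis span: ten phase cycles downstream of the anchor
DEFAULT_SPAN = 10 * PHASE_LENGTH


@dataclass(frozen=True)
class PhasedRead:
    """A 21-nt read placed on a transcript (1-based 5' position)."""

    position: int
    length: int
    counts: Mapping[str, int]  # per-library

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class RegisterProfile:
    """Occupancy of the 21 phasing registers, per library and overall."""

    counts: np.ndarray  # shape (21,)
    per_library: dict[str, np.ndarray] = field(default_factory=dict)
    excluded_non21: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def dominant_register(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def dominant_tied(self) -> bool:
        return int((self.counts == self.counts.max()).sum()) > 1

    @property
    def phase_fraction(self) -> float:
        if self.total == 0:
            return 0.0
        return float(self.counts[self.dominant_register]) / self.total


def assign_registers(
    reads: Sequence[PhasedRead],
    anchor: int,
    *,
    span: int | None = DEFAULT_SPAN,
    include_upstream: bool = False,
) -> RegisterProfile:
    """Bin reads into the 21 phasing registers anchored at ``anchor``.

    Only 21-nt reads are admitted; others are excluded and counted.
    ``span`` limits the analysis to [anchor, anchor + span) (and the
    mirrored upstream span when ``include_upstream``); pass ``None`` for
    no positional limit. Ties for the dominant register resolve to the
    smallest index and are flagged on the profile.
    """
    counts = np.zeros(N_REGISTERS, dtype=np.int64)
    per_library: dict[str, np.ndarray] = {}
    excluded = 0
    for read in reads:
        if read.length != PHASE_LENGTH:
            excluded += read.total
            continue
        offset = read.position - anchor
        if span is not None:
            if include_upstream:
                if not -span <= offset < span:
                    continue
            elif not 0 <= offset < span:
                continue
        register = offset % N_REGISTERS
        counts[register] += read.total
        for library, n in read.counts.items():
            if library not in per_library:
                per_library[library] = np.zeros(N_REGISTERS, dtype=np.int64)
            per_library[library][register] += n
    return RegisterProfile(counts, per_library, excluded)


def phase_statistic(profile: RegisterProfile, *, min_reads: int = 10) -> tuple[float, float]:
    """(phase fraction, Bonferroni-corrected binomial enrichment p-value).

    Raises ``ValueError`` below ``min_reads`` total reads (the profile is
    under-supported).
    """
    n = profile.total
    if n < min_reads:
        raise ValueError(f"under-supported profile: {n} reads < {min_reads}")
    k = int(profile.counts[profile.dominant_register])
    p = float(stats.binom.sf(k - 1, n, 1.0 / N_REGISTERS))
    return profile.phase_fraction, min(1.0, p * N_REGISTERS)


_LABEL_RE = re.compile(r"^(?P<locus>.+)-siRNA\((?P<offset>[+-]\d+)\)$")


def name_phased_sirna(position: int, anchor: int, locus: str) -> str:
    """Deterministic siRNA label: ``<locus>-siRNA(<signed offset>)``.

    The offset is the read 5' position minus the anchor (negative means
    5' of the anchor).
    """
    return f"{locus}-siRNA({position - anchor:+d})"


def parse_sirna_label(label: str) -> tuple[str, int]:
    """Inverse of :func:`name_phased_sirna`: (locus, offset)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not a phased-siRNA label: {label!r}")
    return m.group("locus"), int(m.group("offset"))


def tissue_accumulation(
    profiles: Mapping[str, RegisterProfile], *, register: int = 0
) -> pd.DataFrame:
    """Per-library in-register read totals and fractions, one row per locus.

    ``profiles`` maps locus id -> profile. Fractions sum to 1 across
    libraries for each locus with any in-register reads.
    """
    rows = []
    for locus in sorted(profiles):
        profile = profiles[locus]
        totals = {
            lib: int(arr[register]) for lib, arr in sorted(profile.per_library.items())
        }
        grand = sum(totals.values())
        for lib, n in totals.items():
            rows.append(
                {
                    "locus": locus,
                    "library": lib,
                    "reads": n,
                    "fraction": n / grand if grand else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["locus", "library", "reads", "fraction"])


def profile_to_frame(profile: RegisterProfile) -> pd.DataFrame:
    """Radial-plot-ready table: 21 rows, one column per library plus total."""
    data = {"register": np.arange(N_REGISTERS), "total": profile.counts}
    for library, arr in sorted(profile.per_library.items()):
        data[library] = arr
    return pd.DataFrame(data)
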