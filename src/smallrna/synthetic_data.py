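"""Synthetic genomes, small-RNA libraries and degradome libraries with
planted ground truth.

The generator plants three feature kinds in a random background genome:

* miRNA hairpin loci — a mature/star duplex with 2-nt 3' overhangs, a
  configurable number of duplex mismatches (0-4) and asymmetric bulges
  (0-1), validated at build time by folding the locus in its final
  genomic context so that every planted locus passes the discovery
  duplex criteria by construction (and negative controls fail them);
* TAS-like transcripts — a perfect trigger-miRNA site followed by 21-nt
  phased siRNA positions downstream of the guided cleavage site;
* target transcripts — a complementary site of controlled alignment
  score whose guided-cleavage position receives a degradome tag pile-up.

Read counts are Poisson around per-tissue expectations (negative
binomial optionally); background small-RNA reads are genome substrings
with a fixed categorical length distribution whose mode is 24 nt and
secondary mode 21 nt. Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .config import Thresholds
from .degradome import score_target_site
from .fold import fold
from .hairpin_discovery import evaluate_hairpin, extract_windows
from .read_processing import GenomeHit

BASES = np.array(list("ACGT"))

#: background read length weights (length -> probability); mode 24, then 21
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    18: 0.02, 19: 0.02, 20: 0.05, 21: 0.14, 22: 0.06, 23: 0.08,
    24: 0.40, 25: 0.09, 26: 0.06, 27: 0.04, 28: 0.04,
}

#: default 3' adapter literal appended by the read simulator
DEFAULT_ADAPTER = "TGGAATTCTCGGGTG"

_LOOP_LEN = 15
_PLACEMENT_MARGIN = 1000
_PLACEMENT_STRIDE = 2500

# bases that neither Watson-Crick- nor wobble-pair with the key
_NON_PAIRING = {"A": "ACG", "C": "ACT", "G": "AG", "T": "CT"}


# ----------------------------------------------------------------------
# Specs and planted features
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ToyGenomeSpec:
    scaffold_count: int = 8
    scaffold_length: int = 25_000
    gc_fraction: float = 0.45
    seed: int = 1

    def __post_init__(self):
        if self.scaffold_length < 1000:
            raise ValueError("scaffold_length must be >= 1000")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass
class PlantedMirna:
    name: str
    mature_seq: str
    star_seq: str
    loop_seq: str
    precursor_seq: str
    mature_offset: int  # 0-based offset of the mature inside the precursor
    duplex_mismatches: int
    bulges: int
    arm: str  # '5p' or '3p'
    tissue_profile: dict[str, float]  # expected mature rpm per library
    star_fraction: float = 0.2
    scaffold: str | None = None
    start: int | None = None  # 1-based precursor start
    strand: str = "+"
    negative_control: bool = False
    #: member of the known reference set (excluded from novel discovery)
    known: bool = False

    @property
    def mature_genome_start(self) -> int:
        """1-based forward-strand start of the mature match."""
        if self.strand == "+":
            return self.start + self.mature_offset
        offset_from_end = len(self.precursor_seq) - self.mature_offset - len(self.mature_seq)
        return self.start + offset_from_end


@dataclass
class PlantedTas:
    name: str
    transcript_seq: str
    trigger_name: str
    trigger_seq: str
    cleavage_pos: int  # 1-based: first nt of the first phased siRNA
    phased_sirna_count: int
    off_phase_noise_fraction: float
    tissue_profile: dict[str, float]  # expected total phased-read rpm per library
    trigger_tag_count: int = 30
    scaffold: str | None = None
    start: int | None = None
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.off_phase_noise_fraction < 1:
            raise ValueError("off_phase_noise_fraction must be in [0, 1)")

    def phased_read(self, k: int) -> str:
        pos = self.cleavage_pos - 1 + 21 * k
        return self.transcript_seq[pos : pos + 21]


@dataclass
class PlantedTarget:
    transcript_id: str
    transcript_seq: str
    mirna_id: str
    mirna_seq: str
    site_start: int  # 1-based
    intended_align_score: float
    achieved_align_score: float
    cleavage_pos: int  # 1-based, opposite miRNA position 10
    degradome_tag_count: int
    background_tag_rate: float = 0.0

    def __post_init__(self):
        if self.intended_align_score > 5:
            raise ValueError("intended_align_score must be <= 5")


@dataclass
class LibrarySpec:
    name: str
    depth: int = 50_000
    background_fraction: float = 0.5
    noise: str = "poisson"  # or 'negative_binomial'
    nb_dispersion: float = 10.0

    def __post_init__(self):
        if self.depth < 1000:
            raise ValueError("library depth must be >= 1000")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background fraction must be in [0, 1]")


@dataclass
class Scenario:
    """A generated genome plus every planted feature and derived table."""

    spec: ToyGenomeSpec
    genome: dict[str, str]
    truth: pd.DataFrame
    mirnas: list[PlantedMirna]
    tas_loci: list[PlantedTas]
    targets: list[PlantedTarget]
    transcripts: dict[str, str] = field(default_factory=dict)
    libraries: list[str] = field(default_factory=list)

    @property
    def known_mirnas(self) -> list[PlantedMirna]:
        return [m for m in self.mirnas if m.known]

    @property
    def novel_mirnas(self) -> list[PlantedMirna]:
        return [m for m in self.mirnas if not m.known and not m.negative_control]


# ----------------------------------------------------------------------
# Sequence construction
# ----------------------------------------------------------------------

def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _mutate_non_pairing(rng: np.random.Generator, partner_base: str) -> str:
    """A base that cannot pair (WC or wobble) with ``partner_base``."""
    return rng.choice(list(_NON_PAIRING[partner_base]))


def build_precursor(
    rng: np.random.Generator,
    mature: str,
    *,
    mismatches: int = 0,
    bulges: int = 0,
    loop_len: int = _LOOP_LEN,
    arm: str = "5p",
) -> tuple[str, int, str, str]:
    """Assemble a hairpin precursor around a mature sequence.

    The star is the reverse complement of the paired mature region
    (all but the mature 3'-overhang dinucleotide), degraded by the
    requested number of non-pairing substitutions (symmetric mismatches)
    and single-nucleotide insertions (asymmetric bulges), plus a 2-nt 3'
    overhang. Returns (precursor, mature offset, star, loop).
    """
    L = len(mature)
    star_core = list(revcomp(mature[: L - 2]))  # star_core[i] pairs mature[L-3-i]
    # mutate interior paired positions, keeping duplex ends intact
    slots = list(range(3, len(star_core) - 3))
    rng.shuffle(slots)
    chosen: list[int] = []
    for pos in slots:
        if len(chosen) == mismatches:
            break
        if all(abs(pos - c) > 1 for c in chosen):
            chosen.append(pos)
    if len(chosen) < mismatches:
        raise ValueError("mature too short for the requested mismatches")
    for pos in chosen:
        partner = mature[L - 3 - pos]
        star_core[pos] = _mutate_non_pairing(rng, partner)
    for _ in range(bulges):
        while True:
            pos = int(rng.integers(4, len(star_core) - 4))
            if all(abs(pos - c) > 1 for c in chosen):
                break
        star_core.insert(pos, _mutate_non_pairing(rng, mature[L - 3 - pos]))
        chosen = [c + 1 if c >= pos else c for c in chosen] + [pos]
    overhang = "".join(rng.choice(list("ACT"), size=2))
    star = "".join(star_core) + overhang
    loop = random_seq(rng, loop_len)
    if arm == "5p":
        precursor = mature + loop + star
        offset = 0
    else:
        precursor = star + loop + mature
        offset = len(star) + loop_len
    return precursor, offset, star, loop


def _star_genome_five_prime(mirna: PlantedMirna) -> int:
    """0-based forward-strand coordinate of the planted star's 5' end."""
    if mirna.arm == "5p":
        star_off = len(mirna.mature_seq) + len(mirna.loop_seq)
    else:
        star_off = 0
    start0 = mirna.start - 1
    if mirna.strand == "+":
        return start0 + star_off
    return start0 + len(mirna.precursor_seq) - 1 - star_off


def _evaluate_in_context(
    mirna: PlantedMirna, genome: Mapping[str, str], thresholds: Thresholds
) -> tuple[bool, bool]:
    """Fold the planted locus in its genomic context exactly as the
    discovery stage would.

    Returns (hairpin accepted, predicted star within the star-read
    detection tolerances of the planted star). A positive locus needs
    both — emitted star reads are then always detected — while a
    negative control must fail the hairpin outright.
    """
    hit = GenomeHit(
        mirna.mature_seq, mirna.scaffold, mirna.mature_genome_start - 1, mirna.strand
    )
    for window in extract_windows(hit, genome, thresholds.flank, window_cap=thresholds.window_cap):
        ev = evaluate_hairpin(
            fold(window.sequence, max_len=thresholds.window_cap),
            window.tag_offset,
            window.tag_length,
            max_mismatches=thresholds.duplex_mismatches,
            max_bulges=thresholds.duplex_bulges,
        )
        if not ev.accepted:
            continue
        predicted_five = window.to_genome(ev.star_start)
        predicted_len = ev.star_end - ev.star_start + 1
        star_ok = (
            abs(predicted_five - _star_genome_five_prime(mirna)) <= 1
            and abs(predicted_len - len(mirna.star_seq)) <= 2
        )
        return True, star_ok
    return False, False


# ----------------------------------------------------------------------
# Genome assembly
# ----------------------------------------------------------------------

def _feature_length(feature) -> int:
    if isinstance(feature, PlantedMirna):
        return len(feature.precursor_seq)
    return len(feature.transcript_seq)


def _feature_seq(feature) -> str:
    if isinstance(feature, PlantedMirna):
        return feature.precursor_seq
    return feature.transcript_seq


def generate_genome(
    spec: ToyGenomeSpec,
    planted: Sequence[PlantedMirna | PlantedTas] = (),
) -> tuple[dict[str, str], pd.DataFrame]:
    """Draw a random genome and embed every planted feature.

    Features without coordinates are auto-placed on a deterministic,
    non-overlapping grid; explicitly placed features that overlap raise
    an error naming both features. Returns the genome and a truth table
    (1-based inclusive coordinates, strand-explicit).
    """
    # stream decoupled from feature-sequence draws: with a shared stream a
    # scenario built on the same seed would replay its early draws into the
    # scaffold background, duplicating planted sequences in the genome
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x67656E]))
    genome = {
        f"scaffold_{i + 1}": random_seq(rng, spec.scaffold_length, spec.gc_fraction)
        for i in range(spec.scaffold_count)
    }
    scaffolds = list(genome)
    occupied: dict[str, list[tuple[int, int, str]]] = {s: [] for s in scaffolds}
    slots_per_scaffold = max(
        1, (spec.scaffold_length - 2 * _PLACEMENT_MARGIN) // _PLACEMENT_STRIDE
    )

    auto_index = 0
    for feature in planted:
        length = _feature_length(feature)
        if feature.scaffold is None or feature.start is None:
            while True:
                if auto_index >= slots_per_scaffold * len(scaffolds):
                    raise ValueError("too many planted features for this genome size")
                scaffold = scaffolds[auto_index % len(scaffolds)]
                slot = auto_index // len(scaffolds)
                start0 = _PLACEMENT_MARGIN + slot * _PLACEMENT_STRIDE
                auto_index += 1
                free = all(
                    not (start0 < oe and os_ < start0 + length)
                    for os_, oe, _ in occupied[scaffold]
                )
                if free and start0 + length <= spec.scaffold_length:
                    feature.scaffold = scaffold
                    feature.start = start0 + 1
                    break
        start0 = feature.start - 1
        end0 = start0 + length
        if end0 > spec.scaffold_length or start0 < 0:
            raise ValueError(f"feature {feature.name} does not fit inside {feature.scaffold}")
        for other_start, other_end, other_name in occupied[feature.scaffold]:
            if start0 < other_end and other_start < end0:
                raise ValueError(
                    f"planted features overlap: {feature.name} and {other_name}"
                )
        occupied[feature.scaffold].append((start0, end0, feature.name))
        seq = _feature_seq(feature)
        if feature.strand == "-":
            seq = revcomp(seq)
        ref = genome[feature.scaffold]
        genome[feature.scaffold] = ref[:start0] + seq + ref[end0:]

    rows = []
    for feature in planted:
        kind = "mirna" if isinstance(feature, PlantedMirna) else "tas"
        if isinstance(feature, PlantedMirna):
            klass = "negative" if feature.negative_control else "novel"
        else:
            klass = "tas"
        rows.append(
            {
                "feature": feature.name,
                "kind": kind,
                "class": klass,
                "scaffold": feature.scaffold,
                "start": feature.start,
                "end": feature.start + _feature_length(feature) - 1,
                "strand": feature.strand,
                "sequence": _feature_seq(feature),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["feature", "kind", "class", "scaffold", "start", "end", "strand", "sequence"],
    )
    return genome, truth


# ----------------------------------------------------------------------
# Scenario builder
# ----------------------------------------------------------------------

def _draw_tissue_profile(
    rng: np.random.Generator, libraries: Sequence[str], lo: float, hi: float
) -> dict[str, float]:
    total = float(rng.uniform(lo, hi))
    weights = rng.dirichlet(np.ones(len(libraries)))
    return {lib: total * float(w) for lib, w in zip(libraries, weights)}


def _plant_target_site(
    rng: np.random.Generator, mirna: str, score: float
) -> tuple[str, float]:
    """A target site achieving (approximately) the requested align score
    via non-core mismatches and wobbles. Returns (site, achieved score)."""
    site = list(revcomp(mirna))
    L = len(mirna)
    # miRNA position p (1-based) pairs site index L - p
    budget = score
    positions = list(range(15, L))  # non-core miRNA positions, weight 1.0
    rng.shuffle(positions)
    for p in positions:
        if budget < 1.0 - 1e-9:
            break
        site[L - p] = _mutate_non_pairing(rng, mirna[p - 1])
        budget -= 1.0
    if budget >= 0.5 - 1e-9:
        for p in range(15, L):
            m = mirna[p - 1]
            if site[L - p] == revcomp(m) and m in "GT":
                site[L - p] = "T" if m == "G" else "G"  # G:U wobble, 0.5
                break
    achieved = score_target_site(mirna, "".join(site)).score
    return "".join(site), achieved


def build_scenario(
    seed: int = 1,
    *,
    n_mirnas: int = 10,
    n_tas: int = 2,
    n_targets: int = 6,
    n_negative: int = 0,
    n_known: int = 2,
    libraries: Sequence[str] = ("root", "leaf", "flower", "fruit"),
    genome_spec: ToyGenomeSpec | None = None,
    rpm_range: tuple[float, float] = (2000.0, 8000.0),
    duplex_mismatch_choices: Sequence[int] = (0, 0, 1, 2),
    bulge_choices: Sequence[int] = (0, 0, 0, 1),
    phased_sirna_count: int = 8,
    off_phase_noise_fraction: float = 0.0,
    thresholds: Thresholds | None = None,
    max_tries: int = 60,
) -> Scenario:
    """Assemble a full synthetic scenario with planted ground truth.

    Every planted miRNA is validated in its final genomic context
    against the discovery duplex criteria (negative controls against
    their failure); sequences are redrawn until the check holds, so the
    truth table is guaranteed consistent with the pipeline's contract.
    """
    rng = np.random.default_rng(seed)
    spec = genome_spec or ToyGenomeSpec(seed=seed)
    thresholds = thresholds or Thresholds()

    mirnas: list[PlantedMirna] = []
    for i in range(n_known + n_mirnas + n_negative):
        known = i < n_known
        negative = i >= n_known + n_mirnas
        length = int(rng.choice([21, 21, 21, 22]))
        if negative:
            mm, nb = (5, 0) if rng.random() < 0.5 else (2, 2)
        else:
            mm = int(rng.choice(duplex_mismatch_choices))
            nb = int(rng.choice(bulge_choices))
        arm = "5p" if rng.random() < 0.5 else "3p"
        strand = "+" if rng.random() < 0.67 else "-"
        mature = random_seq(rng, length)
        precursor, offset, star, loop = build_precursor(
            rng, mature, mismatches=mm, bulges=nb, arm=arm
        )
        if known:
            name = f"mir_k{i + 1}"
        elif negative:
            name = f"mir_neg{i - n_known - n_mirnas + 1}"
        else:
            name = f"mir_p{i - n_known + 1}"
        mirnas.append(
            PlantedMirna(
                name=name,
                mature_seq=mature,
                star_seq=star,
                loop_seq=loop,
                precursor_seq=precursor,
                mature_offset=offset,
                duplex_mismatches=mm,
                bulges=nb,
                arm=arm,
                tissue_profile=_draw_tissue_profile(rng, libraries, *rpm_range),
                strand=strand,
                negative_control=negative,
                known=known,
            )
        )

    genome, _ = generate_genome(spec, mirnas)

    # context validation with redraw: positive loci must pass the duplex
    # criteria in situ, negative controls must fail them
    for mirna in mirnas:
        for attempt in range(max_tries):
            accepted, star_ok = _evaluate_in_context(mirna, genome, thresholds)
            realised = (not accepted) if mirna.negative_control else (accepted and star_ok)
            if realised:
                break
            mature = random_seq(rng, len(mirna.mature_seq))
            precursor, offset, star, loop = build_precursor(
                rng,
                mature,
                mismatches=mirna.duplex_mismatches,
                bulges=mirna.bulges,
                arm=mirna.arm,
            )
            mirna.mature_seq = mature
            mirna.precursor_seq = precursor
            mirna.mature_offset = offset
            mirna.star_seq = star
            mirna.loop_seq = loop
            seq = precursor if mirna.strand == "+" else revcomp(precursor)
            ref = genome[mirna.scaffold]
            start0 = mirna.start - 1
            genome[mirna.scaffold] = (
                ref[:start0] + seq + ref[start0 + len(seq):]
            )
        else:
            raise RuntimeError(f"could not realise planted feature {mirna.name}")

    # TAS loci are built from the *final* trigger sequences, then the whole
    # genome is regenerated so every embedding is consistent. Triggers come
    # from the known set when available: multi-mapping of a trigger to its
    # own target site would otherwise break the uniqueness criterion for
    # that miRNA in novel discovery.
    trigger_pool = [m for m in mirnas if m.known] or [
        m for m in mirnas if not m.negative_control
    ]
    tas_loci: list[PlantedTas] = []
    for i in range(n_tas):
        trigger = trigger_pool[i % len(trigger_pool)]
        prefix = random_seq(rng, 80)
        site = revcomp(trigger.mature_seq)
        phased = random_seq(rng, 21 * phased_sirna_count)
        suffix = random_seq(rng, 40)
        transcript = prefix + site + phased + suffix
        cleavage_pos = len(prefix) + (len(trigger.mature_seq) - 10) + 1
        tas_loci.append(
            PlantedTas(
                name=f"tas_p{i + 1}",
                transcript_seq=transcript,
                trigger_name=trigger.name,
                trigger_seq=trigger.mature_seq,
                cleavage_pos=cleavage_pos,
                phased_sirna_count=phased_sirna_count,
                off_phase_noise_fraction=off_phase_noise_fraction,
                tissue_profile=_draw_tissue_profile(rng, libraries, 2000.0, 6000.0),
            )
        )

    genome, truth = generate_genome(spec, [*mirnas, *tas_loci])

    targets: list[PlantedTarget] = []
    mirna_cycle = [m for m in mirnas if not m.negative_control] or mirnas
    for i in range(n_targets):
        mirna = mirna_cycle[i % len(mirna_cycle)]
        intended = float(rng.choice([0.0, 1.0, 2.0, 3.0, 2.5]))
        site, achieved = _plant_target_site(rng, mirna.mature_seq, intended)
        prefix = random_seq(rng, 150)
        suffix = random_seq(rng, 150)
        transcript = prefix + site + suffix
        site_start = len(prefix) + 1
        cleavage = site_start + (len(mirna.mature_seq) - 10)
        targets.append(
            PlantedTarget(
                transcript_id=f"tx_{i + 1:03d}",
                transcript_seq=transcript,
                mirna_id=mirna.name,
                mirna_seq=mirna.mature_seq,
                site_start=site_start,
                intended_align_score=intended,
                achieved_align_score=achieved,
                cleavage_pos=cleavage,
                degradome_tag_count=int(rng.integers(20, 80)),
            )
        )

    transcripts = {t.transcript_id: t.transcript_seq for t in targets}
    for tas in tas_loci:
        transcripts[tas.name] = tas.transcript_seq

    return Scenario(
        spec=spec,
        genome=genome,
        truth=truth,
        mirnas=mirnas,
        tas_loci=tas_loci,
        targets=targets,
        transcripts=transcripts,
        libraries=list(libraries),
    )


# ----------------------------------------------------------------------
# Small-RNA libraries
# ----------------------------------------------------------------------

def _draw_count(rng: np.random.Generator, lam: float, spec: LibrarySpec) -> int:
    if lam <= 0:
        return 0
    if spec.noise == "negative_binomial":
        r = spec.nb_dispersion
        return int(rng.negative_binomial(r, r / (r + lam)))
    return int(rng.poisson(lam))


def generate_srna_libraries(
    scenario: Scenario,
    library_specs: Sequence[LibrarySpec],
    seed: int,
    *,
    adapter: str | None = None,
    partial_adapter_fraction: float = 0.0,
    length_weights: Mapping[int, float] | None = None,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Emit per-library reads and the matching ground-truth counts table.

    Reads are mature/star duplicates (counts drawn around the planted
    tissue profile), 21-nt phased TAS reads, and background genome
    substrings with a 24-nt-dominant length distribution. When
    ``adapter`` is set it is appended in full (or partially for a
    configurable fraction of reads). The counts table records exactly
    what was emitted, so totals are conserved by construction.
    """
    rng = np.random.default_rng(seed)
    weights = dict(length_weights or DEFAULT_LENGTH_WEIGHTS)
    lengths = np.array(sorted(weights))
    probs = np.array([weights[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()

    scaffolds = sorted(scenario.genome)
    reads: dict[str, list[str]] = {}
    rows = []

    def emit(library: str, feature: str, read_kind: str, seq: str, n: int) -> None:
        if n <= 0:
            return
        out = seq
        if adapter:
            if partial_adapter_fraction and rng.random() < partial_adapter_fraction:
                keep = int(rng.integers(6, len(adapter)))
                out = seq + adapter[:keep]
            else:
                out = seq + adapter
        reads[library].extend([out] * n)
        rows.append(
            {"library": library, "feature": feature, "kind": read_kind,
             "sequence": seq, "count": n}
        )

    for spec in library_specs:
        lib = spec.name
        reads[lib] = []
        scale = spec.depth / 1e6
        for mirna in scenario.mirnas:
            lam = mirna.tissue_profile.get(lib, 0.0) * scale
            emit(lib, mirna.name, "mature", mirna.mature_seq, _draw_count(rng, lam, spec))
            emit(
                lib, mirna.name, "star", mirna.star_seq,
                _draw_count(rng, lam * mirna.star_fraction, spec),
            )
        for tas in scenario.tas_loci:
            lam_total = tas.tissue_profile.get(lib, 0.0) * scale
            in_phase = lam_total * (1 - tas.off_phase_noise_fraction)
            for k in range(tas.phased_sirna_count):
                seq = tas.phased_read(k)
                if len(seq) == 21:
                    emit(lib, tas.name, "phased", seq,
                         _draw_count(rng, in_phase / tas.phased_sirna_count, spec))
            n_off = _draw_count(rng, lam_total * tas.off_phase_noise_fraction, spec)
            span = 21 * tas.phased_sirna_count
            for _ in range(n_off):
                while True:
                    off = int(rng.integers(0, span - 21))
                    if off % 21 != 0:
                        break
                pos = tas.cleavage_pos - 1 + off
                emit(lib, tas.name, "off_phase",
                     tas.transcript_seq[pos : pos + 21], 1)
        n_bg = int(round(spec.depth * spec.background_fraction))
        if n_bg:
            bg_lengths = rng.choice(lengths, size=n_bg, p=probs)
            bg_scaffolds = rng.integers(0, len(scaffolds), size=n_bg)
            bg_strands = rng.random(size=n_bg) < 0.5
            for length, sc_idx, minus in zip(bg_lengths, bg_scaffolds, bg_strands):
                ref = scenario.genome[scaffolds[sc_idx]]
                pos = int(rng.integers(0, len(ref) - int(length)))
                seq = ref[pos : pos + int(length)]
                emit(lib, "background", "background", revcomp(seq) if minus else seq, 1)

    counts = pd.DataFrame(
        rows, columns=["library", "feature", "kind", "sequence", "count"]
    )
    return reads, counts


# ----------------------------------------------------------------------
# Degradome libraries
# ----------------------------------------------------------------------

def generate_degradome(
    scenario: Scenario,
    seed: int,
    *,
    depth: int | None = None,
    background_tag_rate: float = 0.0,
    tag_length: int = 20,
) -> tuple[list[tuple[str, int]], pd.DataFrame]:
    """Degradome tags (sequence, count) plus a per-position truth table.

    Guided-cleavage positions of planted targets and TAS trigger sites
    receive their planted counts; background tags are uniform over
    transcript positions at ``background_tag_rate`` tags per nt (or fill
    up to ``depth`` when given). ``depth`` below the planted total is an
    error.
    """
    if not scenario.targets and not scenario.tas_loci:
        raise ValueError("no planted targets or TAS loci to generate a degradome from")
    rng = np.random.default_rng(seed)
    rows = []

    def add(transcript_id: str, seq: str, pos: int, count: int, kind: str) -> None:
        if count <= 0:
            return
        tag = seq[pos - 1 : pos - 1 + tag_length]
        rows.append(
            {"transcript": transcript_id, "position": pos, "kind": kind,
             "sequence": tag, "count": count}
        )

    planted_total = 0
    for target in scenario.targets:
        add(target.transcript_id, target.transcript_seq, target.cleavage_pos,
            target.degradome_tag_count, "cleavage")
        planted_total += target.degradome_tag_count
    for tas in scenario.tas_loci:
        add(tas.name, tas.transcript_seq, tas.cleavage_pos,
            tas.trigger_tag_count, "cleavage")
        planted_total += tas.trigger_tag_count

    if depth is not None and depth < planted_total:
        raise ValueError(
            f"depth {depth} below planted tag total {planted_total}"
        )

    transcripts = scenario.transcripts
    tids = sorted(transcripts)
    if depth is not None:
        n_bg = depth - planted_total
        for _ in range(n_bg):
            tid = tids[int(rng.integers(0, len(tids)))]
            seq = transcripts[tid]
            pos = int(rng.integers(1, len(seq) - tag_length + 2))
            add(tid, seq, pos, 1, "background")
    elif background_tag_rate > 0:
        for tid in tids:
            seq = transcripts[tid]
            n_bg = int(rng.poisson(background_tag_rate * len(seq)))
            for _ in range(n_bg):
                pos = int(rng.integers(1, len(seq) - tag_length + 2))
                add(tid, seq, pos, 1, "background")

    truth = (
        pd.DataFrame(rows, columns=["transcript", "position", "kind", "sequence", "count"])
        .groupby(["transcript", "position", "kind", "sequence"], as_index=False)["count"]
        .sum()
        .sort_values(["transcript", "position", "kind"])
        .reset_index(drop=True)
    )
    tags = [
        (r.sequence, int(r.count))
        for r in truth.itertuples()
    ]
    return tags, truth


# ----------------------------------------------------------------------
# Writers (all plain text)
# ----------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path, *, width: int = 70) -> None:
    with open(path, "w") as out:
        for name in sequences:
            out.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_reads_fasta(reads: Sequence[str], path: str | Path, *, prefix: str = "read") -> None:
    with open(path, "w") as out:
        for i, seq in enumerate(reads, 1):
            out.write(f">{prefix}_{i}\n{seq}\n")


def write_degradome_fasta(tags: Sequence[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as out:
        for i, (seq, count) in enumerate(tags, 1):
            out.write(f">tag_{i}_x{count}\n{seq}\n")


def mirna_references(mirnas: Sequence[PlantedMirna], *, family_prefix: str = "fam") -> dict[str, str]:
    """FASTA entries (``name|family|class`` headers) for a subset of the
    planted matures, usable as a known-miRNA reference set."""
    return {
        f"{m.name}|{family_prefix}_{i + 1}|conserved": m.mature_seq
        for i, m in enumerate(mirnas)
    }


def simulate_ncrna_references(rng: np.random.Generator, n: int = 5, length: int = 80) -> dict[str, str]:
    """Random decoy ncRNA references (tRNA/rRNA stand-ins)."""
    return {f"ncrna_{i + 1}": random_seq(rng, length) for i in range(n)}
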