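"""Pipeline configuration.

Every numeric criterion used by the discovery and validation stages lives
here so a run is fully described by one serialisable object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Thresholds:
    """Numeric criteria applied across the pipeline."""

    #: mismatches tolerated when assigning tags to known references
    known_mismatches: int = 2
    #: mismatches tolerated inside the mature/star duplex of a hairpin
    duplex_mismatches: int = 4
    #: asymmetric bulges tolerated inside the mature/star duplex
    duplex_bulges: int = 1
    #: strict lower bound on (mature+star)/locus reads
    pair_fraction: float = 0.75
    #: strict lower bound on locus-unique read share
    uniqueness_fraction: float = 0.75
    #: target-alignment score cutoff for known (conserved/less-conserved) miRNAs
    align_score_known: float = 4.5
    #: target-alignment score cutoff for novel/candidate miRNAs
    align_score_novel: float = 5.0
    #: minimum insert length kept after trimming
    min_len: int = 15
    #: maximum insert length kept after trimming
    max_len: int = 31
    #: minimum 3' adapter overlap detected at the read end
    adapter_min_overlap: int = 6
    #: genomic flank added on each side of a tag hit when folding
    flank: int = 150
    #: hard cap on the folded window length
    window_cap: int = 400
    #: minimum summed read count for a tag to enter hairpin discovery
    min_discovery_reads: int = 5
    #: maximum genomic loci for a tag to stay in discovery
    max_discovery_loci: int = 20

    def validate(self) -> None:
        if not 0 <= self.known_mismatches <= 5:
            raise ValueError("known_mismatches out of range")
        if self.duplex_mismatches < 0 or self.duplex_bulges < 0:
            raise ValueError("duplex thresholds must be non-negative")
        for name in ("pair_fraction", "uniqueness_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.flank < 50:
            raise ValueError("flank must be >= 50")


@dataclass
class PipelineConfig:
    """Paths, thresholds and labels for a full pipeline run."""

    genome: str = ""
    libraries: dict[str, str] = field(default_factory=dict)
    mirna_reference: str = ""
    ncrna_reference: str = ""
    transcriptome: str = ""
    degradome: str = ""
    intensities: str = ""
    adapter: str = "TGGAATTCTCGGGTG"
    seed: int = 1
    outdir: str = "smallrna_out"
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        self.thresholds.validate()

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        thr = data.pop("thresholds", {})
        cfg = cls(**data, thresholds=Thresholds(**thr))
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
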