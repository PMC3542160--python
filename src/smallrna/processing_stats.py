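"""Precursor-processing statistics from blot band intensities.

APE (arbitrary processing efficiency, percent) is the small-fragment
share of total fragment signal, SFI * 100 / (LFI + SFI). RTA (relative
transcription activity) is total fragment signal over the loading
control, (LFI + SFI) / CFI. The cross-tissue uncoupling summary is a
Spearman rank correlation between APE and RTA: intensities are in
arbitrary units, so only ranks are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BandIntensityRecord:
    """Quantified band intensities for one sample (arbitrary units)."""

    sample: str
    sfi: float  # small (mature) fragment
    lfi: float  # large (precursor) fragment
    cfi: float  # loading-control fragment

    def __post_init__(self):
        if min(self.sfi, self.lfi, self.cfi) < 0:
            raise ValueError("intensities must be non-negative")


def ape(record: BandIntensityRecord) -> float:
    """Arbitrary processing efficiency, percent: SFI*100/(LFI+SFI)."""
    total = record.sfi + record.lfi
    if total == 0:
        raise ValueError(f"no fragment signal for sample {record.sample!r}")
    return record.sfi * 100.0 / total


def rta(record: BandIntensityRecord) -> float:
    """Relative transcription activity: (LFI+SFI)/CFI."""
    if record.cfi <= 0:
        raise ValueError(f"control intensity must be positive for {record.sample!r}")
    return (record.lfi + record.sfi) / record.cfi


def read_intensity_table(path: str | Path) -> list[BandIntensityRecord]:
    """Load a TSV with columns sample, SFI, LFI, CFI (case-insensitive)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return [
        BandIntensityRecord(str(r["sample"]), float(r["sfi"]), float(r["lfi"]), float(r["cfi"]))
        for _, r in df.iterrows()
    ]


def processing_report(
    records: Sequence[BandIntensityRecord],
) -> tuple[pd.DataFrame, dict]:
    """Per-sample APE/RTA table plus an uncoupling summary.

    The summary holds the Spearman correlation between APE and RTA
    across samples with its two-sided p-value; with fewer than two
    samples or zero variance in either statistic the correlation is
    flagged undefined.
    """
    if len(records) < 2:
        raise ValueError("need at least two samples")
    table = pd.DataFrame(
        {
            "sample": [r.sample for r in records],
            "APE": [ape(r) for r in records],
            "RTA": [rta(r) for r in records],
        }
    )
    summary: dict = {"n": len(records)}
    if table["APE"].nunique() < 2 or table["RTA"].nunique() < 2:
        summary.update(correlation=None, p_value=None, defined=False)
    else:
        rho, p = stats.spearmanr(table["APE"], table["RTA"])
        defined = not (math.isnan(rho) or math.isnan(p))
        summary.update(
            correlation=float(rho) if defined else None,
            p_value=float(p) if defined else None,
            defined=defined,
        )
    return table, summary
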