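"""Bundled example catalogs.

Two small TSVs ship with the package: a catalog of 47 peach-specific
miRNAs (per-tissue rpm and star sequences, ``"None detected"`` marking
candidates) and their degradome-validated targets. They serve as
realistic fixtures for the summary operations and as documentation of
the table schemas the pipeline emits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("smallrna.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_mirna_catalog() -> pd.DataFrame:
    """The bundled peach-specific miRNA catalog (47 entries)."""
    return _load("specific_mirnas.tsv")


def load_target_catalog() -> pd.DataFrame:
    """The bundled degradome-validated target catalog."""
    return _load("specific_mirna_targets.tsv")
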