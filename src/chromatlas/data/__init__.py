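"""Bundled published-study statistics used as validation inputs.

Three small TSVs transcribe the per-library read counts, the per-library
quality metrics, and the per-tissue replicate peak-overlap counts reported
for a published cattle/pig multi-tissue ATAC-seq atlas (31 libraries, 8
tissues, 2 biological replicates; one cattle cerebellum replicate was lost
during processing).  The package recomputes the derived columns (percent
informative, NRF, overlap percentages, cohort means) from the raw counts and
checks them against the printed values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_read_counts",
    "load_quality_metrics",
    "load_replicate_overlap",
]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files(__package__).joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_read_counts() -> pd.DataFrame:
    """Raw/mapped/duplicate/informative read counts per library, with the
    published percent-informative column (``pct_raw_printed``)."""
    return _load("library_read_counts.tsv")


def load_quality_metrics() -> pd.DataFrame:
    """Published NRF / FRiP / sJSD per library."""
    return _load("library_quality.tsv")


def load_replicate_overlap() -> pd.DataFrame:
    """Published per-tissue replicate peak counts and overlap percentages."""
    return _load("replicate_overlap.tsv")
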