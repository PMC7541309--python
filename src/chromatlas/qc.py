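"""ATAC-seq library quality statistics.

Implements the standard library QC panel: informative-read percentage,
non-redundant read fraction (NRF, a complexity metric), fraction of reads in
peaks (FRiP, a signal-to-noise metric), binned genome-wide coverage with
RPM/RPKM normalization, replicate Pearson correlation, and a synthetic
Jensen-Shannon distance (sJSD) between the observed per-bin count
distribution and a matched synthetic Poisson background.

The sJSD here is a documented reimplementation of the fingerprint-style
statistic: the observed histogram of per-bin fragment counts is compared,
via Jensen-Shannon divergence (log base 2, square-rooted), against the
histogram of an i.i.d. Poisson sample with the same mean and bin count.  It
is not promised to be bit-compatible with any external tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    EmptySetError,
    GenomeTable,
    PeakSet,
    overlaps_any,
)

__all__ = [
    "LibraryStats",
    "FragmentSet",
    "BinnedCoverage",
    "UndefinedRateError",
    "DegenerateInputError",
    "read_library_stats",
    "write_library_stats",
    "percent_informative",
    "compute_nrf",
    "compute_frip",
    "bin_fragments",
    "js_distance",
    "compute_sjsd",
    "replicate_correlation",
]


class UndefinedRateError(ZeroDivisionError):
    """A rate is requested with a zero denominator."""


class DegenerateInputError(ValueError):
    """The input carries no signal (e.g. all-zero coverage)."""


@dataclass
class LibraryStats:
    """Read-count summary for one sequencing library.

    ``informative_reads`` are the uniquely-mapping, non-duplicate,
    non-mitochondrial reads that survive preprocessing.
    """

    species: str
    tissue: str
    replicate: str
    raw_reads: int
    mapped_reads: int
    duplicate_reads: int
    informative_reads: int

    def __post_init__(self) -> None:
        if self.duplicate_reads > self.mapped_reads:
            raise ValueError("duplicate_reads > mapped_reads")
        if self.informative_reads > self.mapped_reads:
            raise ValueError("informative_reads > mapped_reads")
        if min(self.raw_reads, self.mapped_reads,
               self.duplicate_reads, self.informative_reads) < 0:
            raise ValueError("read counts must be non-negative")


class FragmentSet(PeakSet):
    """Sequenced-fragment intervals for one library (a PeakSet of fragments)."""


_STATS_COLUMNS = [
    "species", "tissue", "replicate",
    "raw_reads", "mapped_reads", "duplicate_reads", "informative_reads",
]


def read_library_stats(path: str | Path) -> list[LibraryStats]:
    """Read a header-carrying TSV of per-library read counts.

    Extra columns (e.g. previously reported percentages) are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"library stats TSV missing columns: {missing}")
    return [
        LibraryStats(
            species=str(r.species), tissue=str(r.tissue), replicate=str(r.replicate),
            raw_reads=int(r.raw_reads), mapped_reads=int(r.mapped_reads),
            duplicate_reads=int(r.duplicate_reads),
            informative_reads=int(r.informative_reads),
        )
        for r in df.itertuples()
    ]


def write_library_stats(stats: Iterable[LibraryStats], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in stats])[_STATS_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def percent_informative(stats: LibraryStats) -> float:
    """Percent of raw reads that were informative, to two decimals."""
    if stats.raw_reads == 0:
        raise UndefinedRateError("raw_reads is zero")
    return round(100.0 * stats.informative_reads / stats.raw_reads, 2)


def compute_nrf(stats: LibraryStats) -> float:
    """Non-redundant read fraction: (mapped - duplicate) / mapped, two decimals."""
    if stats.mapped_reads == 0:
        raise UndefinedRateError("mapped_reads is zero")
    return round(
        (stats.mapped_reads - stats.duplicate_reads) / stats.mapped_reads, 2
    )


def compute_frip(frags: FragmentSet | PeakSet, peaks: PeakSet) -> float:
    """Percent of fragments overlapping any peak by >= 1 bp."""
    if len(frags) == 0:
        raise EmptySetError("FRiP undefined for an empty fragment set")
    in_peak = int(overlaps_any(frags, peaks, min_bp=1).sum())
    return 100.0 * in_peak / len(frags)


@dataclass
class BinnedCoverage:
    """Per-window fragment counts over a genome.

    ``counts`` holds raw integer counts (one vector per chromosome, window
    count = ceil(chrom_len / window)); ``normalization`` tags how
    :meth:`values` scales them for reporting/correlation.
    """

    window: int
    counts: dict[str, np.ndarray]
    normalization: str = "raw"
    total_fragments: int = 0

    def vector(self) -> np.ndarray:
        """Raw counts concatenated in chromosome order."""
        return np.concatenate([self.counts[c] for c in self.counts]) \
            if self.counts else np.array([], dtype=np.int64)

    def values(self) -> np.ndarray:
        """Counts under the tagged normalization, concatenated."""
        v = self.vector().astype(np.float64)
        if self.normalization == "raw":
            return v
        if self.total_fragments == 0:
            raise UndefinedRateError("normalization undefined with no fragments")
        if self.normalization == "RPM":
            return v * 1e6 / self.total_fragments
        if self.normalization == "RPKM":
            return v / ((self.window / 1000.0) * (self.total_fragments / 1e6))
        raise ValueError(f"unknown normalization {self.normalization!r}")

    def compatible_with(self, other: "BinnedCoverage") -> bool:
        return (
            self.window == other.window
            and list(self.counts) == list(other.counts)
            and all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)
        )


def bin_fragments(
    frags: FragmentSet | PeakSet,
    genome: GenomeTable,
    window: int,
    normalization: str = "raw",
) -> BinnedCoverage:
    """Count fragments per fixed-width window (last window truncated).

    A fragment increments every window it overlaps by >= 1 bp.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts = {
        chrom: np.zeros(-(-length // window), dtype=np.int64)
        for chrom, length in genome.lengths.items()
    }
    by_chrom = frags.by_chrom()
    for chrom, (starts, ends) in by_chrom.items():
        if chrom not in counts:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        first = starts // window
        last = (ends - 1) // window
        vec = counts[chrom]
        span = last - first
        for k in range(int(span.max()) + 1 if len(span) else 0):
            sel = span >= k
            np.add.at(vec, first[sel] + k, 1)
    return BinnedCoverage(
        window=window,
        counts=counts,
        normalization=normalization,
        total_fragments=len(frags),
    )


def js_distance(p_counts: Sequence[int] | np.ndarray,
                q_counts: Sequence[int] | np.ndarray) -> float:
    """Jensen-Shannon distance (log base 2) between two per-bin count vectors.

    Each vector is reduced to its histogram over count values, normalized to
    a probability distribution; the JS divergence between the two histograms
    is returned square-rooted, so the value lies in [0, 1].
    """
    p_counts = np.asarray(p_counts, dtype=np.int64)
    q_counts = np.asarray(q_counts, dtype=np.int64)
    if p_counts.size == 0 or q_counts.size == 0:
        raise DegenerateInputError("empty coverage vector")
    hi = int(max(p_counts.max(), q_counts.max()))
    p = np.bincount(p_counts, minlength=hi + 1).astype(np.float64)
    q = np.bincount(q_counts, minlength=hi + 1).astype(np.float64)
    p /= p.sum()
    q /= q.sum()
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        sel = a > 0
        return float(np.sum(a[sel] * np.log2(a[sel] / b[sel])))

    jsd = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    return math.sqrt(max(jsd, 0.0))


def compute_sjsd(cov: BinnedCoverage, seed: int | np.random.Generator = 0) -> float:
    """Synthetic JS distance between observed coverage and a Poisson background.

    The synthetic sample has the same number of bins and mean count as the
    observed coverage, drawn i.i.d. Poisson given ``seed``.  Values near 0
    indicate coverage indistinguishable from uniform noise; strong peak
    concentration pushes the distance toward 1.
    """
    observed = cov.vector()
    if observed.size == 0 or observed.sum() == 0:
        raise DegenerateInputError("all-zero coverage: sJSD undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = float(observed.mean())
    synthetic = rng.poisson(lam, size=observed.size)
    return js_distance(observed, synthetic)


def replicate_correlation(a: BinnedCoverage, b: BinnedCoverage) -> float:
    """Pearson r between two libraries' binned signal (same genome/window)."""
    if not a.compatible_with(b):
        raise ValueError("coverages have different genome/window layout")
    x = a.values()
    y = b.values()
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
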