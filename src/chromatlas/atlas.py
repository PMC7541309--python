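"""Replicate-consensus and tissue-specific open-chromatin atlases.

Per tissue, the reproducible regions are the overlap segments of the two
biological replicates' peak calls, merged.  The cross-tissue consensus atlas
collapses all tissues' reproducible regions into one non-overlapping set and
records, per consensus peak, which tissues it is accessible in (>= 1 bp
overlap with that tissue's reproducible set).  Tissue-specific peaks apply
the stringent definition: reproducible in the tissue in question and not
touched by ANY raw replicate peak of any other tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import (
    GenomeTable,
    PeakSet,
    intersect_regions,
    merge_intervals,
    overlaps_any,
    write_bed,
)

__all__ = [
    "AccessibilityAtlas",
    "AtlasSummary",
    "reproducible_regions",
    "build_atlas",
    "tissue_specific_peaks",
    "activity_distribution",
    "atlas_summary",
]


@dataclass
class AccessibilityAtlas:
    """Consensus peaks with a peak x tissue boolean accessibility matrix."""

    species: str | None
    consensus: PeakSet
    tissues: tuple[str, ...]
    accessibility: np.ndarray  # bool, shape (n_consensus, n_tissues)
    reproducible: dict[str, PeakSet]

    def __post_init__(self) -> None:
        if self.accessibility.shape != (len(self.consensus), len(self.tissues)):
            raise ValueError("accessibility matrix shape mismatch")
        if len(self.consensus) and not self.accessibility.any(axis=1).all():
            raise ValueError("every consensus peak must be accessible somewhere")

    def activity_counts(self) -> np.ndarray:
        """Number of tissues each consensus peak is accessible in."""
        return self.accessibility.sum(axis=1)

    def tissue_index(self, tissue: str) -> int:
        try:
            return self.tissues.index(tissue)
        except ValueError:
            raise KeyError(f"tissue {tissue!r} not in atlas {self.tissues}") from None

    def to_frame(self) -> pd.DataFrame:
        """Accessibility matrix as a DataFrame keyed by peak coordinates."""
        idx = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.consensus]
        return pd.DataFrame(self.accessibility, index=idx, columns=list(self.tissues))

    def export(self, outdir: str | Path, prefix: str = "atlas") -> list[Path]:
        """Write consensus BED + accessibility matrix TSV; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        bed = outdir / f"{prefix}_consensus.bed"
        mat = outdir / f"{prefix}_accessibility.tsv"
        write_bed(self.consensus, bed)
        self.to_frame().rename_axis("peak").to_csv(mat, sep="\t")
        return [bed, mat]


def reproducible_regions(rep_a: PeakSet, rep_b: PeakSet | None = None) -> PeakSet:
    """Regions called as peaks in both biological replicates of a tissue.

    Overlap segments of the two replicate peak sets, merged (gap 0).  For a
    single-replicate tissue, pass the stringently re-called peak set as
    ``rep_a`` alone; it is merged and passed through as already-reproducible.
    """
    if rep_b is None:
        return merge_intervals(rep_a)
    if len(rep_a) == 0 or len(rep_b) == 0:
        warnings.warn(
            f"empty replicate peak set for {rep_a.species}/{rep_a.tissue}; "
            "no reproducible regions",
            stacklevel=2,
        )
        return PeakSet([], species=rep_a.species, tissue=rep_a.tissue)
    out = merge_intervals(intersect_regions(rep_a, rep_b))
    return out.relabel(replicate="consensus")


def build_atlas(
    per_tissue_reproducible: Mapping[str, PeakSet],
    species: str | None = None,
) -> AccessibilityAtlas:
    """Collapse per-tissue reproducible sets into the consensus atlas.

    Consensus = merge of the union over tissues (gap 0, so book-ended
    regions collapse); accessibility[p, t] is true iff consensus peak p
    overlaps tissue t's reproducible set by >= 1 bp.
    """
    if not per_tissue_reproducible:
        raise ValueError("need at least one tissue")
    tissues = tuple(per_tissue_reproducible)
    pooled = PeakSet(
        [iv for ps in per_tissue_reproducible.values() for iv in ps],
        species=species,
        replicate="consensus",
    )
    consensus = merge_intervals(pooled)
    acc = np.zeros((len(consensus), len(tissues)), dtype=bool)
    for j, tissue in enumerate(tissues):
        acc[:, j] = overlaps_any(consensus, per_tissue_reproducible[tissue])
    return AccessibilityAtlas(
        species=species,
        consensus=consensus,
        tissues=tissues,
        accessibility=acc,
        reproducible=dict(per_tissue_reproducible),
    )


def tissue_specific_peaks(
    atlas: AccessibilityAtlas,
    raw_replicate_peaks: Mapping[tuple[str, str], PeakSet],
    tissue: str,
) -> PeakSet:
    """Consensus peaks accessible in ``tissue`` and untouched elsewhere.

    A peak is rejected if it overlaps (>= 1 bp) ANY raw replicate peak call
    of ANY other tissue — even a sub-reproducible single-replicate call.
    ``raw_replicate_peaks`` maps (tissue, replicate) to the raw peak calls.
    """
    j = atlas.tissue_index(tissue)
    keep = atlas.accessibility[:, j].copy()
    for (other_tissue, _rep), raw in raw_replicate_peaks.items():
        if other_tissue == tissue:
            continue
        if len(raw) == 0:
            continue
        keep &= ~overlaps_any(atlas.consensus, raw)
    out = PeakSet(
        [iv for iv, k in zip(atlas.consensus, keep) if k],
        species=atlas.species,
        tissue=tissue,
    )
    return out


def activity_distribution(atlas: AccessibilityAtlas) -> pd.Series:
    """Counts of consensus peaks accessible in exactly k tissues, k = 1..T."""
    ks = atlas.activity_counts()
    t = len(atlas.tissues)
    counts = np.bincount(ks, minlength=t + 1)[1 : t + 1]
    return pd.Series(counts, index=pd.RangeIndex(1, t + 1, name="n_tissues"),
                     name="peaks")


@dataclass(frozen=True)
class AtlasSummary:
    peak_count: int
    mean_width_bp: float | None
    genome_fraction: float


def atlas_summary(atlas: AccessibilityAtlas, genome: GenomeTable) -> AtlasSummary:
    """Peak count, mean width and genome fraction of the consensus set.

    Consensus intervals are non-overlapping, so covered bases equal summed
    widths.  An empty atlas reports a flagged (None) mean width.
    """
    n = len(atlas.consensus)
    covered = atlas.consensus.total_bp()
    mean_width = covered / n if n else None
    return AtlasSummary(
        peak_count=n,
        mean_width_bp=mean_width,
        genome_fraction=covered / genome.total_size,
    )
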