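"""Convenience wiring of the atlas-construction stages.

These helpers assemble the per-tissue reproducible sets and the consensus
atlas from a mapping of raw replicate peak calls, and read such a mapping
from a directory of ``{tissue}_{replicate}.broadPeak`` files — the layout
both the synthetic-world generator and the CLI use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .atlas import AccessibilityAtlas, build_atlas, reproducible_regions
from .intervals import PeakSet, read_bed

__all__ = [
    "read_replicate_peak_dir",
    "reproducible_by_tissue",
    "species_atlas",
]


def read_replicate_peak_dir(
    peak_dir: str | Path,
    dialect: str = "broadPeak",
    species: str | None = None,
) -> dict[tuple[str, str], PeakSet]:
    """Read ``{tissue}_{replicate}.broadPeak`` files into a (tissue, rep) map."""
    peak_dir = Path(peak_dir)
    out: dict[tuple[str, str], PeakSet] = {}
    suffix = ".broadPeak" if dialect == "broadPeak" else ".bed"
    for path in sorted(peak_dir.glob(f"*{suffix}")):
        stem = path.name[: -len(suffix)]
        tissue, _, rep = stem.rpartition("_")
        if not tissue:
            raise ValueError(f"cannot parse tissue/replicate from {path.name}")
        out[(tissue, rep)] = read_bed(path, dialect=dialect, species=species,
                                      tissue=tissue, replicate=rep)
    if not out:
        raise FileNotFoundError(f"no *{suffix} files in {peak_dir}")
    return out


def reproducible_by_tissue(
    raw_peaks: Mapping[tuple[str, str], PeakSet],
    single_replicate_sets: Mapping[str, PeakSet] | None = None,
) -> dict[str, PeakSet]:
    """Per-tissue reproducible regions from raw replicate peak calls.

    Tissues with replicates A and B get the intersect-then-merge treatment;
    tissues listed in ``single_replicate_sets`` (the stringently re-called
    single-replicate case) are merged and passed through.
    """
    tissues = sorted({t for (t, _r) in raw_peaks})
    out: dict[str, PeakSet] = {}
    for tissue in tissues:
        reps = sorted(r for (t, r) in raw_peaks if t == tissue)
        if len(reps) >= 2:
            out[tissue] = reproducible_regions(
                raw_peaks[(tissue, reps[0])], raw_peaks[(tissue, reps[1])]
            )
        else:
            out[tissue] = reproducible_regions(raw_peaks[(tissue, reps[0])])
    if single_replicate_sets:
        for tissue, ps in single_replicate_sets.items():
            out[tissue] = reproducible_regions(ps)
    return out


def species_atlas(
    raw_peaks: Mapping[tuple[str, str], PeakSet],
    species: str | None = None,
    single_replicate_sets: Mapping[str, PeakSet] | None = None,
) -> AccessibilityAtlas:
    """Raw replicate peak calls -> consensus accessibility atlas."""
    per_tissue = reproducible_by_tissue(raw_peaks, single_replicate_sets)
    return build_atlas(per_tissue, species=species)
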