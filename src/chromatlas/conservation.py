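"""Cross-species projection of peaks and conservation classification.

A :class:`HomologyMap` abstracts a whole-genome alignment as directed
blocks: equal-width (source, target) interval pairs with an orientation.
Peaks are projected block-wise (per-base linear transfer, reverse for '-'
blocks), images are clustered by (target chromosome, orientation) with a gap
threshold, and projections hitting more than one cluster are discarded as
multi-locus.  A uniquely projected peak is accessibility-conserved if its
target span overlaps the other species' consensus open chromatin (>= 1 bp),
optionally requiring a shared accessible tissue (after alias translation,
e.g. cortex <-> cerebrum).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureCategory, GeneAnnotation, categorize_labels
from .atlas import AccessibilityAtlas
from .intervals import GenomeInterval, PeakSet

__all__ = [
    "HomologyBlock",
    "HomologyMap",
    "ProjectionStatus",
    "ProjectionResult",
    "ConservationRecord",
    "ThreewayResult",
    "read_homology_map",
    "write_homology_map",
    "project_interval",
    "conserved_accessibility",
    "threeway_conservation",
    "stratified_conservation",
]


@dataclass(frozen=True)
class HomologyBlock:
    """One alignment block: equal-width source and target intervals."""

    source: GenomeInterval
    target: GenomeInterval
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be +/-, got {self.orientation!r}")
        if self.source.width != self.target.width:
            raise ValueError(
                f"block width mismatch: {self.source} vs {self.target}"
            )


class HomologyMap:
    """Directed alignment-block map between two genomes."""

    def __init__(
        self,
        source_species: str,
        target_species: str,
        blocks: Sequence[HomologyBlock],
    ) -> None:
        self.source_species = source_species
        self.target_species = target_species
        self.blocks = tuple(
            sorted(blocks, key=lambda b: (b.source.chrom, b.source.start))
        )
        # source intervals must be non-overlapping within one map
        prev: HomologyBlock | None = None
        for b in self.blocks:
            if (
                prev is not None
                and b.source.chrom == prev.source.chrom
                and b.source.start < prev.source.end
            ):
                raise ValueError(
                    f"overlapping source blocks: {prev.source} and {b.source}"
                )
            prev = b
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for idx, b in enumerate(self.blocks):
            self._by_chrom.setdefault(b.source.chrom, ([], [], []))  # type: ignore
        tmp: dict[str, list[list[int]]] = {}
        for idx, b in enumerate(self.blocks):
            tmp.setdefault(b.source.chrom, [[], [], []])
            tmp[b.source.chrom][0].append(b.source.start)
            tmp[b.source.chrom][1].append(b.source.end)
            tmp[b.source.chrom][2].append(idx)
        self._by_chrom = {
            c: tuple(np.asarray(v, dtype=np.int64) for v in vals)  # type: ignore
            for c, vals in tmp.items()
        }

    def __len__(self) -> int:
        return len(self.blocks)

    def invert(self) -> "HomologyMap":
        """Swap source and target (orientation is preserved)."""
        return HomologyMap(
            self.target_species,
            self.source_species,
            [HomologyBlock(b.target, b.source, b.orientation) for b in self.blocks],
        )

    def overlapping_blocks(self, iv: GenomeInterval) -> list[HomologyBlock]:
        if iv.chrom not in self._by_chrom:
            return []
        starts, ends, idx = self._by_chrom[iv.chrom]
        i = int(np.searchsorted(ends, iv.start, side="right"))
        j = int(np.searchsorted(starts, iv.end, side="left"))
        return [self.blocks[idx[k]] for k in range(i, j)]


_MAP_COLUMNS = [
    "src_chrom", "src_start", "src_end",
    "tgt_species", "tgt_chrom", "tgt_start", "tgt_end", "orientation",
]


def read_homology_map(path: str | Path, source_species: str,
                      target_species: str | None = None) -> HomologyMap:
    """Read a block map TSV (headered; see ``_MAP_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"homology map TSV missing columns: {missing}")
    if target_species is not None:
        df = df[df.tgt_species == target_species]
    else:
        species = sorted(df.tgt_species.unique())
        if len(species) != 1:
            raise ValueError(
                f"map contains several target species {species}; pick one"
            )
        target_species = str(species[0])
    blocks = [
        HomologyBlock(
            GenomeInterval(str(r.src_chrom), int(r.src_start), int(r.src_end)),
            GenomeInterval(str(r.tgt_chrom), int(r.tgt_start), int(r.tgt_end)),
            str(r.orientation),
        )
        for r in df.itertuples()
    ]
    return HomologyMap(source_species, target_species, blocks)


def write_homology_map(hmap: HomologyMap, path: str | Path) -> None:
    rows = [
        {
            "src_chrom": b.source.chrom, "src_start": b.source.start,
            "src_end": b.source.end, "tgt_species": hmap.target_species,
            "tgt_chrom": b.target.chrom, "tgt_start": b.target.start,
            "tgt_end": b.target.end, "orientation": b.orientation,
        }
        for b in hmap.blocks
    ]
    pd.DataFrame(rows, columns=_MAP_COLUMNS).to_csv(path, sep="\t", index=False)


class ProjectionStatus(enum.Enum):
    UNMAPPED = "unmapped"
    UNIQUE = "unique"
    MULTI_LOCUS = "multi_locus"


@dataclass(frozen=True)
class ProjectionResult:
    source: GenomeInterval
    status: ProjectionStatus
    target: GenomeInterval | None = None

    def __post_init__(self) -> None:
        if (self.target is not None) != (self.status is ProjectionStatus.UNIQUE):
            raise ValueError("target present iff status is unique")


def _block_image(iv: GenomeInterval, block: HomologyBlock) -> GenomeInterval | None:
    """Image of iv's overlap with one block, in target coordinates."""
    s = max(iv.start, block.source.start)
    e = min(iv.end, block.source.end)
    if s >= e:
        return None
    off_s = s - block.source.start
    off_e = e - block.source.start
    if block.orientation == "+":
        ts, te = block.target.start + off_s, block.target.start + off_e
    else:
        ts, te = block.target.end - off_e, block.target.end - off_s
    return GenomeInterval(block.target.chrom, ts, te)


def project_interval(
    iv: GenomeInterval,
    hmap: HomologyMap,
    group_gap: int = 10_000,
) -> ProjectionResult:
    """Project one interval through the block map.

    Per-block images are grouped by (target chromosome, orientation);
    groups whose spans are within ``group_gap`` bp of each other are merged.
    0 groups -> unmapped; 1 group -> unique (target = group span);
    >= 2 groups -> multi_locus (discarded downstream).
    """
    images: dict[tuple[str, str], list[GenomeInterval]] = {}
    for block in hmap.overlapping_blocks(iv):
        img = _block_image(iv, block)
        if img is not None:
            images.setdefault((block.target.chrom, block.orientation), []).append(img)
    groups: list[GenomeInterval] = []
    for (chrom, _ori), imgs in images.items():
        imgs = sorted(imgs, key=lambda g: g.start)
        cur_s, cur_e = imgs[0].start, imgs[0].end
        for g in imgs[1:]:
            if g.start - cur_e <= group_gap:
                cur_e = max(cur_e, g.end)
            else:
                groups.append(GenomeInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = g.start, g.end
        groups.append(GenomeInterval(chrom, cur_s, cur_e))
    if not groups:
        return ProjectionResult(iv, ProjectionStatus.UNMAPPED)
    if len(groups) == 1:
        return ProjectionResult(iv, ProjectionStatus.UNIQUE, groups[0])
    return ProjectionResult(iv, ProjectionStatus.MULTI_LOCUS)


@dataclass
class ConservationRecord:
    """Conservation call for one source consensus peak against one target."""

    peak_index: int
    source: GenomeInterval
    target_species: str
    status: ProjectionStatus
    target: GenomeInterval | None = None
    overlaps_consensus: bool = False
    shared_tissues: tuple[str, ...] = ()
    conserved: bool = False


def conserved_accessibility(
    source_atlas: AccessibilityAtlas,
    target_atlas: AccessibilityAtlas,
    hmap: HomologyMap,
    mode: str = "same_tissue",
    tissue_aliases: Mapping[str, str] | None = None,
    group_gap: int = 10_000,
) -> list[ConservationRecord]:
    """Classify each source consensus peak's accessibility conservation.

    ``mode="any_tissue"`` requires only that the unique target span overlaps
    target consensus open chromatin; ``mode="same_tissue"`` additionally
    requires >= 1 tissue (after alias translation) accessible on both sides.
    """
    if mode not in ("any_tissue", "same_tissue"):
        raise ValueError(f"unknown mode {mode!r}")
    if source_atlas.species != hmap.source_species or \
            target_atlas.species != hmap.target_species:
        raise ValueError(
            f"species mismatch: atlases ({source_atlas.species} -> "
            f"{target_atlas.species}) vs map ({hmap.source_species} -> "
            f"{hmap.target_species})"
        )
    tgt_by_chrom = target_atlas.consensus.by_chrom()
    records: list[ConservationRecord] = []
    for i, iv in enumerate(source_atlas.consensus):
        proj = project_interval(iv, hmap, group_gap=group_gap)
        rec = ConservationRecord(
            peak_index=i, source=iv, target_species=hmap.target_species,
            status=proj.status, target=proj.target,
        )
        if proj.status is ProjectionStatus.UNIQUE:
            tgt = proj.target
            hit_tissues: set[str] = set()
            overlapped = False
            if tgt.chrom in tgt_by_chrom:
                starts, ends = tgt_by_chrom[tgt.chrom]
                lo = int(np.searchsorted(ends, tgt.start, side="right"))
                hi = int(np.searchsorted(starts, tgt.end, side="left"))
                hit_rows = [
                    k for k in _consensus_rows(target_atlas, tgt.chrom, lo, hi)
                ]
                overlapped = hi > lo
                for k in hit_rows:
                    for j, t in enumerate(target_atlas.tissues):
                        if target_atlas.accessibility[k, j]:
                            hit_tissues.add(t)
            rec.overlaps_consensus = overlapped
            if overlapped:
                src_tissues = {
                    t for j, t in enumerate(source_atlas.tissues)
                    if source_atlas.accessibility[i, j]
                }
                # shared tissues reported in SOURCE vocabulary so that
                # multi-target intersections compare like with like
                shared = {
                    t for t in src_tissues
                    if (tissue_aliases.get(t, t) if tissue_aliases else t)
                    in hit_tissues
                }
                rec.shared_tissues = tuple(sorted(shared))
                rec.conserved = bool(shared) if mode == "same_tissue" else True
        records.append(rec)
    return records


def _consensus_rows(atlas: AccessibilityAtlas, chrom: str, lo: int, hi: int):
    """Row indices in the atlas matrix for consensus peaks [lo, hi) of chrom."""
    # consensus is chrom-sorted; compute the chrom's global row offset once
    offsets = getattr(atlas, "_row_offsets", None)
    if offsets is None:
        offsets = {}
        for idx, iv in enumerate(atlas.consensus):
            offsets.setdefault(iv.chrom, idx)
        atlas._row_offsets = offsets  # type: ignore[attr-defined]
    base = offsets[chrom]
    return range(base + lo, base + hi)


@dataclass
class ThreewayResult:
    """Three-species conservation sets, anchored on the reference species."""

    reference: str
    others: tuple[str, str]
    mappable_to_all: list[int]
    conserved_in_all: list[int]
    conserved_pair_only: dict[str, list[int]]
    shared_tissue_counts: pd.Series
    records: dict[str, list[ConservationRecord]] = field(default_factory=dict)


def threeway_conservation(
    atlases: Mapping[str, AccessibilityAtlas],
    maps: Mapping[tuple[str, str], HomologyMap],
    reference: str,
    tissue_aliases: Mapping[str, Mapping[str, str]] | None = None,
    group_gap: int = 10_000,
) -> ThreewayResult:
    """Classify reference consensus peaks by conservation across all species.

    ``maps`` must contain the (reference, other) ordered pairs.  A peak is
    mappable-to-all if it projects uniquely to both other species;
    conserved-in-all if additionally a tissue (at least one, the same one)
    is accessible in all three species; conserved-pair-only if the
    same-tissue criterion holds against exactly one of the two others.
    """
    others = tuple(s for s in atlases if s != reference)
    if len(others) != 2:
        raise ValueError("need exactly three atlases")
    recs: dict[str, list[ConservationRecord]] = {}
    for other in others:
        key = (reference, other)
        if key not in maps:
            raise ValueError(f"missing homology map for {key}")
        aliases = tissue_aliases.get(other) if tissue_aliases else None
        recs[other] = conserved_accessibility(
            atlases[reference], atlases[other], maps[key],
            mode="same_tissue", tissue_aliases=aliases, group_gap=group_gap,
        )
    n = len(atlases[reference].consensus)
    mappable, conserved_all = [], []
    pair_only: dict[str, list[int]] = {o: [] for o in others}
    shared_counts: list[int] = []
    for i in range(n):
        r1, r2 = recs[others[0]][i], recs[others[1]][i]
        if not (r1.status is ProjectionStatus.UNIQUE
                and r2.status is ProjectionStatus.UNIQUE):
            continue
        mappable.append(i)
        c1, c2 = r1.conserved, r2.conserved
        if c1 and c2:
            # require a single tissue shared by all three (reference labels
            # are the shared vocabulary after alias translation)
            both = set(r1.shared_tissues) & set(r2.shared_tissues)
            if both:
                conserved_all.append(i)
                shared_counts.append(len(both))
                continue
        if c1 and not c2:
            pair_only[others[0]].append(i)
        elif c2 and not c1:
            pair_only[others[1]].append(i)
    counts = pd.Series(shared_counts, dtype=int).value_counts().sort_index()
    counts.index.name = "n_shared_tissues"
    return ThreewayResult(
        reference=reference,
        others=others,  # type: ignore[arg-type]
        mappable_to_all=mappable,
        conserved_in_all=conserved_all,
        conserved_pair_only=pair_only,
        shared_tissue_counts=counts,
        records=recs,
    )


def stratified_conservation(
    atlas: AccessibilityAtlas,
    records: Sequence[ConservationRecord],
    ann: GeneAnnotation,
    strata: Sequence[str] = ("all", "promoter", "intergenic"),
) -> dict[str, float]:
    """Conserved fraction of consensus peaks per annotation stratum.

    The promoter stratum uses the extended promoter window (2 kb upstream
    to 50 bp downstream of the TSS): a peak is promoter-stratum if its
    category under that window is TSS or Promoter; intergenic-stratum if it
    overlaps no feature.  Fractions are conserved / stratum size (empty
    stratum reports 0.0).
    """
    if len(records) != len(atlas.consensus):
        raise ValueError("records must cover the atlas consensus set")
    labels = categorize_labels(atlas.consensus, ann, promoter_downstream=50)
    conserved = np.array([r.conserved for r in records], dtype=bool)
    out: dict[str, float] = {}
    for stratum in strata:
        if stratum == "all":
            sel = np.ones(len(labels), dtype=bool)
        elif stratum == "promoter":
            sel = np.array(
                [l in (FeatureCategory.TSS, FeatureCategory.PROMOTER) for l in labels]
            )
        elif stratum == "intergenic":
            sel = np.array([l is FeatureCategory.INTERGENIC for l in labels])
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        out[stratum] = float(conserved[sel].sum() / sel.sum()) if sel.any() else 0.0
    return out
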