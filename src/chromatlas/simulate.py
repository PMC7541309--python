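"""Self-contained synthetic three-species ATAC-seq world.

The generator emits, per species: a genome table, an Ensembl-dialect GTF
gene annotation, per-tissue per-replicate broadPeak files, per-library
fragment BEDs, library read-count statistics, pairwise homology-block maps
and a tissue-alias table — every quantity the pipeline measures controlled
by an explicit parameter, with exact truth bookkeeping for
parameter-recovery tests.

Layout: each chromosome is split into three zones — a gene region (genes on
a fixed grid, one TSS each), a distal-slot region (an evenly spaced grid of
candidate regulatory loci, kept clear of gene features), and a noise zone
where irreproducible per-library noise peaks live so they can never collide
with planted loci.  Homologous loci across species share a slot index:
species are built on the same grid, and homology blocks link a source
peak's locus (plus flank) to the same slot in the target genome, so
projection truth is exact by construction.

Planted peak classes: ``housekeeping`` (TSS-centred, accessible in every
tissue of the panel), ``tissue_specific`` (distal, one tissue), ``shared``
(distal, 2..T-1 tissues), and per-target-species private peaks at unused
slots.  A planted peak appears in a replicate's peak file with probability
``replicate_detection`` (boundaries jittered ±10% of width).  Fragments are
placed inside that library's own peaks with probability ``frip_target`` and
strictly outside otherwise; each fragment gains a duplicate copy with
probability ``duplication_rate``, so the expected non-redundant fraction is
1 / (1 + duplication_rate).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    GenomeInterval,
    GenomeTable,
    PeakSet,
    complement,
    merge_intervals,
    read_bed,
    read_genome_table,
    write_genome_table,
)
from .qc import FragmentSet, LibraryStats, read_library_stats, write_library_stats

__all__ = [
    "SimulationConfig",
    "TruthPeak",
    "PartnerLink",
    "TruthTables",
    "World",
    "generate_world",
    "recover_parameters",
]

_GENE_BLOCK = 20_000
_GENE_OFFSET = 4_000
_DEFAULT_TISSUES = (
    "adipose", "cerebellum", "cortex", "hypothalamus",
    "liver", "lung", "muscle", "spleen",
)
# third species mimics a mouse-style panel: no hypothalamus, two renamed labels
_THIRD_SPECIES_RENAMES = {"adipose": "mesenteric_fat", "cortex": "cerebrum"}
_THIRD_SPECIES_DROPS = ("hypothalamus",)


@dataclass
class SimulationConfig:
    """All generator knobs; defaults are the standard study conditions."""

    seed: int = 0
    species: tuple[str, ...] = ("bov", "sus", "mus")
    tissues: tuple[str, ...] = _DEFAULT_TISSUES
    chrom_count: int = 2
    chrom_length: int = 5_000_000
    genes_per_species: int = 200
    housekeeping_peaks: int = 120
    tissue_specific_per_tissue: int = 80
    shared_peaks: int = 400
    private_housekeeping: int = 40
    private_distal: int = 150
    peak_width_median: float = 500.0
    peak_width_sigma: float = 0.45
    peak_width_min: int = 150
    peak_width_max: int = 1200
    replicate_detection: float = 0.8
    boundary_jitter: float = 0.10
    noise_peaks_per_library: float = 150.0
    fragments_per_library: int = 50_000
    frip_target: float = 0.35
    duplication_rate: float = 0.6
    mapped_fraction: float = 0.9
    fragment_min: int = 150
    fragment_max: int = 250
    seq_conservation_promoter: float = 0.8
    seq_conservation_distal: float = 0.5
    far_pair_factor: float = 0.6
    acc_conservation_promoter: float = 0.625
    acc_conservation_distal: float = 0.3
    activity_shuffle_rate: float = 0.25
    reverse_block_rate: float = 0.1
    homology_flank: int = 300

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.tissues = tuple(self.tissues)
        for name in (
            "replicate_detection", "frip_target", "duplication_rate",
            "mapped_fraction", "seq_conservation_promoter",
            "seq_conservation_distal", "far_pair_factor",
            "acc_conservation_promoter", "acc_conservation_distal",
            "activity_shuffle_rate", "reverse_block_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.acc_conservation_promoter < self.acc_conservation_distal:
            raise ValueError(
                "promoter accessibility conservation must be >= distal "
                "(the default world emulates stronger promoter constraint)"
            )
        if self.genes_per_species % self.chrom_count:
            raise ValueError("genes_per_species must divide evenly over chromosomes")
        gene_region = (self.genes_per_species // self.chrom_count) * _GENE_BLOCK
        if gene_region + self.distal_zone_size + self.noise_zone_size \
                > self.chrom_length * 1:
            raise ValueError("chromosome too short for the configured layout")

    # -- layout ----------------------------------------------------------

    @property
    def genes_per_chrom(self) -> int:
        return self.genes_per_species // self.chrom_count

    @property
    def gene_region_size(self) -> int:
        return self.genes_per_chrom * _GENE_BLOCK

    @property
    def distal_zone_size(self) -> int:
        return 2_000_000

    @property
    def noise_zone_size(self) -> int:
        return 1_000_000

    @property
    def n_distal_slots(self) -> int:
        used = (
            self.tissue_specific_per_tissue * len(self.tissues)
            + self.shared_peaks
        )
        return used + self.private_distal * 2  # reserve for both target species

    @property
    def slots_per_chrom(self) -> int:
        return -(-self.n_distal_slots // self.chrom_count)

    def chrom_name(self, species: str, ci: int) -> str:
        return f"{species}_chr{ci + 1}"

    def genome(self, species: str) -> GenomeTable:
        return GenomeTable({
            self.chrom_name(species, ci): self.chrom_length
            for ci in range(self.chrom_count)
        })

    def panel(self, species: str) -> tuple[str, ...]:
        """Tissue labels sampled for a species (third species: renamed panel)."""
        if self.species.index(species) != 2:
            return self.tissues
        out = []
        for t in self.tissues:
            if t in _THIRD_SPECIES_DROPS:
                continue
            out.append(_THIRD_SPECIES_RENAMES.get(t, t))
        return tuple(out)

    def alias_map(self, src: str, tgt: str) -> dict[str, str]:
        """Tissue-label translation from src species' panel to tgt's."""
        out: dict[str, str] = {}
        si, ti = self.species.index(src), self.species.index(tgt)
        if ti == 2 and si != 2:
            out = dict(_THIRD_SPECIES_RENAMES)
        elif si == 2 and ti != 2:
            out = {v: k for k, v in _THIRD_SPECIES_RENAMES.items()}
        return out

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["species"] = list(self.species)
        d["tissues"] = list(self.tissues)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["species"] = tuple(d["species"])
        d["tissues"] = tuple(d["tissues"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthPeak:
    uid: str
    species: str
    pclass: str  # housekeeping | tissue_specific | shared | private_hk | private_distal
    slot: int    # gene index (hk classes) or distal slot index
    chrom: str
    start: int
    end: int
    activity: tuple[str, ...]
    # (tissue, replicate) -> jittered emitted interval, or None if undetected
    detected: dict[tuple[str, str], tuple[int, int] | None] = field(default_factory=dict)

    @property
    def interval(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, name=self.uid)

    def reproducible_tissues(self) -> set[str]:
        return {
            t for t in self.activity
            if self.detected.get((t, "A")) and self.detected.get((t, "B"))
        }


@dataclass
class PartnerLink:
    source_uid: str
    target_species: str
    seq_conserved: bool
    acc_conserved: bool
    activity_shuffled: bool = False
    target_uid: str | None = None


@dataclass
class TruthTables:
    peaks: dict[str, list[TruthPeak]]
    links: dict[tuple[str, str], PartnerLink]

    def by_uid(self, species: str) -> dict[str, TruthPeak]:
        return {p.uid: p for p in self.peaks[species]}


# ---------------------------------------------------------------------------
# World on disk
# ---------------------------------------------------------------------------

class World:
    """Paths and cached readers for one generated world."""

    def __init__(self, config: SimulationConfig, root: Path, truth: TruthTables):
        self.config = config
        self.root = Path(root)
        self.truth = truth
        self._cache: dict = {}

    # path scheme -------------------------------------------------------
    def species_dir(self, sp: str) -> Path:
        return self.root / sp

    def genome_path(self, sp: str) -> Path:
        return self.species_dir(sp) / "genome.tsv"

    def gtf_path(self, sp: str) -> Path:
        return self.species_dir(sp) / "annotation.gtf"

    def peak_path(self, sp: str, tissue: str, rep: str) -> Path:
        return self.species_dir(sp) / "peaks" / f"{tissue}_{rep}.broadPeak"

    def fragment_path(self, sp: str, tissue: str, rep: str) -> Path:
        return self.species_dir(sp) / "fragments" / f"{tissue}_{rep}.bed"

    def stats_path(self) -> Path:
        return self.root / "library_stats.tsv"

    def homology_path(self, src: str, tgt: str) -> Path:
        return self.root / "homology" / f"{src}_to_{tgt}.tsv"

    def alias_path(self) -> Path:
        return self.root / "tissue_aliases.tsv"

    def manifest_path(self) -> Path:
        return self.root / "manifest.tsv"

    # readers -----------------------------------------------------------
    def genome(self, sp: str) -> GenomeTable:
        key = ("genome", sp)
        if key not in self._cache:
            self._cache[key] = read_genome_table(self.genome_path(sp))
        return self._cache[key]

    def annotation(self, sp: str):
        from .annotation import read_gtf

        key = ("ann", sp)
        if key not in self._cache:
            self._cache[key] = read_gtf(self.gtf_path(sp))
        return self._cache[key]

    def raw_peaks(self, sp: str) -> dict[tuple[str, str], PeakSet]:
        key = ("raw", sp)
        if key not in self._cache:
            out = {}
            for tissue in self.config.panel(sp):
                for rep in ("A", "B"):
                    out[(tissue, rep)] = read_bed(
                        self.peak_path(sp, tissue, rep), dialect="broadPeak",
                        species=sp, tissue=tissue, replicate=rep,
                    )
            self._cache[key] = out
        return self._cache[key]

    def fragments(self, sp: str, tissue: str, rep: str) -> FragmentSet:
        ps = read_bed(self.fragment_path(sp, tissue, rep),
                      species=sp, tissue=tissue, replicate=rep)
        return FragmentSet(ps.intervals, species=sp, tissue=tissue, replicate=rep)

    def library_stats(self) -> list[LibraryStats]:
        return read_library_stats(self.stats_path())

    def homology(self, src: str, tgt: str):
        from .conservation import read_homology_map

        return read_homology_map(self.homology_path(src, tgt), src, tgt)

    def tissue_aliases(self, src: str, tgt: str) -> dict[str, str]:
        df = pd.read_csv(self.alias_path(), sep="\t")
        sel = df[(df.src_species == src) & (df.tgt_species == tgt)]
        return dict(zip(sel.src_tissue, sel.tgt_tissue))

    def atlas(self, sp: str):
        from .pipeline import species_atlas

        key = ("atlas", sp)
        if key not in self._cache:
            self._cache[key] = species_atlas(self.raw_peaks(sp), species=sp)
        return self._cache[key]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _widths(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    w = rng.lognormal(np.log(cfg.peak_width_median), cfg.peak_width_sigma, n)
    return np.clip(np.round(w), cfg.peak_width_min, cfg.peak_width_max).astype(np.int64)


@dataclass
class _SpeciesLayout:
    """Deterministic slot coordinates for one species."""

    species: str
    genes: list[dict]           # per gene: chrom, start, end, strand, exons, ...
    tss: np.ndarray             # gene index -> TSS position (genome coords)
    gene_chrom: list[str]
    distal_center: np.ndarray   # slot index -> center position
    distal_chrom: list[str]


def _build_layout(sp: str, cfg: SimulationConfig, rng: np.random.Generator) -> _SpeciesLayout:
    genes: list[dict] = []
    tss: list[int] = []
    gene_chrom: list[str] = []
    for ci in range(cfg.chrom_count):
        chrom = cfg.chrom_name(sp, ci)
        for k in range(cfg.genes_per_chrom):
            block = k * _GENE_BLOCK
            glen = int(rng.integers(6000, 12001))
            strand = "+" if rng.random() < 0.5 else "-"
            gs = block + _GENE_OFFSET
            ge = gs + glen
            e1 = (gs, gs + 400)
            e2 = (gs + 1800, gs + 2200)
            e3 = (ge - 600, ge)
            if strand == "+":
                utr5 = ((e1[0], e1[0] + 150),)
                utr3 = ((e3[1] - 200, e3[1]),)
                cds = ((e1[0] + 150, e1[1]), e2, (e3[0], e3[1] - 200))
            else:
                utr5 = ((e3[1] - 150, e3[1]),)
                utr3 = ((e1[0], e1[0] + 200),)
                cds = ((e1[0] + 200, e1[1]), e2, (e3[0], e3[1] - 150))
            gidx = len(genes)
            genes.append({
                "gene_id": f"{sp}_g{gidx:04d}", "chrom": chrom, "start": gs,
                "end": ge, "strand": strand, "exons": (e1, e2, e3),
                "cds": cds, "utr5": utr5, "utr3": utr3,
            })
            tss.append(gs if strand == "+" else ge - 1)
            gene_chrom.append(chrom)
    spacing = cfg.distal_zone_size / cfg.slots_per_chrom
    centers: list[int] = []
    distal_chrom: list[str] = []
    zone_start = cfg.gene_region_size
    for j in range(cfg.n_distal_slots):
        ci = j // cfg.slots_per_chrom
        k = j % cfg.slots_per_chrom
        offset = int(rng.integers(-400, 401))
        centers.append(zone_start + int((k + 0.5) * spacing) + offset)
        distal_chrom.append(cfg.chrom_name(sp, ci))
    return _SpeciesLayout(
        species=sp, genes=genes, tss=np.asarray(tss, dtype=np.int64),
        gene_chrom=gene_chrom,
        distal_center=np.asarray(centers, dtype=np.int64),
        distal_chrom=distal_chrom,
    )


def _peak_at(layout: _SpeciesLayout, pclass: str, slot: int, width: int) -> tuple[str, int, int]:
    if pclass in ("housekeeping", "private_hk"):
        chrom = layout.gene_chrom[slot]
        center = int(layout.tss[slot])
    else:
        chrom = layout.distal_chrom[slot]
        center = int(layout.distal_center[slot])
    start = center - width // 2
    return chrom, start, start + width


def _write_gtf(layout: _SpeciesLayout, path: Path) -> None:
    with open(path, "w") as fh:
        for g in layout.genes:
            gid = g["gene_id"]
            attrs = f'gene_id "{gid}"; gene_name "{gid}";'
            tattrs = f'gene_id "{gid}"; transcript_id "{gid}.t1"; gene_name "{gid}";'
            fh.write(
                f"{g['chrom']}\tsim\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g['chrom']}\tsim\ttranscript\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{tattrs}\n"
            )
            for ftype, key in (
                ("exon", "exons"), ("CDS", "cds"),
                ("five_prime_utr", "utr5"), ("three_prime_utr", "utr3"),
            ):
                for s, e in g[key]:
                    fh.write(
                        f"{g['chrom']}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t"
                        f"{g['strand']}\t.\t{tattrs}\n"
                    )


def _jitter(rng: np.random.Generator, start: int, end: int, frac: float,
            chrom_len: int) -> tuple[int, int]:
    w = end - start
    d1 = int(round(rng.uniform(-frac * w, frac * w)))
    d2 = int(round(rng.uniform(-frac * w, frac * w)))
    s, e = max(0, start + d1), min(chrom_len, end + d2)
    if s >= e:  # degenerate jitter on a tiny peak; keep original
        s, e = start, end
    return s, e


def _translate_activity(
    act: Sequence[str], src: str, tgt: str, cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    amap = cfg.alias_map(src, tgt)
    panel = cfg.panel(tgt)
    out = tuple(sorted({amap.get(t, t) for t in act} & set(panel)))
    if not out:  # activity entirely in tissues the target panel lacks
        out = (panel[int(rng.integers(len(panel)))],)
    return out


def generate_world(
    cfg: SimulationConfig,
    outdir: str | Path,
) -> World:
    """Generate all world files under ``outdir``; returns the World handle.

    Deterministic given ``cfg.seed`` (byte-identical files on re-run).
    """
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    ref, *targets = cfg.species
    if len(targets) != 2:
        raise ValueError("the generator builds exactly three species")

    layouts = {sp: _build_layout(sp, cfg, rng) for sp in cfg.species}
    genomes = {sp: cfg.genome(sp) for sp in cfg.species}

    # ----- reference peak complement -----------------------------------
    T = len(cfg.tissues)
    truth_peaks: dict[str, list[TruthPeak]] = {sp: [] for sp in cfg.species}
    links: dict[tuple[str, str], PartnerLink] = {}

    hk_slots = sorted(rng.choice(cfg.genes_per_species, cfg.housekeeping_peaks,
                                 replace=False).tolist())
    ref_layout = layouts[ref]
    ref_peaks: list[TruthPeak] = []

    def add_peak(sp: str, pclass: str, slot: int, width: int,
                 activity: tuple[str, ...]) -> TruthPeak:
        layout = layouts[sp]
        chrom, s, e = _peak_at(layout, pclass, slot, width)
        uid = f"{sp}:{pclass}:{slot}"
        p = TruthPeak(uid=uid, species=sp, pclass=pclass, slot=slot,
                      chrom=chrom, start=s, end=e, activity=activity)
        truth_peaks[sp].append(p)
        return p

    panel_ref = cfg.panel(ref)
    for slot in hk_slots:
        w = int(_widths(rng, cfg, 1)[0])
        ref_peaks.append(add_peak(ref, "housekeeping", slot, w, panel_ref))
    slot_cursor = 0
    for tissue in cfg.tissues:
        for _ in range(cfg.tissue_specific_per_tissue):
            w = int(_widths(rng, cfg, 1)[0])
            ref_peaks.append(
                add_peak(ref, "tissue_specific", slot_cursor, w, (tissue,))
            )
            slot_cursor += 1
    for _ in range(cfg.shared_peaks):
        k = int(rng.integers(2, T))
        act = tuple(sorted(
            cfg.tissues[i] for i in rng.choice(T, k, replace=False)
        ))
        w = int(_widths(rng, cfg, 1)[0])
        ref_peaks.append(add_peak(ref, "shared", slot_cursor, w, act))
        slot_cursor += 1
    n_used_distal = slot_cursor

    # ----- conservation draws and target complements --------------------
    for tgt_i, tgt in enumerate(targets):
        factor = 1.0 if tgt_i == 0 else cfg.far_pair_factor
        for p in ref_peaks:
            promoter_like = p.pclass == "housekeeping"
            seq_rate = (cfg.seq_conservation_promoter if promoter_like
                        else cfg.seq_conservation_distal) * factor
            acc_rate = (cfg.acc_conservation_promoter if promoter_like
                        else cfg.acc_conservation_distal)
            seq = bool(rng.random() < seq_rate)
            acc = bool(seq and rng.random() < acc_rate)
            shuffled = bool(
                acc and not promoter_like and rng.random() < cfg.activity_shuffle_rate
            )
            link = PartnerLink(p.uid, tgt, seq_conserved=seq, acc_conserved=acc,
                               activity_shuffled=shuffled)
            if acc:
                act = _translate_activity(p.activity, ref, tgt, cfg, rng)
                if shuffled:
                    panel = cfg.panel(tgt)
                    others = [t for t in panel if t not in act]
                    k = min(len(act), len(others))
                    if k:
                        act = tuple(sorted(
                            others[i] for i in rng.choice(len(others), k,
                                                          replace=False)
                        ))
                w = int(_widths(rng, cfg, 1)[0])
                partner = add_peak(tgt, p.pclass, p.slot, w, act)
                link.target_uid = partner.uid
            links[(p.uid, tgt)] = link

        # private peaks so the target atlas is not just a mirror of the ref
        panel_tgt = cfg.panel(tgt)
        # keep private peaks off every reference housekeeping slot, so a
        # seq-conserved but non-acc-conserved projection can never hit one
        used_genes = set(hk_slots) | {
            pk.slot for pk in truth_peaks[tgt] if pk.pclass == "housekeeping"
        }
        free_genes = [g for g in range(cfg.genes_per_species) if g not in used_genes]
        take = min(cfg.private_housekeeping, len(free_genes))
        pick = sorted(
            free_genes[i]
            for i in rng.choice(len(free_genes), take, replace=False)
        )
        for slot in pick:
            w = int(_widths(rng, cfg, 1)[0])
            add_peak(tgt, "private_hk", slot, w, panel_tgt)
        private_slots = range(
            n_used_distal + tgt_i * cfg.private_distal,
            n_used_distal + (tgt_i + 1) * cfg.private_distal,
        )
        for slot in private_slots:
            k = int(rng.integers(1, len(panel_tgt) + 1))
            act = tuple(sorted(
                panel_tgt[i] for i in rng.choice(len(panel_tgt), k, replace=False)
            ))
            w = int(_widths(rng, cfg, 1)[0])
            add_peak(tgt, "private_distal", slot, w, act)

    # ----- replicate detection, peak files ------------------------------
    for sp in cfg.species:
        peak_dir = root / sp / "peaks"
        peak_dir.mkdir(parents=True, exist_ok=True)
        chrom_len = cfg.chrom_length
        emitted: dict[tuple[str, str], list[tuple[str, int, int, str]]] = {
            (t, r): [] for t in cfg.panel(sp) for r in ("A", "B")
        }
        for p in truth_peaks[sp]:
            for tissue in p.activity:
                for rep in ("A", "B"):
                    if rng.random() < cfg.replicate_detection:
                        s, e = _jitter(rng, p.start, p.end,
                                       cfg.boundary_jitter, chrom_len)
                        p.detected[(tissue, rep)] = (s, e)
                        emitted[(tissue, rep)].append((p.chrom, s, e, p.uid))
                    else:
                        p.detected[(tissue, rep)] = None
        # per-library noise peaks confined to the noise zone
        noise_zone_start = chrom_len - cfg.noise_zone_size
        for (tissue, rep), rows in emitted.items():
            n_noise = int(rng.poisson(cfg.noise_peaks_per_library))
            nw = _widths(rng, cfg, n_noise)
            for i in range(n_noise):
                ci = int(rng.integers(cfg.chrom_count))
                w = int(nw[i])
                s = int(rng.integers(noise_zone_start, chrom_len - w))
                rows.append((cfg.chrom_name(sp, ci), s, s + w,
                             f"noise_{tissue}_{rep}_{i}"))
            rows.sort()
            with open(peak_dir / f"{tissue}_{rep}.broadPeak", "w") as fh:
                for chrom, s, e, name in rows:
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\t0\t.\t0\t-1\t-1\n")

        write_genome_table(genomes[sp], root / sp / "genome.tsv")
        _write_gtf(layouts[sp], root / sp / "annotation.gtf")

    # ----- fragments and library statistics -----------------------------
    stats: list[LibraryStats] = []
    for sp in cfg.species:
        frag_dir = root / sp / "fragments"
        frag_dir.mkdir(parents=True, exist_ok=True)
        for tissue in cfg.panel(sp):
            for rep in ("A", "B"):
                lib_peaks = read_bed(root / sp / "peaks" / f"{tissue}_{rep}.broadPeak",
                                     dialect="broadPeak")
                frame, n_dup = _make_fragments(cfg, genomes[sp], lib_peaks, rng)
                frame.to_csv(frag_dir / f"{tissue}_{rep}.bed", sep="\t",
                             header=False, index=False)
                n = cfg.fragments_per_library
                mapped = n + n_dup
                stats.append(LibraryStats(
                    species=sp, tissue=tissue, replicate=rep,
                    raw_reads=int(round(mapped / cfg.mapped_fraction)),
                    mapped_reads=mapped, duplicate_reads=n_dup,
                    informative_reads=n,
                ))
    write_library_stats(stats, root / "library_stats.tsv")

    # ----- homology maps -------------------------------------------------
    hom_dir = root / "homology"
    hom_dir.mkdir(exist_ok=True)
    from .conservation import HomologyBlock, HomologyMap, write_homology_map

    ref_by_uid = {p.uid: p for p in ref_peaks}
    blocks_by_target: dict[str, list[tuple[str, HomologyBlock]]] = {t: [] for t in targets}
    orientations: dict[tuple[str, str], str] = {}
    for (uid, tgt), link in links.items():
        if not link.seq_conserved:
            continue
        p = ref_by_uid[uid]
        fl = cfg.homology_flank
        src_iv = GenomeInterval(p.chrom, p.start - fl, p.end + fl)
        layout_t = layouts[tgt]
        chrom_t, ts, te = _peak_at(layout_t, p.pclass, p.slot, src_iv.width)
        ori = "-" if rng.random() < cfg.reverse_block_rate else "+"
        orientations[(uid, tgt)] = ori
        blocks_by_target[tgt].append(
            (uid, HomologyBlock(src_iv, GenomeInterval(chrom_t, ts, te), ori))
        )
    for tgt in targets:
        hmap = HomologyMap(ref, tgt, [b for _, b in blocks_by_target[tgt]])
        write_homology_map(hmap, hom_dir / f"{ref}_to_{tgt}.tsv")
        write_homology_map(hmap.invert(), hom_dir / f"{tgt}_to_{ref}.tsv")
    # map between the two target species, through slots conserved in both
    t1, t2 = targets
    uids_both = [
        uid for (uid, t), l in links.items()
        if t == t1 and l.seq_conserved and links[(uid, t2)].seq_conserved
    ]
    cross: list[HomologyBlock] = []
    for uid in uids_both:
        p = ref_by_uid[uid]
        fl = cfg.homology_flank
        w = (p.end - p.start) + 2 * fl
        c1, s1, e1 = _peak_at(layouts[t1], p.pclass, p.slot, w)
        c2, s2, e2 = _peak_at(layouts[t2], p.pclass, p.slot, w)
        o1, o2 = orientations[(uid, t1)], orientations[(uid, t2)]
        ori = "+" if o1 == o2 else "-"
        cross.append(HomologyBlock(GenomeInterval(c1, s1, e1),
                                   GenomeInterval(c2, s2, e2), ori))
    hmap12 = HomologyMap(t1, t2, cross)
    write_homology_map(hmap12, hom_dir / f"{t1}_to_{t2}.tsv")
    write_homology_map(hmap12.invert(), hom_dir / f"{t2}_to_{t1}.tsv")

    # ----- aliases, truth, config, manifest ------------------------------
    alias_rows = []
    for src in cfg.species:
        for tgt in cfg.species:
            if src == tgt:
                continue
            for a, b in sorted(cfg.alias_map(src, tgt).items()):
                alias_rows.append({"src_species": src, "tgt_species": tgt,
                                   "src_tissue": a, "tgt_tissue": b})
    pd.DataFrame(alias_rows,
                 columns=["src_species", "tgt_species", "src_tissue", "tgt_tissue"]
                 ).to_csv(root / "tissue_aliases.tsv", sep="\t", index=False)

    truth = TruthTables(peaks=truth_peaks, links=links)
    _write_truth(truth, root)
    cfg.to_yaml(root / "config.yaml")
    _write_manifest(cfg, root)
    return World(cfg, root, truth)


def _make_fragments(
    cfg: SimulationConfig,
    genome: GenomeTable,
    lib_peaks: PeakSet,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, int]:
    """Fragment table for one library and its duplicate count."""
    n = cfg.fragments_per_library
    fw = rng.integers(cfg.fragment_min, cfg.fragment_max + 1, n)
    in_peak = rng.random(n) < cfg.frip_target

    merged = merge_intervals(lib_peaks)
    p_chrom = np.array([iv.chrom for iv in merged])
    p_start = np.array([iv.start for iv in merged], dtype=np.int64)
    p_end = np.array([iv.end for iv in merged], dtype=np.int64)
    comp = complement(genome, merged)
    c_chrom = np.array([iv.chrom for iv in comp])
    c_start = np.array([iv.start for iv in comp], dtype=np.int64)
    c_len = np.array([iv.width for iv in comp], dtype=np.int64)
    valid = np.maximum(c_len - cfg.fragment_max, 0)
    if valid.sum() == 0:
        raise ValueError("no peak-free space left for background fragments")

    chroms = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)

    idx_in = np.flatnonzero(in_peak)
    if len(merged) == 0 and idx_in.size:
        raise ValueError("cannot place in-peak fragments: library has no peaks")
    if idx_in.size:
        pi = rng.integers(0, len(merged), idx_in.size)
        pw = p_end[pi] - p_start[pi]
        w_eff = np.minimum(fw[idx_in], pw)
        off = np.floor(rng.random(idx_in.size) * (pw - w_eff + 1)).astype(np.int64)
        chroms[idx_in] = p_chrom[pi]
        starts[idx_in] = p_start[pi] + off
        ends[idx_in] = starts[idx_in] + w_eff

    idx_out = np.flatnonzero(~in_peak)
    if idx_out.size:
        probs = valid / valid.sum()
        ci = rng.choice(len(comp), idx_out.size, p=probs)
        off = np.floor(rng.random(idx_out.size) * valid[ci]).astype(np.int64)
        chroms[idx_out] = c_chrom[ci]
        starts[idx_out] = c_start[ci] + off
        ends[idx_out] = starts[idx_out] + fw[idx_out]

    dup = rng.random(n) < cfg.duplication_rate
    n_dup = int(dup.sum())
    frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    frame = pd.concat([frame, frame[dup]], ignore_index=True)
    frame = frame.sort_values(["chrom", "start", "end"], kind="mergesort",
                              ignore_index=True)
    return frame, n_dup


def _write_truth(truth: TruthTables, root: Path) -> None:
    rows = []
    for sp, peaks in truth.peaks.items():
        for p in peaks:
            rows.append({
                "uid": p.uid, "species": sp, "class": p.pclass, "slot": p.slot,
                "chrom": p.chrom, "start": p.start, "end": p.end,
                "activity": ",".join(p.activity),
                "reproducible_in": ",".join(sorted(p.reproducible_tissues())),
            })
    pd.DataFrame(rows).to_csv(root / "truth_peaks.tsv", sep="\t", index=False)
    rows = [
        {
            "source_uid": l.source_uid, "target_species": l.target_species,
            "seq_conserved": l.seq_conserved, "acc_conserved": l.acc_conserved,
            "activity_shuffled": l.activity_shuffled,
            "target_uid": l.target_uid or "",
        }
        for l in truth.links.values()
    ]
    pd.DataFrame(rows).to_csv(root / "truth_links.tsv", sep="\t", index=False)


def _write_manifest(cfg: SimulationConfig, root: Path) -> None:
    rows = []

    def add(path: Path, role: str, **kw) -> None:
        rows.append({
            "path": str(path.relative_to(root)), "role": role,
            "species": kw.get("species", ""), "tissue": kw.get("tissue", ""),
            "replicate": kw.get("replicate", ""),
        })

    for sp in cfg.species:
        add(root / sp / "genome.tsv", "genome_table", species=sp)
        add(root / sp / "annotation.gtf", "gene_annotation", species=sp)
        for tissue in cfg.panel(sp):
            for rep in ("A", "B"):
                add(root / sp / "peaks" / f"{tissue}_{rep}.broadPeak",
                    "replicate_peaks", species=sp, tissue=tissue, replicate=rep)
                add(root / sp / "fragments" / f"{tissue}_{rep}.bed",
                    "fragments", species=sp, tissue=tissue, replicate=rep)
    add(root / "library_stats.tsv", "library_stats")
    for src in cfg.species:
        for tgt in cfg.species:
            if src != tgt:
                add(root / "homology" / f"{src}_to_{tgt}.tsv", "homology_map",
                    species=f"{src}->{tgt}")
    add(root / "tissue_aliases.tsv", "tissue_aliases")
    add(root / "truth_peaks.tsv", "truth")
    add(root / "truth_links.tsv", "truth")
    add(root / "config.yaml", "config")
    pd.DataFrame(rows).to_csv(root / "manifest.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Parameter recovery report
# ---------------------------------------------------------------------------

def recover_parameters(world: World) -> pd.DataFrame:
    """Compare pipeline measurements on the world against its configuration.

    Rows: metric, measured, expected, tolerance, ok.  Stochastic targets use
    3 standard errors of the corresponding binomial; truth-bookkeeping
    targets are exact.
    """
    from .atlas import tissue_specific_peaks
    from .conservation import conserved_accessibility, stratified_conservation
    from .intervals import count_overlapping
    from .qc import compute_frip

    cfg = world.config
    ref = cfg.species[0]
    tgt = cfg.species[1]
    rows: list[dict] = []

    def add(metric: str, measured: float, expected: float, tol: float) -> None:
        rows.append({
            "metric": metric, "measured": measured, "expected": expected,
            "tolerance": tol, "ok": abs(measured - expected) <= tol,
        })

    # FRiP and NRF on the first reference library
    tissue0 = cfg.panel(ref)[0]
    frags = world.fragments(ref, tissue0, "A")
    peaks = world.raw_peaks(ref)[(tissue0, "A")]
    f = cfg.frip_target
    n = cfg.fragments_per_library
    se = float(np.sqrt(f * (1 - f) / n))
    add("frip_pct", compute_frip(frags, peaks), 100 * f, 300 * se)

    stats = [s for s in world.library_stats()
             if (s.species, s.tissue, s.replicate) == (ref, tissue0, "A")][0]
    u = cfg.duplication_rate
    nrf = (stats.mapped_reads - stats.duplicate_reads) / stats.mapped_reads
    # delta-method s.e. of n/(n + Bin(n, u))
    nrf_tol = 0.0 if u == 0 else \
        3 * float(np.sqrt(u * (1 - u) / n)) / (1.0 + u) ** 2 + 1e-9
    add("nrf", nrf, 1.0 / (1.0 + u), nrf_tol)

    # replicate overlap: planted-peak expectation is exact truth bookkeeping;
    # noise-noise coincidences can only add, so they widen the band upward
    rep_a = world.raw_peaks(ref)[(tissue0, "A")]
    rep_b = world.raw_peaks(ref)[(tissue0, "B")]
    _count, pct = count_overlapping(rep_a, rep_b)
    planted_a = sum(1 for p in world.truth.peaks[ref]
                    if p.detected.get((tissue0, "A")))
    planted_both = sum(1 for p in world.truth.peaks[ref]
                       if p.detected.get((tissue0, "A"))
                       and p.detected.get((tissue0, "B")))
    n_noise_a = len(rep_a) - planted_a
    expected_pct = 100.0 * planted_both / len(rep_a)
    add("replicate_overlap_pct", pct, expected_pct,
        100.0 * n_noise_a / len(rep_a) + 1e-9)

    # atlas tissue-specific counts vs planted truth.  A planted peak is
    # recovered as tissue-specific iff it is reproducible in the tissue and
    # no replicate of any other tissue detected it at all; noise-derived
    # reproducible regions can add spurious singletons, hence the allowance
    # when noise is enabled.
    atlas = world.atlas(ref)
    raw = world.raw_peaks(ref)
    for tissue in cfg.panel(ref)[:2]:
        measured = len(tissue_specific_peaks(atlas, raw, tissue))
        expected = sum(
            1 for p in world.truth.peaks[ref]
            if tissue in p.reproducible_tissues()
            and not any(iv for (t, _r), iv in p.detected.items() if t != tissue)
        )
        tol = 0.0 if cfg.noise_peaks_per_library == 0 else max(3.0, 0.2 * expected)
        add(f"tissue_specific_{tissue}", measured, expected, tol)

    # stratified conservation, any-tissue mode.  The truth-derived
    # expectation accounts for partner reproducibility; the configured-rate
    # comparison (seq x acc product) is added when replicate detection is
    # certain, where the two coincide in expectation.
    records = conserved_accessibility(
        atlas, world.atlas(tgt), world.homology(ref, tgt),
        mode="any_tissue", tissue_aliases=world.tissue_aliases(ref, tgt),
    )
    strat = stratified_conservation(atlas, records, world.annotation(ref))
    tgt_by_uid = world.truth.by_uid(tgt)

    def truth_fraction(classes: tuple[str, ...]) -> float:
        num = den = 0
        for p in world.truth.peaks[ref]:
            if p.pclass not in classes or not p.reproducible_tissues():
                continue
            den += 1
            link = world.truth.links[(p.uid, tgt)]
            if link.acc_conserved and link.target_uid:
                if tgt_by_uid[link.target_uid].reproducible_tissues():
                    num += 1
        return num / den if den else 0.0

    add("conserved_fraction_promoter", strat["promoter"],
        truth_fraction(("housekeeping",)), 0.02)
    add("conserved_fraction_intergenic", strat["intergenic"],
        truth_fraction(("tissue_specific", "shared")), 0.02)
    if cfg.replicate_detection == 1.0:
        exp_prom = cfg.seq_conservation_promoter * cfg.acc_conservation_promoter
        exp_dist = cfg.seq_conservation_distal * cfg.acc_conservation_distal
        n_prom = max(cfg.housekeeping_peaks, 1)
        n_dist = max(cfg.tissue_specific_per_tissue * len(cfg.tissues)
                     + cfg.shared_peaks, 1)
        add("conserved_fraction_promoter_configured", strat["promoter"], exp_prom,
            3 * float(np.sqrt(exp_prom * (1 - exp_prom) / n_prom)) + 0.02)
        add("conserved_fraction_intergenic_configured", strat["intergenic"],
            exp_dist,
            3 * float(np.sqrt(exp_dist * (1 - exp_dist) / n_dist)) + 0.02)
    rows.append({
        "metric": "promoter_gt_intergenic",
        "measured": float(strat["promoter"] > strat["intergenic"]),
        "expected": 1.0, "tolerance": 0.0,
        "ok": strat["promoter"] > strat["intergenic"],
    })
    return pd.DataFrame(rows)
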