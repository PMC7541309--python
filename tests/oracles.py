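"""Independent brute-force oracles used to validate the interval algebra.

Everything here works per base (boolean occupancy arrays) or by exhaustive
pairwise scanning, deliberately ignoring the sorted/vectorized code paths
of the package, so the two routes are independent.
"""

from __future__ import annotations

import numpy as np

from chromatlas.annotation import Gene
from chromatlas.intervals import GenomeInterval, GenomeTable, PeakSet


def occupancy(ps, genome: GenomeTable) -> dict[str, np.ndarray]:
    occ = {c: np.zeros(n, dtype=bool) for c, n in genome.lengths.items()}
    for iv in ps:
        occ[iv.chrom][iv.start:iv.end] = True
    return occ


def union_bp(ps, genome: GenomeTable) -> int:
    return int(sum(v.sum() for v in occupancy(ps, genome).values()))


def intersection_bp(a, b, genome: GenomeTable) -> int:
    oa, ob = occupancy(a, genome), occupancy(b, genome)
    return int(sum((oa[c] & ob[c]).sum() for c in genome.lengths))


def brute_count_overlapping(a, b, min_bp: int = 1) -> int:
    count = 0
    for x in a:
        for y in b:
            if x.chrom == y.chrom and \
                    min(x.end, y.end) - max(x.start, y.start) >= min_bp:
                count += 1
                break
    return count


def random_peakset(rng: np.random.Generator, genome: GenomeTable,
                   n: int, max_width: int = 500) -> PeakSet:
    chroms = list(genome.lengths)
    ivs = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        w = int(rng.integers(1, max_width + 1))
        s = int(rng.integers(0, genome.lengths[c] - w))
        ivs.append(GenomeInterval(c, s, s + w))
    return PeakSet(ivs)


# ---------------------------------------------------------------------------
# categorization oracle: test all eight categories independently, apply order
# ---------------------------------------------------------------------------

def brute_categorize(peak: GenomeInterval, genes: list[Gene],
                     tss_flank: int = 50, promoter_length: int = 2000,
                     promoter_downstream: int = 0) -> str:
    def hits(intervals: list[tuple[str, int, int]]) -> bool:
        return any(
            c == peak.chrom and min(e, peak.end) - max(s, peak.start) >= 1
            for c, s, e in intervals
        )

    tss_zones, promoters, tts_zones = [], [], []
    utr5, utr3, cds, introns = [], [], [], []
    for g in genes:
        tss, tts = g.tss, g.tts
        tss_zones.append((g.chrom, tss - tss_flank, tss + tss_flank + 1))
        if g.strand == "+":
            promoters.append((g.chrom, tss - promoter_length,
                              tss + promoter_downstream))
        else:
            promoters.append((g.chrom, tss + 1 - promoter_downstream,
                              tss + 1 + promoter_length))
        tts_zones.append((g.chrom, tts - tss_flank, tts + tss_flank + 1))
        utr5 += [(g.chrom, s, e) for s, e in g.utr5]
        utr3 += [(g.chrom, s, e) for s, e in g.utr3]
        cds += [(g.chrom, s, e) for s, e in g.cds]
        exonic = np.zeros(g.end - g.start, dtype=bool)
        for s, e in g.exons:
            exonic[s - g.start:e - g.start] = True
        if not g.exons:
            exonic[:] = False
        run_start = None
        for i, on in enumerate(~exonic):
            if on and run_start is None:
                run_start = i
            if not on and run_start is not None:
                introns.append((g.chrom, g.start + run_start, g.start + i))
                run_start = None
        if run_start is not None:
            introns.append((g.chrom, g.start + run_start, g.end))
        if not g.exons:
            introns.append((g.chrom, g.start, g.end))
    order = [
        ("TSS", tss_zones), ("Promoter", promoters), ("TTS", tts_zones),
        ("5'UTR", utr5), ("3'UTR", utr3), ("CDS", cds), ("Intron", introns),
    ]
    for label, zone in order:
        zone = [(c, max(s, 0), e) for c, s, e in zone if e > max(s, 0)]
        if hits(zone):
            return label
    return "Intergenic"


# ---------------------------------------------------------------------------
# projection oracle: map each base independently, then cluster
# ---------------------------------------------------------------------------

def brute_project(iv: GenomeInterval, blocks, group_gap: int = 10_000):
    """Returns (status, span) with status in {unmapped, unique, multi_locus}."""
    base_images: dict[tuple[str, str], list[int]] = {}
    for b in blocks:
        for pos in range(iv.start, iv.end):
            if b.source.chrom == iv.chrom and b.source.start <= pos < b.source.end:
                off = pos - b.source.start
                if b.orientation == "+":
                    t = b.target.start + off
                else:
                    t = b.target.end - 1 - off
                base_images.setdefault((b.target.chrom, b.orientation), []).append(t)
    clusters = []
    for (chrom, _ori), positions in base_images.items():
        positions = sorted(positions)
        cs, ce = positions[0], positions[0] + 1
        for p in positions[1:]:
            if p - ce <= group_gap:
                ce = p + 1
            else:
                clusters.append((chrom, cs, ce))
                cs, ce = p, p + 1
        clusters.append((chrom, cs, ce))
    if not clusters:
        return "unmapped", None
    if len(clusters) == 1:
        c, s, e = clusters[0]
        return "unique", (c, s, e)
    return "multi_locus", None


def toy_annotation() -> tuple[GenomeTable, list[Gene]]:
    """Ten genes on two 100 kb chromosomes with full sub-feature structure."""
    genome = GenomeTable({"c1": 100_000, "c2": 100_000})
    genes = []
    for ci, chrom in enumerate(["c1", "c2"]):
        for k in range(5):
            gs = 3000 + k * 18000
            ge = gs + 8000
            strand = "+" if (k + ci) % 2 else "-"
            e1, e2, e3 = (gs, gs + 400), (gs + 3000, gs + 3400), (ge - 600, ge)
            if strand == "+":
                utr5, utr3 = (e1[0], e1[0] + 150), (e3[1] - 200, e3[1])
                cds = ((e1[0] + 150, e1[1]), e2, (e3[0], e3[1] - 200))
            else:
                utr5, utr3 = (e3[1] - 150, e3[1]), (e1[0], e1[0] + 200)
                cds = ((e1[0] + 200, e1[1]), e2, (e3[0], e3[1] - 150))
            genes.append(Gene(
                gene_id=f"g{ci}{k}", name=f"g{ci}{k}", chrom=chrom,
                strand=strand, start=gs, end=ge, exons=(e1, e2, e3),
                cds=cds, utr5=(utr5,), utr3=(utr3,),
            ))
    return genome, genes
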