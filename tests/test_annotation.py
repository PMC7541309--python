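"""Feature categorization, unmappable mask, enrichment test, nearest genes."""

from __future__ import annotations

import numpy as np
import pytest

from chromatlas.annotation import (
    FeatureCategory,
    GeneAnnotation,
    categorize_labels,
    categorize_peak,
    categorize_set,
    enrichment_test,
    nearest_genes,
    read_gtf,
    unmappable_mask,
)
from chromatlas.intervals import GenomeInterval, GenomeTable, PeakSet
from chromatlas.qc import FragmentSet
from oracles import brute_categorize, random_peakset, toy_annotation


def iv(chrom, s, e):
    return GenomeInterval(chrom, s, e)


@pytest.fixture(scope="module")
def toy():
    genome, genes = toy_annotation()
    return genome, genes, GeneAnnotation(genes)


class TestGtfReading:
    def test_gene_models_roundtrip(self, clean_world):
        sp = clean_world.config.species[0]
        ann = clean_world.annotation(sp)
        assert len(ann) == clean_world.config.genes_per_species
        g = ann.genes[0]
        assert g.exons and g.cds and g.utr5 and g.utr3
        # strand-aware TSS: 5'-most transcribed base
        if g.strand == "+":
            assert g.tss == g.start
        else:
            assert g.tss == g.end - 1

    def test_coordinates_converted_to_half_open(self, tmp_path):
        gtf = tmp_path / "one.gtf"
        gtf.write_text(
            'c1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1"; gene_name "g1";\n'
            'c1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t";\n'
        )
        ann = read_gtf(gtf)
        g = ann.genes[0]
        assert (g.start, g.end) == (100, 200)
        assert g.exons == ((100, 150),)


class TestCategorize:
    def test_tss_precedence_over_intron(self, toy):
        _genome, genes, ann = toy
        g = genes[0]
        peak = iv(g.chrom, g.tss - 10, g.tss + 2000)  # spans TSS and intron
        assert categorize_peak(peak, ann) is FeatureCategory.TSS

    def test_promoter_upstream_strand_aware(self, toy):
        _genome, genes, ann = toy
        plus = next(g for g in genes if g.strand == "+")
        peak = iv(plus.chrom, plus.tss - 1000, plus.tss - 900)
        assert categorize_peak(peak, ann) is FeatureCategory.PROMOTER
        minus = next(g for g in genes if g.strand == "-")
        peak = iv(minus.chrom, minus.tss + 900, minus.tss + 1000)
        assert categorize_peak(peak, ann) is FeatureCategory.PROMOTER

    def test_intergenic_far_from_everything(self, toy):
        _genome, _genes, ann = toy
        assert categorize_peak(iv("c1", 95_000, 95_100), ann) \
            is FeatureCategory.INTERGENIC

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle(self, toy, seed):
        genome, genes, ann = toy
        rng = np.random.default_rng(300 + seed)
        peaks = random_peakset(rng, genome, 300, max_width=800)
        ours = [c.value for c in categorize_labels(peaks, ann)]
        expected = [brute_categorize(p, genes) for p in peaks]
        assert ours == expected

    def test_counts_partition_peak_set(self, toy, rng):
        genome, _genes, ann = toy
        peaks = random_peakset(rng, genome, 500, max_width=700)
        counts = categorize_set(peaks, ann)
        assert sum(counts.values()) == len(peaks)

    def test_empty_set_all_zero(self, toy):
        _g, _genes, ann = toy
        assert sum(categorize_set(PeakSet([]), ann).values()) == 0

    def test_gene_free_chrom_all_intergenic(self):
        ann = GeneAnnotation([])
        peaks = PeakSet([iv("cX", 0, 100), iv("cX", 500, 700)])
        counts = categorize_set(peaks, ann)
        assert counts[FeatureCategory.INTERGENIC] == 2


class TestUnmappableMask:
    GENOME = GenomeTable({"c1": 10_000})

    def test_full_coverage_empty_mask(self):
        frags = FragmentSet([iv("c1", w * 500, w * 500 + 10) for w in range(20)])
        assert len(unmappable_mask([frags], self.GENOME, window=500)) == 0

    def test_no_fragments_whole_genome(self):
        mask = unmappable_mask([FragmentSet([])], self.GENOME, window=500)
        assert mask.total_bp() == 10_000

    def test_union_over_libraries(self):
        a = FragmentSet([iv("c1", 0, 10)])
        b = FragmentSet([iv("c1", 9_900, 9_910)])
        mask = unmappable_mask([a, b], self.GENOME, window=500)
        assert mask.total_bp() == 10_000 - 2 * 500

    def test_matches_per_window_census(self, rng):
        libs = [FragmentSet(random_peakset(rng, self.GENOME, 30, 80).intervals)
                for _ in range(3)]
        window = 500
        mask = unmappable_mask(libs, self.GENOME, window=window)
        masked_bp = mask.total_bp()
        expected = 0
        for w in range(10_000 // window):
            ws, we = w * window, (w + 1) * window
            touched = any(
                min(f.end, we) - max(f.start, ws) >= 1
                for lib in libs for f in lib
            )
            if not touched:
                expected += window
        assert masked_bp == expected


class TestEnrichment:
    def test_gene_free_null_is_degenerate_tie(self):
        """With no genes every count collapses to |peaks| (intergenic) or 0;
        a zero-spread null equal to the observation reports p = 0.5."""
        genome = GenomeTable({"c1": 10_000})
        ann = GeneAnnotation([])
        peaks = PeakSet([iv("c1", 0, 100), iv("c1", 500, 600)])
        res = enrichment_test(peaks, ann, genome, iterations=10, seed=0)
        inter = res[FeatureCategory.INTERGENIC]
        assert inter.degenerate and inter.p == 0.5
        assert res[FeatureCategory.TSS].p == 0.5

    def test_degenerate_null_with_excess_observed(self):
        """Constant null strictly below the observation: flagged, p -> 0."""
        from chromatlas.annotation import Gene
        genome = GenomeTable({"c1": 200})
        ann = GeneAnnotation([Gene("g", "g", "c1", "+", 0, 10)])  # TSS zone [0,51)
        peaks = PeakSet([iv("c1", 0, 100)])          # overlaps the TSS zone
        mask = PeakSet([iv("c1", 0, 60)])            # forces null starts >= 60
        res = enrichment_test(peaks, ann, genome, mask=mask,
                              iterations=10, seed=0)
        r = res[FeatureCategory.TSS]
        assert r.degenerate and r.null_sd == 0.0
        assert r.observed == 1 and r.p == 0.0

    def test_planted_tss_enrichment_significant(self, clean_world):
        sp = clean_world.config.species[0]
        atlas = clean_world.atlas(sp)
        res = enrichment_test(
            atlas.consensus, clean_world.annotation(sp),
            clean_world.genome(sp), iterations=50, seed=4,
        )
        assert res[FeatureCategory.TSS].p < 1e-3
        assert res[FeatureCategory.TSS].observed > res[FeatureCategory.TSS].null_mean

    def test_counts_partition_for_all_replicates(self, toy):
        genome, _genes, ann = toy
        rng = np.random.default_rng(5)
        peaks = random_peakset(rng, genome, 50, max_width=300)
        res = enrichment_test(peaks, ann, genome, iterations=20, seed=1)
        totals = np.zeros(20)
        for r in res.values():
            totals += r.null_counts
        assert (totals == len(peaks)).all()

    def test_mask_respected_by_null(self, toy):
        genome, _genes, ann = toy
        rng = np.random.default_rng(6)
        peaks = random_peakset(rng, genome, 30, max_width=200)
        mask = PeakSet([iv("c1", 0, 90_000)])
        from chromatlas.intervals import shuffle_set
        shuffled = shuffle_set(peaks, genome, excluded=mask, seed=8)
        for x in shuffled:
            assert not any(x.overlaps(m) for m in mask)

    def test_deterministic_given_seed(self, toy):
        genome, _genes, ann = toy
        rng = np.random.default_rng(7)
        peaks = random_peakset(rng, genome, 25, max_width=300)
        r1 = enrichment_test(peaks, ann, genome, iterations=10, seed=42)
        r2 = enrichment_test(peaks, ann, genome, iterations=10, seed=42)
        for c in FeatureCategory:
            assert r1[c].p == r2[c].p
            assert (r1[c].null_counts == r2[c].null_counts).all()


class TestNearestGenes:
    def test_overlapping_gene_distance_zero(self, toy):
        _genome, genes, ann = toy
        g = genes[0]
        hits = nearest_genes(PeakSet([iv(g.chrom, g.start + 10, g.start + 60)]), ann)
        assert hits[0].distance == 0
        assert g.gene_id in hits[0].gene_ids

    def test_equidistant_tie_reports_both(self):
        from chromatlas.annotation import Gene
        a = Gene("ga", "ga", "c1", "+", 0, 1000)
        b = Gene("gb", "gb", "c1", "+", 11_200, 12_000)
        ann = GeneAnnotation([a, b])
        peaks = PeakSet([iv("c1", 6000, 6200)])  # 5 kb to either span edge
        hits = nearest_genes(peaks, ann)
        assert set(hits[0].gene_ids) == {"ga", "gb"}
        assert hits[0].distance == 5000

    def test_beyond_max_dist_dropped(self):
        from chromatlas.annotation import Gene
        g = Gene("g", "g", "c1", "+", 0, 100)
        ann = GeneAnnotation([g])
        peaks = PeakSet([iv("c1", 150_000, 150_100)])
        assert nearest_genes(peaks, ann, max_dist=100_000) == {}

    def test_matches_brute_force_scan(self, toy, rng):
        genome, genes, ann = toy
        peaks = random_peakset(rng, genome, 200, max_width=400)
        hits = nearest_genes(peaks, ann, max_dist=100_000)
        for i, p in enumerate(peaks):
            dists = {}
            for g in genes:
                if g.chrom != p.chrom:
                    continue
                d = max(0, max(g.start - p.end, p.start - g.end))
                dists[g.gene_id] = d
            dmin = min(dists.values())
            if dmin > 100_000:
                assert i not in hits
            else:
                assert hits[i].distance == dmin
                assert set(hits[i].gene_ids) == {
                    gid for gid, d in dists.items() if d == dmin
                }
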