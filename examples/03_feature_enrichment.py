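"""Peak categorization against gene annotation, with a shuffle null.

Categorizes the consensus peaks by precedence (TSS > promoter > TTS >
5'UTR > 3'UTR > CDS > intron > intergenic), derives the empirically
unmappable mask (500 bp windows with no fragment in any library), and runs
the 100x randomization enrichment test.
"""

import tempfile

from chromatlas import SimulationConfig, enrichment_test, generate_world, unmappable_mask
from chromatlas.annotation import enrichment_table

cfg = SimulationConfig(
    seed=5, genes_per_species=100, housekeeping_peaks=40,
    tissue_specific_per_tissue=15, shared_peaks=60,
    private_housekeeping=10, private_distal=20,
    fragments_per_library=5_000, noise_peaks_per_library=10.0,
)
world = generate_world(cfg, tempfile.mkdtemp(prefix="chromatlas_enrich_"))
sp = cfg.species[0]
atlas = world.atlas(sp)

frag_sets = [world.fragments(sp, t, r)
             for t in cfg.panel(sp) for r in ("A", "B")]
mask = unmappable_mask(frag_sets, world.genome(sp), window=500)
print(f"unmappable mask: {mask.total_bp():,} bp "
      f"({100 * mask.total_bp() / world.genome(sp).total_size:.1f}% of genome)")

results = enrichment_test(
    atlas.consensus, world.annotation(sp), world.genome(sp),
    mask=mask, iterations=100, seed=2,
)
table = enrichment_table(results)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))

print("""
Housekeeping peaks are planted at TSS, so the observed TSS count sits far
above the shuffled null (tiny p).  'p' is the sqrt(n)-scaled one-sample
t-test; 'p_calibrated' uses a predictive-interval denominator and is the
one that is uniform when peaks are placed at random.""")
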