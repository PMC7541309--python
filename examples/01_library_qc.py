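"""Library quality control on a small synthetic world.

Generates a compact three-species world, then computes the standard ATAC-seq
QC panel for two libraries of the first species: percent informative reads,
NRF (library complexity), FRiP (signal-to-noise), sJSD (divergence of the
binned signal from a uniform background) and the between-replicate Pearson
correlation of binned coverage.
"""

import tempfile

from chromatlas import (
    SimulationConfig,
    bin_fragments,
    compute_frip,
    compute_nrf,
    compute_sjsd,
    generate_world,
    percent_informative,
    replicate_correlation,
)

cfg = SimulationConfig(
    seed=5, genes_per_species=100, housekeeping_peaks=40,
    tissue_specific_per_tissue=15, shared_peaks=60,
    private_housekeeping=10, private_distal=20,
    fragments_per_library=10_000, noise_peaks_per_library=25.0,
)
world = generate_world(cfg, tempfile.mkdtemp(prefix="chromatlas_qc_"))
sp = cfg.species[0]
tissue = cfg.panel(sp)[0]

print(f"{'library':24s} {'%inf':>6s} {'NRF':>5s} {'FRiP%':>6s} {'sJSD':>5s}")
coverages = {}
for rep in ("A", "B"):
    stats = [s for s in world.library_stats()
             if (s.species, s.tissue, s.replicate) == (sp, tissue, rep)][0]
    frags = world.fragments(sp, tissue, rep)
    peaks = world.raw_peaks(sp)[(tissue, rep)]
    cov = bin_fragments(frags, world.genome(sp), window=500)
    coverages[rep] = cov
    print(f"{sp}/{tissue}/{rep:16s} "
          f"{percent_informative(stats):6.2f} {compute_nrf(stats):5.2f} "
          f"{compute_frip(frags, peaks):6.2f} {compute_sjsd(cov, seed=1):5.2f}")

r = replicate_correlation(coverages["A"], coverages["B"])
print(f"\nreplicate Pearson r (500 bp bins): {r:.3f}")
print("""
FRiP tracks the configured in-peak fragment fraction (35%) and NRF tracks
1/(1 + duplication rate) = 0.625.  The replicate correlation is positive
because both replicates sample the same planted peaks, but it stays well
below the ~0.97 of deep real libraries: each replicate misses 20% of peaks
(detection probability 0.8) and carries its own private noise peaks.""")
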