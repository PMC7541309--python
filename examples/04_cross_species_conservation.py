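"""Cross-species conservation of chromatin accessibility.

Projects the reference species' consensus peaks through homology-block maps
onto the other two species, classifies sequence vs accessibility
conservation (any-tissue and same-tissue), stratifies by promoter vs
intergenic, and computes the three-way conserved sets.
"""

import tempfile

from chromatlas import (
    SimulationConfig,
    conserved_accessibility,
    generate_world,
    stratified_conservation,
    threeway_conservation,
)

cfg = SimulationConfig(
    seed=5, genes_per_species=200, housekeeping_peaks=120,
    tissue_specific_per_tissue=40, shared_peaks=200,
    private_housekeeping=20, private_distal=50,
    fragments_per_library=500, noise_peaks_per_library=0.0,
    replicate_detection=1.0,
)
world = generate_world(cfg, tempfile.mkdtemp(prefix="chromatlas_cons_"))
ref, near, far = cfg.species

for tgt in (near, far):
    recs = conserved_accessibility(
        world.atlas(ref), world.atlas(tgt), world.homology(ref, tgt),
        mode="same_tissue", tissue_aliases=world.tissue_aliases(ref, tgt))
    unique = sum(r.status.value == "unique" for r in recs)
    conserved = sum(r.conserved for r in recs)
    print(f"{ref} -> {tgt}: {len(recs)} consensus peaks, "
          f"{unique} mappable, {conserved} same-tissue conserved")

recs_any = conserved_accessibility(
    world.atlas(ref), world.atlas(near), world.homology(ref, near),
    mode="any_tissue", tissue_aliases=world.tissue_aliases(ref, near))
strat = stratified_conservation(world.atlas(ref), recs_any,
                                world.annotation(ref))
print(f"\nconserved fraction ({ref} -> {near}, any tissue): "
      f"all {strat['all']:.2f}, promoter {strat['promoter']:.2f}, "
      f"intergenic {strat['intergenic']:.2f}")

res = threeway_conservation(
    {sp: world.atlas(sp) for sp in cfg.species},
    {(ref, t): world.homology(ref, t) for t in (near, far)},
    reference=ref,
    tissue_aliases={t: world.tissue_aliases(ref, t) for t in (near, far)},
)
print(f"\nthree-way: {len(res.mappable_to_all)} regions mappable to all "
      f"species, {len(res.conserved_in_all)} same-tissue conserved in all")

print("""
Promoter accessibility is markedly more conserved than intergenic
accessibility (configured 0.50 vs 0.15), mirroring the biology that
promoters evolve under stronger constraint than distal enhancers; the
conserved sets shrink monotonically: consensus > mappable > conserved.""")
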