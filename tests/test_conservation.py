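"""Homology projection and cross-species accessibility conservation."""

from __future__ import annotations

import numpy as np
import pytest

from chromatlas.atlas import build_atlas
from chromatlas.conservation import (
    ConservationRecord,
    HomologyBlock,
    HomologyMap,
    ProjectionStatus,
    conserved_accessibility,
    project_interval,
    read_homology_map,
    stratified_conservation,
    threeway_conservation,
    write_homology_map,
)
from chromatlas.intervals import GenomeInterval, PeakSet
from oracles import brute_project


def iv(chrom, s, e):
    return GenomeInterval(chrom, s, e)


def block(sc, ss, se, tc, ts, ori="+"):
    return HomologyBlock(iv(sc, ss, se), iv(tc, ts, ts + (se - ss)), ori)


class TestHomologyMap:
    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            HomologyBlock(iv("a", 0, 100), iv("b", 0, 50))

    def test_overlapping_source_blocks_rejected(self):
        with pytest.raises(ValueError):
            HomologyMap("x", "y", [block("c1", 0, 100, "t1", 0),
                                   block("c1", 50, 150, "t1", 500)])

    def test_tsv_roundtrip(self, tmp_path):
        hmap = HomologyMap("x", "y", [block("c1", 0, 100, "t1", 500, "-"),
                                      block("c1", 200, 300, "t2", 0)])
        p = tmp_path / "map.tsv"
        write_homology_map(hmap, p)
        back = read_homology_map(p, "x", "y")
        assert len(back) == 2
        assert back.blocks[0].orientation == "-"
        assert back.blocks[1].target.chrom == "t2"

    def test_invert_swaps_sides(self):
        hmap = HomologyMap("x", "y", [block("c1", 0, 100, "t1", 500)])
        inv = hmap.invert()
        assert inv.source_species == "y"
        assert inv.blocks[0].source.chrom == "t1"


class TestProjection:
    def test_plus_orientation_linear_transfer(self):
        hmap = HomologyMap("x", "y", [block("c1", 1000, 2000, "t1", 5000)])
        res = project_interval(iv("c1", 1200, 1300), hmap)
        assert res.status is ProjectionStatus.UNIQUE
        assert (res.target.chrom, res.target.start, res.target.end) == \
            ("t1", 5200, 5300)

    def test_minus_orientation_reverses(self):
        hmap = HomologyMap("x", "y", [block("c1", 1000, 2000, "t1", 5000, "-")])
        res = project_interval(iv("c1", 1000, 1100), hmap)
        # first 100 source bases map to the LAST 100 target bases
        assert (res.target.start, res.target.end) == (5900, 6000)

    def test_unmapped_outside_blocks(self):
        hmap = HomologyMap("x", "y", [block("c1", 1000, 2000, "t1", 5000)])
        assert project_interval(iv("c1", 3000, 3100), hmap).status \
            is ProjectionStatus.UNMAPPED

    def test_two_chromosomes_multi_locus(self):
        hmap = HomologyMap("x", "y", [block("c1", 0, 100, "t1", 0),
                                      block("c1", 100, 200, "t2", 0)])
        assert project_interval(iv("c1", 50, 150), hmap).status \
            is ProjectionStatus.MULTI_LOCUS

    def test_nearby_groups_merged_within_gap(self):
        hmap = HomologyMap("x", "y", [block("c1", 0, 100, "t1", 0),
                                      block("c1", 100, 200, "t1", 5000)])
        res = project_interval(iv("c1", 50, 150), hmap, group_gap=10_000)
        assert res.status is ProjectionStatus.UNIQUE
        assert (res.target.start, res.target.end) == (50, 5050)
        far = project_interval(iv("c1", 50, 150), hmap, group_gap=1000)
        assert far.status is ProjectionStatus.MULTI_LOCUS

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(700 + seed)
        blocks = []
        pos = 0
        for _ in range(12):
            pos += int(rng.integers(10, 200))
            w = int(rng.integers(20, 150))
            tgt_chrom = f"t{int(rng.integers(2)) + 1}"
            ts = int(rng.integers(0, 20_000))
            ori = "+" if rng.random() < 0.7 else "-"
            blocks.append(HomologyBlock(
                iv("c1", pos, pos + w), iv(tgt_chrom, ts, ts + w), ori))
            pos += w
        hmap = HomologyMap("x", "y", blocks)
        for _ in range(40):
            s = int(rng.integers(0, pos))
            e = s + int(rng.integers(1, 400))
            res = project_interval(iv("c1", s, e), hmap, group_gap=2000)
            status, span = brute_project(iv("c1", s, e), blocks, group_gap=2000)
            assert res.status.value == status
            if status == "unique":
                assert (res.target.chrom, res.target.start, res.target.end) == span

    def test_image_width_bounded_by_span(self):
        hmap = HomologyMap("x", "y", [block("c1", 0, 100, "t1", 0),
                                      block("c1", 200, 300, "t1", 1000)])
        res = project_interval(iv("c1", 0, 300), hmap)
        image_bp = 100 + 100
        assert res.target.width >= image_bp


def two_species_atlases():
    src = build_atlas({
        "liver": PeakSet([iv("c1", 1000, 1500)]),
        "lung": PeakSet([iv("c1", 8000, 8400)]),
    }, species="x")
    tgt = build_atlas({
        "liver": PeakSet([iv("t1", 51_000, 51_500)]),
        "lung": PeakSet([iv("t1", 60_000, 60_200)]),
    }, species="y")
    hmap = HomologyMap("x", "y", [
        block("c1", 900, 1600, "t1", 50_900),     # liver peak locus
        block("c1", 7900, 8500, "t1", 59_900),    # lung peak locus
    ])
    return src, tgt, hmap


class TestConservedAccessibility:
    def test_same_tissue_shared(self):
        src, tgt, hmap = two_species_atlases()
        recs = conserved_accessibility(src, tgt, hmap, mode="same_tissue")
        liver = recs[0]
        assert liver.conserved and liver.shared_tissues == ("liver",)

    def test_mode_distinction_any_vs_same(self):
        """Target accessible only in lung while source only liver: conserved
        under any_tissue, not under same_tissue."""
        src = build_atlas({"liver": PeakSet([iv("c1", 1000, 1500)])}, species="x")
        tgt = build_atlas({"lung": PeakSet([iv("t1", 51_000, 51_500)])}, species="y")
        hmap = HomologyMap("x", "y", [block("c1", 900, 1600, "t1", 50_900)])
        same = conserved_accessibility(src, tgt, hmap, mode="same_tissue")
        any_ = conserved_accessibility(src, tgt, hmap, mode="any_tissue")
        assert not same[0].conserved
        assert any_[0].conserved and any_[0].overlaps_consensus

    def test_alias_translation(self):
        src = build_atlas({"cortex": PeakSet([iv("c1", 1000, 1500)])}, species="x")
        tgt = build_atlas({"cerebrum": PeakSet([iv("t1", 51_000, 51_500)])},
                          species="y")
        hmap = HomologyMap("x", "y", [block("c1", 900, 1600, "t1", 50_900)])
        recs = conserved_accessibility(src, tgt, hmap, mode="same_tissue",
                                       tissue_aliases={"cortex": "cerebrum"})
        assert recs[0].conserved
        # shared tissues reported in source vocabulary
        assert recs[0].shared_tissues == ("cortex",)

    def test_species_mismatch_raises(self):
        src, tgt, hmap = two_species_atlases()
        bad = HomologyMap("z", "y", list(hmap.blocks))
        with pytest.raises(ValueError):
            conserved_accessibility(src, tgt, bad)

    def test_same_subset_of_any_on_world(self, small_world):
        cfg = small_world.config
        ref, tgt = cfg.species[0], cfg.species[1]
        args = (small_world.atlas(ref), small_world.atlas(tgt),
                small_world.homology(ref, tgt))
        kw = {"tissue_aliases": small_world.tissue_aliases(ref, tgt)}
        same = conserved_accessibility(*args, mode="same_tissue", **kw)
        any_ = conserved_accessibility(*args, mode="any_tissue", **kw)
        same_set = {r.peak_index for r in same if r.conserved}
        any_set = {r.peak_index for r in any_ if r.conserved}
        assert same_set <= any_set

    def test_filtration_conserved_subset_mappable(self, small_world):
        cfg = small_world.config
        ref, tgt = cfg.species[0], cfg.species[2]
        recs = conserved_accessibility(
            small_world.atlas(ref), small_world.atlas(tgt),
            small_world.homology(ref, tgt), mode="same_tissue",
            tissue_aliases=small_world.tissue_aliases(ref, tgt),
        )
        conserved = {r.peak_index for r in recs if r.conserved}
        mappable = {r.peak_index for r in recs
                    if r.status is ProjectionStatus.UNIQUE}
        all_idx = {r.peak_index for r in recs}
        assert conserved <= mappable <= all_idx
        assert len(all_idx) == len(small_world.atlas(ref).consensus)


class TestThreeway:
    def test_counts_match_truth_bookkeeping(self, clean_world):
        cfg = clean_world.config
        ref, t1, t2 = cfg.species
        atlases = {sp: clean_world.atlas(sp) for sp in cfg.species}
        maps = {(ref, t1): clean_world.homology(ref, t1),
                (ref, t2): clean_world.homology(ref, t2)}
        aliases = {t1: clean_world.tissue_aliases(ref, t1),
                   t2: clean_world.tissue_aliases(ref, t2)}
        res = threeway_conservation(atlases, maps, reference=ref,
                                    tissue_aliases=aliases)
        truth = clean_world.truth
        # expected sets from generator bookkeeping (d=1: everything planted
        # is reproducible, so conservation reduces to the drawn flags)
        t1_by_uid = truth.by_uid(t1)
        t2_by_uid = truth.by_uid(t2)
        exp_mappable = exp_all = 0
        for p in truth.peaks[ref]:
            l1, l2 = truth.links[(p.uid, t1)], truth.links[(p.uid, t2)]
            if not (l1.seq_conserved and l2.seq_conserved):
                continue
            exp_mappable += 1
            if not (l1.acc_conserved and l2.acc_conserved):
                continue
            a1 = set(t1_by_uid[l1.target_uid].activity)
            a2 = set(t2_by_uid[l2.target_uid].activity)
            # translate to reference vocabulary
            inv1 = {v: k for k, v in cfg.alias_map(ref, t1).items()}
            inv2 = {v: k for k, v in cfg.alias_map(ref, t2).items()}
            s1 = {inv1.get(t, t) for t in a1} & set(p.activity)
            s2 = {inv2.get(t, t) for t in a2} & set(p.activity)
            if s1 & s2:
                exp_all += 1
        assert len(res.mappable_to_all) == exp_mappable
        assert len(res.conserved_in_all) == exp_all
        assert set(res.conserved_in_all) <= set(res.mappable_to_all)

    def test_shared_tissue_counts_distribution(self, clean_world):
        cfg = clean_world.config
        ref, t1, t2 = cfg.species
        res = threeway_conservation(
            {sp: clean_world.atlas(sp) for sp in cfg.species},
            {(ref, t1): clean_world.homology(ref, t1),
             (ref, t2): clean_world.homology(ref, t2)},
            reference=ref,
            tissue_aliases={t1: clean_world.tissue_aliases(ref, t1),
                            t2: clean_world.tissue_aliases(ref, t2)},
        )
        assert res.shared_tissue_counts.sum() == len(res.conserved_in_all)
        assert (res.shared_tissue_counts.index >= 1).all()

    def test_missing_map_raises(self, clean_world):
        cfg = clean_world.config
        ref, t1, t2 = cfg.species
        with pytest.raises(ValueError):
            threeway_conservation(
                {sp: clean_world.atlas(sp) for sp in cfg.species},
                {(ref, t1): clean_world.homology(ref, t1)},
                reference=ref,
            )


class TestStratified:
    def _records(self, atlas, conserved: bool):
        return [
            ConservationRecord(
                peak_index=i, source=ivl, target_species="y",
                status=ProjectionStatus.UNIQUE if conserved
                else ProjectionStatus.UNMAPPED,
                target=ivl if conserved else None,
                overlaps_consensus=conserved, conserved=conserved,
            )
            for i, ivl in enumerate(atlas.consensus)
        ]

    def test_all_conserved_all_strata_one(self, clean_world):
        sp = clean_world.config.species[0]
        atlas = clean_world.atlas(sp)
        strat = stratified_conservation(
            atlas, self._records(atlas, True), clean_world.annotation(sp))
        assert strat["all"] == 1.0
        assert strat["promoter"] == 1.0
        assert strat["intergenic"] == 1.0

    def test_none_mapped_all_zero(self, clean_world):
        sp = clean_world.config.species[0]
        atlas = clean_world.atlas(sp)
        strat = stratified_conservation(
            atlas, self._records(atlas, False), clean_world.annotation(sp))
        assert set(strat.values()) == {0.0}

    def test_promoter_exceeds_intergenic_on_world(self, clean_world):
        cfg = clean_world.config
        ref, tgt = cfg.species[0], cfg.species[1]
        recs = conserved_accessibility(
            clean_world.atlas(ref), clean_world.atlas(tgt),
            clean_world.homology(ref, tgt), mode="any_tissue",
            tissue_aliases=clean_world.tissue_aliases(ref, tgt),
        )
        strat = stratified_conservation(
            clean_world.atlas(ref), recs, clean_world.annotation(ref))
        assert strat["promoter"] > strat["intergenic"] > 0.0
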