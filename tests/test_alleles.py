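"""Deletion-allele enumeration and in-silico PCR genotyping."""

import logging

import pytest

import tandemcut as tc
from tandemcut.alleles import WT_LABEL, apply_deletion

from conftest import make_genome


def gene(gene_id, start, end, family="A", chrom="c"):
    return tc.GeneCopy(gene_id, family, chrom, start, end, "+")


def allele(chrom, a, b, removed=(), disrupted=()):
    return tc.DeletionAllele(f"{chrom}:del:{a}-{b}", chrom, a, b, tuple(removed), tuple(disrupted))


class TestCutProfile:
    def test_empty_guide_set_gives_empty_profile(self, design_result):
        empty = tc.GuideSet(guides=[], per_gene_sites={}, satisfied={})
        profile = tc.build_cut_profile(empty, design_result.site_index)
        assert profile.cuts == {}

    def test_shared_cut_position_deduplicated(self):
        proto_a = "ACGTTACGGATCCATGCATG"
        # two sites, same protospacer twice at one position is impossible;
        # use two guides whose full-match sites coincide in cut position
        site = tc.TargetSite("c", proto_a, "AGG", "+", 0, 20, 17)
        index = tc.SiteIndex(full={proto_a: [site], "T" * 20: [site]}, seed={})
        gs = tc.GuideSet(guides=[proto_a, "T" * 20], per_gene_sites={}, satisfied={})
        profile = tc.build_cut_profile(gs, index)
        assert profile["c"] == (17,)

    def test_fixture_profile_covers_high_priority_genes(self, default_fixture, design_result):
        profile = tc.build_cut_profile(design_result.guide_set, design_result.site_index)
        high = set(design_result.priorities.high_priority_ids())
        for g in default_fixture.genes:
            if g.gene_id in high:
                inside = [p for p in profile[g.chrom_id] if g.contains(p)]
                assert len(inside) >= 2


class TestDeletionEnumeration:
    def test_pair_arithmetic(self):
        profile = tc.CutProfile({"c": (100, 600)})
        alleles = tc.enumerate_deletion_alleles(profile, [])
        assert len(alleles) == 1
        assert alleles[0].length_bp == 500
        assert (alleles[0].del_start, alleles[0].del_end) == (100, 600)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_pair_count(self, k):
        profile = tc.CutProfile({"c": tuple(range(0, 100 * k, 100))})
        assert len(tc.enumerate_deletion_alleles(profile, [])) == k * (k - 1) // 2

    def test_max_span_cap(self):
        profile = tc.CutProfile({"c": (0, 100, 1000)})
        alleles = tc.enumerate_deletion_alleles(profile, [], max_span=500)
        assert [(a.del_start, a.del_end) for a in alleles] == [(0, 100)]

    def test_removed_and_disrupted_classification(self):
        genes = [gene("left", 0, 50), gene("inner", 100, 150), gene("right", 200, 250),
                 gene("outside", 300, 350)]
        profile = tc.CutProfile({"c": (25, 225)})
        (al,) = tc.enumerate_deletion_alleles(profile, genes)
        assert al.removed_genes == ("inner",)
        assert set(al.disrupted_genes) == {"left", "right"}
        assert not set(al.removed_genes) & set(al.disrupted_genes)

    def test_internal_deletion_disrupts_its_gene(self):
        genes = [gene("g", 0, 1000)]
        profile = tc.CutProfile({"c": (100, 600)})
        (al,) = tc.enumerate_deletion_alleles(profile, genes)
        assert al.removed_genes == () and al.disrupted_genes == ("g",)

    def test_whole_array_join_removes_interior_copies(self, default_fixture, design_result):
        """Joining the first and last cut of the A locus deletes every
        copy that lies fully between them, mirroring a whole-array
        collapse."""
        profile = tc.build_cut_profile(design_result.guide_set, design_result.site_index)
        cuts = profile["chrA"]
        alleles = tc.enumerate_deletion_alleles(profile, default_fixture.genes)
        big = next(
            a for a in alleles if (a.del_start, a.del_end) == (cuts[0], cuts[-1])
        )
        expected_removed = {
            g.gene_id
            for g in default_fixture.genes
            if g.chrom_id == "chrA" and cuts[0] <= g.start and g.end <= cuts[-1]
        }
        assert set(big.removed_genes) == expected_removed
        # first and last A copies carry the boundary cuts, so they survive
        a_copies = [g for g in default_fixture.genes if g.family.startswith("A")]
        assert len(expected_removed) == len(a_copies) - 2
        assert not any(g.family == "NONTARGET" for g in default_fixture.genes
                       if g.gene_id in expected_removed)


class TestPcr:
    def test_wt_multigene_assay_renders_single_band(self, default_fixture):
        for assay in default_fixture.primers:
            pattern = tc.simulate_pcr(assay, default_fixture.genome)
            n_copies = sum(
                1 for g in default_fixture.genes
                if g.family in {"A": ("A1", "A2"), "B": ("B",), "NT": ("NONTARGET",)}[assay.assay_id]
            )
            assert len(pattern.band_sizes) == n_copies  # one product per copy
            assert len(pattern.rendered()) == 1  # equal sizes co-migrate

    def test_internal_deletion_shrinks_band_by_exact_length(self, default_fixture):
        assay = next(p for p in default_fixture.primers if p.assay_id == "A")
        wt = tc.simulate_pcr(assay, default_fixture.genome)
        wt_band = wt.rendered()[0]
        first_a = next(g for g in default_fixture.genes if g.family == "A1")
        # deletion strictly between this copy's primer footprints
        a = first_a.start + 100
        b = first_a.start + 400
        pattern = tc.simulate_pcr(assay, default_fixture.genome, allele("chrA", a, b))
        sizes = sorted(pattern.band_sizes)
        assert sizes.count(wt_band) == len(wt.band_sizes) - 1
        assert sizes[0] == wt_band - (b - a)

    def test_junction_band_across_copies(self, default_fixture):
        """A deletion from inside copy i's amplicon to inside copy j's
        amplicon fuses them: prefix of i + suffix of j; intervening
        copies vanish."""
        assay = next(p for p in default_fixture.primers if p.assay_id == "A")
        wt = tc.simulate_pcr(assay, default_fixture.genome)
        wt_band = wt.rendered()[0]
        a_copies = sorted(
            (g for g in default_fixture.genes if g.family.startswith("A")),
            key=lambda g: g.start,
        )
        first, third = a_copies[0], a_copies[2]
        fwd_off = assay.fwd_start - first.start
        rev_end_off = assay.rev_end - first.start
        a = first.start + 100  # between copy 1's primer footprints
        b = third.start + 300  # between copy 3's primer footprints
        pattern = tc.simulate_pcr(assay, default_fixture.genome, allele("chrA", a, b))
        sizes = sorted(pattern.band_sizes)
        # copies 1 and 3 fuse into one junction product, copy 2 vanishes
        assert len(sizes) == len(wt.band_sizes) - 2
        assert sizes.count(wt_band) == len(wt.band_sizes) - 3
        expected = (a - (first.start + fwd_off)) + ((third.start + rev_end_off) - b)
        assert expected in sizes

    def test_primer_not_found_gives_zero_bands(self, caplog):
        # the forward footprint is a T-run found nowhere else; a deletion
        # excising it must fail amplification with a warning
        genome = make_genome(c="T" * 10 + "ACGTACGTAC" * 11)
        pair = tc.PrimerPair("x", "c", 0, 10, 100, 110, 1000)
        assert genome["c"].sequence[0:10] not in genome["c"].sequence[1:]
        with caplog.at_level(logging.WARNING):
            pattern = tc.simulate_pcr(pair, genome, allele("c", 0, 12))
        assert pattern.band_sizes == ()
        assert any("primer not found" in r.message for r in caplog.records)

    def test_length_conservation(self, default_fixture, design_result):
        """Edited chromosome length = wild-type length - deletion length."""
        profile = tc.build_cut_profile(design_result.guide_set, design_result.site_index)
        alleles = tc.enumerate_deletion_alleles(profile, default_fixture.genes)
        for al in alleles[:50]:
            wt = default_fixture.genome[al.chrom_id].sequence
            assert len(apply_deletion(wt, al)) == len(wt) - al.length_bp


class TestGenotypeCalls:
    def band(self, assay, label, sizes):
        return tc.BandPattern(assay, label, tuple(sizes))

    def test_identical_pattern_is_wild_type(self):
        wt = self.band("A", WT_LABEL, [700])
        assert tc.classify_genotype(wt, self.band("A", "x", [700])) is tc.GenotypeCall.WILD_TYPE

    def test_shifted_band_is_edited(self):
        wt = self.band("A", WT_LABEL, [700])
        assert tc.classify_genotype(wt, self.band("A", "x", [200])) is tc.GenotypeCall.EDITED

    def test_wt_band_plus_novel_band_is_mixed(self):
        wt = self.band("A", WT_LABEL, [700])
        call = tc.classify_genotype(wt, self.band("A", "x", [200, 700]))
        assert call is tc.GenotypeCall.MIXED

    def test_empty_pattern_is_edited_null_allele(self, caplog):
        wt = self.band("A", WT_LABEL, [700])
        with caplog.at_level(logging.WARNING):
            call = tc.classify_genotype(wt, self.band("A", "x", []))
        assert call is tc.GenotypeCall.EDITED

    def test_resolution_masks_small_shifts(self):
        wt = self.band("A", WT_LABEL, [700])
        near = self.band("A", "x", [695])
        far = self.band("A", "y", [600])
        assert tc.classify_genotype(wt, near, resolution_bp=20) is tc.GenotypeCall.WILD_TYPE
        assert tc.classify_genotype(wt, far, resolution_bp=20) is tc.GenotypeCall.EDITED
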