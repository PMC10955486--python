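"""Predict deletion alleles and the PCR band patterns that reveal them.

Every pair of cut positions produced by the selected guide set is a
candidate deletion allele: the interval between the cuts is excised and
the ends rejoin.  A family-wide primer pair amplifies every copy at
equal length, so the wild type shows a single band, while deletion
alleles show smaller bands (within-copy deletions), junction bands
(cross-copy fusions), or lost bands (removed copies).
"""

import tandemcut as tc

fixture = tc.generate_family(tc.FixtureConfig(seed=17))
design = tc.run_design(
    fixture.genome, fixture.genes, fixture.expression,
    tc.RunConfig(target_families=("A1", "A2", "B", "D")),
)

profile = tc.build_cut_profile(design.guide_set, design.site_index)
alleles = tc.enumerate_deletion_alleles(profile, fixture.genes)
print(f"cut positions: " +
      ", ".join(f"{c}:{len(p)}" for c, p in profile.cuts.items()))
print(f"candidate deletion alleles (all cut pairs): {len(alleles)}")

biggest = max(alleles, key=lambda a: a.length_bp)
print(f"largest allele: {biggest.allele_id}, {biggest.length_bp} bp, "
      f"removes {len(biggest.removed_genes)} gene copies")

assay = next(p for p in fixture.primers if p.assay_id == "A")
wt = tc.simulate_pcr(assay, fixture.genome)
print(f"wild-type A-family assay: {len(wt.band_sizes)} products, "
      f"rendered bands {wt.rendered()}")

shown = 0
for allele in alleles:
    if allele.chrom_id != assay.chrom_id:
        continue
    pattern = tc.simulate_pcr(assay, fixture.genome, allele)
    call = tc.classify_genotype(wt, pattern)
    if call is not tc.GenotypeCall.WILD_TYPE and shown < 3:
        print(f"  {allele.allele_id} ({allele.length_bp} bp): "
              f"bands {pattern.rendered()} -> {call.value}")
        shown += 1

# A single wild-type band turning into smaller or multiple bands is the
# gel signature used to track edited alleles through a breeding program.
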