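"""Generate a synthetic tandem-duplicate gene family and inspect it.

The generated genome mirrors a storage-protein gene complex: a 12-copy
A family split over two linked loci, an 8-copy B family on a second
chromosome, a 5-copy pseudogene D family, and a related non-target
family upstream of the A locus.  Every copy of each target family
carries three conserved 23-mer cut windows and conserved primer sites,
so a multiplex design is feasible by construction.
"""

import tandemcut as tc

fixture = tc.generate_family(tc.FixtureConfig(seed=17), out_dir="scratch/family")

print(f"chromosomes: {[f'{c}:{len(s)}bp' for c, s in fixture.genome.items()]}")
counts = {}
for g in fixture.genes:
    counts[g.family] = counts.get(g.family, 0) + 1
print(f"gene copies per family: {counts}")
print(f"planted conserved guides per group: "
      f"{ {k: len(v) for k, v in fixture.planted_guides.items()} }")
print(f"copies planted as dominant-expression targets: {len(fixture.planted_high)}")

# The numbers above describe the design problem: 31 gene copies, of
# which only the expressed, non-pseudogene A/B copies must be covered;
# the D pseudogenes and the non-target family must be left alone.
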