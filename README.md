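# tandemcut

Multiplex CRISPR/Cas9 guide design for tandem-duplicated gene families,
with deletion-allele prediction and in-silico PCR genotyping.

## The problem

Tandem-duplicate gene families — such as the maize 19 kDa alpha-zein
storage-protein genes, with a 12-copy family split over two linked loci,
an 8-copy family on another chromosome, and a 5-copy pseudogene
family — cannot be knocked out one copy at a time.  Because the copies
are near-identical, a single well-chosen gRNA can cut many copies at
once, and a small multiplexed set can cut every expressed copy at
several positions.  Simultaneous cuts across the array then collapse it
by large deletions, and the deletion alleles can be tracked through a
breeding program with a single family-wide PCR marker: the wild type
shows one band, an edited allele shows smaller or multiple bands.

`tandemcut` implements this design procedure end to end:

1. **Site enumeration** — every 20-bp protospacer with a 5'-NGG-3' PAM,
   on both strands, with the blunt cut placed 3 bp 5' of the PAM.
2. **Pairwise matching** — full 20-bp identity and *seed* identity (the
   12 bp adjacent to the PAM, where mismatches abolish cleavage),
   with mismatch positions indexed from the PAM-proximal end.
3. **Expression prioritization** — a gene copy is *high priority* when
   it is not a pseudogene and carries at least a 5% share of its
   family's expression; knockouts must cover exactly these copies.
4. **Filtering** — keep candidates with a perfect 20-bp match in a
   high-priority copy and zero seed-level hits outside the target
   families (genome-wide off-target screen).
5. **Selection** — greedy set multicover: at most 6 guides such that
   every high-priority copy is cut at 2–5 distinct positions in its
   gene body.  An exhaustive solver over small instances serves as a
   correctness oracle.
6. **Allele simulation** — every pair of cuts is a candidate deletion
   allele; PCR band patterns are recomputed on the excised sequence and
   lanes are called `wild_type` / `mixed` / `edited` at gel resolution.

Formally, with high-priority copies $G$, candidate guides $C$, and
$\mathrm{cuts}(c,g)$ the distinct cut positions of guide $c$ with a
perfect protospacer match inside gene $g$, selection selects
$S \subseteq C$, $|S| \le 6$, maximizing coverage greedily until
$\left|\bigcup_{c \in S} \mathrm{cuts}(c,g)\right| \ge 2$ for all
$g \in G$, breaking ties by fewer off-targets, more total matches, then
sequence order, so results are deterministic.

A seeded generator (`tandemcut.fixture`) builds synthetic families with
the architecture above — conserved planted cut windows and primer
sites within otherwise diverged copies, plus a related non-target
family that the design must leave untouched — giving a planted,
solvable problem for tests and demonstrations.

## Worked example

```bash
python examples/design_guides.py
```

prints (seed 17):

```
candidate protospacers in high-priority genes: 752
after full-match + off-target filtering:       718
selected guides (6 of budget 6):
  AGATCTCGGAGCGATGGACG  cuts 16 sites in 16 gene copies
  TTGGGGAGATCTCGGAGCGA  cuts 15 sites in 15 gene copies
  TCTGGCTATAGTATGACATG  cuts 14 sites in 14 gene copies
  CCAAATTCACCCTTGTTTTC  cuts 13 sites in 13 gene copies
  CTCCAGAGAAGACGAATGCG  cuts 13 sites in 13 gene copies
  AATATGGTCCAGATCGTAAT  cuts 8 sites in 8 gene copies
distinct cut positions per high-priority gene: min=2, max=5
design satisfied (every gene cut at >=2 positions): True
```

752 distinct 20-mers occur in the expressed copies; 718 survive the
off-target screen; six of them suffice to cut each of the 17
high-priority copies at 2–5 distinct positions — one guide can serve
up to 16 near-identical copies at once, which is the whole point of
designing against a tandem array.  `examples/build_family.py` and
`examples/simulate_genotyping.py` walk the fixture generator and the
band-pattern prediction the same way.

The same pipeline is available from a shell:

```bash
tandemcut fixture --seed 17 --out family/
tandemcut design --fasta family/genome.fa --gff family/genes.gff3 \
    --expression family/expression.tsv --target-families A1,A2,B,D \
    --out design/run
tandemcut genotype-sim --fasta family/genome.fa --gff family/genes.gff3 \
    --guides design/run.guides.tsv --primers family/primers.tsv \
    --out design/bands.tsv
```

Exit codes: 0 = satisfied design, 2 = infeasible, 1 = error.

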