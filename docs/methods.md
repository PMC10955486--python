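# Methods

## Coordinate model and site definition

All internal coordinates are 0-based half-open intervals on the +
strand; GFF3's 1-based closed convention is converted at the I/O
boundary only.  A target site is a 20-nt protospacer adjacent to a
5'-NGG-3' PAM, enumerated exhaustively on both strands.  The predicted
cut is the canonical SpCas9 blunt cut between protospacer positions 17
and 18 (3 bp 5' of the PAM): `proto_end - 3` for + strand sites,
`proto_start + 3` for − strand sites.  A site belongs to a gene body
iff its cut position lies inside the annotated gene interval (start
inclusive, end exclusive) — the deletion junction forms at the cut, so
the cut decides whether the gene body is disrupted.  Sites whose
protospacer or PAM contains N are excluded from enumeration and never
match; ambiguity is treated conservatively rather than expanded.

## Matching and the seed rule

Guide-vs-site comparison is positional Hamming comparison of the two
20-mers, with mismatch positions indexed 1..20 from the PAM-proximal
end so the seed region is always positions `1..seed_len` regardless of
strand.  `seed_len` defaults to 12: a mismatch at position 12 breaks a
seed match, one at position 13 does not.  The PAM is excluded from
mismatch accounting (any NGG is accepted).  Off-target potential is
operationalized as the count of genome-wide NGG-adjacent sites with a
seed-level match whose cut falls outside every target-family gene body;
the default threshold is 0 (strictest defensible reading — no seed-level
hit tolerated).  The off-target universe is NGG sites only; NAG PAMs,
bulges, and weighted scoring schemes (CFD/MIT) are out of scope.

## Prioritization and target-family scoping

A gene copy is high priority iff it is not flagged a pseudogene, has
non-zero abundance, and holds at least `threshold_frac` (default 0.05)
of its subfamily's total expression.  Pseudogenes are excluded
regardless of measured abundance.  The 5% share is a package default:
the practice it models — concentrating the design on the copies that
dominate the family's expression profile — does not come with a
published cutoff, so the parameter is explicit and configurable.

The pipeline takes an explicit `target_families` set.  Everything
outside those families' gene bodies, including the gene bodies of
related but deliberately untargeted subfamilies, counts as off-target
space.  This is a user declaration rather than an inference because the
decision of which subfamilies are fair game is biological (here: the
pseudogene subfamily belongs to the targeted complex and may be cut
harmlessly; the related subfamily upstream of the main locus must not
be).  With `target_families=None` all annotated families are targets.

## Guide-set selection

Selection is a set multicover: each high-priority copy must be covered
by `min_sites`..`max_sites` distinct cut positions (defaults 2 and 5)
from perfect-match guides, with at most `budget` guides (default 6).
The coverage unit is the distinct cut position within the gene body —
two guides cutting the same position add nothing, because deletions
form between distinct cuts.  `min_sites` is a hard constraint;
`max_sites` is a soft cap (genes over it are flagged `over_max`, the
design is not failed), since a dense family can make the upper bound
structurally unavoidable.  The greedy rule adds the candidate with the
largest marginal coverage toward `min_sites` over still-unsatisfied
genes; ties break by (fewer off-target hits, more total full matches,
lexicographic sequence), making results deterministic.  Structural
infeasibility — a gene that cannot reach `min_sites` even with every
candidate — raises a typed error naming the gene; a merely
budget-exhausted run returns the partial design with per-gene
`satisfied` flags.  An exhaustive solver over all subsets of ≤ 15
candidates provides the exactness oracle in the tests; greedy is not
required to be optimal, only to find a feasible cover whenever one
exists at the budget (verified against the oracle on randomized small
instances).

## Deletion alleles and PCR simulation

Every ordered pair of cut positions on one chromosome defines a
candidate deletion allele: the half-open interval between the cuts is
excised and the ends joined.  Alleles are enumerated, not sampled — no
repair model is assumed, so the package reports the space of candidate
outcomes rather than their frequencies.  A gene fully inside the
deleted interval is `removed`; a gene overlapping the deletion without
being fully removed (one breakpoint in its body, or the whole excision
internal to it) is `disrupted`.  These definitions keep the two sets
disjoint and classify an intra-gene deletion as a disruption.  Small
indels at single cuts are represented only by the disrupted-gene
annotation, not as sequence edits.

PCR is simulated literally: the forward and reverse primer subsequences
are taken from the wild-type reference at the assay's footprints and
located by exact match across the (possibly edited) chromosome; each
forward/reverse occurrence pair within `max_product` yields one product
of size `rev_end − fwd_start` in edited coordinates.  Conserved primer
sites in a multigene family therefore give one product per copy, and
equal-length amplicons collapse to a single observed band.  Junction
products across multi-copy deletions appear only when both primer
occurrences survive the excision.  Band comparison happens at gel
resolution: sizes within `resolution_bp` (default 20 bp, matching what
an agarose gel can separate) co-migrate.  A lane is `wild_type` when
its rendered pattern equals the wild-type lane, `mixed` when all
wild-type bands are present plus novel ones (heterozygote-like), and
`edited` when bands are lost or shifted — including the case of
wild-type bands missing with no novel band (a destroyed primer site or
fused copies) and the empty null-allele pattern, which the enumerated
genotype vocabulary would otherwise leave unclassified.

## The synthetic-family generator

The generator emulates the architecture of a storage-protein gene
complex: 12 A copies split over two linked loci (labelled `A1`, `A2`)
on one chromosome with a 6-copy related non-target family upstream,
8 B copies on a second chromosome, and 5 pseudogene D copies on a
third.  Copies are 750 bp, separated by 2–4 kb random spacers, and
descend from per-family ancestors by substitution-only divergence
(within-family 2%, between-family 8%, non-target-vs-A 15%).
Substitution-only mutation keeps planted windows positionally stable;
indel divergence, gene conversion, and real molecular-evolution models
are deliberately out of scope.

Into every copy of each target family the generator plants three
identical 23-mer windows (random 20-mer + NGG, drawn fresh rather than
inherited from the ancestor, so they recur elsewhere only with
probability ~4⁻¹²) and a conserved forward/reverse primer window pair.
The planted windows make the default design feasible by construction
(two conserved windows per family already satisfy 2 cuts per copy
within budget 6) and make the wild-type assay a single 702-bp band per
family.  Generation-time validation rejects and redraws any fixture in
which a planted guide has a full match outside its own family, a
seed-level match outside the target families, a primer that is not
exactly copy-specific, or an expression draw that blurs the planted
high/low priority split; expression is drawn once (high copies
log-normal around 100 arbitrary units with σ=0.4, one planted low copy
per subfamily at 0.5–3, pseudogenes 0) and written to the TSV, so the
pipeline recovers priorities blind.  The same seed yields byte-identical
output files.

What passing tests on these fixtures shows — and does not show: the
pipeline provably recovers planted, fully conserved target sites,
respects the off-target screen, and computes deletion/band arithmetic
exactly.  Real tandem arrays add indel divergence, segmental
differences between haplotypes, and chromatin effects on cutting
efficiency, none of which are modelled; on real genomes the candidate
pool will be sparser and guide efficacy heterogeneous.

## Problem sizes and defaults

The default fixture genome is ~145 kb over three chromosomes with
~19,000 candidate sites and ~750 candidate guides — sizes chosen so the
full pipeline runs in about a second, which suits a design tool meant
for interactive iteration on a single locus.  Test sweeps use 20
fixture seeds; the greedy/exhaustive comparison uses randomized
instances of ≤ 15 candidates, the bound at which exhaustive subset
search stays instant.

## Known limitations

- No on-target efficiency model: all perfect-match sites are treated as
  equally cuttable.
- The off-target screen is presence/absence at seed level; it does not
  rank partial matches.
- PCR simulation assumes exact primer annealing (no mismatched priming,
  no secondary structure) and rectangular amplification within
  `max_product`.
- Repair outcomes are enumerated, not weighted; predicted allele lists
  say what is possible between cuts, not what is frequent.
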