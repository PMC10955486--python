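"""Predicted multi-cut deletion alleles and in-silico PCR genotyping.

Every ordered pair of cut positions on one chromosome is a candidate
deletion allele: the interval between the two blunt cuts is excised and
the ends rejoin.  Genotyping simulates literal PCR on the edited
sequence: primer subsequences are located by exact match genome-wide, so
a conserved primer pair amplifies every family copy, and a wild-type
multigene assay collapses to a single observed band when the amplicons
are equal length.  Edited alleles yield smaller or extra bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GeneCopy, GenomeSequence, PrimerPair
from .matching import SiteIndex
from .selection import GuideSet
from .sites import revcomp

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION_BP = 20  # gel cannot resolve band shifts below this

WT_LABEL = "WT"


class GenotypeCall(str, Enum):
    WILD_TYPE = "wild_type"
    EDITED = "edited"
    MIXED = "mixed"


@dataclass(frozen=True)
class CutProfile:
    """Distinct, sorted cut positions per chromosome produced by the
    full-match sites of a guide set."""

    cuts: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for chrom, positions in self.cuts.items():
            assert list(positions) == sorted(set(positions)), chrom

    def __getitem__(self, chrom: str) -> tuple[int, ...]:
        return self.cuts.get(chrom, ())


@dataclass(frozen=True)
class DeletionAllele:
    """A join of two cut coordinates: the half-open interval
    [del_start, del_end) is excised and the ends fuse."""

    allele_id: str
    chrom_id: str
    del_start: int
    del_end: int
    removed_genes: tuple[str, ...]  # fully inside the deleted interval
    disrupted_genes: tuple[str, ...]  # contain exactly one breakpoint

    def __post_init__(self) -> None:
        assert self.del_start < self.del_end
        assert not set(self.removed_genes) & set(self.disrupted_genes)

    @property
    def length_bp(self) -> int:
        return self.del_end - self.del_start


@dataclass(frozen=True)
class BandPattern:
    """Predicted amplicon sizes for one assay on one allele.

    ``band_sizes`` keeps multiset semantics (one entry per product);
    ``rendered`` collapses co-migrating bands to what a gel shows."""

    assay_id: str
    allele: str
    band_sizes: tuple[int, ...]

    def rendered(self, resolution_bp: int = DEFAULT_RESOLUTION_BP) -> tuple[int, ...]:
        """Distinct observed bands: sizes within ``resolution_bp`` of an
        already-rendered band co-migrate with it."""
        out: list[int] = []
        for size in sorted(self.band_sizes):
            if not out or size - out[-1] > resolution_bp:
                out.append(size)
        return tuple(out)


def build_cut_profile(guide_set: GuideSet, site_index: SiteIndex) -> CutProfile:
    """Union of cut positions of all full-match sites of the selected
    guides, per chromosome, deduplicated and sorted."""
    per_chrom: dict[str, set[int]] = {}
    for guide in guide_set.guides:
        for s in site_index.full_matches(guide):
            per_chrom.setdefault(s.chrom_id, set()).add(s.cut_pos)
    return CutProfile({c: tuple(sorted(p)) for c, p in sorted(per_chrom.items())})


def enumerate_deletion_alleles(
    cut_profile: CutProfile,
    gene_copies: Sequence[GeneCopy],
    max_span: int | None = None,
) -> list[DeletionAllele]:
    """One allele per pair i<j of cut positions on the same chromosome
    (span capped at ``max_span`` when given); removed and disrupted gene
    lists computed by interval intersection."""
    genes_by_chrom: dict[str, list[GeneCopy]] = {}
    for g in gene_copies:
        genes_by_chrom.setdefault(g.chrom_id, []).append(g)

    alleles: list[DeletionAllele] = []
    for chrom, cuts in cut_profile.cuts.items():
        genes = sorted(genes_by_chrom.get(chrom, []), key=lambda g: g.start)
        for i in range(len(cuts)):
            for j in range(i + 1, len(cuts)):
                a, b = cuts[i], cuts[j]
                if max_span is not None and b - a > max_span:
                    continue
                removed, disrupted = [], []
                for g in genes:
                    if a <= g.start and g.end <= b:
                        removed.append(g.gene_id)
                    elif g.start < b and g.end > a:
                        # overlaps the deletion without being fully removed:
                        # a breakpoint (or the whole excision) lies in the body
                        disrupted.append(g.gene_id)
                alleles.append(
                    DeletionAllele(
                        allele_id=f"{chrom}:del:{a}-{b}",
                        chrom_id=chrom,
                        del_start=a,
                        del_end=b,
                        removed_genes=tuple(removed),
                        disrupted_genes=tuple(disrupted),
                    )
                )
    return alleles


def apply_deletion(sequence: str, allele: DeletionAllele) -> str:
    """Excise the deleted interval and join the cut ends."""
    return sequence[: allele.del_start] + sequence[allele.del_end :]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def simulate_pcr(
    primer_pair: PrimerPair,
    genome: Mapping[str, GenomeSequence],
    allele: DeletionAllele | None = None,
) -> BandPattern:
    """Predict amplicon sizes for one assay on the wild-type genome
    (``allele=None``) or on a deletion allele.

    The forward primer anneals on the + strand and the reverse primer on
    the - strand; both subsequences are taken from the wild-type
    reference at the assay's footprints and then located by exact match
    across the (possibly edited) chromosome, so a conserved primer pair
    yields one product per surviving family copy.  Product size is
    rev_end - fwd_start in edited coordinates, capped at max_product.
    """
    wt_seq = genome[primer_pair.chrom_id].sequence
    fwd = wt_seq[primer_pair.fwd_start : primer_pair.fwd_end]
    rev = wt_seq[primer_pair.rev_start : primer_pair.rev_end]

    if allele is None:
        template = wt_seq
        label = WT_LABEL
    else:
        if allele.chrom_id != primer_pair.chrom_id:
            template = wt_seq  # deletion elsewhere leaves this assay untouched
        else:
            template = apply_deletion(wt_seq, allele)
        label = allele.allele_id

    fwd_starts = _find_all(template, fwd)
    rev_sites = _find_all(template, rev)  # + strand footprint of the - strand primer
    if not fwd_starts or not rev_sites:
        logger.warning(
            "assay %s: primer not found on %s allele", primer_pair.assay_id, label
        )
        return BandPattern(primer_pair.assay_id, label, ())

    sizes = []
    for f in fwd_starts:
        for r in rev_sites:
            end = r + len(rev)
            size = end - f
            if 0 < size <= primer_pair.max_product:
                sizes.append(size)
    return BandPattern(primer_pair.assay_id, label, tuple(sorted(sizes)))


def classify_genotype(
    wt_pattern: BandPattern,
    observed_pattern: BandPattern,
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
) -> GenotypeCall:
    """Call a lane against the wild-type reference lane.

    wild_type: rendered patterns identical.  mixed: all wild-type bands
    present plus novel bands (heterozygote-like).  edited: any novel band
    with wild-type bands missing, or band loss alone (including the empty
    null-allele pattern).  Band identity is judged at gel resolution.
    """
    wt = wt_pattern.rendered(resolution_bp)
    obs = observed_pattern.rendered(resolution_bp)

    if not obs:
        logger.warning(
            "assay %s: empty observed pattern; calling edited (null allele)",
            observed_pattern.assay_id,
        )
        return GenotypeCall.EDITED

    def has_match(size: int, bands: tuple[int, ...]) -> bool:
        return any(abs(size - b) <= resolution_bp for b in bands)

    novel = [s for s in obs if not has_match(s, wt)]
    missing = [s for s in wt if not has_match(s, obs)]

    if not novel and not missing:
        return GenotypeCall.WILD_TYPE
    if novel and not missing:
        return GenotypeCall.MIXED
    return GenotypeCall.EDITED


def band_table(
    patterns: Iterable[tuple[BandPattern, GenotypeCall]],
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
) -> pd.DataFrame:
    rows = [
        {
            "assay_id": p.assay_id,
            "allele": p.allele,
            "band_sizes": ",".join(map(str, p.rendered(resolution_bp))),
            "call": call.value,
        }
        for p, call in patterns
    ]
    return pd.DataFrame(rows)


def write_band_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
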