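"""Protospacer enumeration: every 20-mer adjacent to a 5'-NGG-3' PAM.

Sites are reported on both strands.  Coordinates are 0-based half-open
on the + strand; a site's ``protospacer`` and ``pam`` are read 5'->3'
on the site's own strand.  The predicted blunt SpCas9 cut falls between
protospacer positions 17 and 18 (3 bp 5' of the PAM), which in + strand
coordinates is ``proto_end - 3`` for + sites and ``proto_start + 3``
for - sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GenomeSequence, GeneCopy

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN  # 23
CUT_OFFSET = 3  # bp 5' of the PAM on the protospacer strand

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """One candidate protospacer occurrence with its PAM."""

    chrom_id: str
    protospacer: str
    pam: str
    strand: str
    proto_start: int
    proto_end: int
    cut_pos: int
    gene_id: str | None = None

    @property
    def site_id(self) -> str:
        return f"{self.chrom_id}:{self.proto_start}-{self.proto_end}({self.strand})"

    @property
    def seed(self) -> str:
        """PAM-proximal 12-mer convenience view (full seed is configurable
        downstream; this is the conventional 12 bp)."""
        return self.protospacer[-12:]


def _contains_n(s: str) -> bool:
    return "N" in s


def enumerate_protospacers(
    genome: Mapping[str, GenomeSequence],
    regions: Sequence[tuple[str, int, int]] | None = None,
) -> list[TargetSite]:
    """Exhaustively enumerate NGG-adjacent 20-mers on both strands.

    ``regions``, when given, restricts the scan to 0-based half-open
    intervals ``(chrom_id, start, end)``; a site is reported when its
    full 23-bp footprint lies inside a region.  Sites whose protospacer
    or PAM contains N are excluded.  Output is sorted by
    (chrom, proto_start, strand).
    """
    if regions is not None:
        for chrom_id, start, end in regions:
            if chrom_id not in genome:
                raise ValueError(f"region on unknown chromosome {chrom_id!r}")
            if start < 0 or end > len(genome[chrom_id]) or start >= end:
                raise ValueError(
                    f"region {chrom_id}:{start}-{end} outside chromosome bounds"
                )
        scan: list[tuple[str, int, int]] = list(regions)
    else:
        scan = [(cid, 0, len(gs)) for cid, gs in genome.items()]

    sites: list[TargetSite] = []
    for chrom_id, start, end in scan:
        seq = genome[chrom_id].sequence
        # windows fully inside [start, end)
        for w in range(start, end - SITE_LEN + 1):
            window = seq[w : w + SITE_LEN]
            # + strand: [20-mer][NGG]
            if window[21] == "G" and window[22] == "G":
                proto, pam = window[:20], window[20:]
                if not (_contains_n(proto) or _contains_n(pam)):
                    sites.append(
                        TargetSite(
                            chrom_id=chrom_id,
                            protospacer=proto,
                            pam=pam,
                            strand="+",
                            proto_start=w,
                            proto_end=w + 20,
                            cut_pos=w + 20 - CUT_OFFSET,
                        )
                    )
            # - strand: + strand reads [CCN][20-mer]
            if window[0] == "C" and window[1] == "C":
                proto_plus, pam_plus = window[3:], window[:3]
                if not (_contains_n(proto_plus) or _contains_n(pam_plus)):
                    sites.append(
                        TargetSite(
                            chrom_id=chrom_id,
                            protospacer=revcomp(proto_plus),
                            pam=revcomp(pam_plus),
                            strand="-",
                            proto_start=w + 3,
                            proto_end=w + 23,
                            cut_pos=w + 3 + CUT_OFFSET,
                        )
                    )
    sites.sort(key=lambda s: (s.chrom_id, s.proto_start, s.strand))
    return sites


def assign_sites_to_genes(
    sites: Iterable[TargetSite], gene_copies: Sequence[GeneCopy]
) -> list[TargetSite]:
    """Attach gene_id to each site whose predicted cut falls inside a
    gene body (half-open: start inclusive, end exclusive).

    Membership is decided by the cut position, not protospacer overlap:
    the deletion junction forms at the cut, so the cut determines
    whether the gene body is disrupted.
    """
    by_chrom: dict[str, list[GeneCopy]] = {}
    for g in gene_copies:
        by_chrom.setdefault(g.chrom_id, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.start)

    out: list[TargetSite] = []
    for site in sites:
        gene_id = None
        for g in by_chrom.get(site.chrom_id, ()):
            if g.start > site.cut_pos:
                break
            if g.contains(site.cut_pos):
                gene_id = g.gene_id
                break
        out.append(replace(site, gene_id=gene_id))
    return out


def sites_to_frame(sites: Sequence[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom_id for s in sites],
            "proto_start": [s.proto_start for s in sites],
            "proto_end": [s.proto_end for s in sites],
            "strand": [s.strand for s in sites],
            "protospacer": [s.protospacer for s in sites],
            "pam": [s.pam for s in sites],
            "cut_pos": [s.cut_pos for s in sites],
            "gene_id": [s.gene_id if s.gene_id else "." for s in sites],
        }
    )


def write_sites_tsv(sites: Sequence[TargetSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def write_sites_bed(sites: Sequence[TargetSite], path: str | Path) -> None:
    """BED6 with 0-based half-open protospacer coordinates;
    name = gene_id or '.', score = 0."""
    with open(path, "w") as fh:
        for s in sites:
            name = s.gene_id if s.gene_id else "."
            fh.write(
                f"{s.chrom_id}\t{s.proto_start}\t{s.proto_end}\t{name}\t0\t{s.strand}\n"
            )
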