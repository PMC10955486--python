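"""Guide-vs-site comparison: full matches, seed matches, mismatch maps,
and genome-wide off-target screening.

Mismatch positions are indexed 1..20 from the PAM-PROXIMAL end
(position 1 is the protospacer base adjacent to the PAM), so the seed
region is always positions ``1..seed_len`` regardless of strand.  The
PAM itself is excluded from mismatch accounting: any NGG is accepted.
A site containing N never matches (full=False, seed=False).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GeneCopy, GenomeSequence
from .sites import PROTOSPACER_LEN, TargetSite, enumerate_protospacers

DEFAULT_SEED_LEN = 12


class GuideError(ValueError):
    """Raised for malformed guide sequences."""


def validate_guide(guide_seq: str) -> str:
    guide_seq = guide_seq.upper()
    if len(guide_seq) != PROTOSPACER_LEN:
        raise GuideError(
            f"guide must be {PROTOSPACER_LEN} nt, got {len(guide_seq)}: {guide_seq!r}"
        )
    if set(guide_seq) - set("ACGT"):
        raise GuideError(f"guide contains characters outside ACGT: {guide_seq!r}")
    return guide_seq


@dataclass(frozen=True)
class MatchRecord:
    """The relation between one guide sequence and one target site."""

    guide_seq: str
    site: TargetSite
    mismatch_positions: frozenset[int]  # 1..20 from PAM-proximal end
    full_match: bool
    seed_match: bool
    valid: bool = True  # False when the site contains N

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)


def match_profile(
    guide_seq: str, site: TargetSite, seed_len: int = DEFAULT_SEED_LEN
) -> MatchRecord:
    """Compare a 20-nt guide to a site's protospacer, base by base.

    Position ``p`` (PAM-proximal, 1-based) corresponds to string index
    ``20 - p`` of the 5'->3' protospacer, so the seed occupies the last
    ``seed_len`` characters.
    """
    guide_seq = validate_guide(guide_seq)
    if not 1 <= seed_len <= PROTOSPACER_LEN:
        raise ValueError(f"seed_len must be in 1..{PROTOSPACER_LEN}")
    proto = site.protospacer
    if "N" in proto or "N" in site.pam:
        return MatchRecord(guide_seq, site, frozenset(), False, False, valid=False)
    mismatches = frozenset(
        PROTOSPACER_LEN - i for i in range(PROTOSPACER_LEN) if guide_seq[i] != proto[i]
    )
    full = not mismatches
    seed = all(p > seed_len for p in mismatches)
    return MatchRecord(guide_seq, site, mismatches, full, seed)


def cross_match_matrix(
    candidate_guides: Sequence[str],
    sites: Sequence[TargetSite],
    seed_len: int = DEFAULT_SEED_LEN,
) -> list[list[MatchRecord]]:
    """All-pairs comparison: one MatchRecord per (guide, site).

    Candidates must be deduplicated; a duplicate raises.
    """
    guides = [validate_guide(g) for g in candidate_guides]
    if len(set(guides)) != len(guides):
        raise GuideError("candidate guides must be deduplicated")
    return [[match_profile(g, s, seed_len) for s in sites] for g in guides]


@dataclass
class SiteIndex:
    """Exact-lookup index over a fixed site list.

    ``full`` keys the 20-mer protospacer; ``seed`` keys the PAM-proximal
    ``seed_len``-mer.  Both map to lists of sites, giving O(1) full- and
    seed-match queries without materializing a k x m match matrix.
    """

    seed_len: int = DEFAULT_SEED_LEN
    full: dict[str, list[TargetSite]] = field(default_factory=dict)
    seed: dict[str, list[TargetSite]] = field(default_factory=dict)

    @classmethod
    def build(
        cls, sites: Iterable[TargetSite], seed_len: int = DEFAULT_SEED_LEN
    ) -> "SiteIndex":
        idx = cls(seed_len=seed_len)
        for s in sites:
            if "N" in s.protospacer or "N" in s.pam:
                continue
            idx.full.setdefault(s.protospacer, []).append(s)
            idx.seed.setdefault(s.protospacer[-seed_len:], []).append(s)
        return idx

    def full_matches(self, guide_seq: str) -> list[TargetSite]:
        return self.full.get(guide_seq, [])

    def seed_matches(self, guide_seq: str) -> list[TargetSite]:
        return self.seed.get(guide_seq[-self.seed_len :], [])


@dataclass(frozen=True)
class OffTargetReport:
    """Genome-wide seed-match hits outside the target-family gene bodies."""

    guide_seq: str
    n_seed_hits_outside_family: int
    hit_locations: tuple[TargetSite, ...]

    def __post_init__(self) -> None:
        assert self.n_seed_hits_outside_family == len(self.hit_locations)


def _family_interval_lookup(family_genes: Sequence[GeneCopy]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in family_genes:
        by_chrom.setdefault(g.chrom_id, []).append((g.start, g.end))
    for ivs in by_chrom.values():
        ivs.sort()

    def inside(chrom: str, pos: int) -> bool:
        for start, end in by_chrom.get(chrom, ()):
            if start > pos:
                return False
            if pos < end:
                return True
        return False

    return inside


def offtarget_scan(
    guide_seq: str,
    genome: Mapping[str, GenomeSequence],
    family_genes: Sequence[GeneCopy],
    seed_len: int = DEFAULT_SEED_LEN,
    site_index: SiteIndex | None = None,
) -> OffTargetReport:
    """Count genome-wide NGG-adjacent sites seed-matching the guide whose
    cut position lies outside every target-family gene body.

    ``site_index`` may be supplied to reuse a prebuilt genome-wide index
    (recommended when screening many guides).
    """
    guide_seq = validate_guide(guide_seq)
    if site_index is None:
        site_index = SiteIndex.build(enumerate_protospacers(genome), seed_len=seed_len)
    elif site_index.seed_len != seed_len:
        raise ValueError("site_index was built with a different seed_len")
    inside = _family_interval_lookup(family_genes)
    hits = tuple(
        s
        for s in site_index.seed_matches(guide_seq)
        if not inside(s.chrom_id, s.cut_pos)
    )
    return OffTargetReport(guide_seq, len(hits), hits)


def match_records_to_frame(records: Iterable[MatchRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "guide": r.guide_seq,
                "site_id": r.site.site_id,
                "n_mismatch": r.n_mismatch,
                "mismatch_positions": ",".join(map(str, sorted(r.mismatch_positions))),
                "full": r.full_match,
                "seed": r.seed_match,
            }
        )
    return pd.DataFrame(rows)


def write_offtarget_tsv(reports: Iterable[OffTargetReport], path: str | Path) -> None:
    rows = [
        {
            "guide": r.guide_seq,
            "n_offtarget": r.n_seed_hits_outside_family,
            "locations": ";".join(s.site_id for s in r.hit_locations),
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
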