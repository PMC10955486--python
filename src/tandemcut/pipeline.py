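"""End-to-end design pipeline: scan -> match -> prioritize -> filter ->
select, with a structured log of every filtering decision."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .io import GeneCopy, GenomeSequence
from .matching import DEFAULT_SEED_LEN, OffTargetReport, SiteIndex, offtarget_scan
from .selection import (
    DEFAULT_BUDGET,
    DEFAULT_MAX_OFFTARGET,
    DEFAULT_MAX_SITES,
    DEFAULT_MIN_SITES,
    DEFAULT_THRESHOLD_FRAC,
    GuideSet,
    PriorityAssignment,
    assign_priority,
    candidate_protospacers,
    coverage_report,
    filter_candidates,
    select_guide_set,
)
from .sites import TargetSite, assign_sites_to_genes, enumerate_protospacers

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_INFEASIBLE = 2


@dataclass(frozen=True)
class RunConfig:
    """Design-run parameters (defaults are the realized design constants:
    12-bp seed, budget of 6 guides, 2-5 cut sites per gene)."""

    seed_len: int = DEFAULT_SEED_LEN
    budget: int = DEFAULT_BUDGET
    min_sites: int = DEFAULT_MIN_SITES
    max_sites: int = DEFAULT_MAX_SITES
    max_offtarget: int = DEFAULT_MAX_OFFTARGET
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    resolution_bp: int = 20
    target_families: tuple[str, ...] | None = None  # None = all families present

    def __post_init__(self) -> None:
        if not 1 <= self.seed_len <= 20:
            raise ValueError("seed_len must be in 1..20")
        if self.min_sites > self.max_sites:
            raise ValueError("min_sites must be <= max_sites")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class DesignResult:
    """Everything a design run produced, for reporting and simulation."""

    config: RunConfig
    sites: list[TargetSite]
    site_index: SiteIndex
    priorities: PriorityAssignment
    candidates: list[str]
    filtered_candidates: list[str]
    offtargets: dict[str, OffTargetReport]
    guide_set: GuideSet
    target_genes: list[GeneCopy]

    @property
    def satisfied(self) -> bool:
        return self.guide_set.all_satisfied


def run_design(
    genome: Mapping[str, GenomeSequence],
    gene_copies: Sequence[GeneCopy],
    expression: Mapping[str, float] | None = None,
    config: RunConfig = RunConfig(),
) -> DesignResult:
    """Run the full guide-design procedure on loaded inputs.

    ``config.target_families`` restricts the design to the named
    subfamily labels; genes outside them define off-target space.
    """
    logger.info("design config: %s", dataclasses.asdict(config))

    if config.target_families is None:
        target_labels = {g.family for g in gene_copies}
    else:
        target_labels = set(config.target_families)
        unknown = target_labels - {g.family for g in gene_copies}
        if unknown:
            raise ValueError(f"target families not in annotation: {sorted(unknown)}")
    target_genes = [g for g in gene_copies if g.family in target_labels]

    sites = assign_sites_to_genes(enumerate_protospacers(genome), gene_copies)
    logger.info("enumerated %d candidate sites", len(sites))
    site_index = SiteIndex.build(sites, seed_len=config.seed_len)

    priorities = assign_priority(
        target_genes, expression, threshold_frac=config.threshold_frac
    )
    logger.info(
        "high-priority genes: %s", ", ".join(priorities.high_priority_ids()) or "(none)"
    )

    candidates = candidate_protospacers(sites, priorities)
    logger.info("%d distinct candidate protospacers in high-priority genes", len(candidates))

    offtargets = {
        guide: offtarget_scan(
            guide, genome, target_genes, seed_len=config.seed_len, site_index=site_index
        )
        for guide in candidates
    }
    filtered = filter_candidates(
        candidates, site_index, offtargets, priorities, max_offtarget=config.max_offtarget
    )
    logger.info("%d candidates remain after filtering", len(filtered))

    guide_set = select_guide_set(
        filtered,
        site_index,
        priorities,
        offtarget_reports=offtargets,
        budget=config.budget,
        min_sites=config.min_sites,
        max_sites=config.max_sites,
    )
    logger.info(
        "selected %d guide(s); design %s",
        guide_set.size,
        "satisfied" if guide_set.all_satisfied else "NOT satisfied",
    )
    return DesignResult(
        config=config,
        sites=sites,
        site_index=site_index,
        priorities=priorities,
        candidates=candidates,
        filtered_candidates=filtered,
        offtargets=offtargets,
        guide_set=guide_set,
        target_genes=target_genes,
    )


def write_design_outputs(
    result: DesignResult, gene_copies: Sequence[GeneCopy], prefix: str | Path
) -> None:
    """Write PREFIX.guides.tsv and PREFIX.coverage.tsv."""
    import pandas as pd

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    rows = []
    for guide in result.guide_set.guides:
        hits = result.site_index.full_matches(guide)
        fams = sorted(
            {g.family for g in gene_copies for s in hits if s.gene_id == g.gene_id}
        )
        per_gene = sorted(
            f"{s.gene_id}:{s.cut_pos}" for s in hits if s.gene_id is not None
        )
        rows.append(
            {
                "guide": guide,
                "families_hit": ",".join(fams),
                "gene_cut_positions": ";".join(per_gene),
                "n_offtarget": result.offtargets[guide].n_seed_hits_outside_family,
            }
        )
    pd.DataFrame(
        rows, columns=["guide", "families_hit", "gene_cut_positions", "n_offtarget"]
    ).to_csv(f"{prefix}.guides.tsv", sep="\t", index=False)

    coverage_report(result.guide_set, result.site_index, list(gene_copies)).to_csv(
        f"{prefix}.coverage.tsv", sep="\t", index=False
    )
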