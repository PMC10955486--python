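"""Expression-based gene prioritization, candidate filtering, and
coverage-constrained guide-set selection.

The selection problem is a set multicover: each high-priority gene copy
must be cut at ``min_sites`` to ``max_sites`` distinct positions inside
its gene body by guides with a perfect 20-bp protospacer match, using at
most ``budget`` guides.  A greedy heuristic solves desk-scale instances;
an exhaustive solver over all subsets of <= 15 candidates serves as a
correctness oracle in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .io import GeneCopy
from .matching import OffTargetReport, SiteIndex
from .sites import TargetSite

logger = logging.getLogger(__name__)

DEFAULT_BUDGET = 6
DEFAULT_MIN_SITES = 2
DEFAULT_MAX_SITES = 5
DEFAULT_THRESHOLD_FRAC = 0.05
DEFAULT_MAX_OFFTARGET = 0


class PriorityReason(str, Enum):
    PSEUDOGENE_EXCLUDED = "pseudogene_excluded"
    BELOW_THRESHOLD = "below_threshold"
    DOMINANT_EXPRESSION = "dominant_expression"


@dataclass(frozen=True)
class PriorityAssignment:
    """Per-gene high-priority flag with the reason for the call."""

    high_priority: dict[str, bool]
    reason: dict[str, PriorityReason]

    def high_priority_ids(self) -> list[str]:
        return sorted(g for g, hp in self.high_priority.items() if hp)


def assign_priority(
    gene_copies: Sequence[GeneCopy],
    expression: Mapping[str, float] | None = None,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> PriorityAssignment:
    """Mark the gene copies that dominate their family's expression.

    A copy is high priority iff it is not a pseudogene, is expressed, and
    its abundance is at least ``threshold_frac`` of its family's total.
    Pseudogenes are excluded regardless of measured abundance.  When
    ``expression`` is None, the abundances carried on the GeneCopy
    records are used.
    """
    expr = {
        g.gene_id: (
            expression.get(g.gene_id, 0.0) if expression is not None else g.expression
        )
        for g in gene_copies
    }
    family_total: dict[str, float] = {}
    for g in gene_copies:
        family_total[g.family] = family_total.get(g.family, 0.0) + expr[g.gene_id]

    high: dict[str, bool] = {}
    reason: dict[str, PriorityReason] = {}
    for g in gene_copies:
        if g.pseudogene:
            high[g.gene_id] = False
            reason[g.gene_id] = PriorityReason.PSEUDOGENE_EXCLUDED
        elif expr[g.gene_id] > 0 and expr[g.gene_id] >= threshold_frac * family_total[g.family]:
            high[g.gene_id] = True
            reason[g.gene_id] = PriorityReason.DOMINANT_EXPRESSION
        else:
            high[g.gene_id] = False
            reason[g.gene_id] = PriorityReason.BELOW_THRESHOLD
    return PriorityAssignment(high, reason)


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------


def filter_candidates(
    candidates: Sequence[str],
    site_index: SiteIndex,
    offtarget_reports: Mapping[str, OffTargetReport],
    priorities: PriorityAssignment,
    max_offtarget: int = DEFAULT_MAX_OFFTARGET,
) -> list[str]:
    """Keep a candidate iff it has >= 1 perfect 20-bp match whose cut
    falls in a high-priority gene AND its seed-level off-target count is
    within ``max_offtarget``.

    Filtering decisions are logged per guide.
    """
    kept: list[str] = []
    for guide in candidates:
        full_hits = site_index.full_matches(guide)
        in_high = any(
            s.gene_id is not None and priorities.high_priority.get(s.gene_id, False)
            for s in full_hits
        )
        if not in_high:
            logger.info("guide %s removed: no full match in a high-priority gene", guide)
            continue
        n_off = offtarget_reports[guide].n_seed_hits_outside_family
        if n_off > max_offtarget:
            logger.info("guide %s removed: %d off-target seed hits", guide, n_off)
            continue
        logger.info("guide %s kept", guide)
        kept.append(guide)
    return kept


# ---------------------------------------------------------------------------
# Guide-set selection
# ---------------------------------------------------------------------------


@dataclass
class GuideSet:
    """A selected multiplex guide set with per-gene coverage accounting.

    ``per_gene_sites`` lists the distinct cut positions covered by full
    matches inside each high-priority gene body; ``satisfied`` flags
    genes whose distinct-cut count reached ``min_sites``; genes covered
    at more than ``max_sites`` positions are flagged ``over_max`` but the
    design is not failed for it.
    """

    guides: list[str]
    per_gene_sites: dict[str, list[int]]
    satisfied: dict[str, bool]
    over_max: dict[str, bool] = field(default_factory=dict)
    infeasible_genes: list[str] = field(default_factory=list)

    @property
    def all_satisfied(self) -> bool:
        return bool(self.satisfied) and all(self.satisfied.values())

    @property
    def size(self) -> int:
        return len(self.guides)


class InfeasibleDesignError(RuntimeError):
    """No candidate subset can satisfy minimum coverage for the named genes."""

    def __init__(self, genes: Sequence[str]):
        self.genes = list(genes)
        super().__init__(
            "no candidate subset reaches minimum coverage for gene(s): "
            + ", ".join(self.genes)
        )


def _coverage_map(
    candidates: Sequence[str],
    site_index: SiteIndex,
    high_genes: set[str],
) -> dict[str, dict[str, set[int]]]:
    """guide -> gene_id -> set of distinct cut positions (full matches in
    high-priority gene bodies only)."""
    cov: dict[str, dict[str, set[int]]] = {}
    for guide in candidates:
        per_gene: dict[str, set[int]] = {}
        for s in site_index.full_matches(guide):
            if s.gene_id in high_genes:
                per_gene.setdefault(s.gene_id, set()).add(s.cut_pos)
        cov[guide] = per_gene
    return cov


def _accounting(
    chosen: Sequence[str],
    coverage: Mapping[str, Mapping[str, set[int]]],
    high_genes: set[str],
    min_sites: int,
    max_sites: int,
) -> tuple[dict[str, list[int]], dict[str, bool], dict[str, bool]]:
    per_gene: dict[str, set[int]] = {g: set() for g in sorted(high_genes)}
    for guide in chosen:
        for gene, cuts in coverage[guide].items():
            per_gene[gene].update(cuts)
    sites = {g: sorted(c) for g, c in per_gene.items()}
    satisfied = {g: len(c) >= min_sites for g, c in per_gene.items()}
    over = {g: len(c) > max_sites for g, c in per_gene.items()}
    return sites, satisfied, over


def select_guide_set(
    candidates: Sequence[str],
    site_index: SiteIndex,
    priorities: PriorityAssignment,
    offtarget_reports: Mapping[str, OffTargetReport] | None = None,
    budget: int = DEFAULT_BUDGET,
    min_sites: int = DEFAULT_MIN_SITES,
    max_sites: int = DEFAULT_MAX_SITES,
) -> GuideSet:
    """Greedy weighted multicover over filtered candidates.

    Iteratively adds the candidate contributing the most new
    (gene, cut_pos) coverage toward ``min_sites`` over still-unsatisfied
    genes; ties broken by (fewer off-target hits, more total full
    matches, lexicographic guide sequence); stops when every
    high-priority gene is satisfied or the budget is exhausted.

    Raises InfeasibleDesignError when some high-priority gene cannot
    reach ``min_sites`` even with every candidate selected.
    """
    high_genes = set(priorities.high_priority_ids())
    coverage = _coverage_map(candidates, site_index, high_genes)

    # structural infeasibility: a gene short of min_sites under ALL candidates
    all_sites, all_sat, _ = _accounting(
        list(candidates), coverage, high_genes, min_sites, max_sites
    )
    impossible = [g for g, ok in all_sat.items() if not ok]
    if impossible:
        raise InfeasibleDesignError(impossible)

    n_off = {
        g: (offtarget_reports[g].n_seed_hits_outside_family if offtarget_reports else 0)
        for g in candidates
    }
    n_full = {g: len(site_index.full_matches(g)) for g in candidates}

    chosen: list[str] = []
    covered: dict[str, set[int]] = {g: set() for g in high_genes}
    remaining = sorted(set(candidates))

    while len(chosen) < budget:
        unsatisfied = {g for g in high_genes if len(covered[g]) < min_sites}
        if not unsatisfied:
            break

        def gain(guide: str) -> int:
            total = 0
            for gene in unsatisfied:
                cuts = coverage[guide].get(gene)
                if cuts:
                    now = len(covered[gene])
                    total += min(len(covered[gene] | cuts), min_sites) - min(now, min_sites)
            return total

        best = None
        best_key = None
        for guide in remaining:
            g = gain(guide)
            if g <= 0:
                continue
            key = (-g, n_off[guide], -n_full[guide], guide)
            if best_key is None or key < best_key:
                best, best_key = guide, key
        if best is None:
            break  # no candidate helps any unsatisfied gene
        chosen.append(best)
        remaining.remove(best)
        for gene, cuts in coverage[best].items():
            covered[gene].update(cuts)

    sites, satisfied, over = _accounting(chosen, coverage, high_genes, min_sites, max_sites)
    unsat = [g for g, ok in satisfied.items() if not ok]
    if unsat:
        logger.warning(
            "budget %d exhausted with %d gene(s) unsatisfied: %s",
            budget,
            len(unsat),
            ", ".join(unsat),
        )
    return GuideSet(
        guides=chosen, per_gene_sites=sites, satisfied=satisfied, over_max=over
    )


def exhaustive_guide_set(
    candidates: Sequence[str],
    site_index: SiteIndex,
    priorities: PriorityAssignment,
    budget: int = DEFAULT_BUDGET,
    min_sites: int = DEFAULT_MIN_SITES,
    max_sites: int = DEFAULT_MAX_SITES,
    max_candidates: int = 15,
) -> GuideSet | None:
    """Exact solver: smallest candidate subset (<= budget) satisfying all
    high-priority genes, or None when no subset does.

    Exponential; refuses instances above ``max_candidates``.  Intended as
    the correctness oracle for the greedy heuristic.
    """
    cands = sorted(set(candidates))
    if len(cands) > max_candidates:
        raise ValueError(
            f"exhaustive solver limited to {max_candidates} candidates, got {len(cands)}"
        )
    high_genes = set(priorities.high_priority_ids())
    coverage = _coverage_map(cands, site_index, high_genes)
    for k in range(0, min(budget, len(cands)) + 1):
        for subset in itertools.combinations(cands, k):
            sites, satisfied, over = _accounting(
                subset, coverage, high_genes, min_sites, max_sites
            )
            if all(satisfied.values()):
                return GuideSet(
                    guides=list(subset),
                    per_gene_sites=sites,
                    satisfied=satisfied,
                    over_max=over,
                )
    return None


def coverage_report(
    guide_set: GuideSet,
    site_index: SiteIndex,
    gene_copies: Sequence[GeneCopy],
) -> pd.DataFrame:
    """Per-gene table of distinct covered cut positions for ALL annotated
    genes (including non-target families, whose counts document the
    specificity of the design)."""
    per_gene: dict[str, set[int]] = {g.gene_id: set() for g in gene_copies}
    for guide in guide_set.guides:
        for s in site_index.full_matches(guide):
            if s.gene_id in per_gene:
                per_gene[s.gene_id].add(s.cut_pos)
    rows = []
    for g in gene_copies:
        cuts = sorted(per_gene[g.gene_id])
        rows.append(
            {
                "gene_id": g.gene_id,
                "family": g.family,
                "n_sites": len(cuts),
                "cut_positions": ",".join(map(str, cuts)),
                "satisfied": guide_set.satisfied.get(g.gene_id, False),
            }
        )
    return pd.DataFrame(rows)


def candidate_protospacers(
    sites: Sequence[TargetSite], priorities: PriorityAssignment
) -> list[str]:
    """The candidate pool: distinct protospacers of sites cutting inside
    high-priority gene bodies."""
    high = set(priorities.high_priority_ids())
    return sorted(
        {s.protospacer for s in sites if s.gene_id in high and "N" not in s.protospacer}
    )
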