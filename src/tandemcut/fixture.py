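"""Seeded generator of synthetic tandem-duplicate gene families.

The generated genome mirrors the architecture of the maize 19 kDa
alpha-zein complex: an A family of 12 copies split over two linked loci
on one chromosome (labelled ``A1`` and ``A2``), a B family of 8 copies
on a second chromosome, a D family of 5 pseudogene copies on a third,
and a related but non-target family (standing in for the 22 kDa
subclass) upstream of the A locus on the A chromosome.

Each family descends from a common ancestral gene by substitution-only
divergence, which keeps planted windows positionally stable.  Into every
copy of each target family the generator plants

* ``n_guide_windows`` identical 23-mer windows (20-mer protospacer +
  NGG PAM) at fixed offsets — conserved cut sites that guarantee a
  coverage-constrained design is feasible by construction, and
* one forward and one reverse primer window — conserved primer sites so
  a single assay amplifies every family copy at equal product length.

Planted guide content is drawn at random (not from the ancestor), so it
recurs outside the family only by 4^-12 chance; generation-time
validation rejects any draw whose planted guides have full matches
outside their own family or seed-level matches outside the target
families, and retries with fresh randomness.

Expression is drawn once and written to the TSV; most copies of each
expressed family are "high" (log-normal around 100), one copy per
family is planted "low" (below the 5% family-share threshold), and
pseudogene copies are 0.  The design pipeline never sees the planted
labels; the manifest records them for test assertions only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    GeneCopy,
    GenomeSequence,
    PrimerPair,
    write_expression,
    write_fasta,
    write_gff3,
    write_primers,
)
from .matching import SiteIndex
from .sites import enumerate_protospacers

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """Raised when no valid fixture can be generated for the config."""


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic family architecture.

    Defaults reproduce the studied complex: 12 A copies over two loci,
    8 B copies, 5 pseudogene D copies, 6 non-target copies.
    """

    seed: int = 17
    a1_copies: int = 6
    a2_copies: int = 6
    b_copies: int = 8
    d_copies: int = 5
    nontarget_copies: int = 6
    gene_length: int = 750
    spacer_min: int = 2000
    spacer_max: int = 4000
    within_divergence: float = 0.02
    between_divergence: float = 0.08
    nontarget_divergence: float = 0.15
    n_guide_windows: int = 3
    primer_length: int = 22
    low_copies_per_family: int = 1
    expression_high_mean: float = 100.0
    expression_high_sigma: float = 0.4
    threshold_frac: float = 0.05  # planted-low copies must fall below this share
    max_product: int = 1500
    max_attempts: int = 20

    def __post_init__(self) -> None:
        for name in (
            "within_divergence",
            "between_divergence",
            "nontarget_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("a1_copies", "a2_copies", "b_copies", "d_copies", "nontarget_copies"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.spacer_min > self.spacer_max or self.spacer_min < 0:
            raise ValueError("invalid spacer range")
        if self.gene_length < 2 * (self.primer_length + 30) + 23 * self.n_guide_windows:
            raise ValueError("gene_length too small to hold planted windows")

    @property
    def target_families(self) -> tuple[str, ...]:
        return ("A1", "A2", "B", "D")

    def guide_window_offsets(self) -> list[int]:
        """Evenly spaced window starts strictly between the primer
        footprints."""
        lo = self.primer_length + 60
        hi = self.gene_length - self.primer_length - 60 - 23
        if self.n_guide_windows == 1:
            return [(lo + hi) // 2]
        step = (hi - lo) // (self.n_guide_windows - 1)
        return [lo + i * step for i in range(self.n_guide_windows)]

    @property
    def fwd_primer_offset(self) -> int:
        return 20

    @property
    def rev_primer_offset(self) -> int:
        return self.gene_length - self.primer_length - 28


@dataclass
class FixtureResult:
    """In-memory view of one generated fixture."""

    config: FixtureConfig
    genome: dict[str, GenomeSequence]
    genes: list[GeneCopy]
    expression: dict[str, float]
    primers: list[PrimerPair]
    planted_guides: dict[str, list[str]]  # family group -> protospacer list
    planted_high: list[str]  # gene ids planted as high priority
    manifest: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only divergence: each base flips to one of the three
    other bases with probability ``rate``."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    mask = rng.random(len(arr)) < rate
    if mask.any():
        idx = np.flatnonzero(mask)
        for i in idx:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _plant(seq: str, offset: int, content: str) -> str:
    return seq[:offset] + content + seq[offset + len(content) :]


# family groups share planted windows and primer assays:
#   "A" spans labels A1+A2 (two linked loci of one family)
_GROUP_LABELS = {"A": ("A1", "A2"), "B": ("B",), "D": ("D",), "NT": ("NONTARGET",)}


def _attempt(config: FixtureConfig, rng: np.random.Generator) -> FixtureResult:
    L = config.gene_length
    offsets = config.guide_window_offsets()
    fwd_off, rev_off = config.fwd_primer_offset, config.rev_primer_offset
    plen = config.primer_length

    anc = {"A": _random_seq(rng, L)}
    anc["B"] = _mutate(rng, anc["A"], config.between_divergence)
    anc["D"] = _mutate(rng, anc["A"], config.between_divergence)
    anc["NT"] = _mutate(rng, anc["A"], config.nontarget_divergence)

    # planted window content per family group
    guide_windows: dict[str, list[str]] = {}
    for group in ("A", "B", "D"):
        windows = []
        for _ in offsets:
            proto = _random_seq(rng, 20)
            pam = _BASES[rng.integers(0, 4)] + "GG"
            windows.append(proto + pam)
        guide_windows[group] = windows
    primer_windows = {
        group: (_random_seq(rng, plen), _random_seq(rng, plen))
        for group in ("A", "B", "NT")
    }

    def make_copy(group: str) -> str:
        seq = _mutate(rng, anc[group], config.within_divergence)
        for off, window in zip(offsets, guide_windows.get(group, [])):
            seq = _plant(seq, off, window)
        if group in primer_windows:
            fwd, rev = primer_windows[group]
            seq = _plant(seq, fwd_off, fwd)
            seq = _plant(seq, rev_off, rev)
        return seq

    def spacer() -> str:
        return _random_seq(rng, int(rng.integers(config.spacer_min, config.spacer_max + 1)))

    genes: list[GeneCopy] = []

    def build_chrom(chrom_id: str, blocks: list[tuple[str, str, int]]) -> str:
        """blocks: (group, family_label, n_copies); genes separated by
        random spacers, loci separated by a wider gap."""
        parts = [_random_seq(rng, 1000)]
        pos = 1000
        for group, family, n_copies in blocks:
            for k in range(n_copies):
                seq = make_copy(group)
                label_count = sum(1 for g in genes if g.family == family)
                gene_id = f"{family}_{label_count + 1}"
                genes.append(
                    GeneCopy(
                        gene_id=gene_id,
                        family=family,
                        chrom_id=chrom_id,
                        start=pos,
                        end=pos + L,
                        strand="+",
                        pseudogene=family == "D",
                    )
                )
                parts.append(seq)
                pos += L
                sp = spacer()
                parts.append(sp)
                pos += len(sp)
            gap = _random_seq(rng, 5000)
            parts.append(gap)
            pos += len(gap)
        return "".join(parts)

    chrom_a = build_chrom(
        "chrA",
        [
            ("NT", "NONTARGET", config.nontarget_copies),
            ("A", "A1", config.a1_copies),
            ("A", "A2", config.a2_copies),
        ],
    )
    chrom_b = build_chrom("chrB", [("B", "B", config.b_copies)])
    chrom_d = build_chrom("chrD", [("D", "D", config.d_copies)])
    genome = {
        "chrA": GenomeSequence("chrA", chrom_a),
        "chrB": GenomeSequence("chrB", chrom_b),
        "chrD": GenomeSequence("chrD", chrom_d),
    }

    # --- expression -------------------------------------------------------
    expression: dict[str, float] = {}
    planted_high: list[str] = []
    for family in ("A1", "A2", "B", "NONTARGET"):
        members = [g for g in genes if g.family == family]
        n_low = config.low_copies_per_family if family != "NONTARGET" else 0
        low_ids = {g.gene_id for g in members[-n_low:]} if n_low else set()
        mean = config.expression_high_mean if family != "NONTARGET" else 50.0
        for g in members:
            if g.gene_id in low_ids:
                expression[g.gene_id] = float(rng.uniform(0.5, 3.0))
            else:
                expression[g.gene_id] = float(
                    rng.lognormal(np.log(mean), config.expression_high_sigma)
                )
                if family != "NONTARGET":
                    planted_high.append(g.gene_id)
    for g in genes:
        if g.family == "D":
            expression[g.gene_id] = 0.0
    genes = [
        dataclasses.replace(g, expression=expression[g.gene_id]) for g in genes
    ]

    # --- primer assays (copy 1 of each assayed group) ---------------------
    primers: list[PrimerPair] = []
    for assay, family in (("A", "A1"), ("B", "B"), ("NT", "NONTARGET")):
        first = next(g for g in genes if g.family == family)
        primers.append(
            PrimerPair(
                assay_id=assay,
                chrom_id=first.chrom_id,
                fwd_start=first.start + fwd_off,
                fwd_end=first.start + fwd_off + plen,
                rev_start=first.start + rev_off,
                rev_end=first.start + rev_off + plen,
                max_product=config.max_product,
            )
        )

    # --- validation -------------------------------------------------------
    _validate(config, genome, genes, expression, guide_windows, primer_windows, planted_high)

    planted = {grp: [w[:20] for w in ws] for grp, ws in guide_windows.items()}
    result = FixtureResult(
        config=config,
        genome=genome,
        genes=genes,
        expression=expression,
        primers=primers,
        planted_guides=planted,
        planted_high=sorted(planted_high),
    )
    result.manifest = _build_manifest(result, guide_windows, offsets)
    return result


def _validate(
    config: FixtureConfig,
    genome: dict[str, GenomeSequence],
    genes: list[GeneCopy],
    expression: dict[str, float],
    guide_windows: dict[str, list[str]],
    primer_windows: dict[str, tuple[str, str]],
    planted_high: list[str],
) -> None:
    sites = enumerate_protospacers(genome)
    from .sites import assign_sites_to_genes  # local to avoid import cycle at module load

    sites = assign_sites_to_genes(sites, genes)
    index = SiteIndex.build(sites)

    target_labels = set(config.target_families)
    target_gene_ids = {g.gene_id for g in genes if g.family in target_labels}
    group_gene_ids = {
        grp: {g.gene_id for g in genes if g.family in labels}
        for grp, labels in _GROUP_LABELS.items()
    }
    group_sizes = {grp: len(ids) for grp, ids in group_gene_ids.items()}

    all_planted = [w[:20] for ws in guide_windows.values() for w in ws]
    if len(set(all_planted)) != len(all_planted):
        raise GenerationError("planted guide collision")
    if len({p[-12:] for p in all_planted}) != len(all_planted):
        raise GenerationError("planted guide seed collision")

    for group, windows in guide_windows.items():
        own = group_gene_ids[group]
        for window in windows:
            guide = window[:20]
            full = index.full_matches(guide)
            if len(full) != group_sizes[group] or any(
                s.gene_id not in own for s in full
            ):
                raise GenerationError(
                    f"planted guide for group {group} has stray full matches"
                )
            for s in index.seed_matches(guide):
                if s.gene_id not in target_gene_ids:
                    raise GenerationError(
                        f"planted guide for group {group} has a seed-level match "
                        f"outside the target families at {s.site_id}"
                    )

    # primers occur exactly once per family copy
    for group, (fwd, rev) in primer_windows.items():
        n = group_sizes[group]
        for primer in (fwd, rev):
            count = sum(gs.sequence.count(primer) for gs in genome.values())
            if count != n:
                raise GenerationError(f"primer for group {group} not copy-specific")

    # planted-high copies pass the expression share threshold, planted-low fail
    family_total: dict[str, float] = {}
    for g in genes:
        family_total[g.family] = family_total.get(g.family, 0.0) + expression[g.gene_id]
    for g in genes:
        if g.family in ("A1", "A2", "B"):
            share_ok = expression[g.gene_id] >= config.threshold_frac * family_total[g.family]
            if (g.gene_id in planted_high) != share_ok:
                raise GenerationError("expression draw violates planted priority split")


def _build_manifest(
    result: FixtureResult, guide_windows: dict[str, list[str]], offsets: list[int]
) -> dict:
    return {
        "config": dataclasses.asdict(result.config),
        "genes": [
            {
                "gene_id": g.gene_id,
                "family": g.family,
                "chrom": g.chrom_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "pseudogene": g.pseudogene,
                "expression": result.expression[g.gene_id],
                "planted_high": g.gene_id in result.planted_high,
            }
            for g in result.genes
        ],
        "planted_guides": {
            group: [
                {"protospacer": w[:20], "pam": w[20:], "gene_offset": off}
                for w, off in zip(windows, offsets)
            ]
            for group, windows in guide_windows.items()
        },
        "planted_high": result.planted_high,
        "assays": [dataclasses.asdict(p) for p in result.primers],
    }


def generate_family(config: FixtureConfig, out_dir: str | Path | None = None) -> FixtureResult:
    """Generate a fixture; optionally write
    ``genome.fa / genes.gff3 / expression.tsv / primers.tsv /
    manifest.json`` under ``out_dir``.

    Deterministic: the same config (including seed) yields byte-identical
    outputs.  Raises GenerationError when validation keeps failing
    (e.g. divergence rates that make planting collide).
    """
    rng = np.random.default_rng(config.seed)
    last_error: Exception | None = None
    for attempt in range(config.max_attempts):
        try:
            result = _attempt(config, rng)
            break
        except GenerationError as exc:
            logger.info("fixture attempt %d rejected: %s", attempt + 1, exc)
            last_error = exc
    else:
        raise GenerationError(
            f"no valid fixture after {config.max_attempts} attempts: {last_error}"
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(result.genome, out / "genome.fa")
        write_gff3(result.genes, out / "genes.gff3")
        write_expression(result.expression, out / "expression.tsv")
        write_primers(result.primers, out / "primers.tsv")
        manifest = dict(result.manifest)
        manifest["files"] = {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in ("genome.fa", "genes.gff3", "expression.tsv", "primers.tsv")
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        result.manifest = manifest
    return result
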