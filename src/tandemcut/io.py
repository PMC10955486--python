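"""Reading and writing the external formats, plus the coordinate model.

All internal coordinates are 0-based half-open intervals on the forward
(+) strand of the reference.  GFF3's 1-based closed convention is
converted at the I/O boundary and nowhere else.

Sequences are uppercase DNA over the alphabet {A, C, G, T, N}.  ``N``
bases are legal in input but are excluded from protospacer matching
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence (chromosome or locus)."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.chrom_id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.chrom_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCopy:
    """An annotated gene-family member.

    ``start``/``end`` are a 0-based half-open genomic interval on the
    + strand; ``strand`` records the annotated transcription strand.
    ``family`` is a free-form subfamily label (e.g. ``A1``, ``B``).
    """

    gene_id: str
    family: str
    chrom_id: str
    start: int
    end: int
    strand: str
    pseudogene: bool = False
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.expression < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative expression")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Half-open membership: start inclusive, end exclusive."""
        return self.start <= pos < self.end


@dataclass(frozen=True)
class PrimerPair:
    """A genotyping assay: forward and reverse primer footprints on the
    wild-type reference plus a maximum resolvable product size."""

    assay_id: str
    chrom_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    max_product: int

    def __post_init__(self) -> None:
        if not (self.fwd_start < self.fwd_end <= self.rev_start < self.rev_end):
            raise ValueError(
                f"assay {self.assay_id!r}: forward interval must lie upstream of reverse"
            )
        if self.max_product <= 0:
            raise ValueError(f"assay {self.assay_id!r}: max_product must be positive")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a FASTA file into a map of chrom_id -> GenomeSequence.

    Sequences are uppercased; duplicate record ids and empty records are
    rejected.
    """
    path = Path(path)
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise FormatError(f"duplicate FASTA record id {record.id!r} in {path}")
        genome[record.id] = GenomeSequence(record.id, str(record.seq).upper())
    if not genome:
        raise FormatError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Mapping[str, GenomeSequence] | Mapping[str, str], path: str | Path) -> None:
    """Write sequences to FASTA (60-column wrapped)."""
    records = []
    for chrom_id, seq in genome.items():
        raw = seq.sequence if isinstance(seq, GenomeSequence) else str(seq)
        records.append(SeqRecord(Seq(raw), id=chrom_id, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(
    path: str | Path,
    genome: Mapping[str, GenomeSequence] | None = None,
    expression: Mapping[str, float] | None = None,
) -> list[GeneCopy]:
    """Parse gene-level features from a GFF3 file into GeneCopy records.

    Only ``gene`` features are consumed.  Required attributes: ``ID`` and
    ``family``; optional ``pseudogene=true|false`` (default false).  GFF3
    1-based closed coordinates become 0-based half-open internally.

    When ``genome`` is given, features on unknown chromosomes or outside
    their chromosome raise a FormatError.  When ``expression`` is given,
    abundances are joined onto the records (absent genes default to 0
    with a warning).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    copies: list[GeneCopy] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        attrs = feat.attributes
        if "ID" not in attrs or not attrs["ID"]:
            raise FormatError(f"gene feature at {feat.seqid}:{feat.start} lacks ID")
        if "family" not in attrs or not attrs["family"]:
            raise FormatError(f"gene {attrs['ID'][0]!r} lacks required 'family' attribute")
        gene_id = attrs["ID"][0]
        if gene_id in seen:
            raise FormatError(f"duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        pseudo = attrs.get("pseudogene", ["false"])[0].lower() in ("true", "1", "yes")
        start0 = feat.start - 1  # 1-based closed -> 0-based half-open
        end0 = feat.end
        if genome is not None:
            if feat.seqid not in genome:
                raise FormatError(
                    f"gene {gene_id!r} lies on unknown chromosome {feat.seqid!r}"
                )
            if end0 > len(genome[feat.seqid]):
                raise FormatError(
                    f"gene {gene_id!r} extends past the end of {feat.seqid!r}"
                )
        expr = 0.0
        if expression is not None:
            if gene_id in expression:
                expr = expression[gene_id]
            else:
                logger.warning("gene %s absent from expression table; defaulting to 0", gene_id)
        copies.append(
            GeneCopy(
                gene_id=gene_id,
                family=attrs["family"][0],
                chrom_id=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                pseudogene=pseudo,
                expression=expr,
            )
        )
    return copies


def write_gff3(copies: Iterable[GeneCopy], path: str | Path) -> None:
    """Write GeneCopy records as gene features (internal half-open
    coordinates converted back to GFF3 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in copies:
            attrs = (
                f"ID={g.gene_id};family={g.family};"
                f"pseudogene={'true' if g.pseudogene else 'false'}"
            )
            fh.write(
                "\t".join(
                    [
                        g.chrom_id,
                        "tandemcut",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Tab-separated tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> dict[str, float]:
    """Read a two-column ``gene_id<TAB>abundance`` table (with header).

    Abundances must be non-negative numbers.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"expression table {path} needs two tab-separated columns")
    ids = df.iloc[:, 0].astype(str)
    values = pd.to_numeric(df.iloc[:, 1], errors="raise").astype(float)
    if (values < 0).any():
        bad = ids[values < 0].iloc[0]
        raise FormatError(f"negative abundance for gene {bad!r}")
    return dict(zip(ids, values))


def write_expression(expression: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(expression), "abundance": list(expression.values())}
    ).to_csv(path, sep="\t", index=False)


_PRIMER_COLUMNS = [
    "assay_id",
    "chrom",
    "fwd_start",
    "fwd_end",
    "rev_start",
    "rev_end",
    "max_product",
]


def read_primers(path: str | Path) -> list[PrimerPair]:
    """Read primer assays from a TSV with columns
    ``assay_id, chrom, fwd_start, fwd_end, rev_start, rev_end, max_product``
    (coordinates 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PRIMER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"primer table {path} missing columns: {missing}")
    return [
        PrimerPair(
            assay_id=str(row.assay_id),
            chrom_id=str(row.chrom),
            fwd_start=int(row.fwd_start),
            fwd_end=int(row.fwd_end),
            rev_start=int(row.rev_start),
            rev_end=int(row.rev_end),
            max_product=int(row.max_product),
        )
        for row in df.itertuples()
    ]


def write_primers(primers: Iterable[PrimerPair], path: str | Path) -> None:
    rows = [
        (p.assay_id, p.chrom_id, p.fwd_start, p.fwd_end, p.rev_start, p.rev_end, p.max_product)
        for p in primers
    ]
    pd.DataFrame(rows, columns=_PRIMER_COLUMNS).to_csv(path, sep="\t", index=False)
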