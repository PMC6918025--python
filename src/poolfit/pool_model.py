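"""Domain types and I/O for barcoded insertion pools and gene annotations.

A pooled T-DNA insertional mutant library is represented as an
:class:`InsertionPool`: a set of uniquely barcoded insertions, each mapped to
a genomic position.  Gene annotations (:class:`Gene`) provide the frame for
assigning insertions to the genes they disrupt and for FPKM computation
downstream (``length_nt`` is the transcript length).

Coordinates are 1-based and inclusive throughout, matching GFF3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

BARCODE_ALPHABET = frozenset("ACGT")

_ANNOTATION_TSV_COLUMNS = [
    "gene_id", "scaffold", "start", "end", "strand", "length_nt", "description",
]
_POOL_TSV_COLUMNS = ["barcode", "scaffold", "position", "strand"]


@dataclass(frozen=True)
class Gene:
    """A gene annotation record.

    ``length_nt`` is the transcript length used for FPKM; for GFF3 input
    without an explicit length attribute it defaults to the genomic span.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    length_nt: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.length_nt < 1:
            raise ValueError(f"gene {self.gene_id}: length_nt must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, scaffold: str, position: int) -> bool:
        return scaffold == self.scaffold and self.start <= position <= self.end


@dataclass(frozen=True)
class Insertion:
    """A single barcoded T-DNA insertion at a mapped genomic position.

    ``assigned_genes`` holds the ids of all genes whose span contains the
    insertion site (empty for intergenic insertions).  Strand is recorded but
    ignored by assignment: an insertion disrupts the locus on both strands.
    """

    barcode: str
    scaffold: str
    position: int
    strand: str
    assigned_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.barcode or not set(self.barcode) <= BARCODE_ALPHABET:
            raise ValueError(f"barcode {self.barcode!r} is not over ACGT")
        if self.position < 1:
            raise ValueError(f"insertion {self.barcode}: position must be >= 1")


@dataclass
class InsertionPool:
    """A deep-sequenced pool of uniquely barcoded insertions."""

    insertions: list[Insertion] = field(default_factory=list)
    genome_name: str = ""

    def __post_init__(self) -> None:
        barcodes = [ins.barcode for ins in self.insertions]
        if len(barcodes) != len(set(barcodes)):
            seen: set[str] = set()
            dupes = sorted({b for b in barcodes if b in seen or seen.add(b)})
            raise ValueError(f"duplicate barcodes in pool: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.insertions)

    def __iter__(self):
        return iter(self.insertions)

    @property
    def barcodes(self) -> list[str]:
        return [ins.barcode for ins in self.insertions]

    def barcode_to_genes(self) -> dict[str, frozenset[str]]:
        """Map each barcode to the ids of the genes it disrupts."""
        return {ins.barcode: ins.assigned_genes for ins in self.insertions}


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_gene_annotation(path, format: str = "tsv") -> list[Gene]:
    """Read a gene annotation table from TSV or GFF3.

    TSV needs the columns gene_id, scaffold, start, end, strand, length_nt,
    description.  For GFF3, features of type ``gene`` are used; transcript
    length defaults to the genomic span unless a ``length_nt`` attribute is
    present.

    Raises ``ValueError`` for malformed rows (naming the line) and for
    duplicate gene ids.
    """
    if format == "tsv":
        genes = _read_annotation_tsv(path)
    elif format == "gff3":
        genes = _read_annotation_gff3(path)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValueError(f"duplicate gene_id in annotation: {', '.join(dupes)}")
    return genes


def _read_annotation_tsv(path) -> list[Gene]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _ANNOTATION_TSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation TSV missing columns: {', '.join(missing)}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            genes.append(
                Gene(
                    gene_id=row.gene_id,
                    scaffold=row.scaffold,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    length_nt=int(row.length_nt),
                    description=getattr(row, "description", "") or "",
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed annotation row at line {i}: {exc}") from exc
    return genes


def _read_annotation_gff3(path) -> list[Gene]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        length = feat.attributes.get("length_nt")
        desc = feat.attributes.get("description", feat.attributes.get("Name", [""]))
        genes.append(
            Gene(
                gene_id=gene_id,
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                length_nt=int(length[0]) if length else feat.end - feat.start + 1,
                description=desc[0] if desc else "",
            )
        )
    return genes


def write_gene_annotation(genes: list[Gene], path) -> None:
    df = pd.DataFrame(
        [
            (g.gene_id, g.scaffold, g.start, g.end, g.strand, g.length_nt,
             g.description)
            for g in genes
        ],
        columns=_ANNOTATION_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pool table I/O
# ---------------------------------------------------------------------------

def read_pool_table(path, genome_name: str = "") -> InsertionPool:
    """Read a barcode pool table (TSV: barcode, scaffold, position, strand).

    An optional ``assigned_genes`` column (semicolon-joined gene ids) is
    honoured; other extra columns are ignored.  Duplicate or non-ACGT
    barcodes raise ``ValueError``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return InsertionPool([], genome_name=genome_name)
    missing = [c for c in _POOL_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pool table missing columns: {', '.join(missing)}")
    insertions = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        assigned: frozenset[str] = frozenset()
        if "assigned_genes" in df.columns:
            raw = getattr(row, "assigned_genes")
            if isinstance(raw, str) and raw:
                assigned = frozenset(raw.split(";"))
        try:
            insertions.append(
                Insertion(
                    barcode=row.barcode,
                    scaffold=row.scaffold,
                    position=int(row.position),
                    strand=row.strand,
                    assigned_genes=assigned,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed pool row at line {i}: {exc}") from exc
    return InsertionPool(insertions, genome_name=genome_name)


def write_pool_table(pool: InsertionPool, path) -> None:
    df = pd.DataFrame(
        [
            (ins.barcode, ins.scaffold, ins.position, ins.strand,
             ";".join(sorted(ins.assigned_genes)))
            for ins in pool
        ],
        columns=_POOL_TSV_COLUMNS + ["assigned_genes"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Insertion -> gene assignment
# ---------------------------------------------------------------------------

def assign_insertions(
    pool: InsertionPool,
    genes: list[Gene],
    central_fraction: float | None = None,
) -> InsertionPool:
    """Assign each insertion to every gene whose span contains its position.

    Containment is over the full annotated gene span by default.  If
    ``central_fraction`` is given (e.g. 0.8), only insertions within the
    central fraction of the span are assigned — an option for libraries where
    insertions near gene ends may not disrupt function.  Insertions may hit
    overlapping genes and are then assigned to all of them; intergenic
    insertions get an empty assignment.  Idempotent.
    """
    spans: list[tuple[str, int, int, str]] = []
    for g in genes:
        if central_fraction is None:
            spans.append((g.scaffold, g.start, g.end, g.gene_id))
        else:
            if not 0 < central_fraction <= 1:
                raise ValueError("central_fraction must be in (0, 1]")
            margin = (g.span * (1 - central_fraction)) / 2
            spans.append(
                (g.scaffold, g.start + margin, g.end - margin, g.gene_id)
            )

    by_scaffold: dict[str, list[tuple[float, float, str]]] = {}
    for scaffold, lo, hi, gid in spans:
        by_scaffold.setdefault(scaffold, []).append((lo, hi, gid))

    assigned = []
    n_multi = 0
    for ins in pool:
        hits = frozenset(
            gid
            for lo, hi, gid in by_scaffold.get(ins.scaffold, ())
            if lo <= ins.position <= hi
        )
        if len(hits) > 1:
            n_multi += 1
        assigned.append(replace(ins, assigned_genes=hits))
    if n_multi:
        logger.info(
            "%d insertions fall in overlapping genes and count toward each",
            n_multi,
        )
    return InsertionPool(assigned, genome_name=pool.genome_name)
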