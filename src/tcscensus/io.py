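"""Reading, validation, and writing of genome annotations and metadata.

A genome annotation here is the minimal substrate needed for a two-component
system (TCS) census: gene coordinates on contigs plus per-gene Pfam domain
assignments. Real inputs come from genome warehouses (e.g. JGI IMG exports)
as GFF3 plus delimited domain tables; synthetic inputs are written by
:mod:`tcscensus.simulate` in the same dialects.

Coordinates are 1-based inclusive (GFF3 convention). Strand is read and
carried but ignored by all downstream computations, which use gene start
points only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "DomainAssignment",
    "GenomeAnnotation",
    "GenomeMetadata",
    "AnnotationError",
    "normalize_pfam_accession",
    "read_genome_annotation",
    "write_genome_annotation",
    "read_metadata",
    "metadata_to_frame",
]

GENE_TABLE_COLUMNS = ["gene_id", "genome_id", "contig_id", "start", "end", "strand", "is_protein_coding"]
DOMAIN_TABLE_COLUMNS = ["gene_id", "pfam_accession", "domain_name"]

LIFESTYLES = frozenset({"copiotroph", "oligotroph", "ambiguous", "unknown"})
DATASETS = frozenset({"marine", "reference"})


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotation input."""


_PFAM_RE = re.compile(r"^(?:pfam|pf)?(\d+)(?:\.\d+)?$", re.IGNORECASE)


def normalize_pfam_accession(raw: str) -> str:
    """Normalize a Pfam accession to the canonical ``PF#####`` form.

    Accepts the spellings found in the wild — ``pfam02518``, ``PF02518``,
    ``PF00072.27`` (version suffix stripped), bare digits — case-insensitively,
    zero-padding the numeric part to five digits.

    Raises
    ------
    AnnotationError
        If the token has no digits or more than five significant digits.
    """
    token = str(raw).strip()
    if not token:
        raise AnnotationError("empty Pfam accession")
    m = _PFAM_RE.match(token)
    if m is None:
        raise AnnotationError(f"malformed Pfam accession: {raw!r}")
    digits = m.group(1)
    if len(digits.lstrip("0")) > 5:
        raise AnnotationError(f"Pfam accession out of range: {raw!r}")
    return f"PF{int(digits):05d}"


@dataclass(frozen=True)
class GeneRecord:
    """One gene on one contig; ``start``/``end`` are 1-based inclusive bp."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "unknown"
    is_protein_coding: bool = True

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise AnnotationError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "unknown"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainAssignment:
    """A Pfam domain assigned to a gene; accession is canonical ``PF#####``."""

    gene_id: str
    pfam_accession: str
    domain_name: str | None = None

    def __post_init__(self) -> None:
        if not re.fullmatch(r"PF\d{5}", self.pfam_accession):
            raise AnnotationError(
                f"non-canonical Pfam accession {self.pfam_accession!r}; "
                "use normalize_pfam_accession()"
            )


@dataclass
class GenomeAnnotation:
    """Genes plus domain assignments for a single genome.

    ``n_protein_coding`` (the per-100-genes normalization denominator) is
    derived from the gene list and validated on construction; every domain
    assignment must reference a known gene.
    """

    genome_id: str
    genes: list[GeneRecord]
    domains: list[DomainAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        seen: set[str] = set()
        dupes = {i for i in ids if i in seen or seen.add(i)}  # type: ignore[func-returns-value]
        if dupes:
            raise AnnotationError(f"duplicate gene_id(s) in {self.genome_id}: {sorted(dupes)}")
        unknown = sorted({d.gene_id for d in self.domains} - set(ids))
        if unknown:
            raise AnnotationError(
                f"domain assignments reference unknown gene_id(s) in {self.genome_id}: {unknown}"
            )

    @property
    def n_protein_coding(self) -> int:
        return sum(1 for g in self.genes if g.is_protein_coding)

    @property
    def contigs(self) -> list[tuple[str, int]]:
        """Contig ids with lengths inferred as the max gene end per contig."""
        ends: dict[str, int] = {}
        for g in self.genes:
            ends[g.contig_id] = max(ends.get(g.contig_id, 0), g.end)
        return sorted(ends.items())

    def domains_by_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {g.gene_id: set() for g in self.genes}
        for d in self.domains:
            out[d.gene_id].add(d.pfam_accession)
        return out


@dataclass(frozen=True)
class GenomeMetadata:
    """Taxonomy, habitat, lifestyle and dataset membership for one genome."""

    genome_id: str
    phylum: str = ""
    taxclass: str = ""
    genus: str = ""
    habitat: str = ""
    lifestyle: str = "unknown"
    dataset: str = "reference"
    genome_size_bp: int = 0

    def __post_init__(self) -> None:
        if self.lifestyle not in LIFESTYLES:
            raise AnnotationError(f"{self.genome_id}: lifestyle {self.lifestyle!r} not in {sorted(LIFESTYLES)}")
        if self.dataset not in DATASETS:
            raise AnnotationError(f"{self.genome_id}: dataset {self.dataset!r} not in {sorted(DATASETS)}")
        if self.genome_size_bp <= 0:
            raise AnnotationError(f"{self.genome_id}: genome_size_bp must be > 0")


def _coerce_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n"):
        return False
    raise AnnotationError(f"cannot interpret {value!r} as boolean")


def _genes_from_gff3(path: Path, genome_id: str) -> list[GeneRecord]:
    # gffutils in-memory db; CDS features define protein-coding genes, the
    # GFF3 ID attribute is the gene id.
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        id_spec="ID",
    )
    genes: list[GeneRecord] = []
    for ftype, coding in (("CDS", True), ("gene", True)):
        for feat in db.features_of_type(ftype):
            genes.append(
                GeneRecord(
                    gene_id=feat.id,
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=feat.strand if feat.strand in ("+", "-") else "unknown",
                    is_protein_coding=coding,
                )
            )
    # a gene feature wrapping a CDS of the same ID would duplicate; prefer CDS
    seen: set[str] = set()
    unique: list[GeneRecord] = []
    for g in genes:
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            unique.append(g)
    return unique


def _genes_from_tsv(path: Path, genome_id: str | None) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"gene_id", "contig_id", "start", "end"} - set(df.columns)
    if missing:
        raise AnnotationError(f"gene table {path}: missing column(s) {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                genome_id=str(getattr(row, "genome_id", genome_id) or genome_id or "genome"),
                contig_id=str(row.contig_id),
                start=int(row.start),
                end=int(row.end),
                strand=str(getattr(row, "strand", "unknown")),
                is_protein_coding=_coerce_bool(getattr(row, "is_protein_coding", True)),
            )
        )
    return genes


def read_genome_annotation(
    gene_table_path: str | Path,
    domain_table_path: str | Path | None = None,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read a genome annotation from a GFF3 or TSV gene table plus a TSV domain table.

    The gene-table format is inferred from the extension (``.gff``/``.gff3``
    vs anything else, treated as tab-delimited). GFF3 coordinates are taken
    as 1-based inclusive. Domain accessions are normalized to ``PF#####``.
    An absent or empty domain table yields an annotation with no TCS
    candidates, which is valid.
    """
    gene_path = Path(gene_table_path)
    if genome_id is None:
        genome_id = gene_path.stem.removesuffix(".genes")
    if gene_path.suffix.lower() in (".gff", ".gff3"):
        genes = _genes_from_gff3(gene_path, genome_id)
    else:
        genes = _genes_from_tsv(gene_path, genome_id)

    domains: list[DomainAssignment] = []
    if domain_table_path is not None:
        ddf = pd.read_csv(domain_table_path, sep="\t", comment="#", dtype=str)
        if len(ddf):
            missing = {"gene_id", "pfam_accession"} - set(ddf.columns)
            if missing:
                raise AnnotationError(f"domain table {domain_table_path}: missing column(s) {sorted(missing)}")
            for row in ddf.itertuples(index=False):
                name = getattr(row, "domain_name", None)
                domains.append(
                    DomainAssignment(
                        gene_id=str(row.gene_id),
                        pfam_accession=normalize_pfam_accession(row.pfam_accession),
                        domain_name=None if name is None or pd.isna(name) else str(name),
                    )
                )
    return GenomeAnnotation(genome_id=genome_id, genes=genes, domains=domains)


def write_genome_annotation(
    annotation: GenomeAnnotation,
    gene_table_path: str | Path,
    domain_table_path: str | Path,
) -> None:
    """Write the TSV dialect that :func:`read_genome_annotation` reads back."""
    gdf = pd.DataFrame(
        [
            (g.gene_id, g.genome_id, g.contig_id, g.start, g.end, g.strand, g.is_protein_coding)
            for g in annotation.genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    gdf.to_csv(gene_table_path, sep="\t", index=False)
    ddf = pd.DataFrame(
        [(d.gene_id, d.pfam_accession, d.domain_name or "") for d in annotation.domains],
        columns=DOMAIN_TABLE_COLUMNS,
    )
    ddf.to_csv(domain_table_path, sep="\t", index=False)


def _normalize_lifestyle(raw, genome_id: str) -> str:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return "unknown"
    s = str(raw).strip().lower()
    if s in LIFESTYLES:
        return s
    # mixed designations like "Varies/copiotroph" are ambiguous, not dropped
    if "/" in s or "varies" in s:
        return "ambiguous"
    logger.warning("genome %s: unrecognized lifestyle %r mapped to 'unknown'", genome_id, raw)
    return "unknown"


def read_metadata(metadata_table_path: str | Path) -> list[GenomeMetadata]:
    """Read the genome metadata table (TSV).

    Required columns: ``genome_id``, ``genome_size_bp``. Lifestyle strings
    are case-folded; mixed designations map to ``ambiguous``; unrecognized
    ones map to ``unknown`` with a logged warning, never silently dropped.
    """
    df = pd.read_csv(metadata_table_path, sep="\t", comment="#")
    for col in ("genome_id", "genome_size_bp"):
        if col not in df.columns:
            raise AnnotationError(f"metadata table missing required column {col!r}")
    records: list[GenomeMetadata] = []
    for row in df.itertuples(index=False):
        gid = str(row.genome_id)
        size = getattr(row, "genome_size_bp")
        if pd.isna(size):
            raise AnnotationError(f"genome {gid}: missing genome_size_bp")
        dataset = str(getattr(row, "dataset", "reference")).strip().lower()
        records.append(
            GenomeMetadata(
                genome_id=gid,
                phylum=str(getattr(row, "phylum", "") or ""),
                taxclass=str(getattr(row, "taxclass", getattr(row, "_class", "")) or ""),
                genus=str(getattr(row, "genus", "") or ""),
                habitat=str(getattr(row, "habitat", "") or ""),
                lifestyle=_normalize_lifestyle(getattr(row, "lifestyle", None), gid),
                dataset=dataset,
                genome_size_bp=int(size),
            )
        )
    return records


def metadata_to_frame(records: Sequence[GenomeMetadata] | Iterable[GenomeMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.genome_id, m.phylum, m.taxclass, m.genus, m.habitat, m.lifestyle, m.dataset, m.genome_size_bp)
            for m in records
        ],
        columns=["genome_id", "phylum", "taxclass", "genus", "habitat", "lifestyle", "dataset", "genome_size_bp"],
    )
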