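"""Core record types and file I/O shared by every pipeline stage.

Coordinates are 1-based and inclusive on both ends throughout (GenBank
convention); span arithmetic is always ``to - from + 1``.  Protein sequences
are uppercased on read and stop characters (``*``) stripped; ``X`` is allowed
and never matches any signature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneRecord",
    "ClusterInterval",
    "ClusterTable",
    "Report",
    "REPORT_SCHEMA",
    "read_genbank_cluster",
    "read_protein_fasta",
    "read_gene_table",
    "read_cluster_table",
    "write_report",
    "read_report",
    "validate_report",
    "sort_genes",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class GeneRecord:
    """One protein-coding gene: identity, translation, coordinates and role."""

    gene_id: str
    protein_seq: str
    start: int
    end: int
    strand: str = "+"
    role: str = ""

    def __post_init__(self) -> None:
        self.protein_seq = self.protein_seq.upper().replace("*", "")
        if not self.protein_seq:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        bad = set(self.protein_seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: non-amino-acid characters {sorted(bad)}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)


@dataclass(frozen=True)
class ClusterInterval:
    """One BGC row of a cluster coordinate table."""

    cluster_id: int
    product_type: str
    from_bp: int
    to_bp: int

    def __post_init__(self) -> None:
        if self.from_bp <= 0 or self.to_bp <= 0:
            raise ValueError(f"cluster {self.cluster_id}: coordinates must be positive")
        if self.from_bp > self.to_bp:
            raise ValueError(
                f"cluster {self.cluster_id}: from {self.from_bp} > to {self.to_bp}"
            )

    @property
    def span_bp(self) -> int:
        return self.to_bp - self.from_bp + 1


@dataclass
class ClusterTable:
    """An ordered cluster coordinate table tied to a genome length."""

    intervals: list[ClusterInterval]
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for iv in self.intervals:
            if iv.to_bp > self.genome_length:
                raise ValueError(
                    f"cluster {iv.cluster_id} exceeds genome length "
                    f"({iv.to_bp} > {self.genome_length})"
                )

    def __len__(self) -> int:
        return len(self.intervals)


REPORT_SCHEMA: dict[str, Any] = {
    "type": "object",
    "required": ["stage", "payload", "provenance"],
    "properties": {
        "stage": {"type": "string"},
        "payload": {"type": "object"},
        "provenance": {
            "type": "object",
            "required": ["inputs", "config_hash", "seed"],
        },
    },
}


@dataclass
class Report:
    """A JSON-serializable stage report with provenance."""

    stage: str
    payload: dict[str, Any]
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        prov = {"inputs": [], "config_hash": "", "seed": None}
        prov.update(self.provenance)
        return {"stage": self.stage, "payload": self.payload, "provenance": prov}


def validate_report(doc: Any) -> None:
    """Structural validation of a report document against :data:`REPORT_SCHEMA`.

    Raises ``ValueError`` on the first violation.
    """
    if not isinstance(doc, dict):
        raise ValueError("report document must be a JSON object")
    for key in REPORT_SCHEMA["required"]:
        if key not in doc:
            raise ValueError(f"report missing required key '{key}'")
    if not isinstance(doc["stage"], str):
        raise ValueError("report 'stage' must be a string")
    if not isinstance(doc["payload"], dict):
        raise ValueError("report 'payload' must be an object")
    prov = doc["provenance"]
    if not isinstance(prov, dict):
        raise ValueError("report 'provenance' must be an object")
    for key in REPORT_SCHEMA["properties"]["provenance"]["required"]:
        if key not in prov:
            raise ValueError(f"report provenance missing key '{key}'")


def write_report(report: Report, path: str | Path) -> None:
    """Serialize a report to canonical JSON (sorted keys, 2-space indent).

    The payload is checked for serializability *before* anything is written,
    so a failure never leaves a partial file behind.
    """
    doc = report.to_dict()
    try:
        text = json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"report payload is not JSON-serializable: {exc}") from exc
    validate_report(doc)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_report(path: str | Path) -> Report:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    validate_report(doc)
    return Report(stage=doc["stage"], payload=doc["payload"], provenance=doc["provenance"])


def sort_genes(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Total, stable gene order: ascending start, ties broken by gene_id."""
    return sorted(genes, key=lambda g: (g.start, g.gene_id))


def read_genbank_cluster(path: str | Path) -> list[GeneRecord]:
    """Read CDS features of a GenBank flat file as :class:`GeneRecord` objects.

    One record per CDS carrying a ``/translation`` qualifier; a CDS without a
    translation is skipped with a warning.  ``gene_id`` is taken from
    ``/gene``, else ``/locus_tag``, else ``CDS_<n>``.  For joined or
    minus-strand locations ``start`` is the leftmost base.  Records are
    returned ordered by ascending start coordinate.
    """
    path = Path(path)
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise ValueError(f"unparseable GenBank file {path}: {exc}") from exc
    if not seqrecords:
        raise ValueError(f"unparseable GenBank file {path}: no records found")

    genes: list[GeneRecord] = []
    n_cds = 0
    for rec in seqrecords:
        for feature in rec.features:
            if feature.type != "CDS":
                continue
            n_cds += 1
            quals = feature.qualifiers
            gene_id = (
                quals.get("gene", [None])[0]
                or quals.get("locus_tag", [None])[0]
                or f"CDS_{n_cds}"
            )
            translation = quals.get("translation", [None])[0]
            if not translation:
                warnings.warn(f"{path.name}: CDS {gene_id} lacks /translation; skipped")
                continue
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    protein_seq=translation,
                    start=int(feature.location.start) + 1,
                    end=int(feature.location.end),
                    strand="-" if feature.location.strand == -1 else "+",
                    role=quals.get("product", [""])[0],
                )
            )
    return sort_genes(genes)


def read_protein_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a protein FASTA; coordinates default to record order (1 aa = 3 bp)."""
    genes = []
    offset = 1
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        genes.append(
            GeneRecord(
                gene_id=rec.id,
                protein_seq=seq,
                start=offset,
                end=offset + 3 * len(seq) - 1,
            )
        )
        offset += 3 * len(seq) + 100
    return genes


def read_gene_table(path: str | Path, genes: list[GeneRecord]) -> list[GeneRecord]:
    """Apply a gene-order table (TSV: gene, start, end, strand[, role]) to
    FASTA-derived records, replacing their placeholder coordinates."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    by_id = {g.gene_id: g for g in genes}
    out = []
    for row in df.itertuples(index=False):
        if row.gene not in by_id:
            raise ValueError(f"gene table row '{row.gene}' has no FASTA record")
        g = by_id[row.gene]
        out.append(
            GeneRecord(
                gene_id=g.gene_id,
                protein_seq=g.protein_seq,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                role=getattr(row, "role", g.role) or g.role,
            )
        )
    return sort_genes(out)


def read_cluster_table(path: str | Path, genome_length: int) -> ClusterTable:
    """Read a TSV cluster table (header: cluster, product, from, to)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["cluster", "product", "from", "to"]
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"cluster table {path} must start with columns {required}, "
            f"got {list(df.columns[:4])}"
        )
    intervals = []
    rows = df.itertuples(index=False, name=None)
    for i, (cluster, product, from_raw, to_raw, *_) in enumerate(rows, start=2):
        try:
            cluster_id = int(cluster)
            from_bp = int(from_raw)
            to_bp = int(to_raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {i}: non-integer coordinate") from exc
        if from_bp > to_bp:
            raise ValueError(f"{path} row {i}: from {from_bp} > to {to_bp}")
        intervals.append(ClusterInterval(cluster_id, str(product), from_bp, to_bp))
    return ClusterTable(intervals=intervals, genome_length=genome_length)
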