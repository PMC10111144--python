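"""FASTA input/output, CoGenT-style header codec, sequence fingerprinting
and disease-annotation joins.

The identifier scheme used throughout is the dash-separated CoGenT-style
header::

    [proteome id]-[NCBI taxon id]-[organism tag]-[release year]-
    [proteome counter]-[domain code]-[protein counter]

e.g. ``UP000593564-00004442-Came_sine-22-000001-E-000699``.  Taxon ids are
zero-padded to 8 digits and the two counters to 6; the domain code is one of
A (Archaea), B (Bacteria) or E (Eukaryota).  Padding is regenerated on
encode and ignored on decode, so ``encode(decode(h)) == h`` for canonically
padded headers.

Disease annotations are Disease Ontology identifiers (``DOID:<digits>``)
joined onto records at the gene level: every transcript of an associated
gene receives the gene's full DOID set.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ProteinRecord",
    "CogentHeader",
    "SequenceFingerprint",
    "FastaParseError",
    "HeaderFormatError",
    "DoidValidationError",
    "read_fasta",
    "write_fasta",
    "encode_cogent_header",
    "decode_cogent_header",
    "fingerprint_sequence",
    "read_association_table",
    "annotate_with_doids",
    "extract_gene_token",
]

DOID_PATTERN = re.compile(r"^DOID:\d+$")

_GENE_TOKEN = re.compile(r"\bgene:(\S+)")
_DOID_TAG = re.compile(r"\s*DOID=(\S+(?:\s+DOID:\d+)*)\s*$")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the line."""


class HeaderFormatError(ValueError):
    """Raised when a CoGenT-style header string cannot be decoded."""


class DoidValidationError(ValueError):
    """Raised when a disease identifier does not match ``DOID:<digits>``."""


@dataclass(frozen=True)
class CogentHeader:
    """Decoded form of the seven dash-separated header fields."""

    urp_id: str
    taxon_id: int
    organism_tag: str
    release_year: int
    proteome_counter: int
    domain_code: str
    protein_counter: int

    def __post_init__(self) -> None:
        if self.domain_code not in {"A", "B", "E"}:
            raise HeaderFormatError(
                f"domain code must be A, B or E, got {self.domain_code!r}"
            )
        for name in ("taxon_id", "proteome_counter", "protein_counter"):
            if getattr(self, name) <= 0:
                raise HeaderFormatError(f"{name} must be positive")

    @property
    def proteome_id(self) -> str:
        """Proteome-resolving prefix: the first two encoded fields."""
        return f"{self.urp_id}-{self.taxon_id:08d}"


@dataclass
class ProteinRecord:
    """One protein sequence with identifier metadata and disease annotations."""

    id: str
    description: str
    sequence: str
    doids: list[str] = field(default_factory=list)
    header_meta: CogentHeader | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        seen: list[str] = []
        for doid in self.doids:
            if doid not in seen:
                seen.append(doid)
        self.doids = seen

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceFingerprint:
    """128-bit digest of a residue string; identifiers never contribute."""

    digest: str


def encode_cogent_header(header: CogentHeader) -> str:
    return (
        f"{header.urp_id}-{header.taxon_id:08d}-{header.organism_tag}-"
        f"{header.release_year:02d}-{header.proteome_counter:06d}-"
        f"{header.domain_code}-{header.protein_counter:06d}"
    )


def decode_cogent_header(header: str) -> CogentHeader:
    """Parse a dash-separated CoGenT-style header string.

    The organism tag itself must not contain dashes; the string must split
    into exactly seven fields.
    """
    parts = header.split("-")
    if len(parts) != 7:
        raise HeaderFormatError(
            f"expected 7 dash-separated fields, got {len(parts)}: {header!r}"
        )
    urp_id, taxon, organism, year, p_counter, domain, n_counter = parts
    try:
        return CogentHeader(
            urp_id=urp_id,
            taxon_id=int(taxon),
            organism_tag=organism,
            release_year=int(year),
            proteome_counter=int(p_counter),
            domain_code=domain,
            protein_counter=int(n_counter),
        )
    except ValueError as exc:
        if isinstance(exc, HeaderFormatError):
            raise
        raise HeaderFormatError(f"non-numeric field in header {header!r}") from exc


def fingerprint_sequence(sequence: str) -> SequenceFingerprint:
    """MD5 digest of the uppercased residue string.

    Matches at 100% sequence identity only: no canonicalization of
    ambiguity letters, no whitespace tolerance, no identifier input.
    """
    if not sequence:
        raise ValueError("cannot fingerprint an empty sequence")
    return SequenceFingerprint(hashlib.md5(sequence.upper().encode("ascii")).hexdigest())


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, preserving entry order.

    Sequences are uppercased and stripped of whitespace.  A ``DOID=`` tag at
    the end of the description (as written by :func:`write_fasta`) is parsed
    back into the record's ``doids`` list.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
        handle.seek(0)
        records: list[ProteinRecord] = []
        for title, seq in SimpleFastaParser(handle):
            fields = title.split(None, 1)
            rec_id = fields[0]
            description = fields[1] if len(fields) > 1 else ""
            doids: list[str] = []
            tag = _DOID_TAG.search(description)
            if tag:
                doids = tag.group(1).split()
                description = description[: tag.start()].rstrip()
            try:
                meta = decode_cogent_header(rec_id)
            except HeaderFormatError:
                meta = None
            records.append(
                ProteinRecord(
                    id=rec_id,
                    description=description,
                    sequence="".join(seq.split()).upper(),
                    doids=doids,
                    header_meta=meta,
                )
            )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA; DOIDs are appended as a ``DOID=`` tag."""
    with open(path, "w") as handle:
        for rec in records:
            desc = rec.description
            if rec.doids:
                desc = (desc + " " if desc else "") + "DOID=" + " ".join(rec.doids)
            header = f">{rec.id} {desc}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def extract_gene_token(record: ProteinRecord) -> str | None:
    """Default gene key: the ``gene:<ID>`` token of the description."""
    m = _GENE_TOKEN.search(record.description)
    return m.group(1) if m else None


def read_association_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-disease association TSV with columns gene_id, doid
    (extra columns such as disease_name are ignored)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "doid"} - set(table.columns)
    if missing:
        raise ValueError(f"association table lacks columns: {sorted(missing)}")
    return table


def annotate_with_doids(
    records: Sequence[ProteinRecord],
    associations: pd.DataFrame,
    gene_key: Callable[[ProteinRecord], str | None] = extract_gene_token,
) -> list[ProteinRecord]:
    """Attach each gene's full DOID set to every transcript of that gene.

    ``associations`` needs gene_id and doid columns; duplicated (gene, DOID)
    pairs collapse to one annotation.  Records whose gene has no association
    (or yields no gene key) get an empty list.  Sequences, identifiers and
    record order are never modified.
    """
    doids_by_gene: dict[str, list[str]] = {}
    for gene_id, doid in zip(associations["gene_id"], associations["doid"]):
        if not DOID_PATTERN.match(str(doid)):
            raise DoidValidationError(
                f"invalid disease identifier {doid!r} (expected DOID:<digits>)"
            )
        bucket = doids_by_gene.setdefault(str(gene_id), [])
        if doid not in bucket:
            bucket.append(str(doid))
    out: list[ProteinRecord] = []
    for rec in records:
        gene = gene_key(rec)
        doids = doids_by_gene.get(gene, []) if gene is not None else []
        out.append(replace(rec, doids=list(doids)))
    return out
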