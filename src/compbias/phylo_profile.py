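"""Phylogenetic profiles from tabular homology-search hit tables.

Consumes the standard 12-column tabular format (qseqid, sseqid, pident,
length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore),
filters hits by significance (E-value < 0.001 and percent identity >= 21,
with no alignment-geometry requirement), and assembles a queries-by-
proteomes hit-count matrix.  Subject identifiers are resolved to proteomes
through their CoGenT-style prefix (the first two dash-separated fields) or
through an explicit subject-to-proteome mapping.

For display-oriented downstream steps the matrix rows can be standardized
(mean 0, sample sd 1) and ordered by hierarchical clustering (Euclidean
distance, average linkage), matching the conventions of R heatmap
packages; rendering itself is out of scope — the scaled, ordered matrix is
the product.

Note on upstream searches: profiles in this pipeline are built from
searches run with composition-based statistics conditioned on sequence
properties (DIAMOND/BLAST option ``--comp-based-stats 3``), which this
package documents but never executes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

__all__ = [
    "HitRecord",
    "ProfileConfig",
    "ProfileMatrix",
    "TaxonSummary",
    "HitTableParseError",
    "ProteomeResolutionError",
    "parse_hit_table",
    "filter_significant",
    "resolve_proteome",
    "build_profile",
    "scale_rows",
    "cluster_order",
    "coverage_summary",
    "queries_hitting_subset",
]

TABULAR_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class HitTableParseError(ValueError):
    """Raised for malformed tabular hit lines; the message names the line."""


class ProteomeResolutionError(KeyError):
    """Raised when a subject id cannot be mapped to a proteome."""


@dataclass(frozen=True)
class HitRecord:
    """One line of the 12-column tabular hit format (extra columns kept)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclass(frozen=True)
class ProfileConfig:
    """Hit significance: E-value strictly below ``max_evalue`` and percent
    identity at least ``min_identity`` (the values used throughout are
    0.001 and 21)."""

    max_evalue: float = 0.001
    min_identity: float = 21.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")


@dataclass
class ProfileMatrix:
    """Queries x proteomes significant-hit counts.

    The column set is the declared proteome universe: a proteome with no
    hits is an all-zero column, never a missing one.  ``domain_codes``
    optionally carries the A/B/E taxonomic domain per proteome.
    """

    counts: pd.DataFrame
    domain_codes: dict[str, str] | None = None

    @property
    def queries(self) -> list[str]:
        return list(self.counts.index)

    @property
    def proteomes(self) -> list[str]:
        return list(self.counts.columns)

    def binary(self) -> pd.DataFrame:
        """Presence/absence view for classic profiling."""
        return (self.counts > 0).astype(int)


@dataclass
class TaxonSummary:
    """Per-query taxonomic coverage over the proteome universe."""

    table: pd.DataFrame  # n_proteomes_with_hit, coverage_fraction, n_A/B/E
    taxids: dict[str, list[int]]  # query -> NCBI taxids of hit proteomes
    n_proteomes: int

    def coverage_percent(self, query: str) -> int:
        """Coverage as an integer percent, as reported in summaries."""
        return round(100 * float(self.table.loc[query, "coverage_fraction"]))


def _parse_line(line: str, lineno: int, path: str) -> HitRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise HitTableParseError(
            f"{path}: line {lineno}: expected >=12 tab-separated columns, "
            f"got {len(fields)}"
        )
    try:
        return HitRecord(
            query_id=fields[0],
            subject_id=fields[1],
            percent_identity=float(fields[2]),
            alignment_length=int(fields[3]),
            evalue=float(fields[10]),
            bitscore=float(fields[11]),
            extra=tuple(fields[12:]),
        )
    except ValueError as exc:
        raise HitTableParseError(
            f"{path}: line {lineno}: unparseable numeric field ({exc})"
        ) from exc


def parse_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tabular hit file; scientific-notation E-values are
    accepted; blank and ``#`` comment lines are skipped."""
    path = Path(path)
    records: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            records.append(_parse_line(line, lineno, str(path)))
    return records


def filter_significant(
    hits: Iterable[HitRecord], config: ProfileConfig | None = None
) -> list[HitRecord]:
    """Keep hits with evalue < max_evalue and identity >= min_identity.

    Order-preserving and idempotent; no coverage or alignment-geometry
    condition is applied.
    """
    config = config or ProfileConfig()
    return [
        h
        for h in hits
        if h.evalue < config.max_evalue and h.percent_identity >= config.min_identity
    ]


def resolve_proteome(
    subject_id: str, mapping: Mapping[str, str] | None = None
) -> str:
    """Map a subject id to its proteome.

    With an explicit ``mapping`` the subject id is looked up directly;
    otherwise the CoGenT-style prefix (first two dash-separated fields,
    proteome accession + zero-padded taxon id) is used.
    """
    if mapping is not None:
        try:
            return mapping[subject_id]
        except KeyError:
            raise ProteomeResolutionError(
                f"subject id {subject_id!r} absent from the supplied mapping"
            ) from None
    parts = subject_id.split("-")
    if len(parts) < 2:
        raise ProteomeResolutionError(
            f"subject id {subject_id!r} is not CoGenT-style and no mapping "
            "was supplied"
        )
    return f"{parts[0]}-{parts[1]}"


def build_profile(
    hits: Iterable[HitRecord],
    queries: Sequence[str],
    proteomes: Sequence[str],
    mapping: Mapping[str, str] | None = None,
    domain_codes: Mapping[str, str] | None = None,
) -> ProfileMatrix:
    """Count significant hits per (query, proteome) over a declared universe.

    Every hit's subject must resolve to a proteome in ``proteomes``;
    queries or proteomes without hits appear as zero rows/columns.
    """
    counts = pd.DataFrame(
        0, index=list(queries), columns=list(proteomes), dtype=np.int64
    )
    proteome_set = set(proteomes)
    for hit in hits:
        proteome = resolve_proteome(hit.subject_id, mapping)
        if proteome not in proteome_set:
            raise ProteomeResolutionError(
                f"subject {hit.subject_id!r} resolves to {proteome!r}, "
                "which is outside the declared proteome universe"
            )
        if hit.query_id not in counts.index:
            raise ProteomeResolutionError(
                f"hit query {hit.query_id!r} not in the declared query list"
            )
        counts.loc[hit.query_id, proteome] += 1
    return ProfileMatrix(
        counts=counts,
        domain_codes=dict(domain_codes) if domain_codes is not None else None,
    )


def scale_rows(matrix: ProfileMatrix | pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0 and sample (n-1) sd 1.

    Constant rows (zero variance) map to all-zero rows rather than NaN,
    mirroring how heatmap row scaling degrades gracefully.
    """
    counts = matrix.counts if isinstance(matrix, ProfileMatrix) else matrix
    values = counts.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True) if values.shape[1] > 1 else np.zeros_like(means)
    centered = values - means
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sds > 0, centered / np.where(sds > 0, sds, 1.0), 0.0)
    return pd.DataFrame(scaled, index=counts.index, columns=counts.columns)


def cluster_order(matrix: pd.DataFrame, axis: str = "rows") -> list[int]:
    """Dendrogram leaf order from hierarchical agglomerative clustering
    (Euclidean distance, average linkage); deterministic for fixed input."""
    if axis not in {"rows", "columns"}:
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix.to_numpy(dtype=float)
    if axis == "columns":
        data = data.T
    n = data.shape[0]
    if n == 0:
        raise ValueError("nothing to cluster along the requested axis")
    if n == 1:
        return [0]
    tree = linkage(data, method="average", metric="euclidean")
    return [int(i) for i in leaves_list(tree)]


def coverage_summary(
    matrix: ProfileMatrix,
    taxonomy: Mapping[str, tuple[int, str]],
) -> TaxonSummary:
    """Per-query coverage of the proteome universe.

    ``taxonomy`` maps every proteome id to (NCBI taxid, domain code).
    The summary carries, per query: the number of proteomes with at least
    one significant hit, that count as a fraction of the universe, the
    per-domain breakdown, and the exportable taxid list (e.g. for
    taxonomy-cartography tools).
    """
    for proteome in matrix.proteomes:
        if proteome not in taxonomy:
            raise KeyError(f"proteome {proteome!r} missing from taxonomy map")
    presence = matrix.counts.to_numpy() > 0
    proteomes = matrix.proteomes
    n_total = len(proteomes)
    domains = np.array([taxonomy[p][1] for p in proteomes])
    taxid_arr = np.array([taxonomy[p][0] for p in proteomes])

    rows = []
    taxids: dict[str, list[int]] = {}
    for i, query in enumerate(matrix.queries):
        mask = presence[i]
        n_hit = int(mask.sum())
        rows.append(
            {
                "n_proteomes_with_hit": n_hit,
                "coverage_fraction": n_hit / n_total,
                "n_A": int((mask & (domains == "A")).sum()),
                "n_B": int((mask & (domains == "B")).sum()),
                "n_E": int((mask & (domains == "E")).sum()),
            }
        )
        taxids[query] = sorted({int(t) for t in taxid_arr[mask]})
    table = pd.DataFrame(rows, index=matrix.queries).rename_axis("query")
    return TaxonSummary(table=table, taxids=taxids, n_proteomes=n_total)


def queries_hitting_subset(
    matrix: ProfileMatrix, proteome_subset: Sequence[str]
) -> list[str]:
    """Queries with at least one significant hit inside a proteome subset.

    A single-element result identifies the "only gene with hits in this
    clade" situation used when reading clade-restricted homology.
    """
    missing = [p for p in proteome_subset if p not in set(matrix.proteomes)]
    if missing:
        raise KeyError(f"subset proteomes not in matrix: {missing}")
    sub = matrix.counts.loc[:, list(proteome_subset)]
    return [q for q in matrix.queries if int(sub.loc[q].sum()) > 0]
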