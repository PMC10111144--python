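"""Transcript filtering, disease x low-complexity contingency statistics,
amino-acid composition profiles and the disease-by-residue PCA.

The central statistic is a 2x2 chi-square test of independence between
disease association (any attached DOID) and low-complexity presence (any
detected biased region) over transcripts, with no Yates continuity
correction, and the companion enrichment fold

    (disease_lc / disease_hc) / (nondisease_lc / nondisease_hc)

i.e. the odds ratio of low-complexity presence in disease-associated
versus non-disease transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .cast_bias import STANDARD_RESIDUES, CastResult
from .sequence_io import ProteinRecord

__all__ = [
    "FilterConfig",
    "ContingencyTable2x2",
    "ChiSquareResult",
    "AAProfile",
    "DegenerateTableError",
    "filter_transcripts",
    "build_contingency",
    "chi_square_2x2",
    "enrichment_fold",
    "odds_ratio_ci",
    "aa_frequencies",
    "normalized_bias_profile",
    "build_doid_aa_matrix",
    "doid_aa_pca",
]


class DegenerateTableError(ValueError):
    """Raised when a contingency table has a zero marginal."""


@dataclass(frozen=True)
class FilterConfig:
    """Length filter: drop transcripts shorter than ``min_length`` residues
    unless they carry a disease annotation (default keeps those)."""

    min_length: int = 80
    keep_short_if_disease: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Disease association x low-complexity presence counts (transcripts).

    Row 1: non-disease, row 2: disease; column 1: low complexity (lc),
    column 2: high complexity (hc, no detectable bias).
    """

    n_nondisease_lc: int
    n_nondisease_hc: int
    n_disease_lc: int
    n_disease_hc: int

    def __post_init__(self) -> None:
        if min(self.n_nondisease_lc, self.n_nondisease_hc,
               self.n_disease_lc, self.n_disease_hc) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("grand total must be positive")

    @property
    def total(self) -> int:
        return (self.n_nondisease_lc + self.n_nondisease_hc
                + self.n_disease_lc + self.n_disease_hc)

    @property
    def lc_total(self) -> int:
        return self.n_nondisease_lc + self.n_disease_lc

    @property
    def hc_total(self) -> int:
        return self.n_nondisease_hc + self.n_disease_hc

    @property
    def disease_total(self) -> int:
        return self.n_disease_lc + self.n_disease_hc

    @property
    def nondisease_total(self) -> int:
        return self.n_nondisease_lc + self.n_nondisease_hc

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.n_nondisease_lc, self.n_nondisease_hc],
             [self.n_disease_lc, self.n_disease_hc]],
            dtype=np.int64,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.as_array(),
            index=["non_disease", "disease"],
            columns=["low_complexity", "high_complexity"],
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float


@dataclass(frozen=True)
class AAProfile:
    """Per-residue biased-region score totals, background frequencies and
    the frequency-normalized profile (total_score / frequency)."""

    total_score: dict[str, int]
    frequency: dict[str, float]
    normalized_score: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total_score": pd.Series(self.total_score),
                "frequency": pd.Series(self.frequency),
                "normalized_score": pd.Series(self.normalized_score),
            }
        ).rename_axis("residue")


def filter_transcripts(
    records: Sequence[ProteinRecord], config: FilterConfig | None = None
) -> list[ProteinRecord]:
    """Apply the short-transcript noise filter, order-preserving.

    A record is kept iff it is at least ``min_length`` residues long, or it
    carries at least one DOID and ``keep_short_if_disease`` is set.
    """
    config = config or FilterConfig()
    return [
        rec
        for rec in records
        if len(rec) >= config.min_length
        or (config.keep_short_if_disease and rec.doids)
    ]


def build_contingency(
    records: Sequence[ProteinRecord], lc_flags: Mapping[str, bool]
) -> ContingencyTable2x2:
    """Count each record once by (disease association) x (low complexity)."""
    cells = [[0, 0], [0, 0]]
    for rec in records:
        if rec.id not in lc_flags:
            raise KeyError(f"no low-complexity flag for record {rec.id!r}")
        disease = 1 if rec.doids else 0
        lc = 0 if lc_flags[rec.id] else 1  # column 0 = lc, column 1 = hc
        cells[disease][lc] += 1
    return ContingencyTable2x2(
        n_nondisease_lc=cells[0][0],
        n_nondisease_hc=cells[0][1],
        n_disease_lc=cells[1][0],
        n_disease_hc=cells[1][1],
    )


def chi_square_2x2(
    table: ContingencyTable2x2, alpha: float = 0.01
) -> ChiSquareResult:
    """Pearson chi-square test of independence, df=1, no continuity
    correction; significance compared against ``alpha`` (default 0.01)."""
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise DegenerateTableError("table has a zero marginal")
    res = stats.chi2_contingency(arr, correction=False)
    p = float(res.pvalue)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )


def enrichment_fold(table: ContingencyTable2x2) -> float:
    """Odds ratio of low-complexity presence, disease vs non-disease."""
    if table.n_disease_hc == 0 or table.n_nondisease_hc == 0:
        raise ValueError("zero high-complexity count: fold undefined")
    if table.n_nondisease_lc == 0:
        raise ValueError("zero non-disease low-complexity count: fold undefined")
    return (table.n_disease_lc / table.n_disease_hc) / (
        table.n_nondisease_lc / table.n_nondisease_hc
    )


def odds_ratio_ci(
    table: ContingencyTable2x2, confidence: float = 0.95
) -> tuple[float, float]:
    """Wald confidence interval for the odds ratio on the log scale."""
    a, b = table.n_disease_lc, table.n_disease_hc
    c, d = table.n_nondisease_lc, table.n_nondisease_hc
    if min(a, b, c, d) == 0:
        raise ValueError("all four cells must be positive for a Wald CI")
    log_or = np.log(enrichment_fold(table))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def aa_frequencies(records: Sequence[ProteinRecord]) -> dict[str, float]:
    """Pooled frequencies of the 20 standard residues over the corpus.

    Ambiguity letters (B, Z, X, U, O) are excluded from both numerator and
    denominator; the returned fractions sum to 1.
    """
    counts = {r: 0 for r in STANDARD_RESIDUES}
    for rec in records:
        for ch in rec.sequence:
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("corpus contains no standard residues")
    return {r: c / total for r, c in counts.items()}


def normalized_bias_profile(
    total_scores: Mapping[str, int], frequencies: Mapping[str, float]
) -> AAProfile:
    """Per-residue profile normalized by background composition
    (total_score / frequency); residues with score 0 map to 0."""
    totals = {r: int(total_scores.get(r, 0)) for r in STANDARD_RESIDUES}
    freqs = {r: float(frequencies.get(r, 0.0)) for r in STANDARD_RESIDUES}
    normalized: dict[str, float] = {}
    for r in STANDARD_RESIDUES:
        if totals[r] == 0:
            normalized[r] = 0.0
        elif freqs[r] <= 0:
            raise ValueError(f"residue {r} has positive score but zero frequency")
        else:
            normalized[r] = totals[r] / freqs[r]
    return AAProfile(total_score=totals, frequency=freqs, normalized_score=normalized)


def build_doid_aa_matrix(
    records: Sequence[ProteinRecord], results: Iterable[CastResult]
) -> pd.DataFrame:
    """Disease-by-residue score matrix.

    Cell (DOID, residue) is the sum of biased-region scores with that bias
    residue over all transcripts annotated with that DOID; a row appears
    only when its DOID annotates at least one biased transcript.
    """
    by_id = {rec.id: rec for rec in records}
    cells: dict[str, dict[str, float]] = {}
    for result in results:
        rec = by_id.get(result.record_id)
        if rec is None or not rec.doids or not result.regions:
            continue
        for doid in rec.doids:
            row = cells.setdefault(doid, {r: 0.0 for r in STANDARD_RESIDUES})
            for residue, score in result.total_score_by_residue.items():
                row[residue] += score
    matrix = pd.DataFrame.from_dict(cells, orient="index").reindex(
        columns=list(STANDARD_RESIDUES), fill_value=0.0
    )
    return matrix.sort_index().rename_axis("doid")


def doid_aa_pca(
    records: Sequence[ProteinRecord],
    results: Iterable[CastResult],
    n_components: int = 2,
    residues_as_observations: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the disease-by-residue score matrix.

    Rows (observations) are DOIDs by default; set
    ``residues_as_observations`` to transpose.  Columns are mean-centered
    but not variance-scaled, preserving score magnitudes.  Returns the
    matrix, the component loadings (components x features) and the
    explained-variance fractions.
    """
    matrix = build_doid_aa_matrix(records, results)
    if matrix.shape[0] < 2:
        raise DegenerateTableError(
            "need at least 2 disease identifiers with biased transcripts"
        )
    data = matrix.T if residues_as_observations else matrix
    n_components = min(n_components, min(data.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(data.to_numpy())
    loadings = pd.DataFrame(
        pca.components_,
        index=[f"PC{i + 1}" for i in range(n_components)],
        columns=data.columns,
    )
    return matrix, loadings, pca.explained_variance_ratio_
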