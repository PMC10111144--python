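"""Compositional-bias detection by iterative homopolymer scoring and masking.

A query sequence is scored position-by-position against a homopolymer of
each of the 20 standard residues using an unbiased substitution matrix
(BLOSUM62 by default); aligning to a homopolymer reduces to a per-position
matrix lookup.  The maximal-sum contiguous segment of each profile is the
candidate biased region for that residue type.  In each pass the
best-scoring candidate at or above the threshold (default 40) is reported,
every occurrence of its bias residue inside the segment is masked with X,
and detection repeats on the masked sequence until no residue type reaches
the threshold.  Masking only the biased residue, not the whole segment,
lets overlapping biases of different residue types surface in later passes.

Coordinates are 1-based inclusive and refer to the original sequence
(masking preserves length, so positions are stable across passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import substitution_matrices

from .sequence_io import ProteinRecord

__all__ = [
    "STANDARD_RESIDUES",
    "ScoringMatrix",
    "CastConfig",
    "BiasedRegion",
    "CastResult",
    "CastIterationError",
    "homopolymer_score_profile",
    "max_scoring_segment",
    "detect_bias",
    "mask_fasta",
    "total_scores_by_residue",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


class CastIterationError(RuntimeError):
    """Raised when the mask-and-redetect loop exceeds its safety bound."""


@dataclass(frozen=True)
class ScoringMatrix:
    """Symmetric integer substitution scores over residue pairs.

    The mask character X always scores 0 against everything so that masked
    positions can neither help nor hurt later passes; letters absent from
    the underlying matrix (U, O) also score 0.
    """

    name: str
    scores: Mapping[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        if a == "X" or b == "X":
            return 0
        return self.scores.get((a, b), 0)

    def diagonal(self, residue: str) -> int:
        return self.score(residue, residue)

    @classmethod
    def blosum62(cls) -> "ScoringMatrix":
        return _blosum62()


_BLOSUM62_CACHE: ScoringMatrix | None = None


def _blosum62() -> ScoringMatrix:
    global _BLOSUM62_CACHE
    if _BLOSUM62_CACHE is None:
        raw = substitution_matrices.load("BLOSUM62")
        scores = {
            (a, b): int(raw[a, b])
            for a in raw.alphabet
            for b in raw.alphabet
            if a != "*" and b != "*"
        }
        _BLOSUM62_CACHE = ScoringMatrix("BLOSUM62", scores)
    return _BLOSUM62_CACHE


@dataclass(frozen=True)
class CastConfig:
    """Detection parameters; the defaults reproduce CAST's published ones."""

    threshold: int = 40
    matrix: ScoringMatrix | None = None
    mask_char: str = "X"
    max_iterations: int | None = None  # default: 2 x sequence length

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if len(self.mask_char) != 1:
            raise ValueError("mask_char must be a single character")

    def resolved_matrix(self) -> ScoringMatrix:
        return self.matrix if self.matrix is not None else ScoringMatrix.blosum62()


@dataclass(frozen=True)
class BiasedRegion:
    """One detected compositionally biased tract (1-based inclusive)."""

    bias_residue: str
    start: int
    end: int
    score: int
    iteration: int


@dataclass
class CastResult:
    record_id: str
    regions: list[BiasedRegion]
    masked_sequence: str
    total_score_by_residue: dict[str, int] = field(default_factory=dict)

    @property
    def has_bias(self) -> bool:
        return bool(self.regions)


def homopolymer_score_profile(
    sequence: str, residue: str, matrix: ScoringMatrix | None = None
) -> list[int]:
    """Per-position scores of ``sequence`` against a homopolymer of ``residue``."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if residue not in STANDARD_RESIDUES:
        raise ValueError(f"{residue!r} is not one of the 20 standard residues")
    m = matrix if matrix is not None else ScoringMatrix.blosum62()
    return [m.score(ch, residue) for ch in sequence]


def max_scoring_segment(scores: Sequence[int]) -> tuple[int, int, int] | None:
    """Maximal-sum contiguous segment of ``scores``, 1-based inclusive.

    Returns ``(start, end, score)`` or None when no segment has positive
    sum.  Ties are broken leftmost-first, then shortest: a single linear
    scan that starts each candidate at the earliest minimum of the prefix
    sums and only replaces the incumbent on a strictly larger sum yields
    exactly that segment.
    """
    if len(scores) == 0:
        raise ValueError("score list must be non-empty")
    best_sum = 0
    best: tuple[int, int, int] | None = None
    prefix = 0
    min_prefix = 0
    min_prefix_idx = 0  # earliest index attaining the minimum prefix
    for j, s in enumerate(scores, start=1):
        prefix += s
        total = prefix - min_prefix
        if total > best_sum:
            best_sum = total
            best = (min_prefix_idx + 1, j, total)
        if prefix < min_prefix:
            min_prefix = prefix
            min_prefix_idx = j
    return best


def detect_bias(sequence: str, config: CastConfig | None = None) -> CastResult:
    """Run the iterative mask-and-redetect procedure on one sequence.

    Each pass evaluates all 20 homopolymer profiles on the current
    (progressively masked) sequence and keeps the highest-scoring segment
    at or above the threshold, ties broken alphabetically by residue.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    config = config or CastConfig()
    matrix = config.resolved_matrix()
    seq = list(sequence.upper())
    limit = config.max_iterations if config.max_iterations is not None else 2 * len(seq)

    regions: list[BiasedRegion] = []
    iteration = 0
    while True:
        iteration += 1
        if iteration > limit:
            raise CastIterationError(
                f"no convergence after {limit} iterations "
                f"(threshold={config.threshold}); configuration may not terminate"
            )
        current = "".join(seq)
        best: tuple[int, str, int, int] | None = None  # (score, residue, start, end)
        for residue in STANDARD_RESIDUES:
            profile = homopolymer_score_profile(current, residue, matrix)
            seg = max_scoring_segment(profile)
            if seg is None or seg[2] < config.threshold:
                continue
            start, end, score = seg
            if best is None or score > best[0]:
                best = (score, residue, start, end)
        if best is None:
            break
        score, residue, start, end = best
        regions.append(
            BiasedRegion(
                bias_residue=residue,
                start=start,
                end=end,
                score=score,
                iteration=iteration,
            )
        )
        for i in range(start - 1, end):
            if seq[i] == residue:
                seq[i] = config.mask_char

    totals: dict[str, int] = {}
    for region in regions:
        totals[region.bias_residue] = totals.get(region.bias_residue, 0) + region.score
    return CastResult(
        record_id="",
        regions=regions,
        masked_sequence="".join(seq),
        total_score_by_residue=totals,
    )


def mask_fasta(
    records: Sequence[ProteinRecord], config: CastConfig | None = None
) -> tuple[list[tuple[ProteinRecord, CastResult]], list[ProteinRecord]]:
    """Partition records into (biased-with-result, unbiased).

    The partition is exhaustive and disjoint; every CastResult carries its
    record id.
    """
    if not records:
        raise ValueError("records must be non-empty")
    config = config or CastConfig()
    biased: list[tuple[ProteinRecord, CastResult]] = []
    clean: list[ProteinRecord] = []
    for rec in records:
        result = detect_bias(rec.sequence, config)
        result.record_id = rec.id
        if result.has_bias:
            biased.append((rec, result))
        else:
            clean.append(rec)
    return biased, clean


def total_scores_by_residue(results: Iterable[CastResult]) -> dict[str, int]:
    """Genome-wide per-residue sums of biased-region scores (0 where none)."""
    totals = {r: 0 for r in STANDARD_RESIDUES}
    for result in results:
        for residue, score in result.total_score_by_residue.items():
            totals[residue] += score
    return totals
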