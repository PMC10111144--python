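"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: segment search is
exhaustive enumeration, the iterative detection oracle re-enumerates every
residue and every contiguous segment at every pass, and the clustering
oracle is a naive agglomerative merge over explicit member lists.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_RAW = substitution_matrices.load("BLOSUM62")


def oracle_score(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return 0
    if a not in _RAW.alphabet or b not in _RAW.alphabet:
        return 0
    return int(_RAW[a, b])


def oracle_max_segment(scores) -> tuple[int, int, int] | None:
    """Exhaustive maximal positive-sum segment; ties: min start, then min
    length. 1-based inclusive coordinates."""
    best = None
    best_key = None
    n = len(scores)
    for i in range(n):
        for j in range(i, n):
            total = sum(scores[i : j + 1])
            if total <= 0:
                continue
            key = (-total, i, j - i)
            if best_key is None or key < best_key:
                best_key = key
                best = (i + 1, j + 1, total)
    return best


def oracle_detect(sequence: str, threshold: int = 40, mask_char: str = "X"):
    """Reference iterative detection: at each pass enumerate all residues
    and all contiguous segments, report the best segment at/above the
    threshold (ties alphabetical by residue), mask occurrences of the bias
    residue within it, repeat.  Returns (regions, masked_sequence) with
    regions as (residue, start, end, score, iteration) tuples."""
    seq = list(sequence.upper())
    regions = []
    iteration = 0
    while True:
        iteration += 1
        if iteration > 2 * len(seq) + 5:
            raise RuntimeError("oracle failed to terminate")
        best = None  # (-score, residue, start, end)
        for residue in _RESIDUES:
            profile = [oracle_score(ch, residue) for ch in seq]
            seg = oracle_max_segment(profile)
            if seg is None or seg[2] < threshold:
                continue
            start, end, score = seg
            key = (-score, residue)
            if best is None or key < (-best[3], best[0]):
                best = (residue, start, end, score)
        if best is None:
            break
        residue, start, end, score = best
        regions.append((residue, start, end, score, iteration))
        for i in range(start - 1, end):
            if seq[i] == residue:
                seq[i] = mask_char
    return regions, "".join(seq)


def oracle_upgma_merges(rows: np.ndarray):
    """Naive average-linkage agglomeration.

    Returns the merge history as a list of frozensets of original row
    indices (the member set of every internal cluster formed), with
    inter-cluster distance = mean pairwise Euclidean distance between
    original rows.
    """
    n = rows.shape[0]
    dist = {
        (i, j): float(np.linalg.norm(rows[i] - rows[j]))
        for i, j in itertools.combinations(range(n), 2)
    }

    def avg(c1: frozenset, c2: frozenset) -> float:
        pairs = [dist[tuple(sorted((i, j)))] for i in c1 for j in c2]
        return sum(pairs) / len(pairs)

    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = min(itertools.combinations(clusters, 2), key=lambda pair: avg(*pair))
        merged = best[0] | best[1]
        clusters = [c for c in clusters if c not in best] + [merged]
        merges.append(merged)
    return merges
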