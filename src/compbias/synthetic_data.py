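"""Synthetic corpora with controlled ground truth.

Everything the pipeline consumes can be generated here with a known answer
attached: proteomes with planted compositionally biased tracts (residue,
length, purity all controlled), gene-disease association tables with a
planted odds ratio linking tract presence to disease, and tabular homology
hit tables realizing a planted presence/count profile over named proteomes.

Defaults mirror the human-genome study conditions: tract prevalence 0.37
and baseline disease probability 0.03 (the transcript-level rates implied
by the genome-wide contingency counts), with a planted odds ratio of 1.8.
Background sequence composition is uniform over the 20 standard residues
by default; a human-like composition is available so frequency
normalization can be exercised with non-trivial weights.  These generators
emulate the statistical structure of the real data (bias prevalence,
association odds, presence/absence patterns), not its evolutionary
structure: there is no substitution model, no homology between synthetic
proteins, and no phylogenetic signal beyond the planted profile.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cast_bias import STANDARD_RESIDUES
from .disease_enrichment import ContingencyTable2x2
from .phylo_profile import TABULAR_COLUMNS
from .sequence_io import ProteinRecord

__all__ = [
    "TractSpec",
    "SyntheticSpec",
    "PlantedTract",
    "ProteinTruth",
    "SyntheticTruth",
    "SyntheticSpecError",
    "HUMAN_LIKE_COMPOSITION",
    "generate_proteome",
    "generate_disease_labels",
    "generate_hit_table",
    "balanced_background",
    "odds_to_probability",
    "simulate_association_counts",
]

# Approximate human proteome composition (fractions, UniProt statistics),
# exposed so normalization by background frequency is non-trivial.
HUMAN_LIKE_COMPOSITION = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}


class SyntheticSpecError(ValueError):
    """Raised when a synthetic specification is internally inconsistent."""


@dataclass(frozen=True)
class TractSpec:
    """One plantable biased tract: residue, length, purity (fraction of
    tract positions forced to the residue) and per-protein insertion
    probability."""

    residue: str
    length: int
    purity: float = 1.0
    probability: float = 1.0

    def __post_init__(self) -> None:
        if self.residue not in STANDARD_RESIDUES:
            raise SyntheticSpecError(f"unknown residue {self.residue!r}")
        if self.length < 1:
            raise SyntheticSpecError("tract length must be >= 1")
        if not 0 < self.purity <= 1:
            raise SyntheticSpecError("purity must be in (0, 1]")
        if not 0 <= self.probability <= 1:
            raise SyntheticSpecError("probability must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    n_proteins: int = 1000
    length_range: tuple[int, int] = (80, 400)
    tracts: tuple[TractSpec, ...] = (TractSpec("S", 14, 1.0, 0.37),)
    baseline_disease_probability: float = 0.03
    odds_ratio: float = 1.8
    composition: dict[str, float] | None = None  # None: uniform over 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SyntheticSpecError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise SyntheticSpecError("invalid length range")
        for tract in self.tracts:
            if tract.length > lo:
                raise SyntheticSpecError(
                    f"tract of length {tract.length} cannot fit in the "
                    f"shortest protein ({lo} residues)"
                )
        if not 0 <= self.baseline_disease_probability < 1:
            raise SyntheticSpecError("baseline disease probability must be in [0, 1)")
        if self.odds_ratio <= 0:
            raise SyntheticSpecError("odds ratio must be positive")


@dataclass(frozen=True)
class PlantedTract:
    residue: str
    start: int  # 1-based inclusive
    end: int
    purity: float


@dataclass
class ProteinTruth:
    protein_id: str
    tracts: list[PlantedTract] = field(default_factory=list)
    disease: bool = False
    doids: list[str] = field(default_factory=list)

    @property
    def has_tract(self) -> bool:
        return bool(self.tracts)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated corpus."""

    proteins: list[ProteinTruth] = field(default_factory=list)
    profile: "np.ndarray | None" = None  # planted (query x proteome) counts
    profile_queries: list[str] = field(default_factory=list)
    profile_proteomes: list[str] = field(default_factory=list)

    def by_id(self) -> dict[str, ProteinTruth]:
        return {p.protein_id: p for p in self.proteins}


def _composition_arrays(
    composition: dict[str, float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(STANDARD_RESIDUES))
    if composition is None:
        probs = np.full(20, 1 / 20)
    else:
        probs = np.array([composition[r] for r in STANDARD_RESIDUES], dtype=float)
        probs = probs / probs.sum()
    return letters, probs


def generate_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate protein records with planted tracts and their truth.

    Background residues are drawn i.i.d. from the spec's composition; each
    tract is inserted (with its probability) at a uniformly chosen
    position, its positions set to the tract residue with the purity
    probability (impure positions are redrawn from the background).  The
    FASTA description carries a ``gene:`` token (one synthetic gene per
    protein) so downstream annotation joins work unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    letters, probs = _composition_arrays(spec.composition)
    lo, hi = spec.length_range
    records: list[ProteinRecord] = []
    truth = SyntheticTruth()
    for i in range(spec.n_proteins):
        protein_id = f"SYN{i + 1:06d}"
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=length, p=probs)
        planted: list[PlantedTract] = []
        for tract in spec.tracts:
            if rng.random() >= tract.probability:
                continue
            start0 = int(rng.integers(0, length - tract.length + 1))
            for pos in range(start0, start0 + tract.length):
                if tract.purity >= 1.0 or rng.random() < tract.purity:
                    seq[pos] = tract.residue
                else:
                    seq[pos] = rng.choice(letters, p=probs)
            planted.append(
                PlantedTract(
                    residue=tract.residue,
                    start=start0 + 1,
                    end=start0 + tract.length,
                    purity=tract.purity,
                )
            )
        records.append(
            ProteinRecord(
                id=protein_id,
                description=f"synthetic protein gene:{protein_id}",
                sequence="".join(seq),
            )
        )
        truth.proteins.append(ProteinTruth(protein_id=protein_id, tracts=planted))
    return records, truth


def odds_to_probability(p0: float, odds_ratio: float) -> float:
    """Disease probability for tract carriers implied by the planted odds
    ratio: odds1 = odds_ratio * p0/(1-p0)."""
    if not 0 <= p0 < 1:
        raise SyntheticSpecError("baseline probability must be in [0, 1)")
    odds = odds_ratio * p0 / (1 - p0)
    p1 = odds / (1 + odds)
    if not 0 <= p1 < 1:
        raise SyntheticSpecError("implied carrier probability outside [0, 1)")
    return p1


def generate_disease_labels(
    truth: SyntheticTruth, spec: SyntheticSpec
) -> list[tuple[str, str, str]]:
    """Assign disease labels with the planted odds ratio and return
    association rows (gene_id, doid, disease_name).

    Tract-free proteins are diseased with the baseline probability p0;
    tract carriers with the probability implied by the odds ratio.  Labels
    are recorded in the truth.  Uses a seed offset so labels are
    independent of the sequence draws yet reproducible from the same spec.
    """
    rng = np.random.default_rng((spec.seed + 1) & 0x7FFFFFFF)
    p0 = spec.baseline_disease_probability
    p1 = odds_to_probability(p0, spec.odds_ratio)
    rows: list[tuple[str, str, str]] = []
    for protein in truth.proteins:
        p = p1 if protein.has_tract else p0
        protein.disease = bool(rng.random() < p)
        protein.doids = ["DOID:4"] if protein.disease else []  # DOID:4 = disease root
        if protein.disease:
            rows.append((protein.protein_id, "DOID:4", "disease"))
    return rows


def simulate_association_counts(
    n: int,
    tract_prevalence: float,
    p0: float,
    odds_ratio: float,
    rng: np.random.Generator,
) -> ContingencyTable2x2:
    """Vectorized label-only draw of the disease x low-complexity table.

    Equivalent in distribution to generating a full corpus (assuming every
    planted tract is detected and no background bias, the regime the
    planted-tract recovery property certifies) but fast enough for
    calibration studies with hundreds of replicates at n = 20000.
    """
    p1 = odds_to_probability(p0, odds_ratio)
    has_tract = rng.random(n) < tract_prevalence
    p = np.where(has_tract, p1, p0)
    disease = rng.random(n) < p
    return ContingencyTable2x2(
        n_nondisease_lc=int((has_tract & ~disease).sum()),
        n_nondisease_hc=int((~has_tract & ~disease).sum()),
        n_disease_lc=int((has_tract & disease).sum()),
        n_disease_hc=int((~has_tract & disease).sum()),
    )


def balanced_background(length: int, rng: np.random.Generator) -> str:
    """A bias-free random background: concatenated random permutations of
    the 20-residue alphabet, so no residue can locally dominate and no
    segment approaches the detection threshold."""
    blocks = []
    remaining = length
    letters = np.array(list(STANDARD_RESIDUES))
    while remaining > 0:
        perm = rng.permutation(letters)
        blocks.append("".join(perm[: min(20, remaining)]))
        remaining -= 20
    return "".join(blocks)[:length]


def generate_hit_table(
    presence: np.ndarray,
    queries: Sequence[str],
    proteomes: Sequence[str],
    seed: int = 0,
    noise_rate: float = 0.0,
    identity_range: tuple[float, float] = (25.0, 95.0),
) -> tuple[list[str], SyntheticTruth]:
    """Emit tabular hit rows realizing a planted (query x proteome) count
    matrix, plus the attached truth.

    ``presence`` holds non-negative integers: the number of significant
    hits to emit per cell, each with evalue < 0.001 and identity >= 21.
    ``noise_rate`` adds, per emitted true row, a Poisson-thinned number of
    decoy rows each failing exactly one significance filter (inflated
    E-value or sub-threshold identity) so that filtering must remove them.
    Proteome ids must be CoGenT-resolvable prefixes (``UPx-taxid``);
    subject ids extend them to full seven-field headers.
    """
    presence = np.asarray(presence)
    if presence.shape != (len(queries), len(proteomes)):
        raise SyntheticSpecError(
            f"presence matrix shape {presence.shape} does not match "
            f"{len(queries)} queries x {len(proteomes)} proteomes"
        )
    if (presence < 0).any():
        raise SyntheticSpecError("hit counts must be non-negative")
    rng = np.random.default_rng(seed)
    id_lo, id_hi = identity_range
    rows: list[str] = []

    def emit(query: str, proteome: str, counter: int, significant: bool) -> None:
        subject = f"{proteome}-Syn_org-22-000001-E-{counter:06d}"
        if significant:
            pident = float(rng.uniform(id_lo, id_hi))
            evalue = float(10 ** rng.uniform(-50, -4))  # < 1e-3 by construction
        elif rng.random() < 0.5:
            pident = float(rng.uniform(id_lo, id_hi))
            evalue = float(10 ** rng.uniform(-2, 1))  # fails the E-value filter
        else:
            pident = float(rng.uniform(5.0, 20.5))  # fails the identity filter
            evalue = float(10 ** rng.uniform(-50, -4))
        aln_len = int(rng.integers(50, 500))
        bits = float(rng.uniform(50, 800))
        fields = (
            query, subject, f"{pident:.1f}", str(aln_len), "0", "0",
            "1", str(aln_len), "1", str(aln_len),
            f"{evalue:.3e}", f"{bits:.1f}",
        )
        assert len(fields) == len(TABULAR_COLUMNS)
        rows.append("\t".join(fields))

    counter = 0
    for qi, query in enumerate(queries):
        for pi, proteome in enumerate(proteomes):
            for _ in range(int(presence[qi, pi])):
                counter += 1
                emit(query, proteome, counter, significant=True)
                for _ in range(rng.poisson(noise_rate)):
                    counter += 1
                    emit(query, proteome, counter, significant=False)

    truth = SyntheticTruth(
        profile=presence.copy(),
        profile_queries=list(queries),
        profile_proteomes=list(proteomes),
    )
    return rows, truth
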