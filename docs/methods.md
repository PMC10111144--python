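# Methods

## Detection model

A compositionally biased region is modelled as a tract whose alignment to
a homopolymer of some residue *r* scores highly under an unbiased
substitution matrix. Because the target is a homopolymer, the alignment
degenerates to a per-position lookup: position *i* of the profile for *r*
is `B62(s_i, r)`. The candidate region for *r* is the maximal-sum
contiguous segment of that profile (found in one linear pass; ties broken
leftmost-first, then shortest, so detection is deterministic). Detection
is iterative: each pass evaluates all 20 profiles on the current sequence,
reports the single best segment with score at or above the threshold
(ties between residue types broken by score, then alphabetically), masks
every occurrence of the detected residue *inside* the segment with `X`,
and repeats on the masked sequence. Masking only the biased residue — not
the whole segment — allows a second residue type biased in an overlapping
window to be reported in a later pass. Reported coordinates are 1-based
inclusive and always refer to the original sequence; masking preserves
length, so positions are stable across passes. Whether overlapping-bias
coordinates should instead refer to the progressively masked sequence is
genuinely ambiguous in the procedure's lineage; this implementation
reports original-sequence coordinates.

Parameters: threshold 40 (score units of the matrix; the value below
which single-pass reports stop), matrix BLOSUM62 (NCBI integer values via
biopython; overridable), mask character `X`. `X` is defined to score 0
against every residue — including the published BLOSUM62 `X` entries —
so masked positions are strictly neutral and can never re-trigger or
extend a detection; `B`/`Z` keep their matrix entries, `U`/`O` (absent
from BLOSUM62) score 0, and none of the ambiguity letters is eligible as
a bias residue. The safety bound on passes is 2 × sequence length; each
productive pass masks at least one residue occurrence in practice, and a
configuration that stops masking raises an explicit iteration error
rather than looping.

Termination/threshold properties (raising the threshold never adds
regions; masked length equals input length; flanks outside segments are
untouched) and full agreement with a brute-force oracle — exhaustive
enumeration of every residue type and every contiguous segment at every
pass — are asserted in the test suite over seeded random sequences.

## Enrichment statistics

The analysis unit is the transcript. Transcripts shorter than 80 residues
are removed unless they carry at least one DOID (the exemption is a
config flag). The 2×2 table crosses disease association (any DOID) with
low-complexity presence (any reported region). The test is Pearson's
chi-square with df = 1 and no continuity correction
(`scipy.stats.chi2_contingency(correction=False)`; the closed-form
`N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` identity is cross-checked numerically
in tests), significance compared to α = 0.01. The enrichment fold is the
odds ratio of low-complexity presence in disease vs non-disease
transcripts, reported unrounded (display convention: one decimal). Wald
confidence intervals on the log odds ratio support the simulation
calibration.

Per-residue profiles sum region scores by bias residue and divide by the
corpus amino-acid frequency (fractions over the 20 standard residues,
ambiguity letters excluded from numerator and denominator; the
normalization is scale-free up to a constant, so fractions vs percentages
is a documented convention, not a result-changing choice). The
disease-by-residue matrix assigns to cell (DOID, r) the summed scores of
r-biased regions over transcripts annotated with that DOID; columns are
mean-centered but not variance-scaled before PCA (singular value
decomposition via scikit-learn), preserving the score magnitudes the
profile visibly reflects. The matrix orientation (DOIDs as observations)
is the default; a flag transposes it, since either reading of the
disease–composition structure is defensible.

## Phylogenetic profiles

Hits arrive in the standard 12-column tabular format; significance is
E-value strictly below 0.001 and percent identity at least 21 (strict vs
non-strict following the stated thresholds exactly; the identity column
is used as the similarity measure — the phrase "sequence similarity" is
ambiguous between identity and similarity, and the tabular format carries
identity). No coverage or alignment-geometry condition is applied.
Subjects resolve to proteomes through the first two fields of their
CoGenT-style identifier (accession + zero-padded taxon id); an explicit
subject→proteome mapping is accepted for other naming schemes. Cells are
raw hit counts (a `binary()` view collapses to presence/absence for
classic profiling); the column universe is declared, so absence is an
explicit zero. Row scaling uses the sample (n−1) standard deviation with
constant rows mapping to zeros; ordering comes from hierarchical
agglomerative clustering with Euclidean distance and average linkage
(scipy), and tests verify that every cluster of a brute-force UPGMA
agglomeration is contiguous in the returned leaf order — leaf-flip
orientation is a library convention, cluster contiguity is the invariant.
Coverage summaries count proteomes, not species: a taxon with several
proteomes contributes each of them (the distinction matters when reading
"detected in N proteomes" statements). Upstream searches are expected to
run with composition-based statistics (`--comp-based-stats 3`); this
package consumes their output and never executes the search.

## Synthetic data

Generators are pure functions of (spec, seed) and emit ground truth
alongside every file. Proteins draw background residues i.i.d. from a
stated composition (uniform by default; a human-like table is provided so
frequency normalization is exercised with non-trivial weights) and plant
tracts of controlled residue, length, purity and insertion probability at
recorded coordinates. Disease labels follow a two-point model: baseline
probability p₀ for tract-free proteins and the probability implied by a
planted odds ratio ω for carriers, so the empirical 2×2 odds ratio
estimates ω. Defaults mirror the genome-scale study conditions: tract
prevalence 0.37 and baseline disease probability 0.03 (the
transcript-level rates implied by the published contingency marginals),
ω = 1.8. Hit tables realize a planted count matrix with significant rows
by construction and optional decoy rows that each fail exactly one
significance filter.

What the generators do **not** emulate: evolutionary structure. There is
no substitution model, no homology among synthetic proteins, no
length/composition correlation, and no phylogenetic signal beyond the
planted profile. Passing tests therefore certify the statistical
machinery (detection, counting, testing, matrix assembly) under the
stated prevalence/odds conditions — they do not certify detection
behaviour on real proteomes, where bias purity, flanking composition and
transcript redundancy differ.

A `balanced_background` helper builds bias-free backgrounds as
concatenated random permutations of the 20-letter alphabet: no residue
can locally dominate, so no segment approaches the threshold and planted
tracts sit in certifiably clean context for recovery tests.

## Calibration study sizes

The association-recovery study uses corpora of 20000 transcripts: 100
replicates for CI coverage of ω = 1.8 (coverage must reach 90/100), and
1000 replicates for the null (ω = 1) rejection rate at α = 0.01. The
larger null count is a resolution choice: with 100 replicates the
empirical rate is quantized to multiples of 0.01 and a perfectly
calibrated test lands on exactly zero rejections with probability
0.99¹⁰⁰ ≈ 0.37, making a near-nominal band uninformative; 1000 replicates
resolve rates of a few per mille. Replicates use the vectorized
label-only generator, which is distributionally equivalent to the full
corpus under certified perfect tract recovery.

## Known limitations

- Gene→transcript joins default to a `gene:` token in the FASTA
  description; real Ensembl exports may key the association on gene,
  transcript or protein identifiers, so the join key is configurable.
- The fingerprint (MD5 of the uppercase residue string) matches at 100%
  identity only; it does no cross-database reconciliation beyond digest
  equality.
- Heatmap and taxonomy-cartography rendering are out of scope; the
  scaled, cluster-ordered matrix and per-query taxid lists are the
  exported products.
- Genome-scale published counts (e.g. 38095 biased transcripts) depend on
  specific external data releases and are reproduced here only at the
  level of the printed contingency arithmetic, not by re-running the
  external searches.
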