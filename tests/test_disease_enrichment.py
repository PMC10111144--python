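"""Transcript filter, contingency statistics, composition profiles, PCA."""

import numpy as np
import pytest

from compbias.cast_bias import CastResult, detect_bias
from compbias.disease_enrichment import (
    AAProfile,
    ContingencyTable2x2,
    DegenerateTableError,
    FilterConfig,
    aa_frequencies,
    build_contingency,
    build_doid_aa_matrix,
    chi_square_2x2,
    doid_aa_pca,
    enrichment_fold,
    filter_transcripts,
    normalized_bias_profile,
    odds_ratio_ci,
)
from conftest import make_record

GENOME_TABLE = ContingencyTable2x2(36250, 62827, 1845, 1780)


class TestFilterTranscripts:
    def test_short_kept_only_with_disease(self):
        records = [
            make_record("a", "A" * 50),
            make_record("b", "A" * 79, doids=["DOID:1"]),
            make_record("c", "A" * 100),
        ]
        kept = filter_transcripts(records)
        assert [r.id for r in kept] == ["b", "c"]

    def test_all_long_is_identity(self):
        records = [make_record(f"r{i}", "A" * 90) for i in range(4)]
        assert filter_transcripts(records) == records

    def test_disease_exemption_can_be_disabled(self):
        records = [make_record("b", "A" * 79, doids=["DOID:1"])]
        config = FilterConfig(keep_short_if_disease=False)
        assert filter_transcripts(records, config) == []

    def test_never_drops_disease_records_by_default(self, rng):
        records = [
            make_record(f"r{i}", "A" * int(rng.integers(10, 200)),
                        doids=["DOID:1"] if rng.random() < 0.5 else [])
            for i in range(50)
        ]
        kept_ids = {r.id for r in filter_transcripts(records)}
        for rec in records:
            if rec.doids:
                assert rec.id in kept_ids


class TestBuildContingency:
    def test_all_four_cells(self):
        records = [
            make_record("a", "A" * 90),                     # nondisease
            make_record("b", "A" * 90),                     # nondisease
            make_record("c", "A" * 90, doids=["DOID:1"]),   # disease
            make_record("d", "A" * 90, doids=["DOID:1"]),   # disease
        ]
        flags = {"a": True, "b": False, "c": True, "d": False}
        table = build_contingency(records, flags)
        assert table.as_array().tolist() == [[1, 1], [1, 1]]

    def test_counts_conserve_records(self, rng):
        records = [
            make_record(f"r{i}", "A" * 90,
                        doids=["DOID:1"] if rng.random() < 0.3 else [])
            for i in range(40)
        ]
        flags = {r.id: bool(rng.random() < 0.5) for r in records}
        assert build_contingency(records, flags).total == 40

    def test_missing_flag_raises(self):
        records = [make_record("a", "A" * 90)]
        with pytest.raises(KeyError, match="a"):
            build_contingency(records, {})

    def test_order_invariance(self, rng):
        records = [
            make_record(f"r{i}", "A" * 90,
                        doids=["DOID:1"] if i % 3 == 0 else [])
            for i in range(30)
        ]
        flags = {r.id: i % 2 == 0 for i, r in enumerate(records)}
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert build_contingency(records, flags) == build_contingency(shuffled, flags)


class TestChiSquare:
    def test_reproduces_genome_wide_statistic(self):
        res = chi_square_2x2(GENOME_TABLE)
        assert res.statistic == pytest.approx(306.8467, abs=1e-3)
        assert res.df == 1
        assert res.p_value < 1e-5
        assert res.significant

    def test_proportional_table_scores_zero(self):
        res = chi_square_2x2(ContingencyTable2x2(10, 20, 30, 60))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 5000, size=4))
            table = ContingencyTable2x2(a, b, c, d)
            n = a + b + c + d
            closed = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            got = chi_square_2x2(table).statistic
            assert got == pytest.approx(closed, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2(ContingencyTable2x2(0, 10, 0, 10))


class TestEnrichmentFold:
    def test_reproduces_genome_wide_fold(self):
        fold = enrichment_fold(GENOME_TABLE)
        assert fold == pytest.approx(1.7964, abs=5e-4)
        assert round(fold, 1) == 1.8

    def test_proportional_table_gives_unity(self):
        assert enrichment_fold(ContingencyTable2x2(10, 20, 30, 60)) \
            == pytest.approx(1.0)

    def test_row_swap_inverts(self):
        swapped = ContingencyTable2x2(1845, 1780, 36250, 62827)
        assert enrichment_fold(swapped) == pytest.approx(
            1 / enrichment_fold(GENOME_TABLE)
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            enrichment_fold(ContingencyTable2x2(10, 20, 5, 0))

    def test_wald_ci_brackets_the_point_estimate(self):
        lo, hi = odds_ratio_ci(GENOME_TABLE)
        assert lo < enrichment_fold(GENOME_TABLE) < hi
        assert hi - lo < 0.5  # large-sample interval is tight


class TestAAFrequencies:
    def test_single_letter_corpus(self):
        freqs = aa_frequencies([make_record("a", "AAAA")])
        assert freqs["A"] == 1.0
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_uniform_pair(self):
        freqs = aa_frequencies([make_record("a", "AG")])
        assert freqs["A"] == freqs["G"] == 0.5

    def test_ambiguity_letters_excluded(self):
        freqs = aa_frequencies([make_record("a", "AXXBA")])
        assert freqs["A"] == 1.0

    def test_normalization_over_random_corpus(self, rng):
        records = [
            make_record(f"r{i}", "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=50)))
            for i in range(10)
        ]
        assert sum(aa_frequencies(records).values()) == pytest.approx(1.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            aa_frequencies([make_record("a", "XXX")])


class TestNormalizedProfile:
    def test_score_over_frequency(self):
        profile = normalized_bias_profile({"S": 100}, {"S": 0.08})
        assert profile.normalized_score["S"] == pytest.approx(1250.0)

    def test_zero_score_maps_to_zero(self):
        profile = normalized_bias_profile({}, {"S": 0.08})
        assert profile.normalized_score["S"] == 0.0

    def test_doubling_frequencies_halves_profile(self):
        scores = {"Q": 80, "S": 120}
        freqs = {"Q": 0.04, "S": 0.08}
        doubled = {r: 2 * f for r, f in freqs.items()}
        p1 = normalized_bias_profile(scores, freqs)
        p2 = normalized_bias_profile(scores, doubled)
        for r in ("Q", "S"):
            assert p2.normalized_score[r] == pytest.approx(p1.normalized_score[r] / 2)

    def test_positive_score_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            normalized_bias_profile({"W": 50}, {"W": 0.0})

    def test_frame_export_is_per_residue(self):
        frame = normalized_bias_profile({"S": 100}, {"S": 0.1}).to_frame()
        assert list(frame.columns) == ["total_score", "frequency", "normalized_score"]
        assert len(frame) == 20


def _biased_corpus():
    """Three diseases over transcripts carrying different biased tracts."""
    # flanks chosen to score negatively against each tract residue, so the
    # reported segment is exactly the planted tract
    records = [
        make_record("t1", "MKV" + "S" * 14 + "WYH", doids=["DOID:1"]),
        make_record("t2", "MKV" + "S" * 12 + "WYH", doids=["DOID:1"]),
        make_record("t3", "MKV" + "Q" * 10 + "WYH", doids=["DOID:2"]),
        make_record("t4", "MKV" + "E" * 9 + "WYH", doids=["DOID:3"]),
        make_record("t5", "ACDEFGHIKLMNPQRSTVWY", doids=["DOID:3"]),  # no bias
    ]
    results = []
    for rec in records:
        res = detect_bias(rec.sequence)
        res.record_id = rec.id
        results.append(res)
    return records, results


class TestDoidAaMatrix:
    def test_cells_sum_region_scores_per_doid(self):
        records, results = _biased_corpus()
        matrix = build_doid_aa_matrix(records, results)
        assert matrix.loc["DOID:1", "S"] == 14 * 4 + 12 * 4  # S-S diagonal = 4
        assert matrix.loc["DOID:2", "Q"] == 50
        assert matrix.loc["DOID:3", "E"] == 45  # 9 x E-E diagonal (5)
        # DOID:3 has one biased and one clean transcript: still one row
        assert set(matrix.index) == {"DOID:1", "DOID:2", "DOID:3"}

    def test_nonnegative_and_20_columns(self):
        records, results = _biased_corpus()
        matrix = build_doid_aa_matrix(records, results)
        assert matrix.shape[1] == 20
        assert (matrix.to_numpy() >= 0).all()


class TestDoidAaPCA:
    def test_rank_one_matrix_explained_by_first_component(self):
        records = [
            make_record("t1", "MKV" + "S" * 20 + "ACDEFGH", doids=["DOID:1"]),
            make_record("t2", "MKV" + "S" * 10 + "ACDEFGH", doids=["DOID:2"]),
            make_record("t3", "MKV" + "S" * 15 + "ACDEFGH", doids=["DOID:3"]),
        ]
        results = []
        for rec in records:
            res = detect_bias(rec.sequence)
            res.record_id = rec.id
            results.append(res)
        _, loadings, variance = doid_aa_pca(records, results, n_components=2)
        assert variance[0] == pytest.approx(1.0)
        assert abs(loadings.loc["PC1"]).idxmax() == "S"

    def test_agrees_with_covariance_eigendecomposition(self, rng):
        data = rng.normal(size=(5, 20)) * rng.integers(1, 10, size=20)
        records = []
        results = []
        residues = "ACDEFGHIKLMNPQRSTVWY"
        # wrap the random matrix in synthetic results: one DOID per row
        for i, row in enumerate(np.abs(data)):
            rec = make_record(f"t{i}", "A" * 90, doids=[f"DOID:{i}"])
            res = CastResult(
                record_id=rec.id,
                regions=[],
                masked_sequence=rec.sequence,
                total_score_by_residue={r: float(v) for r, v in zip(residues, row)},
            )
            # a placeholder region marks the record as biased; only the
            # per-residue totals enter the matrix
            from compbias.cast_bias import BiasedRegion
            res.regions = [BiasedRegion("A", 1, 1, 40, 1)]
            records.append(rec)
            results.append(res)
        matrix, loadings, variance = doid_aa_pca(records, results, n_components=3)
        X = matrix.to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = eigvals[order]
        eigvecs = eigvecs[:, order]
        expected_ratio = eigvals / eigvals.sum()
        assert variance == pytest.approx(expected_ratio[:3], rel=1e-8)
        for k in range(3):
            got = loadings.iloc[k].to_numpy()
            want = eigvecs[:, k]
            # eigenvectors are sign-ambiguous
            assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)

    def test_fewer_than_two_diseases_rejected(self):
        records = [make_record("t1", "S" * 90, doids=["DOID:1"])]
        res = detect_bias(records[0].sequence)
        res.record_id = "t1"
        with pytest.raises(DegenerateTableError):
            doid_aa_pca(records, [res])
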