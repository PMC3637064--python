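import io
import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enrichkit.enrich import (
    ContingencyCounts,
    LibraryIndex,
    EnrichmentTable,
    InputGeneList,
    RankBackground,
    benchmark_rank_recovery,
    calibrate_background,
    combined_score,
    enrich,
    fisher_exact_p,
    rank_by_p,
    rank_zscore,
)
from enrichkit.genesets import GeneSet, GeneSetLibrary
from enrichkit import fixtures as fx

from conftest import make_list


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Independent exact-rational oracle: P(X >= k) by direct enumeration."""
    denom = comb(N, n)
    total = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(total, denom)


class TestFisherExactP:
    def test_zero_overlap_gives_one(self):
        assert fisher_exact_p(ContingencyCounts(k=0, n=4, K=5, N=20)) == 1.0

    def test_worked_example(self):
        # N=20, K=5, n=4, k=2: oracle value frozen from exact enumeration
        expected = float(hypergeom_upper_tail(2, 4, 5, 20))
        assert expected == pytest.approx(0.24871001031991744, abs=1e-15)
        p = fisher_exact_p(ContingencyCounts(k=2, n=4, K=5, N=20))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_term_covering_universe(self):
        assert fisher_exact_p(ContingencyCounts(k=4, n=4, K=20, N=20)) == 1.0

    @pytest.mark.parametrize(
        "k,n,K,N", [(-1, 4, 5, 20), (3, 2, 5, 20), (2, 4, 25, 20), (2, 25, 5, 20)]
    )
    def test_invalid_counts_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            ContingencyCounts(k=k, n=n, K=K, N=N)

    @given(st.integers(1, 25), st.data())
    @settings(max_examples=100)
    def test_agrees_with_oracle(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        p = fisher_exact_p(ContingencyCounts(k=k, n=n, K=K, N=N))
        assert p == pytest.approx(
            float(min(hypergeom_upper_tail(k, n, K, N), 1)), abs=1e-12
        )

    @given(st.integers(2, 30), st.data())
    @settings(max_examples=50)
    def test_monotone_nonincreasing_in_k(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ps = [
            fisher_exact_p(ContingencyCounts(k=k, n=n, K=K, N=N))
            for k in range(0, min(n, K) + 1)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestCombinedScore:
    def test_p_one_gives_zero(self):
        assert combined_score(1.0, -5.0) == 0.0

    def test_z_zero_gives_zero(self):
        assert combined_score(0.3, 0.0) == 0.0

    def test_worked_example(self):
        assert combined_score(0.01, -2.0) == pytest.approx(
            math.log(0.01) * -2.0, abs=1e-12
        )

    def test_enriched_terms_score_positive(self):
        assert combined_score(1e-6, -3.0) > 0

    @pytest.mark.parametrize("p", [0.0, -0.5, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            combined_score(p, -1.0)

    def test_tiny_p_clamped_finite(self):
        assert math.isfinite(combined_score(1e-320, -2.0))


class TestRankZscore:
    def test_observed_equals_mean(self):
        assert rank_zscore(150, (150.0, 10.0)) == 0.0

    def test_worked_example(self):
        assert rank_zscore(130, (150.0, 10.0)) == pytest.approx(-2.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            rank_zscore(130, (150.0, 0.0))


class TestRankByP:
    def test_single_term_rank_one(self):
        lib = GeneSetLibrary([GeneSet(term="T", genes=frozenset({"A", "B"}))])
        out = rank_by_p(lib, make_list("A"), universe=["A", "B", "C"])
        assert out == [("T", pytest.approx(out[0][1]), 1)]

    def test_planted_term_ranks_first(self, medium_random_library):
        lib = medium_random_library
        gl = fx.planted_enrichment_list(lib, "TERM0010", 0.8, 40, seed=3)
        ranking = {t: r for t, _p, r in rank_by_p(lib, gl)}
        assert ranking["TERM0010"] == 1

    def test_identical_sets_get_adjacent_ranks_by_tie_rule(self):
        lib = GeneSetLibrary(
            [
                GeneSet(term="B_TERM", genes=frozenset({"A", "B"})),
                GeneSet(term="A_TERM", genes=frozenset({"A", "B"})),
            ]
        )
        out = dict((t, r) for t, _p, r in rank_by_p(lib, make_list("A", "B")))
        assert out["A_TERM"] == 1 and out["B_TERM"] == 2  # lexicographic tie

    def test_disjoint_input_errors(self, tiny_library):
        with pytest.raises(ValueError, match="universe"):
            rank_by_p(tiny_library, make_list("ZZZ"))

    def test_ranks_are_permutation(self, medium_random_library):
        gl = fx.random_gene_list(medium_random_library.universe, 50, seed=5)
        ranks = sorted(r for _t, _p, r in rank_by_p(medium_random_library, gl))
        assert ranks == list(range(1, len(medium_random_library) + 1))


class TestCalibrateBackground:
    def test_deterministic(self, small_random_library):
        a = calibrate_background(
            small_random_library, n_lists=50, list_lengths=[20], seed=3
        )
        b = calibrate_background(
            small_random_library, n_lists=50, list_lengths=[20], seed=3
        )
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.sd, b.sd)

    def test_single_term_library_rejected(self):
        lib = GeneSetLibrary([GeneSet(term="T", genes=frozenset({"A", "B"}))])
        with pytest.raises(ValueError):
            calibrate_background(lib, n_lists=10, list_lengths=[1])

    def test_symmetric_terms_equal_mean_ranks_up_to_tie_rule(self):
        # Two interchangeable disjoint terms. Their mean ranks are equal up
        # to the documented deterministic tie rule (lexicographic within
        # equal p), which systematically favors the lex-earlier term.
        # Independent oracle: draw overlap counts from the multivariate
        # hypergeometric and apply the same tie rule.
        lib = GeneSetLibrary(
            [
                GeneSet(term="TA", genes=frozenset(f"A{i}" for i in range(20))),
                GeneSet(term="TB", genes=frozenset(f"B{i}" for i in range(20))),
            ],
            universe=[f"A{i}" for i in range(20)] + [f"B{i}" for i in range(20)]
            + [f"C{i}" for i in range(60)],
        )
        bg = calibrate_background(lib, n_lists=2000, list_lengths=[10], seed=1)
        rng = np.random.default_rng(99)
        ks = rng.multivariate_hypergeometric([20, 20, 60], 10, size=20000)
        # equal set sizes: p ordering == overlap ordering; ties go to TA
        oracle_mean_a = float(np.mean(np.where(ks[:, 0] >= ks[:, 1], 1, 2)))
        se = 0.5 / math.sqrt(2000) + 0.5 / math.sqrt(20000)
        assert bg.mean[0][0] == pytest.approx(oracle_mean_a, abs=5 * se)
        # ranks are a permutation of {1, 2}, so the means sum to 3 exactly
        assert bg.mean[0].sum() == pytest.approx(3.0)

    def test_ten_disjoint_terms_match_exchangeable_oracle(self):
        # Ten equal-size disjoint terms: mean ranks average 5.5 exactly and
        # match an independent multivariate-hypergeometric + tie-rule oracle.
        genes = [f"G{i:03d}" for i in range(200)]
        sets = [
            GeneSet(term=f"T{j}", genes=frozenset(genes[20 * j : 20 * (j + 1)]))
            for j in range(10)
        ]
        lib = GeneSetLibrary(sets)
        bg = calibrate_background(lib, n_lists=2000, list_lengths=[30], seed=2)
        assert bg.mean[0].mean() == pytest.approx(5.5)
        rng = np.random.default_rng(98)
        ks = rng.multivariate_hypergeometric([20] * 10, 30, size=20000)
        # rank by (-k, lex index); equal sizes make p monotone in k
        oracle = np.empty_like(ks)
        lex = np.arange(10)
        ranks_1_10 = np.arange(1, 11)
        for row in range(len(ks)):
            order = np.lexsort((lex, -ks[row]))
            oracle[row, order] = ranks_1_10
        oracle_means = oracle.mean(axis=0)
        se = bg.sd[0] / math.sqrt(2000) + bg.sd[0] / math.sqrt(20000)
        assert np.all(np.abs(bg.mean[0] - oracle_means) <= 4 * se)

    def test_nearest_bin_lookup(self, small_random_library):
        bg = calibrate_background(
            small_random_library, n_lists=20, list_lengths=[10, 50], seed=3
        )
        assert bg.bins == [10, 50]
        assert bg.nearest_bin(12) == 0
        assert bg.nearest_bin(45) == 1

    def test_json_round_trip(self, small_random_library, tmp_path):
        bg = calibrate_background(
            small_random_library, n_lists=20, list_lengths=[10], seed=3
        )
        path = str(tmp_path / "bg.json")
        bg.save(path)
        back = RankBackground.load(path)
        assert back.terms == bg.terms
        assert np.array_equal(back.mean, bg.mean)
        assert np.array_equal(back.sd, bg.sd)
        assert (back.seed, back.n_simulations) == (bg.seed, bg.n_simulations)


class TestEnrich:
    @pytest.fixture
    def background(self, medium_random_library):
        return calibrate_background(
            medium_random_library, n_lists=300, list_lengths=[40], seed=9
        )

    def test_p_value_mode_needs_no_background(self, medium_random_library):
        gl = fx.random_gene_list(medium_random_library.universe, 40, seed=1)
        table = enrich(gl, medium_random_library)
        ps = [r.p_value for r in table]
        assert ps == sorted(ps)

    def test_z_mode_without_background_errors(self, medium_random_library):
        gl = fx.random_gene_list(medium_random_library.universe, 40, seed=1)
        with pytest.raises(ValueError, match="background"):
            enrich(gl, medium_random_library, sort_mode="z_score")

    def test_background_mismatch_lists_missing_terms(self, medium_random_library, background):
        other = GeneSetLibrary(
            list(medium_random_library.sets)
            + [GeneSet(term="EXTRA", genes=frozenset({"G00001"}))]
        )
        gl = fx.random_gene_list(other.universe, 40, seed=1)
        with pytest.raises(ValueError, match="EXTRA"):
            enrich(gl, other, background=background, sort_mode="z_score")

    def test_planted_term_first_under_all_modes(self, medium_random_library, background):
        gl = fx.planted_enrichment_list(medium_random_library, "TERM0005", 0.9, 40, seed=2)
        table = enrich(gl, medium_random_library, background=background)
        for mode in ("p_value", "z_score", "combined"):
            assert table.resort(mode).records[0].term == "TERM0005"

    def test_resort_conserves_records(self, medium_random_library, background):
        gl = fx.random_gene_list(medium_random_library.universe, 40, seed=4)
        table = enrich(gl, medium_random_library, background=background)
        for mode in ("p_value", "z_score", "combined"):
            assert sorted(r.term for r in table.resort(mode)) == sorted(
                r.term for r in table
            )

    def test_overlap_genes_recorded(self, tiny_library):
        table = enrich(make_list("A", "B", "C"), tiny_library)
        rec = {r.term: r for r in table}
        assert rec["S1"].overlap_genes == frozenset({"A", "B"})
        assert rec["S3"].overlap_genes == frozenset({"C"})

    def test_tsv_export_header_and_shape(self, tiny_library):
        table = enrich(make_list("A", "B"), tiny_library)
        buf = io.StringIO()
        table.to_tsv(buf)
        lines = buf.getvalue().splitlines()
        assert lines[0].split("\t") == [
            "Term", "Overlap (k/K)", "P-value", "Z-score", "Combined Score", "Genes",
        ]
        assert len(lines) == 1 + len(tiny_library)

    def test_json_round_trip(self, medium_random_library, background):
        gl = fx.random_gene_list(medium_random_library.universe, 40, seed=4)
        table = enrich(gl, medium_random_library, background=background,
                       sort_mode="combined")
        buf = io.StringIO()
        table.to_json(buf)
        buf.seek(0)
        back = EnrichmentTable.from_json(buf)
        assert back.to_dict() == table.to_dict()


class TestNullCalibrationProperty:
    def test_null_z_centered(self, medium_random_library):
        # scoring random lists against their own background: z ~ (0, 1)
        lib = medium_random_library
        L = 40
        bg = calibrate_background(lib, n_lists=800, list_lengths=[L], seed=31)
        idx = LibraryIndex(lib)
        rng = np.random.default_rng(32)
        uni = len(idx.universe)
        draws = np.array(
            [rng.choice(uni, size=L, replace=False) for _ in range(500)]
        )
        ranks = idx.rank_matrix(draws, L)
        z = (ranks - bg.mean[0][None, :]) / bg.sd[0][None, :]
        assert abs(z.mean()) < 0.1
        assert 0.8 < z.std() < 1.2


class TestBenchmark:
    def test_label_must_exist(self, medium_random_library):
        bg = calibrate_background(
            medium_random_library, n_lists=50, list_lengths=[10], seed=3
        )
        bogus = InputGeneList(
            genes=frozenset(list(medium_random_library.universe)[:10]),
            label="NOPE",
        )
        with pytest.raises(ValueError, match="NOPE"):
            benchmark_rank_recovery(medium_random_library, [bogus], bg)

    def test_identical_list_ranks_first_by_p(self, medium_random_library):
        bg = calibrate_background(
            medium_random_library, n_lists=50, list_lengths=[10], seed=3
        )
        term = "TERM0003"
        genes = medium_random_library[term].genes
        gl = InputGeneList(genes=genes, label=term)
        res = benchmark_rank_recovery(medium_random_library, [gl], bg)
        assert res.ranks["p_value"] == [1]

    def test_cumulative_histogram_monotone(self, medium_random_library):
        bg = calibrate_background(
            medium_random_library, n_lists=50, list_lengths=[40], seed=3
        )
        lists = [
            fx.planted_enrichment_list(
                medium_random_library, f"TERM{i:04d}", 0.8, 40, seed=100 + i
            )
            for i in range(1, 6)
        ]
        res = benchmark_rank_recovery(medium_random_library, lists, bg)
        ranks, cum = res.cumulative_histogram("p_value")
        assert ranks == sorted(ranks)
        assert cum == list(range(1, 6))
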