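"""Hypergeometric ORA: exact tail, BH correction, skip rule, null behaviour."""

import itertools
import math

import numpy as np
import pytest

from snpclust.enrichment import (
    GeneSet, bh_qvalues, hypergeometric_tail, read_gmt, run_grouped_ora, run_ora,
)
from snpclust.errors import ConfigurationError


def enumeration_tail(k, n, m, N):
    """Brute-force oracle: enumerate every n-subset of an N-element universe
    whose first m elements are marked, and count overlaps >= k."""
    universe = range(N)
    marked = set(range(m))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_oracle(pvals):
    """Quadratic-time step-up oracle: q_(i) = min_{j>=i} p_(j)*T/j, capped at 1."""
    T = len(pvals)
    order = sorted(range(T), key=lambda i: pvals[i])
    q = [0.0] * T
    for pos, i in enumerate(order):
        q[i] = min(min(pvals[order[r]] * T / (r + 1) for r in range(pos, T)), 1.0)
    return q


class TestHypergeometricTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_tail(0, 5, 3, 10) == 1.0

    def test_two_of_two_drawn_from_five_of_ten(self):
        # C(5,2)/C(10,2) = 10/45
        assert hypergeometric_tail(2, 2, 5, 10) == pytest.approx(10 / 45)

    def test_full_overlap_closed_form(self):
        # C(4,4)*C(16,0)/C(20,4) = 1/4845
        assert hypergeometric_tail(4, 4, 4, 20) == pytest.approx(1 / math.comb(20, 4))

    @pytest.mark.parametrize("N", [4, 7, 10])
    def test_equals_enumeration_on_small_universes(self, N):
        for m in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(0, min(m, n) + 1):
                    assert hypergeometric_tail(k, n, m, N) == pytest.approx(
                        enumeration_tail(k, n, m, N), abs=1e-12)

    def test_non_increasing_in_overlap(self):
        tails = [hypergeometric_tail(k, 10, 20, 100) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            hypergeometric_tail(5, 4, 10, 20)
        with pytest.raises(ConfigurationError):
            hypergeometric_tail(0, 30, 10, 20)


class TestBhQvalues:
    def test_single_p_unchanged(self):
        assert bh_qvalues([0.03]).tolist() == [0.03]

    def test_hand_computed_step_up(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_constant_vector_unchanged(self):
        assert bh_qvalues([0.2, 0.2, 0.2]).tolist() == pytest.approx([0.2] * 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        pvals = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40))).tolist()
        assert bh_qvalues(pvals).tolist() == pytest.approx(bh_oracle(pvals))

    def test_monotone_along_sorted_order(self):
        rng = np.random.default_rng(42)
        pvals = rng.uniform(0.001, 1, size=50)
        q = bh_qvalues(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_qvalues([0.0, 0.5])


class TestReadGmt:
    def test_duplicate_genes_collapsed(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tA\tB\tA\n")
        sets = read_gmt(path)
        assert sets[0].genes == {"A", "B"}
        assert sets[0].source_db == "desc"

    def test_short_line_skipped_with_order_preserved(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdb\tA\tB\nBAD_LINE\nS2\tdb\tC\nS3\tdb\tD\tE\n")
        names = [s.name for s in read_gmt(path)]
        assert names == ["S1", "S2", "S3"]

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("")
        assert read_gmt(path) == []


def _sets(*specs):
    return [GeneSet(name=n, source_db="db", genes=frozenset(g)) for n, g in specs]


class TestRunOra:
    def test_disjoint_query_yields_no_results(self):
        sets = _sets(("S1", "ABC"), ("S2", "DEF"))
        assert run_ora({"X", "Y"}, sets, universe=frozenset("ABCDEFXY")) == []

    def test_whole_set_query_attains_minimal_p_for_its_size(self):
        sets = _sets(("S1", "ABCD"), ("S2", "EFGH"), ("S3", "ABEF"))
        results = run_ora(set("ABCD"), sets, universe="auto")
        assert results[0].set_name == "S1"
        same_size = [r.p_value for r in results]
        assert results[0].p_value == min(same_size)

    def test_sets_below_min_overlap_are_skipped_entirely(self):
        sets = _sets(("S1", "ABX"), ("S2", "AYZ"))
        results = run_ora(set("AB"), sets, universe=frozenset("ABXYZ"), min_overlap=2)
        assert [r.set_name for r in results] == ["S1"]
        assert results[0].q_value == results[0].p_value  # family of one test

    def test_output_independent_of_set_order(self):
        sets = _sets(("S1", "ABCD"), ("S2", "ABEF"), ("S3", "CDEF"))
        a = run_ora(set("ABCD"), sets, universe="auto")
        b = run_ora(set("ABCD"), list(reversed(sets)), universe="auto")
        assert [(r.set_name, r.p_value, r.q_value) for r in a] == \
               [(r.set_name, r.p_value, r.q_value) for r in b]

    def test_integer_universe_sets_background_size(self):
        sets = _sets(("S1", "AB"))
        res = run_ora(set("AB"), sets, universe=100)
        assert res[0].N == 100
        assert res[0].p_value == pytest.approx(1 / math.comb(100, 2))

    def test_empty_intersection_with_universe_is_error(self):
        sets = _sets(("S1", "AB"))
        with pytest.raises(ConfigurationError):
            run_ora({"Z"}, sets, universe=frozenset("AB"))

    def test_type_one_error_rate_under_null(self):
        # random queries against random sets: across all sets (tested or
        # skipped), fewer than 2% should reach p < 0.01
        rng = np.random.default_rng(123)
        universe = [f"G{i}" for i in range(1000)]
        sets = [
            GeneSet(name=f"S{j}", source_db="db",
                    genes=frozenset(rng.choice(universe, size=15, replace=False)))
            for j in range(50)
        ]
        n_sets_total = 0
        n_small_p = 0
        for _ in range(1000):
            query = frozenset(rng.choice(universe, size=20, replace=False))
            results = run_ora(query, sets, universe=frozenset(universe), min_overlap=1)
            n_sets_total += len(sets)
            n_small_p += sum(r.p_value < 0.01 for r in results)
        assert n_small_p / n_sets_total <= 0.02


class TestGroupedOra:
    def test_three_labels_give_three_result_lists(self):
        sets = _sets(("S1", "ABCD"), ("S2", "EFGH"))
        out = run_grouped_ora(
            {"combined": set("ABEF"), "bc": set("AB"), "crc": set("EF")},
            sets, universe="auto")
        assert set(out) == {"combined", "bc", "crc"}

    def test_set_untested_for_sublabel_appears_only_in_combined(self):
        sets = _sets(("S1", "ABCD"), ("S2", "EFGH"))
        out = run_grouped_ora(
            {"combined": set("ABEF"), "crc": set("EFX")},
            sets, universe=frozenset("ABCDEFGHX"))
        assert "S1" in [r.set_name for r in out["combined"]]
        assert "S1" not in [r.set_name for r in out["crc"]]

    def test_identical_queries_give_identical_results(self):
        sets = _sets(("S1", "ABCD"))
        out = run_grouped_ora({"x": set("AB"), "y": set("AB")}, sets, universe="auto")
        assert [(r.set_name, r.p_value) for r in out["x"]] == \
               [(r.set_name, r.p_value) for r in out["y"]]

    def test_empty_query_label_yields_empty_list(self):
        sets = _sets(("S1", "ABCD"))
        out = run_grouped_ora({"x": set("AB"), "empty": set()}, sets, universe="auto")
        assert out["empty"] == []
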