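"""Concordant-transition statistic, Fisher test and the all-pairs screen."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevoscreen.coevolution import (
    ConcordanceTable,
    bonferroni_adjust,
    compute_transitions,
    concordance_table,
    fisher_exact_one_sided,
    screen_all_pairs,
    top_k_partners,
    transition_matrix,
)


def brute_force_fisher(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact one-sided P by enumerating all tables with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    if denom == 0:
        return Fraction(1)
    total = Fraction(0)
    for a_prime in range(min(r1, c1) + 1):
        c_prime = c1 - a_prime
        if 0 <= c_prime <= r2 and a_prime >= a:
            total += Fraction(comb(r1, a_prime) * comb(r2, c_prime), denom)
    return total


binary_profiles = st.lists(st.integers(0, 1), min_size=2, max_size=30)


class TestComputeTransitions:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ([1, 1, 1], [0, 0]),
            ([1, 0, 1, 0], [-1, 1, -1]),
            ([0, 0, 1, 1, 1, 0], [0, 1, 0, 0, -1]),
        ],
    )
    def test_signed_transitions(self, profile, expected):
        assert compute_transitions(np.array(profile)).tolist() == expected

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="non-binary"):
            compute_transitions(np.array([0, 2, 1]))

    @settings(deadline=None, derandomize=True)
    @given(binary_profiles)
    def test_nonzero_exactly_where_profile_changes(self, profile):
        trans = compute_transitions(np.array(profile))
        for i in range(len(profile) - 1):
            assert (trans[i] != 0) == (profile[i] != profile[i + 1])


class TestConcordanceTable:
    def test_identical_profiles_all_concordant(self):
        t = compute_transitions(np.array([1, 1, 0, 0, 1]))
        table = concordance_table(t, t)
        assert (table.a, table.b, table.c, table.d, table.disc) == (2, 0, 0, 2, 0)

    def test_antiphase_profiles_all_discordant(self):
        t_a = compute_transitions(np.array([1, 0, 1, 0]))
        t_b = compute_transitions(np.array([0, 1, 0, 1]))
        table = concordance_table(t_a, t_b)
        assert (table.a, table.b, table.c, table.d, table.disc) == (0, 0, 0, 0, 3)

    def test_staggered_losses_land_in_b_and_c(self):
        t_a = compute_transitions(np.array([1, 0, 0]))
        t_b = compute_transitions(np.array([1, 1, 0]))
        table = concordance_table(t_a, t_b)
        assert (table.a, table.b, table.c, table.d, table.disc) == (0, 1, 1, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            concordance_table(np.array([0, 1]), np.array([0, 1, 0]))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=2, max_size=30))
    def test_symmetry_and_partition(self, paired):
        pa, pb = zip(*paired)
        t_a = compute_transitions(np.array(pa))
        t_b = compute_transitions(np.array(pb))
        n = len(t_a)
        fwd = concordance_table(t_a, t_b)
        rev = concordance_table(t_b, t_a)
        # swapping the genes transposes b/c and leaves everything else
        assert (rev.a, rev.b, rev.c, rev.d, rev.disc) == (
            fwd.a, fwd.c, fwd.b, fwd.d, fwd.disc)
        assert fwd.n_boundaries == n  # boundaries are conserved

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ConcordanceTable(a=-1, b=0, c=0, d=0)


class TestFisherOneSided:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((2, 0, 0, 2), 1 / 6),
            ((3, 1, 1, 3), 17 / 70),
            ((0, 0, 0, 5), 1.0),  # degenerate: no transitions at all
            ((0, 0, 0, 0), 1.0),
        ],
    )
    def test_small_tables_match_enumeration(self, table, expected):
        p = fisher_exact_one_sided(ConcordanceTable(*table))
        assert p == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_a_at_fixed_margins(self):
        # shifting concordance from off-diagonal into a never raises P
        pvals = [
            fisher_exact_one_sided(ConcordanceTable(a, 5 - a, 5 - a, a))
            for a in range(6)
        ]
        assert all(p1 >= p2 for p1, p2 in zip(pvals, pvals[1:]))

    def test_matches_scipy_convention(self):
        from scipy.stats import fisher_exact

        table = ConcordanceTable(8, 2, 3, 20)
        _, p_ref = fisher_exact([[8, 2], [3, 20]], alternative="greater")
        assert fisher_exact_one_sided(table) == pytest.approx(p_ref, rel=1e-10)


class TestBonferroni:
    def test_cap_scale_and_order(self):
        assert bonferroni_adjust([0.5], 3).tolist() == [1.0]
        assert bonferroni_adjust([2e-5], 100) == pytest.approx([2e-3])
        adj = bonferroni_adjust([1e-9, 1e-2], 1000)
        assert adj == pytest.approx([1e-6, 1.0])
        assert adj[0] < adj[1]  # ranking preserved

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError, match="m"):
            bonferroni_adjust([0.5], 0)


def _matrix(rows: dict[str, list[int]]) -> pd.DataFrame:
    genomes = [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=genomes)


class TestScreenAllPairs:
    def test_constant_gene_excluded_and_m_counts_tested_pairs(self):
        mat = _matrix({
            "g1": [1, 0, 1, 0],
            "g2": [1, 0, 1, 0],
            "flat": [1, 1, 1, 1],
        })
        pairs = screen_all_pairs(mat)
        assert len(pairs) == 1  # m = 1, flat gene never enters a pair
        assert {pairs[0].gene_a, pairs[0].gene_b} == {"g1", "g2"}
        assert pairs[0].p_adj == pairs[0].p_raw

    def test_three_genes_bonferroni_times_three(self):
        mat = _matrix({
            "g1": [1, 0, 0, 1, 0],
            "g2": [1, 1, 0, 1, 0],
            "g3": [0, 1, 1, 0, 1],
        })
        pairs = screen_all_pairs(mat)
        assert len(pairs) == 3
        for p in pairs:
            assert p.p_adj == pytest.approx(min(1.0, 3 * p.p_raw))

    def test_no_significant_pairs_when_all_adjusted_one(self):
        mat = _matrix({"g1": [1, 0, 1], "g2": [0, 1, 1], "g3": [1, 1, 0]})
        pairs = screen_all_pairs(mat, alpha=0.001)
        assert not any(p.significant for p in pairs)

    def test_pairwise_counts_agree_with_per_pair_path(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(8, 25)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(25)],
        )
        trans = transition_matrix(mat)
        by_pair = {
            frozenset((p.gene_a, p.gene_b)): p for p in screen_all_pairs(mat)
        }
        for i, ga in enumerate(mat.index):
            for gb in mat.index[i + 1:]:
                ref = concordance_table(
                    trans.loc[ga].to_numpy(), trans.loc[gb].to_numpy())
                got = by_pair[frozenset((ga, gb))]
                assert got.table == ref
                assert got.p_raw == pytest.approx(
                    fisher_exact_one_sided(ref), abs=1e-14)

    def test_all_constant_matrix_rejected(self):
        mat = _matrix({"g1": [1, 1, 1], "g2": [0, 0, 0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            screen_all_pairs(mat)


class TestTopKPartners:
    def test_identical_partner_ranks_first(self):
        rng = np.random.default_rng(11)
        rows = {f"bg{i}": rng.integers(0, 2, 30).tolist() for i in range(10)}
        query = rng.integers(0, 2, 30)
        while (np.diff(query) != 0).sum() < 4:
            query = rng.integers(0, 2, 30)
        rows["query"] = query.tolist()
        rows["twin"] = query.tolist()
        ranked = top_k_partners(_matrix(rows), "query", k=3)
        assert ranked[0][0] == "twin"

    def test_k_exceeding_eligible_returns_all(self):
        mat = _matrix({"g1": [1, 0, 1], "g2": [0, 1, 0], "g3": [1, 1, 0]})
        ranked = top_k_partners(mat, "g1", k=50)
        assert len(ranked) == 2

    def test_tie_broken_lexicographically(self):
        mat = _matrix({
            "query": [1, 0, 1, 0],
            "zz": [1, 0, 1, 0],
            "aa": [1, 0, 1, 0],
        })
        ranked = top_k_partners(mat, "query", k=2)
        assert [g for g, _ in ranked] == ["aa", "zz"]

    def test_unknown_and_filtered_query_rejected(self):
        mat = _matrix({"g1": [1, 0, 1], "flat": [1, 1, 1]})
        with pytest.raises(KeyError):
            top_k_partners(mat, "nope", k=1)
        with pytest.raises(ValueError, match="filter"):
            top_k_partners(mat, "flat", k=1)
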