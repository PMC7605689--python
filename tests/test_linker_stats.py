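"""Linker statistics: exact-enumeration oracle, BH, extended network."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netboxpy import (
    AlteredGeneSet,
    adjust_pvalues,
    build_extended_network,
    find_candidate_linkers,
    linker_pvalue,
)

from conftest import net_from_edges


# ----------------------------------------------------------------------
# independent oracles


def hypergeom_tail_exact(N, A, k, x):
    """Pr(X >= x) by exact rational arithmetic on the closed form."""
    total = comb(N, k)
    hits = sum(comb(A, i) * comb(N - A, k - i) for i in range(x, min(k, A) + 1))
    return Fraction(hits, total)


def hypergeom_tail_enumeration(N, A, k, x):
    """Pr(X >= x) by enumerating all C(N, k) equally likely neighbor sets."""
    altered = set(range(A))
    hits = sum(
        1 for s in itertools.combinations(range(N), k) if sum(i in altered for i in s) >= x
    )
    return Fraction(hits, comb(N, k))


def bh_stepup(p):
    """Textbook BH step-up: p_(i) * n / i with cumulative-min from the top."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adj, 0, 1)
    return out


def random_params(rng, n_max=12):
    N = int(rng.integers(2, n_max + 1))
    A = int(rng.integers(0, N + 1))
    k = int(rng.integers(1, N + 1))
    x = int(rng.integers(0, k + 1))
    return N, A, k, x


# ----------------------------------------------------------------------
# candidate identification


class TestFindCandidates:
    def test_path_linker(self, path_alb):
        net, altered = path_alb
        assert find_candidate_linkers(net, altered) == ["L"]

    def test_altered_clique_has_no_candidates(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        altered = AlteredGeneSet.from_genes(["A", "B", "C"], net)
        assert find_candidate_linkers(net, altered) == []

    def test_star_center_is_candidate(self):
        net = net_from_edges([("C", f"l{i}") for i in range(5)])
        altered = AlteredGeneSet.from_genes(["l0", "l1", "l2"], net)
        assert find_candidate_linkers(net, altered) == ["C"]

    def test_altered_genes_never_candidates(self):
        # B is altered and neighbors altered A; it must not be tested
        net = net_from_edges([("A", "B"), ("B", "C")])
        altered = AlteredGeneSet.from_genes(["A", "B"], net)
        assert find_candidate_linkers(net, altered) == ["C"]


# ----------------------------------------------------------------------
# hypergeometric p-values


class TestLinkerPvalue:
    def test_x_zero_is_one(self):
        assert linker_pvalue(100, 30, 5, 0, mode="tail") == 1.0

    def test_hand_enumerated_case(self):
        # N=10, A=4, k=3, x=3: C(4,3)/C(10,3) = 4/120
        p = linker_pvalue(10, 4, 3, 3)
        assert p == pytest.approx(4 / 120, rel=1e-12)
        assert hypergeom_tail_enumeration(10, 4, 3, 3) == Fraction(4, 120)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            N, A, k, x = random_params(rng, n_max=10)
            expect = hypergeom_tail_enumeration(N, A, k, x)
            assert linker_pvalue(N, A, k, x) == pytest.approx(float(expect), rel=1e-12, abs=1e-300)

    def test_tail_is_sum_of_points(self, rng):
        for _ in range(50):
            N, A, k, x = random_params(rng)
            total = sum(linker_pvalue(N, A, k, i, mode="legacy_point") for i in range(x, k + 1))
            assert linker_pvalue(N, A, k, x) == pytest.approx(total, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("bad", [(5, 2, 6, 1), (5, 6, 2, 1), (5, 2, 2, 3), (5, 2, 2, -1)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            linker_pvalue(*bad)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            linker_pvalue(10, 3, 2, 1, mode="bogus")

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_x_and_N(self, data):
        """Tail p never increases with x, nor with N (growing the population
        with A and k fixed dilutes the altered genes)."""
        N = data.draw(st.integers(3, 40))
        A = data.draw(st.integers(1, N))
        k = data.draw(st.integers(1, N))
        x = data.draw(st.integers(1, k))
        p = linker_pvalue(N, A, k, x)
        if x < k:
            assert linker_pvalue(N, A, k, x + 1) <= p + 1e-15
        assert linker_pvalue(N + 1, A, k, x) <= p + 1e-15

    def test_numerically_stable_at_interactome_scale(self):
        p = linker_pvalue(100_000, 500, 50, 20)
        assert 0.0 < p < 1e-15  # far tail, still a clean positive probability


# ----------------------------------------------------------------------
# BH adjustment


class TestAdjustPvalues:
    def test_single_value_identity(self):
        assert adjust_pvalues([0.2])[0] == pytest.approx(0.2)

    def test_hand_stepup_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        assert adjust_pvalues([0.4] * 5) == pytest.approx([0.4] * 5)

    def test_matches_textbook_stepup_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert adjust_pvalues(p) == pytest.approx(bh_stepup(p), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 1.5])


# ----------------------------------------------------------------------
# extended network


class TestBuildExtendedNetwork:
    def test_path_linker_by_enumeration(self, path_alb):
        net, altered = path_alb
        ext, results = build_extended_network(net, altered, cutoff=1.0)
        (res,) = results
        assert res.gene == "L" and res.degree == 2 and res.altered_neighbors == 2
        # population N=2 (other nodes), A=2 altered, k=2, x=2 -> Pr = 1
        assert res.p_raw == pytest.approx(float(hypergeom_tail_enumeration(2, 2, 2, 2)))
        assert ext.network.nodes == {"A", "L", "B"}
        assert ext.node_role == {"A": "altered", "L": "linker", "B": "altered"}

    def test_degenerate_cutoff_accepts_every_candidate(self, planted_default):
        truth = planted_default
        ext, results = build_extended_network(truth.network, truth.altered, cutoff=1.0)
        assert all(r.accepted for r in results)
        expected = truth.altered.mapped | {r.gene for r in results}
        isolated = {n for n in expected if not any(
            nb in expected for nb in truth.network.graph.neighbors(n))}
        assert ext.network.nodes == expected - isolated

    def test_table_covers_all_candidates_sorted(self, planted_default):
        truth = planted_default
        _, results = build_extended_network(truth.network, truth.altered)
        keys = [(r.p_raw, r.gene) for r in results]
        assert keys == sorted(keys)
        assert {r.gene for r in results} == set(
            find_candidate_linkers(truth.network, truth.altered))
        for r in results:
            assert 1 <= r.altered_neighbors <= r.degree
            assert r.p_adjusted >= r.p_raw - 1e-15

    def test_disconnected_altered_pair_is_error(self):
        net = net_from_edges([("A", "B"), ("C", "D")], extra_nodes=["X", "Y"])
        altered = AlteredGeneSet.from_genes(["A", "C"], net)
        # neither altered gene connects to the other or to an accepted linker
        with pytest.raises(ValueError, match="no connected altered genes"):
            build_extended_network(net, altered, cutoff=1e-12)

    def test_isolated_altered_reported_not_kept(self):
        net = net_from_edges([("A", "B")], extra_nodes=["Z"])
        altered = AlteredGeneSet.from_genes(["A", "B", "Z"], net)
        ext, _ = build_extended_network(net, altered)
        assert "Z" not in ext.network.nodes
        assert ext.dropped_altered == ["Z"]

    def test_inclusive_cutoff_boundary(self):
        """A candidate whose adjusted p is exactly 0.05 is accepted at the default cutoff.

        Construction: hub altered gene with 19 unaltered spoke nodes plus a
        degree-1 candidate L attached to it. Population N = 20, A = 1,
        k = 1, x = 1 gives Pr(X >= 1) = 1/20 = 0.05 exactly; with a single
        candidate BH leaves it unchanged.
        """
        edges = [("ALT", f"s{i:02d}") for i in range(19)] + [("ALT", "L")]
        net = net_from_edges(edges)
        # all 20 spokes are candidates with identical p = 0.05, so BH leaves
        # every adjusted value at exactly 0.05
        altered = AlteredGeneSet.from_genes(["ALT"], net)
        _, results = build_extended_network(net, altered, cutoff=0.05)
        by_gene = {r.gene: r for r in results}
        assert by_gene["L"].p_raw == 0.05
        assert by_gene["L"].p_adjusted == 0.05
        assert by_gene["L"].accepted


def test_population_counts_isolated_nodes():
    """Adding an isolated node changes N and therefore every raw p-value."""
    edges = [("A", "L"), ("B", "L"), ("A", "B"), ("C", "D")]
    net = net_from_edges(edges)
    altered = AlteredGeneSet.from_genes(["A", "B"], net)
    _, res1 = build_extended_network(net, altered, cutoff=1.0)
    net2 = net_from_edges(edges, extra_nodes=["ISO"])
    _, res2 = build_extended_network(net2, AlteredGeneSet.from_genes(["A", "B"], net2), cutoff=1.0)
    p1 = {r.gene: r.p_raw for r in res1}
    p2 = {r.gene: r.p_raw for r in res2}
    assert set(p1) == set(p2)
    assert all(p2[g] != p1[g] for g in p1)
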