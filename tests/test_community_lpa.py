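from __future__ import annotations

from collections import Counter

import networkx as nx
import numpy as np
import pytest

from metnetcov.community_lpa import (COVERED, UNCOVERED, dark_subgraph,
                                     lpa_aggregate, lpa_single_run,
                                     pathway_enrichment, prepare_lpa_input)
from metnetcov.coverage import CoverageLabels
from _oracles import fisher_oracle, lpa_absorption


def star(n_leaves=3):
    g = nx.star_graph(n_leaves)
    initial = {0: UNCOVERED, **{i: COVERED for i in range(1, n_leaves + 1)}}
    return g, initial


def path3():
    g = nx.path_graph(3)  # a(cov) - b(unc) - c(unc)
    return g, {0: COVERED, 1: UNCOVERED, 2: UNCOVERED}


class TestSingleRun:
    def test_uniform_label_is_fixed_point(self):
        g = nx.erdos_renyi_graph(15, 0.3, seed=1)
        initial = {n: COVERED for n in g.nodes}
        assert lpa_single_run(g, initial, 0) == initial

    def test_isolated_nodes_keep_initial(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("iso")
        out = lpa_single_run(g, {"a": COVERED, "b": COVERED, "iso": UNCOVERED}, 5)
        assert out["iso"] == UNCOVERED

    def test_complete_graph_strict_majority_wins(self):
        g = nx.complete_graph(7)
        initial = {n: (COVERED if n < 5 else UNCOVERED) for n in g.nodes}
        for seed in range(10):
            out = lpa_single_run(g, initial, seed)
            assert set(out.values()) == {COVERED}

    def test_star_center_can_flip_covered(self):
        # an unmapped metabolite surrounded by mapped ones joins the
        # covered community whenever it is updated before its leaves
        g, initial = star()
        outcomes = {
            tuple(lpa_single_run(g, initial, seed).values()) for seed in range(60)
        }
        assert (COVERED,) * 4 in outcomes

    def test_path_both_outcomes_occur(self):
        g, initial = path3()
        outcomes = {
            tuple(lpa_single_run(g, initial, seed).values()) for seed in range(100)
        }
        assert (COVERED,) * 3 in outcomes and (UNCOVERED,) * 3 in outcomes


def _vote_check(graph, initial, n_runs=4000, seed=0):
    """Compare simulated final-state frequencies with the exact absorption
    distribution of the sweep Markov chain, within 3 binomial SEs."""
    adj = {n: set(graph.neighbors(n)) for n in graph.nodes}
    init01 = {n: (1 if initial[n] == COVERED else 0) for n in graph.nodes}
    exact = lpa_absorption(adj, init01)
    res = lpa_aggregate(graph, initial, n_runs=n_runs, master_seed=seed,
                        keep_per_run=True)
    nodes = sorted(graph.nodes)
    counts = Counter(
        tuple(1 if run[n] == COVERED else 0 for n in nodes)
        for run in res.per_run_labels
    )
    for state, p in exact.items():
        observed = counts.get(state, 0) / n_runs
        se = np.sqrt(max(p * (1 - p), 1e-9) / n_runs)
        assert abs(observed - p) <= 3 * se + 1e-12, (state, observed, p)
    # no mass outside the exact support
    assert sum(counts.values()) == n_runs
    assert set(counts) <= set(exact)
    return exact, res


class TestAgainstEnumeration:
    def test_star_matches_markov_oracle(self):
        g, initial = star()
        exact, _ = _vote_check(g, initial)
        # exactly half of the update orders let the center flip first
        assert exact[(1, 1, 1, 1)] == pytest.approx(0.5, abs=1e-9)

    def test_path_matches_markov_oracle(self):
        g, initial = path3()
        exact, res = _vote_check(g, initial)
        assert 0.0 < res.vote_fraction[0] < 1.0  # node a: both fates occur


class TestAggregate:
    def test_reproducible(self):
        g = nx.erdos_renyi_graph(25, 0.15, seed=2)
        initial = {n: (COVERED if n % 3 else UNCOVERED) for n in g.nodes}
        r1 = lpa_aggregate(g, initial, n_runs=40, master_seed=9)
        r2 = lpa_aggregate(g, initial, n_runs=40, master_seed=9)
        assert r1.aggregate == r2.aggregate
        assert r1.vote_fraction == r2.vote_fraction

    def test_deterministic_instance_equals_single_run(self):
        # two triangles with unanimous labels never tie
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        initial = {n: (COVERED if n < 3 else UNCOVERED) for n in g.nodes}
        res = lpa_aggregate(g, initial, n_runs=11, master_seed=4)
        assert res.aggregate == lpa_single_run(g, initial, 123)
        assert set(res.vote_fraction.values()) <= {0.0, 1.0}

    def test_dark_subgraph_partition(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        initial = {n: (COVERED if n < 3 else UNCOVERED) for n in g.nodes}
        res = lpa_aggregate(g, initial, n_runs=25, master_seed=0)
        sub, comps, frac = dark_subgraph(res, g)
        assert set(sub.nodes) == res.dark_nodes == {3, 4, 5}
        assert comps == [{3, 4, 5}]
        assert frac == pytest.approx(0.5)

    def test_no_dark_nodes_empty_subgraph(self):
        g = nx.path_graph(4)
        initial = {n: COVERED for n in g.nodes}
        res = lpa_aggregate(g, initial, n_runs=5, master_seed=0)
        sub, comps, frac = dark_subgraph(res, g)
        assert sub.number_of_nodes() == 0 and comps == [] and frac == 0.0


class TestPrepareInput:
    def test_ambiguous_and_isolated_excluded(self):
        g = nx.Graph([("a", "b"), ("b", "amb")])
        g.add_node("iso")
        labels = CoverageLabels(
            mapped={"a": True, "b": False, "amb": False, "iso": True},
            basis={"a": "A" * 14, "b": "B" * 14, "amb": None, "iso": "C" * 14},
        )
        sub, initial = prepare_lpa_input(g, labels)
        assert set(sub.nodes) == {"a", "b"}
        assert initial == {"a": COVERED, "b": UNCOVERED}


class TestEnrichment:
    def test_closed_form_fully_dark_pathway(self):
        universe = {f"n{i}" for i in range(10)}
        dark = {f"n{i}" for i in range(5)}
        rows = pathway_enrichment(dark, {"p": set(dark)}, universe)
        # all 5 members inside a 5-node dark half: p = 1 / C(10,5)
        assert rows[0].p_value == pytest.approx(1 / 252, rel=1e-9)

    def test_proportional_pathway_not_enriched(self):
        universe = {f"n{i}" for i in range(20)}
        dark = {f"n{i}" for i in range(10)}
        pathway = {"p": {"n0", "n1", "n10", "n11"}}  # half in, half out
        rows = pathway_enrichment(dark, pathway, universe)
        assert rows[0].p_value > 0.5

    def test_bh_adjustment(self):
        universe = {f"n{i}" for i in range(40)}
        dark = {f"n{i}" for i in range(8)}
        rows = pathway_enrichment(
            dark,
            {"hot": {f"n{i}" for i in range(6)}, "cold": {f"n{i}" for i in range(30, 38)}},
            universe,
        )
        by_name = {r.pathway: r for r in rows}
        m = len(rows)
        # with two pathways: q = min(1, m*p/rank) with monotonicity
        ps = sorted(r.p_value for r in rows)
        qs = sorted(r.q_value for r in rows)
        assert qs[0] == pytest.approx(min(m * ps[0] / 1, ps[1]))
        assert all(0 <= r.q_value <= 1 for r in rows)
        assert by_name["hot"].q_value < by_name["cold"].q_value

    def test_fisher_matches_hypergeometric_oracle(self):
        universe = {f"n{i}" for i in range(30)}
        dark = {f"n{i}" for i in range(9)}
        members = {f"n{i}" for i in range(5, 17)}
        rows = pathway_enrichment(dark, {"p": members}, universe)
        k = len(members & dark)
        table = [[k, len(members) - k],
                 [len(dark) - k, len(universe) - len(members) - len(dark) + k]]
        assert rows[0].p_value == pytest.approx(
            fisher_oracle(table, "greater"), abs=1e-12)

    def test_pathway_outside_universe_skipped(self):
        rows = pathway_enrichment({"a"}, {"ghost": {"zz"}}, {"a", "b"})
        assert rows == []
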