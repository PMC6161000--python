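from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from metnetcov.coverage import (coverage_summary, map_coverage,
                                neighborhood_coverage, per_library_coverage)
from metnetcov.identifiers import MergedLibrary, SpectralLibrary, parse_key


def graph_with_blocks(node_blocks: dict[str, str | None]) -> nx.Graph:
    g = nx.Graph()
    for node, block in node_blocks.items():
        g.add_node(node, first_block=block or "")
    return g


def merged_of(*blocks: str) -> MergedLibrary:
    return MergedLibrary(blocks=frozenset(blocks),
                         provenance={b: frozenset({"lib"}) for b in blocks})


B = [c * 14 for c in "ABCDEFGHIJ"]


class TestMapCoverage:
    def test_block_membership(self):
        g = graph_with_blocks({"n1": B[0], "n2": B[1], "amb": None})
        labels = map_coverage(g, merged_of(B[0]))
        assert labels.mapped == {"n1": True, "n2": False, "amb": False}
        assert labels.basis["amb"] is None

    def test_planted_rate_recovered(self):
        # nodes mapped independently at rate p: observed fraction within
        # binomial noise of p
        rng = np.random.default_rng(3)
        p, n = 0.6, 400
        blocks = {f"n{i}": B[0] if rng.random() < p else B[1] for i in range(n)}
        labels = map_coverage(graph_with_blocks(blocks), merged_of(B[0]))
        observed = labels.n_mapped / n
        assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestCoverageSummary:
    def test_category_percentages(self):
        blocks = {f"m{i}": B[0] for i in range(4)}
        blocks |= {f"u{i}": B[1] for i in range(4)}
        blocks |= {"a0": None, "a1": None}
        labels = map_coverage(graph_with_blocks(blocks), merged_of(B[0]))
        summ = coverage_summary(None, labels, name="toy")
        assert (summ.n_total, summ.n_found, summ.n_ambiguous) == (10, 4, 2)
        assert summ.pct_found == pytest.approx(40.0)
        assert summ.pct_ambiguous == pytest.approx(20.0)
        assert summ.pct_found + summ.pct_not_found + summ.pct_ambiguous == pytest.approx(100.0)
        assert summ.pct_found_of_annotated == pytest.approx(50.0)

    def test_all_mapped(self):
        labels = map_coverage(graph_with_blocks({"x": B[0], "y": B[0]}), merged_of(B[0]))
        summ = coverage_summary(None, labels)
        assert (summ.pct_found, summ.pct_not_found, summ.pct_ambiguous) == (100.0, 0.0, 0.0)

    def test_relabeling_invariance(self):
        blocks = {"x": B[0], "y": B[1], "z": None}
        renamed = {f"node_{k}": v for k, v in blocks.items()}
        s1 = coverage_summary(None, map_coverage(graph_with_blocks(blocks), merged_of(B[0])))
        s2 = coverage_summary(None, map_coverage(graph_with_blocks(renamed), merged_of(B[0])))
        assert s1.as_dict() | {"model": ""} == s2.as_dict() | {"model": ""}


class TestPerLibrary:
    def _lib(self, name, blocks):
        keys = frozenset(parse_key(f"{b}-AAAAAAAAAA-N") for b in blocks)
        return SpectralLibrary(name=name, keys=keys)

    def test_single_library_matches_summary(self):
        g = graph_with_blocks({"x": B[0], "y": B[1], "z": B[2]})
        lib = self._lib("solo", [B[0], B[1]])
        matrix = per_library_coverage([("g", g)], [lib])
        labels = map_coverage(g, lib.blocks)
        assert matrix.loc[0, "pct_found"] == pytest.approx(
            coverage_summary(g, labels).pct_found)

    def test_disjoint_library_is_zero(self):
        g = graph_with_blocks({"x": B[0], "y": B[1]})
        matrix = per_library_coverage([("g", g)], [self._lib("other", [B[5]])])
        assert (matrix["pct_found"] == 0).all()

    def test_planted_overlap_matrix(self):
        g1 = graph_with_blocks({f"a{i}": B[i] for i in range(4)})   # blocks 0-3
        g2 = graph_with_blocks({f"b{i}": B[i + 2] for i in range(4)})  # blocks 2-5
        libs = [self._lib("l1", [B[0], B[1]]), self._lib("l2", [B[2], B[3]])]
        matrix = per_library_coverage([("g1", g1), ("g2", g2)], libs).set_index(
            ["model", "library"])["pct_found"]
        assert matrix[("g1", "l1")] == pytest.approx(50.0)
        assert matrix[("g1", "l2")] == pytest.approx(50.0)
        assert matrix[("g2", "l1")] == pytest.approx(0.0)
        assert matrix[("g2", "l2")] == pytest.approx(50.0)


class TestNeighborhood:
    def test_fraction_of_mapped_neighbors(self):
        g = nx.star_graph(4)
        g = nx.relabel_nodes(g, {0: "hub", 1: "m1", 2: "m2", 3: "m3", 4: "u"})
        for n in g.nodes:
            g.nodes[n]["first_block"] = B[0] if n.startswith("m") else B[1]
        labels = map_coverage(g, merged_of(B[0]))
        labels, stats = neighborhood_coverage(g, labels)
        assert labels.neighborhood_fraction["hub"] == pytest.approx(0.75)
        assert all(0.0 <= f <= 1.0 for f in labels.neighborhood_fraction.values())

    def test_all_mapped_graph(self):
        g = nx.path_graph(5)
        for n in g.nodes:
            g.nodes[n]["first_block"] = B[0]
        labels = map_coverage(g, merged_of(B[0]))
        labels, stats = neighborhood_coverage(g, labels)
        assert all(f == 1.0 for f in labels.neighborhood_fraction.values())
        assert stats.share_half_neighbors_mapped == 1.0
        assert stats.n_bin_90_100_unmapped == 0

    def test_isolated_nodes_excluded_and_histogram_sums(self):
        g = nx.path_graph(4)
        g.add_node("iso")
        for n in g.nodes:
            g.nodes[n]["first_block"] = B[0] if n in (0, 1) else B[1]
        labels = map_coverage(g, merged_of(B[0]))
        labels, stats = neighborhood_coverage(g, labels)
        assert "iso" not in labels.neighborhood_fraction
        assert stats.n_connected == 4
        assert stats.histogram["n_total"].sum() == stats.n_connected

    def test_90_100_bin_is_inclusive(self):
        # hub with 10 neighbors, exactly 1 mapped: unmapped fraction 0.9
        g = nx.star_graph(10)
        for n in g.nodes:
            g.nodes[n]["first_block"] = B[0] if n == 1 else B[1]
        labels = map_coverage(g, merged_of(B[0]))
        labels, stats = neighborhood_coverage(g, labels)
        assert stats.n_bin_90_100_unmapped >= 1  # the hub, at exactly 0.9
        assert stats.n_bin_90_100_unmapped_self_unmapped >= 1

    def test_edgeless_graph_is_error(self):
        g = nx.Graph()
        g.add_node("x", first_block=B[0])
        with pytest.raises(ValueError):
            neighborhood_coverage(g, map_coverage(g, merged_of(B[0])))
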