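"""Synthetic inputs with planted ground truth.

The generator emulates the statistical situation the pipeline is built to
detect: a metabolic network containing a well-covered main region and a
sparsely connected, poorly covered block ("dark" region), spectral
libraries hitting the two regions at very different rates, a share of
ambiguously annotated metabolites, and heavy-tailed publication counts
that differ by coverage status.

The planted structure is a two-block model: each block gets a uniform
random spanning tree (guaranteeing within-block connectivity) plus
independent extra edges, with the dark block much sparser — hence lower
clustering — and only a handful of bridges between blocks.  Every intended
edge is realized in the emitted SBML as a two-substrate/two-product
reaction sharing a carbon-free cofactor pair, so the carbon-conservation
filter of the graph builder is exercised on every reaction.

What this does *not* emulate: real stoichiometry, realistic chemistry of
the generated identifiers, hub cofactor structure, or the modular overlap
of real pathways.  Passing recovery tests here shows the pipeline detects
a planted sparse low-coverage region under its stated assumptions, not
that real metabolic dark areas have this exact structure.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate", "generate_graph", "truth_check"]

_UPPER = np.array(list(string.ascii_uppercase))


@dataclass
class GeneratorConfig:
    """Planted-partition generator settings.

    The edge-probability defaults keep ``p_between`` well below both
    within-block densities, the regime in which the planted structure is
    detectable at all.
    """

    n_nodes: int = 100
    n_dark: int = 20
    #: extra-edge probabilities on top of each block's spanning tree
    p_in_covered: float = 0.06
    p_in_dark: float = 0.03
    p_between: float = 0.001
    cover_rate_main: float = 0.7
    cover_rate_dark: float = 0.1
    frac_ambiguous: float = 0.10
    #: number of decoy pathways drawn from the covered block, plus one
    #: planted pathway inside the dark block
    n_decoy_pathways: int = 5
    planted_pathway_size: int = 12
    decoy_pathway_size: int = 15
    #: log-normal article-count law (meanlog, sdlog) per coverage class,
    #: with an atom at zero for a share of each class
    pub_mapped_law: tuple[float, float] = (4.0, 1.5)
    pub_unmapped_law: tuple[float, float] = (2.0, 1.5)
    pub_zero_share_mapped: float = 0.05
    pub_zero_share_unmapped: float = 0.30
    frac_no_cid: float = 0.07
    #: route every inter-block edge through one designated dark node,
    #: making it the unique bridge on all inter-block shortest paths
    single_dark_bridge: bool = False
    seed: int = 0

    def validate(self) -> None:
        probs = [self.p_in_covered, self.p_in_dark, self.p_between,
                 self.cover_rate_main, self.cover_rate_dark, self.frac_ambiguous,
                 self.pub_zero_share_mapped, self.pub_zero_share_unmapped,
                 self.frac_no_cid]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0 < self.n_dark < self.n_nodes:
            raise ValueError("need 0 < n_dark < n_nodes")
        if self.planted_pathway_size > self.n_dark:
            raise ValueError("planted pathway cannot exceed the dark block")
        if self.decoy_pathway_size > self.n_nodes - self.n_dark:
            raise ValueError("decoy pathway cannot exceed the covered block")


@dataclass
class SyntheticTruth:
    """Ground truth keyed by graph-level node ids (InChIKey first block for
    annotated nodes, model id for ambiguous ones)."""

    dark_members: set[str]
    library_membership: dict[str, bool]
    ambiguous: set[str]
    pathway_assignment: dict[str, list[str]]
    planted_pathway: str
    pub_counts: dict[str, int | None]
    node_cids: dict[str, int | None]
    bridge_node: str | None
    model_to_graph: dict[str, str]
    edges: list[tuple[str, str]]

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["dark_members"] = sorted(self.dark_members)
        data["ambiguous"] = sorted(self.ambiguous)
        data["edges"] = [list(e) for e in self.edges]
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def _random_key(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        first = "".join(rng.choice(_UPPER, 14))
        if first in used:
            continue
        used.add(first)
        middle = "".join(rng.choice(_UPPER, 10))
        return f"{first}-{middle}-N"


def _block_graph(rng: np.random.Generator, members: list[int], p_extra: float) -> list[tuple[int, int]]:
    """Random spanning tree (random attachment order) plus Bernoulli extras."""
    edges: set[tuple[int, int]] = set()
    order = list(rng.permutation(members))
    for i, node in enumerate(order[1:], start=1):
        anchor = order[int(rng.integers(0, i))]
        edges.add(tuple(sorted((node, anchor))))
    for i, u in enumerate(members):
        for v in members[i + 1:]:
            if rng.random() < p_extra:
                edges.add(tuple(sorted((u, v))))
    return sorted(edges)


def generate_graph(config: GeneratorConfig) -> tuple[nx.Graph, dict[int, bool], int | None]:
    """Planted two-block graph on integer nodes 0..n-1.

    Returns the graph, a node -> is_dark map, and the designated bridge
    node (dark side) when ``single_dark_bridge`` is set.  Nodes
    ``0..n_dark-1`` form the dark block.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dark = list(range(config.n_dark))
    covered = list(range(config.n_dark, config.n_nodes))
    edges = _block_graph(rng, dark, config.p_in_dark)
    edges += _block_graph(rng, covered, config.p_in_covered)

    bridge_node: int | None = None
    bridges: list[tuple[int, int]] = []
    if config.single_dark_bridge:
        bridge_node = int(rng.choice(dark))
        n_bridges = max(1, rng.binomial(len(dark) * len(covered), config.p_between))
        targets = rng.choice(covered, size=min(n_bridges, len(covered)), replace=False)
        bridges = [tuple(sorted((bridge_node, int(t)))) for t in targets]
    else:
        for u in dark:
            for v in covered:
                if rng.random() < config.p_between:
                    bridges.append((u, v))
        if not bridges:  # keep the two blocks connected
            bridges.append((int(rng.choice(dark)), int(rng.choice(covered))))
    g = nx.Graph()
    g.add_nodes_from(range(config.n_nodes))
    g.add_edges_from(edges + bridges)
    is_dark = {i: (i < config.n_dark) for i in range(config.n_nodes)}
    return g, is_dark, bridge_node


def _write_sbml(path: Path, species_rows: list[dict], reactions: list[tuple[str, list[str], list[str]]]) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel("synthetic_model")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)
    for row in species_rows:
        sp = model.createSpecies()
        sp.setId(row["id"])
        sp.setName(row["name"])
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        notes = [f"<p>FORMULA: {row['formula']}</p>"]
        if row.get("inchikey"):
            notes.append(f"<p>INCHIKEY: {row['inchikey']}</p>")
        if row.get("kegg"):
            notes.append(f"<p>KEGG: {row['kegg']}</p>")
        sp.setNotes(
            '<body xmlns="http://www.w3.org/1999/xhtml">' + "".join(notes) + "</body>"
        )
    for rid, subs, prods in reactions:
        rxn = model.createReaction()
        rxn.setId(rid)
        rxn.setReversible(True)
        rxn.setFast(False)
        for s in subs:
            ref = rxn.createReactant()
            ref.setSpecies(s)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for p in prods:
            ref = rxn.createProduct()
            ref.setSpecies(p)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def generate(config: GeneratorConfig, outdir: str | Path) -> SyntheticTruth:
    """Emit a complete synthetic input bundle and its ground truth.

    Files written to ``outdir``: ``model.sbml.xml``, two spectral-library
    lists (``library_main.txt``, ``library_extra.txt``), ``pathways.tsv``,
    ``publications.tsv``, ``node_cids.tsv`` and ``truth.json``.  Everything
    is a deterministic function of the config (including its seed).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, is_dark, bridge_idx = generate_graph(config)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))

    n = config.n_nodes
    used_blocks: set[str] = set()
    ambiguous_idx = set(
        int(i) for i in rng.choice(n, size=round(config.frac_ambiguous * n), replace=False)
    )
    if bridge_idx is not None:
        ambiguous_idx.discard(bridge_idx)  # the planted bridge must be mappable

    model_ids, graph_ids, keys = [], [], []
    species_rows: list[dict] = []
    for i in range(n):
        mid = f"M{i:04d}"
        carbons = int(rng.integers(3, 21))
        formula = f"C{carbons}H{int(rng.integers(4, 2 * carbons + 3))}O{int(rng.integers(1, 7))}"
        if i in ambiguous_idx:
            key = None
            gid = mid
            kegg = f"C9{i:04d}"  # reference that no local table resolves
        else:
            key = _random_key(rng, used_blocks)
            gid = key.split("-")[0]
            kegg = None
        model_ids.append(mid)
        graph_ids.append(gid)
        keys.append(key)
        species_rows.append(
            {"id": mid, "name": f"metabolite {i}", "formula": formula,
             "inchikey": key, "kegg": kegg}
        )
    # carbon-free cofactor pair shared by every reaction: valid structures,
    # removed from the graph by the carbon-conservation rule alone
    cof_a_key = _random_key(rng, used_blocks)
    cof_b_key = _random_key(rng, used_blocks)
    species_rows.append({"id": "cof_a", "name": "cofactor A", "formula": "H3O4P",
                         "inchikey": cof_a_key, "kegg": None})
    species_rows.append({"id": "cof_b", "name": "cofactor B", "formula": "H4O7P2",
                         "inchikey": cof_b_key, "kegg": None})

    reactions = [
        (f"R{k:04d}", [model_ids[u], "cof_a"], [model_ids[v], "cof_b"])
        for k, (u, v) in enumerate(sorted(graph.edges))
    ]
    _write_sbml(outdir / "model.sbml.xml", species_rows, reactions)

    # --- libraries: annotated nodes drawn at per-class cover rates,
    # split across two sources with overlap, plus out-of-network decoys
    in_library: dict[int, bool] = {}
    for i in range(n):
        if keys[i] is None:
            in_library[i] = False
            continue
        rate = config.cover_rate_dark if is_dark[i] else config.cover_rate_main
        in_library[i] = bool(rng.random() < rate)
    lib_members = [i for i in range(n) if in_library[i]]
    main_lines, extra_lines = [], []
    for i in lib_members:
        which = rng.random()
        if which < 0.6:
            main_lines.append(keys[i])
        elif which < 0.8:
            extra_lines.append(keys[i])
        else:
            main_lines.append(keys[i])
            extra_lines.append(keys[i])
    for _ in range(30):  # decoy compounds absent from the network
        main_lines.append(_random_key(rng, used_blocks))
    for _ in range(10):
        extra_lines.append(_random_key(rng, used_blocks))
    for path, lines in ((outdir / "library_main.txt", main_lines),
                        (outdir / "library_extra.txt", extra_lines)):
        shuffled = list(rng.permutation(lines))
        path.write_text("\n".join(["# synthetic spectral library"] + shuffled) + "\n")

    # --- pathways: one planted inside the dark block, decoys in the covered
    dark_idx = [i for i in range(n) if is_dark[i]]
    covered_idx = [i for i in range(n) if not is_dark[i]]
    planted = rng.choice(dark_idx, size=config.planted_pathway_size, replace=False)
    pathway_assignment: dict[str, list[str]] = {
        "planted_dark_pathway": sorted(graph_ids[i] for i in planted)
    }
    for d in range(config.n_decoy_pathways):
        members = rng.choice(covered_idx, size=config.decoy_pathway_size, replace=False)
        pathway_assignment[f"decoy_pathway_{d}"] = sorted(graph_ids[i] for i in members)
    with open(outdir / "pathways.tsv", "w") as fh:
        fh.write("node\tpathway\n")
        for pathway, members in pathway_assignment.items():
            for gid in members:
                fh.write(f"{gid}\t{pathway}\n")

    # --- publication counts: heavy-tailed, class-dependent, atom at zero
    node_cids: dict[str, int | None] = {}
    pub_counts: dict[str, int | None] = {}
    cid_pool = rng.choice(np.arange(10_000, 10_000_000), size=n, replace=False)
    pub_rows = []
    for i in range(n):
        gid = graph_ids[i]
        if rng.random() < config.frac_no_cid:
            node_cids[gid] = None
            pub_counts[gid] = None
            continue
        cid = int(cid_pool[i])
        node_cids[gid] = cid
        mapped = in_library[i]
        zero_share = (config.pub_zero_share_mapped if mapped
                      else config.pub_zero_share_unmapped)
        if rng.random() < zero_share:
            count = 0
        else:
            mu, sigma = config.pub_mapped_law if mapped else config.pub_unmapped_law
            count = max(1, int(round(rng.lognormal(mu, sigma))))
        pub_counts[gid] = count
        pub_rows.append((cid, count))
    with open(outdir / "publications.tsv", "w") as fh:
        fh.write("cid\tn_articles\n")
        for cid, count in pub_rows:
            fh.write(f"{cid}\t{count}\n")
    with open(outdir / "node_cids.tsv", "w") as fh:
        fh.write("node\tcid\n")
        for gid, cid in node_cids.items():
            fh.write(f"{gid}\t{'' if cid is None else cid}\n")

    truth = SyntheticTruth(
        dark_members={graph_ids[i] for i in dark_idx},
        library_membership={graph_ids[i]: in_library[i] for i in range(n)},
        ambiguous={graph_ids[i] for i in ambiguous_idx},
        pathway_assignment=pathway_assignment,
        planted_pathway="planted_dark_pathway",
        pub_counts=pub_counts,
        node_cids=node_cids,
        bridge_node=graph_ids[bridge_idx] if bridge_idx is not None else None,
        model_to_graph=dict(zip(model_ids, graph_ids)),
        edges=sorted((min(graph_ids[u], graph_ids[v]), max(graph_ids[u], graph_ids[v]))
                     for u, v in graph.edges),
    )
    truth.to_json(outdir / "truth.json")
    return truth


def truth_check(
    predicted_dark: set[str],
    truth: SyntheticTruth,
    universe: set[str],
    *,
    enrichment=None,
    ranking=None,
) -> dict:
    """Recovery metrics of a pipeline run against the planted truth.

    ``universe`` is the set of nodes the detection actually ran on (the
    annotated, connected graph); planted dark members outside it cannot be
    recovered and are excluded from recall.  Optional: the enrichment rows
    (rank of the planted pathway by q-value) and the betweenness ranking
    DataFrame (rank of the planted bridge node).
    """
    unknown = predicted_dark - universe
    if unknown:
        raise ValueError(f"predicted nodes outside the analysed universe: {sorted(unknown)[:5]}")
    relevant = truth.dark_members & universe
    tp = len(predicted_dark & relevant)
    precision = tp / len(predicted_dark) if predicted_dark else 0.0
    recall = tp / len(relevant) if relevant else float("nan")
    report: dict = {
        "n_relevant_dark": len(relevant),
        "n_predicted_dark": len(predicted_dark),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }
    if enrichment is not None:
        order = [row.pathway for row in enrichment]
        report["planted_pathway_rank"] = (
            order.index(truth.planted_pathway) + 1
            if truth.planted_pathway in order else None
        )
    if ranking is not None and truth.bridge_node is not None:
        nodes = list(ranking["node"])
        report["bridge_rank"] = (
            nodes.index(truth.bridge_node) + 1 if truth.bridge_node in nodes else None
        )
    return report
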