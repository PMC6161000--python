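"""Two-label Label Propagation aggregated over randomized runs.

Every node starts labelled *covered* or *uncovered* by its spectral-library
mapping status.  Asynchronous label propagation then lets each node adopt
the majority label of its neighbors — ties broken uniformly at random —
until every node's label is among the majority labels of its neighborhood.
Densely connected regions thus reach a common label quickly: an unmapped
metabolite surrounded by mapped ones joins the well-covered community (its
absence from libraries is compensated by its neighbors), while a mapped
metabolite buried in an unmapped region joins the poorly covered one.

A single run depends on the random update order and tie resolutions, so the
assignment is aggregated over many independently seeded runs by per-node
majority vote.  The nodes voted *uncovered* form the dark area; its induced
subgraph, components, and pathway enrichment characterize the parts of
metabolism invisible to current spectral libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .coverage import CoverageLabels

__all__ = [
    "COVERED",
    "UNCOVERED",
    "LpaResult",
    "EnrichmentRow",
    "lpa_single_run",
    "lpa_aggregate",
    "dark_subgraph",
    "pathway_enrichment",
    "prepare_lpa_input",
]

log = logging.getLogger(__name__)

COVERED = "covered"
UNCOVERED = "uncovered"

#: guards pathological oscillation; the stability criterion makes
#: non-termination essentially impossible in practice
MAX_SWEEPS = 1000


@dataclass
class LpaResult:
    initial: dict[str, str]
    runs: int
    aggregate: dict[str, str]
    vote_fraction: dict[str, float]  # share of runs assigning "covered"
    dark_nodes: set[str] = field(default_factory=set)
    dark_components: list[set[str]] = field(default_factory=list)
    per_run_labels: list[dict[str, str]] | None = None


class _Propagator:
    """Index-based LPA state shared across runs on one graph."""

    def __init__(self, graph: nx.Graph, initial_labels: dict[str, str],
                 include_self_vote: bool = False):
        self.nodes = list(graph.nodes)
        index = {n: i for i, n in enumerate(self.nodes)}
        self.neighbors = [
            np.array([index[v] for v in graph.neighbors(n)], dtype=np.intp)
            for n in self.nodes
        ]
        self.initial = np.array(
            [1 if initial_labels[n] == COVERED else 0 for n in self.nodes],
            dtype=np.int8,
        )
        self.include_self_vote = include_self_vote
        self.active = np.array([len(nb) > 0 for nb in self.neighbors])

    def run(self, rng: np.random.Generator) -> np.ndarray:
        labels = self.initial.copy()
        n = len(self.nodes)
        for sweep in range(MAX_SWEEPS):
            for i in rng.permutation(n):
                nbrs = self.neighbors[i]
                if len(nbrs) == 0:
                    continue  # isolated nodes keep their initial label
                ones = int(labels[nbrs].sum())
                zeros = len(nbrs) - ones
                if self.include_self_vote:
                    if labels[i]:
                        ones += 1
                    else:
                        zeros += 1
                if ones > zeros:
                    labels[i] = 1
                elif zeros > ones:
                    labels[i] = 0
                else:
                    labels[i] = rng.integers(0, 2)
            if self._stable(labels):
                return labels
        log.warning("LPA hit the %d-sweep cap without stabilizing", MAX_SWEEPS)
        return labels

    def _stable(self, labels: np.ndarray) -> bool:
        # stable when every connected node's label is a (possibly tied)
        # majority label of its neighborhood
        for i, nbrs in enumerate(self.neighbors):
            if len(nbrs) == 0:
                continue
            ones = int(labels[nbrs].sum())
            zeros = len(nbrs) - ones
            if labels[i] == 1 and ones < zeros:
                return False
            if labels[i] == 0 and zeros < ones:
                return False
        return True


def lpa_single_run(
    graph: nx.Graph,
    initial_labels: dict[str, str],
    rng_seed: int | np.random.Generator,
    *,
    include_self_vote: bool = False,
) -> dict[str, str]:
    """One asynchronous LPA run with a freshly shuffled order each sweep.

    A node adopts the strict majority label among its neighbors (its own
    current label does not vote, per the original LPA formulation; switch
    with ``include_self_vote``); exact ties are broken uniformly at random.
    Terminates when every node's label is among its neighborhood's majority
    labels.  Isolated nodes keep their initial label.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    prop = _Propagator(graph, initial_labels, include_self_vote)
    labels = prop.run(rng)
    return {n: (COVERED if l else UNCOVERED) for n, l in zip(prop.nodes, labels)}


def lpa_aggregate(
    graph: nx.Graph,
    initial_labels: dict[str, str],
    n_runs: int = 1000,
    master_seed: int = 0,
    *,
    include_self_vote: bool = False,
    keep_per_run: bool = False,
) -> LpaResult:
    """Aggregate ``n_runs`` independently seeded LPA runs by majority vote.

    Run seeds are spawned deterministically from ``master_seed``, so the
    whole result is reproducible.  A node's final label is *covered* when
    more than half the runs say so; an exact 50/50 split falls back to the
    node's initial label (a conservative tie rule: no evidence, no flip).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    prop = _Propagator(graph, initial_labels, include_self_vote)
    seeds = np.random.SeedSequence(master_seed).spawn(n_runs)
    votes = np.zeros(len(prop.nodes), dtype=np.int64)
    per_run: list[dict[str, str]] | None = [] if keep_per_run else None
    for seed in seeds:
        labels = prop.run(np.random.default_rng(seed))
        votes += labels
        if per_run is not None:
            per_run.append(
                {n: (COVERED if l else UNCOVERED) for n, l in zip(prop.nodes, labels)}
            )
    vote_fraction = votes / n_runs
    aggregate = {}
    for i, node in enumerate(prop.nodes):
        if vote_fraction[i] > 0.5:
            aggregate[node] = COVERED
        elif vote_fraction[i] < 0.5:
            aggregate[node] = UNCOVERED
        else:
            aggregate[node] = initial_labels[node]
    result = LpaResult(
        initial=dict(initial_labels),
        runs=n_runs,
        aggregate=aggregate,
        vote_fraction={n: float(vote_fraction[i]) for i, n in enumerate(prop.nodes)},
        per_run_labels=per_run,
    )
    result.dark_nodes = {n for n, lab in aggregate.items() if lab == UNCOVERED}
    result.dark_components = [
        set(c) for c in sorted(
            nx.connected_components(graph.subgraph(result.dark_nodes)),
            key=len, reverse=True,
        )
    ]
    return result


def prepare_lpa_input(
    graph: nx.Graph,
    labels: CoverageLabels,
    *,
    exclude_ambiguous: bool = True,
    exclude_isolated: bool = True,
) -> tuple[nx.Graph, dict[str, str]]:
    """Restrict the graph to LPA-eligible nodes and build initial labels.

    Ambiguous-identifier nodes (no first block) are removed by default —
    they can never be mapped, so their uncovered label carries no signal —
    as are isolated nodes, which label propagation cannot touch.
    """
    keep = []
    for node in graph.nodes:
        if exclude_ambiguous and labels.basis.get(node) is None:
            continue
        keep.append(node)
    sub = graph.subgraph(keep).copy()
    if exclude_isolated:
        sub.remove_nodes_from([n for n in sub.nodes if sub.degree(n) == 0])
    initial = {n: (COVERED if labels.mapped[n] else UNCOVERED) for n in sub.nodes}
    return sub, initial


def dark_subgraph(result: LpaResult, graph: nx.Graph) -> tuple[nx.Graph, list[set[str]], float]:
    """Induced subgraph on the dark nodes, its components, and the dark
    fraction of the (annotated) analysed graph."""
    sub = graph.subgraph(result.dark_nodes).copy()
    comps = [set(c) for c in sorted(nx.connected_components(sub), key=len, reverse=True)]
    n_universe = len(result.aggregate)
    frac = len(result.dark_nodes) / n_universe if n_universe else 0.0
    return sub, comps, frac


@dataclass
class EnrichmentRow:
    pathway: str
    k_dark: int   # pathway members inside the dark area
    n_dark: int   # dark-area size
    K_path: int   # pathway size within the universe
    N: int        # universe size
    p_value: float
    q_value: float = float("nan")


def pathway_enrichment(
    dark_nodes: set[str],
    pathway_table: pd.DataFrame | dict[str, set[str]],
    universe: set[str],
    *,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Right-tailed Fisher exact test per pathway, BH-corrected.

    ``pathway_table`` maps nodes to pathways, either as a DataFrame with
    ``node``/``pathway`` columns or as pathway -> node-set dict.  Pathways
    with no member in the universe are skipped with a warning.  Rows are
    returned sorted by q then p; membership of the dark area at q <= alpha
    is the overrepresentation call.
    """
    if isinstance(pathway_table, pd.DataFrame):
        path_sets: dict[str, set[str]] = {
            str(p): set(g["node"]) for p, g in pathway_table.groupby("pathway")
        }
    else:
        path_sets = {p: set(m) for p, m in pathway_table.items()}

    dark = dark_nodes & universe
    rows: list[EnrichmentRow] = []
    for pathway, members in sorted(path_sets.items()):
        in_universe = members & universe
        if not in_universe:
            log.warning("pathway %r has no member in the universe; skipped", pathway)
            continue
        k = len(in_universe & dark)
        table = [
            [k, len(in_universe) - k],
            [len(dark) - k, len(universe) - len(in_universe) - len(dark) + k],
        ]
        _, p = fisher_exact(table, alternative="greater")
        rows.append(
            EnrichmentRow(
                pathway=pathway,
                k_dark=k,
                n_dark=len(dark),
                K_path=len(in_universe),
                N=len(universe),
                p_value=float(p),
            )
        )
    if rows:
        _, q_values, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
        for row, q in zip(rows, q_values):
            row.q_value = float(q)
    rows.sort(key=lambda r: (r.q_value, r.p_value, r.pathway))
    return rows


def lpa_table(result: LpaResult) -> pd.DataFrame:
    """Per-node TSV-ready table (initial, aggregate, vote fraction)."""
    return pd.DataFrame(
        {
            "node": list(result.aggregate),
            "initial": [result.initial[n] for n in result.aggregate],
            "aggregate": [result.aggregate[n] for n in result.aggregate],
            "vote_fraction_covered": [result.vote_fraction[n] for n in result.aggregate],
        }
    )
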