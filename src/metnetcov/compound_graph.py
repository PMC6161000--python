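"""Carbon-conserving compound graph construction.

Nodes are structure-resolved metabolites of the merged model; an edge joins
a substrate and a product of the same reaction when at least one carbon
atom is conserved between them.  The carbon rule prunes the biologically
spurious shortcuts that side compounds (water, phosphate, CO2) would
otherwise create: a kinase reaction connects glucose to glucose-6-phosphate
and ATP to ADP, but not glucose to ADP.

Edge weights record the shared-carbon count; downstream analyses (label
propagation, betweenness) treat the graph as unweighted.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .model_ingest import MetabolicModel, MetaboliteEntry, Status

__all__ = [
    "carbon_count",
    "shared_carbons",
    "build_graph",
    "components",
    "write_gml",
    "read_gml",
    "DEFAULT_BLACKLIST",
]

log = logging.getLogger(__name__)

#: Inorganic carbonated species removed by hand; the carbon rule alone would
#: keep them and they shortcut half the network.  Matched on lowered name
#: or first block.
DEFAULT_BLACKLIST: frozenset[str] = frozenset(
    {
        "co2", "carbon dioxide",
        "hco3", "hco3-", "bicarbonate", "hydrogencarbonate",
        "co", "carbon monoxide",
        "cn-", "cyanide", "hydrogen cyanide",
        "co3", "carbonate",
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count(formula_or_inchi: str) -> int | None:
    """Number of carbon atoms in an elemental formula or InChI.

    For an InChI the second (formula) layer is used; dot-separated
    multi-component formulas are summed.  Returns ``None`` when the string
    cannot be read as a formula, 0 for carbon-free species.
    """
    if not formula_or_inchi:
        return None
    s = formula_or_inchi.strip()
    if s.startswith("InChI="):
        layers = s.split("/")
        if len(layers) < 2:
            return None
        s = layers[1]
    total = 0
    for part in s.split("."):
        part = re.sub(r"^\d+", "", part)  # leading multiplier in InChI formulas
        for m in _FORMULA_TOKEN.finditer(part):
            if m.group(0) and m.group(1) == "C":
                total += int(m.group(2) or 1)
    # reject strings that are mostly not element tokens (e.g. free text)
    plain = re.sub(r"[.\d]", "", s)
    if not plain or not re.fullmatch(r"([A-Z][a-z]?)+", plain):
        return None
    return total


def shared_carbons(
    u: MetaboliteEntry,
    v: MetaboliteEntry,
    reaction_id: str | None = None,
    atom_map: Mapping[tuple[str, str, str], int] | None = None,
) -> int:
    """Carbons conserved between a substrate and a product.

    With an atom-mapping table — keyed ``(reaction_id, substrate_id,
    product_id)`` in either orientation — the curated count is returned.
    Without one, the fallback estimate is ``min(C_u, C_v)``, a deliberate
    upper-bound heuristic under which the edge-retention test reduces to
    "both endpoints carry at least one carbon".
    """
    if atom_map is not None and reaction_id is not None:
        for key in ((reaction_id, u.model_id, v.model_id),
                    (reaction_id, v.model_id, u.model_id)):
            if key in atom_map:
                return atom_map[key]
    cu = u.carbon_count or 0
    cv = v.carbon_count or 0
    return min(cu, cv)


def _is_blacklisted(entry: MetaboliteEntry, blacklist: frozenset[str]) -> bool:
    probes = {entry.name.lower(), entry.model_id.lower()}
    if entry.first_block:
        probes.add(entry.first_block.lower())
    return bool(probes & blacklist)


def build_graph(
    model: MetabolicModel,
    blacklist: Iterable[str] = DEFAULT_BLACKLIST,
    atom_map: Mapping[tuple[str, str, str], int] | None = None,
    *,
    include_ambiguous: bool = True,
) -> nx.Graph:
    """Build the undirected compound graph from a merged, classified model.

    Every substrate-product pair of every reaction is a candidate edge,
    retained iff it conserves >= 1 carbon and neither endpoint is
    blacklisted or carbon-free.  Parallel candidates collapse to one edge
    keeping the maximum weight and the union of reaction provenance.
    Ambiguous-denomination entries participate by default (they do carry
    reactions) but are flagged unmappable; generic, macromolecule and
    reference-free entries never enter the graph.

    The result is invariant to reaction order and substrate/product order.
    """
    blacklist = frozenset(b.lower() for b in blacklist)
    eligible = {Status.STRUCTURE_RESOLVED}
    if include_ambiguous:
        eligible.add(Status.AMBIGUOUS_DENOMINATION)

    nodes: dict[str, MetaboliteEntry] = {}
    n_excluded = 0
    for entry in model.metabolites:
        if entry.status not in eligible:
            continue
        if entry.carbon_count is None and entry.status is Status.STRUCTURE_RESOLVED:
            log.warning("%s: unknown carbon count, node excluded", entry.model_id)
            n_excluded += 1
            continue
        if (entry.carbon_count or 0) < 1:
            continue  # carbon-free species cannot conserve a carbon
        if _is_blacklisted(entry, blacklist):
            continue
        nodes[entry.model_id] = entry

    g = nx.Graph()
    for mid, entry in nodes.items():
        g.add_node(
            mid,
            name=entry.name,
            first_block=entry.first_block or "",
            status=entry.status.value if entry.status else "",
            carbon_count=int(entry.carbon_count or 0),
        )

    for rxn in model.reactions:
        for s in rxn.substrates:
            if s not in nodes:
                continue
            for p in rxn.products:
                if p not in nodes or p == s:
                    continue
                w = shared_carbons(nodes[s], nodes[p], rxn.reaction_id, atom_map)
                if w < 1:
                    continue
                u, v = sorted((s, p))
                if g.has_edge(u, v):
                    data = g[u][v]
                    data["weight"] = max(data["weight"], w)
                    data["reactions"].add(rxn.reaction_id)
                else:
                    g.add_edge(u, v, weight=w, reactions={rxn.reaction_id})
    return g


def components(graph: nx.Graph) -> list[set[str]]:
    """Connected components in decreasing size (ties by smallest member)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


# --- GML exchange ---------------------------------------------------------

def write_gml(graph: nx.Graph, path: str | Path) -> None:
    """Write the compound graph as GML, the format the field exchanges
    processed networks in.  Set-valued edge provenance is serialized as a
    comma-joined string."""
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        if isinstance(data.get("reactions"), set):
            data["reactions"] = ",".join(sorted(data["reactions"]))
    nx.write_gml(g, str(path))


def read_gml(path: str | Path) -> nx.Graph:
    """Read a GML compound graph, restoring provenance sets."""
    g = nx.read_gml(str(path))
    for _, _, data in g.edges(data=True):
        if isinstance(data.get("reactions"), str):
            data["reactions"] = set(data["reactions"].split(",")) if data["reactions"] else set()
    return g
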