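"""Mapping spectral libraries onto models/graphs and coverage statistics.

Coverage is established by InChIKey first-block identity: a node is
*mapped* when its first block occurs in the merged library, i.e. at least
one spectral database holds a measured spectrum of a pure standard with the
same molecular connectivity.  Nodes without a resolvable first block
(ambiguous denominations) can never be mapped and are counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .identifiers import MergedLibrary, SpectralLibrary, merge_libraries
from .model_ingest import MetabolicModel, Status

__all__ = [
    "CoverageLabels",
    "CoverageSummary",
    "map_coverage",
    "coverage_summary",
    "per_library_coverage",
    "neighborhood_coverage",
    "NeighborhoodStats",
    "load_annotated_gml",
]

#: Fig-5-style deciles of the *unmapped*-neighbor fraction, from fully
#: covered neighborhoods (first bin) to 90-100% uncovered (last bin).
#: Bins are left-open, right-closed except the first, which is [0, 0.1];
#: the last bin therefore covers (0.9, 1.0] and the 90-100% summary count
#: below uses the inclusive convention [0.9, 1.0] stated in the metadata.
DECILE_EDGES = np.linspace(0.0, 1.0, 11)


@dataclass
class CoverageLabels:
    """Per-node mapped state plus (optional) neighborhood fractions."""

    mapped: dict[str, bool]
    basis: dict[str, str | None]
    #: fraction of neighbors mapped; defined exactly for degree >= 1 nodes
    neighborhood_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def n_mapped(self) -> int:
        return sum(self.mapped.values())


@dataclass
class CoverageSummary:
    model: str
    n_total: int
    n_found: int
    n_not_found: int
    n_ambiguous: int

    @property
    def pct_found(self) -> float:
        return 100.0 * self.n_found / self.n_total if self.n_total else 0.0

    @property
    def pct_not_found(self) -> float:
        return 100.0 * self.n_not_found / self.n_total if self.n_total else 0.0

    @property
    def pct_ambiguous(self) -> float:
        return 100.0 * self.n_ambiguous / self.n_total if self.n_total else 0.0

    @property
    def pct_found_of_annotated(self) -> float:
        """Coverage among entries that do carry an InChIKey."""
        annotated = self.n_found + self.n_not_found
        return 100.0 * self.n_found / annotated if annotated else 0.0

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "model": self.model,
            "n_total": self.n_total,
            "n_found": self.n_found,
            "n_not_found": self.n_not_found,
            "n_ambiguous": self.n_ambiguous,
            "pct_found": self.pct_found,
            "pct_not_found": self.pct_not_found,
            "pct_ambiguous": self.pct_ambiguous,
            "pct_found_of_annotated": self.pct_found_of_annotated,
        }


def _node_blocks(graph_or_model) -> dict[str, str | None]:
    """node id -> first block (or None) for a graph or a model."""
    if isinstance(graph_or_model, nx.Graph):
        return {
            n: (data.get("first_block") or None)
            for n, data in graph_or_model.nodes(data=True)
        }
    blocks: dict[str, str | None] = {}
    for entry in graph_or_model.metabolites:
        blocks[entry.model_id] = entry.first_block
    return blocks


def map_coverage(
    graph_or_model: nx.Graph | MetabolicModel,
    merged: MergedLibrary | frozenset[str] | set[str],
) -> CoverageLabels:
    """Label every node/entry mapped or unmapped by first-block lookup."""
    blocks = merged.blocks if isinstance(merged, MergedLibrary) else frozenset(merged)
    basis = _node_blocks(graph_or_model)
    mapped = {n: (b is not None and b in blocks) for n, b in basis.items()}
    return CoverageLabels(mapped=mapped, basis=basis)


def coverage_summary(
    graph_or_model: nx.Graph | MetabolicModel,
    labels: CoverageLabels,
    name: str = "",
) -> CoverageSummary:
    """Counts and percentages for the three coverage categories.

    ``found`` / ``not found`` partition entries with an InChIKey;
    ``ambiguous`` gathers those without one.  Both the all-entries and the
    annotated-only denominator are exposed, since coverage figures are
    quoted against either.
    """
    n_found = n_not_found = n_ambiguous = 0
    for node, block in labels.basis.items():
        if block is None:
            n_ambiguous += 1
        elif labels.mapped[node]:
            n_found += 1
        else:
            n_not_found += 1
    if not name:
        name = getattr(graph_or_model, "name", "") or "graph"
    return CoverageSummary(
        model=name,
        n_total=n_found + n_not_found + n_ambiguous,
        n_found=n_found,
        n_not_found=n_not_found,
        n_ambiguous=n_ambiguous,
    )


def per_library_coverage(
    models: Sequence[tuple[str, nx.Graph | MetabolicModel]],
    libs: Sequence[SpectralLibrary],
) -> pd.DataFrame:
    """Model x library matrix of percent mapped, plus per-library quartiles.

    Returns a tidy DataFrame with one row per (model, library) holding the
    percentage of the model's entries mapped by that library alone; the
    per-library distribution over models (box-plot data) is obtained by
    grouping on ``library``.
    """
    rows = []
    for model_name, gm in models:
        for lib in libs:
            labels = map_coverage(gm, lib.blocks)
            summ = coverage_summary(gm, labels, name=model_name)
            rows.append(
                {
                    "model": model_name,
                    "library": lib.name,
                    "pct_found": summ.pct_found,
                    "pct_found_of_annotated": summ.pct_found_of_annotated,
                    "n_found": summ.n_found,
                    "n_total": summ.n_total,
                }
            )
    return pd.DataFrame(rows)


def library_quartiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quartile summary of per-model coverage for each library."""
    return (
        matrix.groupby("library")["pct_found"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .reset_index()
    )


@dataclass
class NeighborhoodStats:
    """Summary of neighborhood coverage over connected nodes."""

    n_connected: int
    share_half_neighbors_mapped: float  # fraction with >= 0.5 of neighbors mapped
    share_any_neighbor_mapped: float
    n_bin_90_100_unmapped: int          # neighborhoods 90-100% unmapped (inclusive)
    n_bin_90_100_unmapped_self_unmapped: int
    histogram: pd.DataFrame             # Fig-5 deciles split by own mapped status


def neighborhood_coverage(
    graph: nx.Graph, labels: CoverageLabels
) -> tuple[CoverageLabels, NeighborhoodStats]:
    """Per-node fraction of mapped neighbors and its decile histogram.

    Only connected nodes (degree >= 1) enter; isolated nodes have no
    neighborhood to speak of.  "At least half" is inclusive (fraction
    >= 0.5), and the 90-100%-unmapped bin is the closed interval
    [0.9, 1.0] of the unmapped-neighbor fraction.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("neighborhood coverage undefined: graph has no edges")
    fractions: dict[str, float] = {}
    for node in graph.nodes:
        neighbors = list(graph.neighbors(node))
        if not neighbors:
            continue
        fractions[node] = sum(labels.mapped[v] for v in neighbors) / len(neighbors)
    labels.neighborhood_fraction = fractions

    n_connected = len(fractions)
    share_half = sum(f >= 0.5 for f in fractions.values()) / n_connected
    share_any = sum(f > 0.0 for f in fractions.values()) / n_connected
    in_last_bin = [n for n, f in fractions.items() if (1.0 - f) >= 0.9]
    n_last = len(in_last_bin)
    n_last_self_unmapped = sum(not labels.mapped[n] for n in in_last_bin)

    unmapped_frac = np.array([1.0 - fractions[n] for n in fractions])
    own_mapped = np.array([labels.mapped[n] for n in fractions])
    hist_rows = []
    bins = np.clip(np.digitize(unmapped_frac, DECILE_EDGES[1:-1], right=True), 0, 9)
    for b in range(10):
        sel = bins == b
        hist_rows.append(
            {
                "bin_low": DECILE_EDGES[b],
                "bin_high": DECILE_EDGES[b + 1],
                "n_mapped": int(np.sum(sel & own_mapped)),
                "n_unmapped": int(np.sum(sel & ~own_mapped)),
                "n_total": int(np.sum(sel)),
            }
        )
    stats = NeighborhoodStats(
        n_connected=n_connected,
        share_half_neighbors_mapped=share_half,
        share_any_neighbor_mapped=share_any,
        n_bin_90_100_unmapped=n_last,
        n_bin_90_100_unmapped_self_unmapped=n_last_self_unmapped,
        histogram=pd.DataFrame(hist_rows),
    )
    return labels, stats


def load_annotated_gml(path: str | Path, mapped_attr: str = "mapped") -> tuple[nx.Graph, CoverageLabels]:
    """Load a pre-built compound graph whose nodes carry a mapped flag.

    Accepts boolean, 0/1 integer or "true"/"false" string attributes; a
    node lacking both the flag and a first block is treated as ambiguous
    (never mapped).
    """
    g = nx.read_gml(str(path))
    mapped: dict[str, bool] = {}
    basis: dict[str, str | None] = {}
    for node, data in g.nodes(data=True):
        basis[node] = data.get("first_block") or None
        raw = data.get(mapped_attr)
        if isinstance(raw, str):
            mapped[node] = raw.strip().lower() in {"1", "true", "yes", "mapped"}
        else:
            mapped[node] = bool(raw)
    return g, CoverageLabels(mapped=mapped, basis=basis)


def coverage_table(labels: CoverageLabels) -> pd.DataFrame:
    """Per-node TSV-ready table (mapped, first block, neighborhood fraction)."""
    rows = []
    for node in labels.mapped:
        rows.append(
            {
                "node": node,
                "mapped": labels.mapped[node],
                "first_block": labels.basis.get(node) or "",
                "neighborhood_fraction": labels.neighborhood_fraction.get(node, float("nan")),
            }
        )
    return pd.DataFrame(rows)
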