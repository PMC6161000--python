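"""End-to-end pipeline: libraries -> model -> graph -> coverage -> LPA ->
centrality -> literature, with all figure data emitted as TSV/JSON.

Reports are data, not rendered figures: every numeric summary written to
the report bundle is re-derivable from the per-node tables emitted next to
it.  A MANIFEST records the configuration, seeds, boundary conventions and
a checksum per output file, so two runs with the same config and seed can
be compared byte by byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .identifiers import (library_summary, load_library, merge_libraries,
                          write_merged_tsv)
from .model_ingest import (classification_summary, classify_entries,
                           merge_compartments, parse_model, resolve_identifiers)
from .compound_graph import (DEFAULT_BLACKLIST, build_graph, components,
                             read_gml, write_gml)
from .coverage import (coverage_summary, coverage_table, load_annotated_gml,
                       map_coverage, neighborhood_coverage)
from .community_lpa import (dark_subgraph, lpa_aggregate, lpa_table,
                            pathway_enrichment, prepare_lpa_input)
from .literature import attach_publications, literature_tests
from .topology import clustering_comparison, rank_dark_by_betweenness

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str
    #: either an SBML model or a pre-built compound graph (GML with a
    #: per-node ``mapped`` flag or ``first_block`` attributes)
    model: str | None = None
    graph_gml: str | None = None
    libraries: list[str] = field(default_factory=list)
    xref_tables: list[str] = field(default_factory=list)
    pathway_table: str | None = None
    pub_table: str | None = None
    node_cid_table: str | None = None
    blacklist: str | None = None
    atom_map: str | None = None
    #: stage toggles
    run_lpa: bool = True
    run_topology: bool = True
    run_literature: bool = True
    #: LPA parameters
    n_runs: int = 1000
    master_seed: int = 0
    include_self_vote: bool = False
    exclude_ambiguous: bool = True
    top_k: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if (self.model is None) == (self.graph_gml is None):
            raise ValueError("exactly one of model / graph_gml must be set")
        for label in ("model", "graph_gml", "pathway_table", "pub_table",
                      "node_cid_table", "blacklist", "atom_map"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{label}: {value}")
        for path in self.libraries + self.xref_tables:
            if not Path(path).exists():
                raise FileNotFoundError(path)


def _read_atom_map(path: str | Path) -> dict[tuple[str, str, str], int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        (r.reaction_id, r.substrate_id, r.product_id): int(r.shared_carbons)
        for r in df.itertuples(index=False)
    }


def _read_blacklist(path: str | Path) -> frozenset[str]:
    lines = Path(path).read_text().splitlines()
    return frozenset(
        l.strip().lower() for l in lines if l.strip() and not l.startswith("#")
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; return the MANIFEST dict.

    Any stage failure aborts with :class:`PipelineError` naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"metnetcov {__version__}",
        "config": dataclasses.asdict(config),
        "conventions": {
            "matching": "InChIKey first block",
            "neighbor_half_covered": "fraction >= 0.5 inclusive",
            "bin_90_100_unmapped": "unmapped-neighbor fraction in [0.9, 1.0] inclusive",
            "lpa_vote": "pure neighbor vote" if not config.include_self_vote else "self vote included",
            "lpa_aggregate_tie": "tie (vote 0.5) keeps the initial label",
            "lpa_scope": "all components, isolated nodes excluded",
            "shared_carbons": "atom map when provided, else min(C_u, C_v) heuristic",
            "betweenness": "unweighted, full graph; ranking restricted to dark area",
        },
        "stages": {},
    }
    stage_times: dict[str, float] = {}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                stage_times[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
        return _Timer()

    # --- libraries --------------------------------------------------------
    merged = None
    if config.libraries:
        with _stage("merge_libraries"):
            libs = [load_library(p) for p in config.libraries]
            merged = merge_libraries(libs)
            write_merged_tsv(merged, outdir / "merged_library.tsv")
            summary = library_summary(libs, merged)
            (outdir / "library_summary.json").write_text(json.dumps(summary, indent=2))
            manifest["stages"]["merge_libraries"] = summary["merged"]

    # --- model / graph ----------------------------------------------------
    labels = None
    if config.model is not None:
        with _stage("ingest_model"):
            model = parse_model(config.model)
            model = resolve_identifiers(model, config.xref_tables)
            model = classify_entries(model)
            model = merge_compartments(model)
            summary = classification_summary(model)
            (outdir / "classification_summary.json").write_text(json.dumps(summary, indent=2))
            manifest["stages"]["ingest_model"] = summary
        with _stage("build_graph"):
            blacklist = (_read_blacklist(config.blacklist)
                         if config.blacklist else DEFAULT_BLACKLIST)
            atom_map = _read_atom_map(config.atom_map) if config.atom_map else None
            graph = build_graph(model, blacklist, atom_map)
            write_gml(graph, outdir / "compound_graph.gml")
            comp_sizes = [len(c) for c in components(graph)]
            manifest["stages"]["build_graph"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "component_sizes": comp_sizes[:20],
                "atom_map": config.atom_map is not None,
            }
    else:
        with _stage("load_graph"):
            graph, labels = load_annotated_gml(config.graph_gml)
            manifest["stages"]["load_graph"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
            }

    # --- coverage ---------------------------------------------------------
    with _stage("coverage"):
        if labels is None:
            if merged is None:
                raise ValueError("coverage from a model requires libraries")
            labels = map_coverage(graph, merged)
        summ = coverage_summary(graph, labels)
        labels, nstats = neighborhood_coverage(graph, labels)
        coverage_table(labels).to_csv(outdir / "coverage_per_node.tsv", sep="\t", index=False)
        nstats.histogram.to_csv(outdir / "neighborhood_histogram.tsv", sep="\t", index=False)
        manifest["stages"]["coverage"] = {
            **summ.as_dict(),
            "n_connected": nstats.n_connected,
            "share_half_neighbors_mapped": nstats.share_half_neighbors_mapped,
            "share_any_neighbor_mapped": nstats.share_any_neighbor_mapped,
            "n_bin_90_100_unmapped": nstats.n_bin_90_100_unmapped,
            "n_bin_90_100_unmapped_self_unmapped": nstats.n_bin_90_100_unmapped_self_unmapped,
        }

    # --- LPA --------------------------------------------------------------
    result = None
    if config.run_lpa:
        with _stage("lpa"):
            lpa_graph, initial = prepare_lpa_input(
                graph, labels, exclude_ambiguous=config.exclude_ambiguous
            )
            result = lpa_aggregate(
                lpa_graph, initial, n_runs=config.n_runs,
                master_seed=config.master_seed,
                include_self_vote=config.include_self_vote,
            )
            lpa_table(result).to_csv(outdir / "lpa_per_node.tsv", sep="\t", index=False)
            dark, comps, frac = dark_subgraph(result, lpa_graph)
            write_gml(dark, outdir / "dark_subgraph.gml")
            manifest["stages"]["lpa"] = {
                "n_runs": config.n_runs,
                "master_seed": config.master_seed,
                "n_analysed": len(result.aggregate),
                "n_dark": len(result.dark_nodes),
                "dark_fraction": frac,
                "dark_component_sizes": [len(c) for c in comps][:20],
            }
            if config.pathway_table:
                pathways = pd.read_csv(config.pathway_table, sep="\t")
                rows = pathway_enrichment(
                    result.dark_nodes, pathways, set(result.aggregate)
                )
                pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
                    outdir / "pathway_enrichment.tsv", sep="\t", index=False
                )
                manifest["stages"]["lpa"]["n_pathways_q05"] = sum(
                    r.q_value <= 0.05 for r in rows
                )

    # --- topology ---------------------------------------------------------
    if config.run_topology:
        if result is None:
            raise PipelineError("topology", ValueError("requires the lpa stage (run_lpa=true)"))
        with _stage("topology"):
            ranking = rank_dark_by_betweenness(lpa_graph, result, k=config.top_k)
            ranking.to_csv(outdir / "dark_betweenness_topk.tsv", sep="\t", index=False)
            comparison = clustering_comparison(lpa_graph, result)
            comparison.per_node.to_csv(outdir / "clustering_per_node.tsv", sep="\t", index=False)
            comparison.summary.to_csv(outdir / "clustering_summary.tsv", sep="\t", index=False)
            means = comparison.per_node.groupby("area")["local_clustering"].mean()
            manifest["stages"]["topology"] = {
                "top_k": int(len(ranking)),
                "mean_clustering": {k: float(v) for k, v in means.items()},
                "edges_within_covered": comparison.edges_within_covered,
                "edges_within_dark": comparison.edges_within_dark,
                "edges_between": comparison.edges_between,
            }

    # --- literature -------------------------------------------------------
    if config.run_literature and config.pub_table and config.node_cid_table:
        with _stage("literature"):
            cids = pd.read_csv(config.node_cid_table, sep="\t")
            cid_map = {
                str(r.node): (int(r.cid) if pd.notna(r.cid) else None)
                for r in cids.itertuples(index=False)
            }
            cid_map = {n: c for n, c in cid_map.items() if n in labels.mapped}
            records = attach_publications(cid_map, config.pub_table)
            report = literature_tests(records, labels)
            (outdir / "literature_report.json").write_text(json.dumps(report, indent=2))
            manifest["stages"]["literature"] = {
                "wilcoxon_p": report["wilcoxon"]["p_value"],
                "fisher_p": report["fisher"]["p_value"],
            }

    manifest["stage_seconds"] = stage_times
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "MANIFEST.json"
    }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
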