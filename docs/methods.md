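# Methods

## Chemical identity and library merging

All matching between spectral libraries and network metabolites uses the
first block of the InChIKey: 14 uppercase letters hashing molecular
connectivity only.  Stereoisomers, protonation states and charge variants
share a first block; since a typical MS experiment cannot distinguish
them either, first-block identity is the right granularity for coverage
questions, at the cost of occasionally conflating tautomers whose InChIs
differ (e.g. cyclic vs open-chain monosaccharide representations).
Libraries are plain one-key-per-line text; keys are upper-cased before
validation (lowercase keys in the wild are treated as typos), lines
failing the `14-10-1` layout are counted and skipped rather than fatal
(real exports contain header junk), and a file with no valid key is an
error.  The merged index keeps per-block provenance (which libraries
contributed it); merging is a set union, hence order-invariant and
idempotent.

## Model ingestion

SBML Level 2/3 models are read with libsbml.  Cross-references are
harvested from MIRIAM RDF annotations and from Recon-style notes fields
(`FORMULA:`, `INCHIKEY:`, `HMDB:` ...), because genome-scale models stash
identifiers in both places.  Local TSV tables (source_db, source_id,
inchikey, formula) stand in for web-service resolution; an entry acquires
an InChIKey through any reference it carries.  When sources disagree on
the first block the winner follows a fixed priority — model-native >
ChEBI > HMDB > PubChem > KEGG — on the grounds that native annotations
were curated together with the model; conflicts are logged.

Every entry receives exactly one status.  Precedence: *generic* (R/X
tokens in the formula, or names like "an alcohol" — configurable
patterns, since no canonical detection rule exists) > *macromolecule*
(carbon count above a configurable threshold, default 200: beyond any
plausible metabolomics mass range) > *structure_resolved* (valid
InChIKey) > *no_xref* (no reference at all; such entries cannot be
resolved even in principle and are dropped downstream) >
*ambiguous_denomination* (some reference, no resolvable structure).

Compartment merging collapses entries sharing a first block (or, for
unresolved entries, the compartment-stripped id) into one node, so
protonation-state and stereoisomer duplicates disappear together with
compartment copies; reactions are rewritten onto merged ids and pure
transport reactions, which become self-loops, are dropped.  The operation
is idempotent and never increases the node count.

## Compound graph

Nodes are structure-resolved metabolites with ≥ 1 carbon; ambiguous
entries are kept as nodes (they participate in reactions) but flagged
unmappable.  For every reaction, each substrate–product pair is a
candidate edge, retained iff it conserves at least one carbon atom.
Shared-carbon counts come from an atom-mapping table when the user
supplies one; otherwise the fallback estimate is `min(C_u, C_v)`, under
which retention reduces to "both endpoints carry carbon".  The fallback
is recorded in the output metadata — edge weights under it are an upper
bound, which is why all downstream analyses (LPA, betweenness, clustering)
deliberately treat the graph as unweighted.  A small editable blacklist
(CO₂, bicarbonate, carbonate, CO, cyanide) removes inorganic carbonated
species the carbon rule alone would keep.  Reaction direction is ignored
throughout; parallel candidates collapse into one edge keeping the
maximum weight and the union of reaction provenance.  GML is the exchange
format for built graphs.

## Coverage statistics

A node is mapped when its first block is in the merged index; nodes
without a first block are never mapped and are counted as a separate
*ambiguous* category.  Coverage percentages are emitted against two
denominators (all entries, and entries carrying an InChIKey) because both
are in common use.  Neighborhood coverage — the fraction of a node's
neighbors that are mapped — is defined exactly for nodes of degree ≥ 1;
isolated nodes are excluded from all neighborhood statistics.  Boundary
conventions, also written into every MANIFEST: "at least half mapped"
means fraction ≥ 0.5 inclusive; the "90–100% unmapped" summary bin is the
closed interval [0.9, 1.0] of the unmapped-neighbor fraction (the decile
histogram's last bin is (0.9, 1.0], so the two can differ by nodes at
exactly 0.9).

## Two-label label propagation

Initial labels are the mapped/unmapped states.  One run performs
asynchronous sweeps: a fresh uniformly random node order per sweep, each
node adopting the strict majority label among its neighbors, exact ties
broken uniformly at random.  The node's own label does not vote (pure
neighbor vote, the original LPA formulation; switchable).  Termination
uses the stability criterion — every connected node's label is among the
(possibly tied) majority labels of its neighborhood — rather than a
label fixed point, which random tie-breaking might never reach; a
1000-sweep cap guards pathological cases with a logged warning.  Isolated
nodes keep their initial label, and ambiguous-identifier nodes are
removed before propagation by default: their uncovered status is an
artifact of annotation, not of spectral coverage, and carries no signal.
Propagation runs on all components, not only the largest.

Because one run depends on order and tie resolution, the final assignment
aggregates `n_runs` (default 1000) independent runs whose seeds are
spawned deterministically from a master seed: a node is covered when more
than half the runs say so, and an exact 50/50 vote falls back to the
node's initial label (no evidence, no flip).  The uncovered nodes form
the dark area; its induced subgraph, component sizes and fraction of the
analysed nodes are reported.  Pathway overrepresentation in the dark area
uses one-sided (greater) Fisher exact tests on the 2×2 membership table
per pathway, Benjamini–Hochberg-corrected across pathways, significance
at q ≤ 0.05.

## Prioritization and literature statistics

Betweenness is exact unweighted Brandes centrality computed on the full
analysed graph; only the *ranking* is restricted to dark nodes, since a
dark metabolite's bridging role is defined by the whole network.  Raw
pair counts and `2/((n−1)(n−2))`-normalized values are both emitted (the
ranking is identical); ties break by node id for determinism.  The
clustering comparison reports local clustering coefficients per area on
the largest component only, plus the within/between-area edge counts.

Publication counts join nodes to a local (CID → article count) table;
nodes without a CID or without a table entry are excluded and counted.
Two tests, two-sided by default since sidedness is configurable: a
Wilcoxon rank-sum comparison of counts between mapped and unmapped
metabolites restricted to those with ≥ 1 article (exact permutation
enumeration over pooled mid-ranks when the number of group assignments is
≤ 20 000 — exact even under ties — else normal approximation with tie and
continuity correction), and a Fisher exact test of (has ≥ 1 article) ×
(mapped), with per-cell Pearson residuals `(obs − exp)/√exp` whose
squares sum to the chi-squared statistic.

## Synthetic data generator

The generator plants the structure the pipeline is meant to find.  Two
blocks — 80 "covered-regime" nodes and a 20-node dark block — each get a
uniform random spanning tree (guaranteeing within-block connectivity)
plus independent extra edges: `p_in_covered = 0.06` (mean degree ≈ 6.6,
modest clustering), `p_in_dark = 0.03` (mean degree ≈ 2.5, near-tree,
low clustering), `p_between = 0.001` (1–2 bridge edges, minimum one so
the graph stays connected).  These densities realize a sparse,
low-clustering dark region that is nearly disconnected from the rest —
the regime in which a planted low-coverage block is detectable at all
(`p_between ≪ p_in`).  Library membership is Bernoulli per node at
`cover_rate_main = 0.7` vs `cover_rate_dark = 0.1`; 10% of nodes are made
ambiguous (an unresolvable KEGG-style reference instead of an InChIKey);
publication counts are log-normal with class-dependent location
(meanlog 4.0 mapped vs 2.0 unmapped, sdlog 1.5) plus an atom at zero
(5% / 30%) and 7% of nodes lack a CID entirely.  Every intended edge is
emitted as a two-substrate/two-product SBML reaction sharing a carbon-free
cofactor pair, so ingestion plus the carbon filter must reproduce exactly
the intended edge set.  An optional mode routes all inter-block edges
through a single designated dark node, creating a planted bridge that
must top the betweenness prioritization.

The generator does **not** emulate real stoichiometry, hub cofactors,
overlapping pathways, or chemically meaningful identifiers.  Recovery
results on it show that the pipeline correctly detects a sparse planted
low-coverage region under its own model assumptions — not that real
metabolic dark areas have this structure.

## Numerical and reproducibility choices

LPA run seeds are spawned from the master seed via `SeedSequence`, so an
aggregated result is a pure function of (graph, initial labels, n_runs,
master_seed).  The pipeline MANIFEST records configuration, conventions,
per-stage timings and SHA-256 checksums of every emitted file; two runs
with identical config and seed produce identical checksums.  Tests
compare LPA behavior against an exact Markov-chain enumeration of sweep
outcomes on small fixtures, betweenness against exhaustive simple-path
enumeration on graphs of ≤ 8 nodes, and Fisher/Wilcoxon p-values against
hypergeometric summation and full permutation enumeration respectively.
Planted-recovery checks use 100-node instances, 1000-run aggregation and
10–20 generator seeds, sizes at which results are stable while the whole
suite stays fast.

## Known limitations

- Without an atom-mapping table, the min-carbon heuristic can retain
  substrate–product pairs that share no actual atoms (e.g. glucose–ADP in
  a kinase reaction); supplying curated mappings is the fix, and the
  hexokinase fixture in the tests demonstrates the difference.
- First-block identity conflates tautomers with distinct first blocks in
  the opposite direction (missed matches) and cannot rescue entries whose
  only identifier is a name.
- The published human-network statistics can only be reproduced against
  the original study's distributed compound graph, which this package
  does not bundle; the corresponding tests state this explicitly when the
  file is absent.
- LPA with majority voting has no resolution parameter: very small
  uncovered pockets inside a well-covered region are (by design) absorbed
  into the covered community.
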