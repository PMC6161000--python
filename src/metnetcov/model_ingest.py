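"""Metabolic-model ingestion: SBML parsing, identifier resolution,
entry classification and compartment merging.

A genome-scale metabolic model arrives as SBML with one species per
metabolite *per compartment*.  This module turns it into a single
cell-scale model in which each chemical structure appears once: species
annotations (MIRIAM URIs and Recon-style notes fields) are harvested into
cross-references, InChIKeys are attached from local cross-reference tables,
every entry is classified by how well its structure is defined, and
compartment duplicates are collapsed on the InChIKey first block.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .identifiers import InChIKeyError, parse_key

__all__ = [
    "Status",
    "MetaboliteEntry",
    "ReactionEntry",
    "MetabolicModel",
    "parse_model",
    "resolve_identifiers",
    "classify_entries",
    "merge_compartments",
    "XREF_PRIORITY",
]

log = logging.getLogger(__name__)

#: Sources ordered by trust when two tables disagree on the first block.
#: Model-native annotations were curated together with the model and win.
XREF_PRIORITY: tuple[str, ...] = ("native", "chebi", "hmdb", "pubchem", "kegg")

#: Default textual markers of generic (R-group / compound-class) entries.
GENERIC_FORMULA_TOKENS: tuple[str, ...] = ("R", "X")
GENERIC_NAME_PATTERNS: tuple[str, ...] = (r"\(generic\)", r"^an? [a-z]")

#: Entries with more carbons than this are treated as macromolecules.
MACROMOLECULE_CARBON_THRESHOLD = 200


class Status(str, Enum):
    """Annotation-status class of a model entry (exhaustive, exclusive)."""

    STRUCTURE_RESOLVED = "structure_resolved"
    AMBIGUOUS_DENOMINATION = "ambiguous_denomination"
    MACROMOLECULE = "macromolecule"
    GENERIC = "generic"
    NO_XREF = "no_xref"


@dataclass
class MetaboliteEntry:
    model_id: str
    name: str = ""
    compartment: str = ""
    xrefs: dict[str, str] = field(default_factory=dict)
    formula: str | None = None
    carbon_count: int | None = None
    status: Status | None = None
    #: model ids collapsed into this entry by merge_compartments
    members: tuple[str, ...] = ()

    @property
    def first_block(self) -> str | None:
        key = self.xrefs.get("inchikey")
        if key is None:
            return None
        try:
            return parse_key(key).first_block
        except InChIKeyError:
            return None


@dataclass
class ReactionEntry:
    reaction_id: str
    substrates: list[str]
    products: list[str]
    reversible: bool = True


@dataclass
class MetabolicModel:
    metabolites: list[MetaboliteEntry]
    reactions: list[ReactionEntry]
    merged: bool = False
    name: str = ""

    def entry(self, model_id: str) -> MetaboliteEntry:
        return self._index()[model_id]

    def _index(self) -> dict[str, MetaboliteEntry]:
        return {m.model_id: m for m in self.metabolites}


# --- SBML parsing ---------------------------------------------------------

# MIRIAM URI fragments -> xref source names
_MIRIAM_PATTERNS = {
    "chebi": re.compile(r"chebi[/:](CHEBI[:%3A]*\d+|\d+)", re.I),
    "hmdb": re.compile(r"hmdb[/:](HMDB\d+)", re.I),
    "kegg": re.compile(r"kegg\.compound[/:]([A-Z]\d{5})", re.I),
    "pubchem": re.compile(r"pubchem\.compound[/:](\d+)", re.I),
    "inchikey": re.compile(r"inchikey[/:]([A-Z]{14}-[A-Z]{10}-[A-Z])", re.I),
}
_INCHI_RE = re.compile(r"(InChI=1S?/[^\s<\"]+)")
# Recon-style "<p>FORMULA: C6H12O6</p>" notes lines
_NOTES_FIELD_RE = re.compile(r"([A-Z ]+?):\s*([^<\n]+)")


def _harvest_xrefs(annotation_xml: str, notes_xml: str) -> tuple[dict[str, str], str | None]:
    """Extract cross-references and an elemental formula from SBML blobs."""
    xrefs: dict[str, str] = {}
    formula: str | None = None
    for source, pat in _MIRIAM_PATTERNS.items():
        m = pat.search(annotation_xml)
        if m:
            xrefs[source] = m.group(1)
    m = _INCHI_RE.search(annotation_xml + " " + notes_xml)
    if m:
        xrefs["inchi"] = m.group(1)
    for key, value in _NOTES_FIELD_RE.findall(notes_xml):
        key = key.strip().upper()
        value = value.strip()
        if not value or value.lower() in {"none", "na"}:
            continue
        if key == "FORMULA":
            formula = value
        elif key == "INCHIKEY":
            xrefs.setdefault("inchikey", value)
        elif key == "INCHI":
            xrefs.setdefault("inchi", value)
        elif key == "CHEBI":
            xrefs.setdefault("chebi", value)
        elif key == "HMDB":
            xrefs.setdefault("hmdb", value)
        elif key in {"KEGG", "KEGGID", "KEGG ID"}:
            xrefs.setdefault("kegg", value)
        elif key in {"PUBCHEM", "PUBCHEM CID", "PUBCHEMID"}:
            xrefs.setdefault("pubchem", value)
    return xrefs, formula


def parse_model(path: str | Path, name: str | None = None) -> MetabolicModel:
    """Parse an SBML Level 2/3 document into a :class:`MetabolicModel`.

    One :class:`MetaboliteEntry` per species (boundary species included;
    they fall out later via classification), one :class:`ReactionEntry` per
    reaction.  MIRIAM RDF annotations and Recon-style notes fields are both
    harvested.  A document with no reactions is rejected.
    """
    import libsbml

    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ValueError(f"invalid SBML in {path}: {first.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"{path} contains no SBML model")
    if sbml_model.getNumReactions() == 0:
        raise ValueError(f"{path}: model has zero reactions")

    entries: list[MetaboliteEntry] = []
    for sp in sbml_model.getListOfSpecies():
        ann = sp.getAnnotationString() if sp.isSetAnnotation() else ""
        notes = sp.getNotesString() if sp.isSetNotes() else ""
        xrefs, formula = _harvest_xrefs(ann, notes)
        # FBC package carries formulas on species plugins in L3 models
        fbc = sp.getPlugin("fbc")
        if formula is None and fbc is not None and fbc.isSetChemicalFormula():
            formula = fbc.getChemicalFormula()
        entries.append(
            MetaboliteEntry(
                model_id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment(),
                xrefs=xrefs,
                formula=formula,
            )
        )

    reactions: list[ReactionEntry] = []
    for rxn in sbml_model.getListOfReactions():
        subs = [ref.getSpecies() for ref in rxn.getListOfReactants()]
        prods = [ref.getSpecies() for ref in rxn.getListOfProducts()]
        if not subs or not prods:
            continue  # exchange/sink pseudo-reactions carry no transition
        reactions.append(
            ReactionEntry(
                reaction_id=rxn.getId(),
                substrates=subs,
                products=prods,
                reversible=rxn.getReversible(),
            )
        )
    if not reactions:
        raise ValueError(f"{path}: no reaction with both substrates and products")
    return MetabolicModel(
        metabolites=entries, reactions=reactions, name=name or sbml_model.getId()
    )


# --- identifier resolution ------------------------------------------------

def read_xref_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV cross-reference table (source_db, source_id, inchikey[, formula])."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"source_db", "source_id", "inchikey"}
    if not required.issubset(df.columns):
        raise ValueError(f"xref table {path} lacks columns {required - set(df.columns)}")
    df["source_db"] = df["source_db"].str.lower()
    return df


def resolve_identifiers(
    model: MetabolicModel,
    tables: Sequence[pd.DataFrame | str | Path] = (),
) -> MetabolicModel:
    """Attach InChIKeys transitively through any cross-reference carried.

    Local tables stand in for the PubChem/HMDB/ChEBI lookups: each maps a
    source identifier to an InChIKey (and optionally a formula).  When two
    sources disagree on the first block, the winner follows
    :data:`XREF_PRIORITY` and the conflict is logged.
    """
    frames = [t if isinstance(t, pd.DataFrame) else read_xref_table(t) for t in tables]
    lookup: dict[tuple[str, str], tuple[str, str | None]] = {}
    for df in frames:
        for row in df.itertuples(index=False):
            formula = getattr(row, "formula", "") or None
            lookup[(row.source_db, str(row.source_id))] = (row.inchikey, formula)

    n_conflicts = 0
    for entry in model.metabolites:
        # candidates in priority order: native annotation first
        candidates: list[tuple[str, str, str | None]] = []
        if "inchikey" in entry.xrefs:
            candidates.append(("native", entry.xrefs["inchikey"], None))
        for source in XREF_PRIORITY[1:]:
            sid = entry.xrefs.get(source)
            if sid is None:
                continue
            hit = lookup.get((source, sid))
            if hit is not None:
                candidates.append((source, hit[0], hit[1]))
        valid = []
        for source, key, formula in candidates:
            try:
                valid.append((source, parse_key(key), formula))
            except InChIKeyError:
                log.warning("%s: unparseable InChIKey %r from %s", entry.model_id, key, source)
        if not valid:
            continue
        blocks = {k.first_block for _, k, _ in valid}
        if len(blocks) > 1:
            n_conflicts += 1
            log.info(
                "%s: conflicting first blocks %s; keeping %s per priority",
                entry.model_id, sorted(blocks), valid[0][0],
            )
        source, key, formula = valid[0]
        entry.xrefs["inchikey"] = key.full_key
        if entry.formula is None and formula:
            entry.formula = formula
    if n_conflicts:
        log.info("resolve_identifiers: %d first-block conflicts resolved by priority", n_conflicts)
    return model


# --- classification -------------------------------------------------------

def _looks_generic(entry: MetaboliteEntry,
                   formula_tokens: tuple[str, ...],
                   name_patterns: tuple[str, ...]) -> bool:
    if entry.formula:
        # an R/X token in a formula marks an undefined substituent
        tokens = re.findall(r"[A-Z][a-z]?", entry.formula)
        if any(t in formula_tokens for t in tokens):
            return True
    return any(re.search(p, entry.name) for p in name_patterns)


def classify_entries(
    model: MetabolicModel,
    *,
    generic_formula_tokens: tuple[str, ...] = GENERIC_FORMULA_TOKENS,
    generic_name_patterns: tuple[str, ...] = GENERIC_NAME_PATTERNS,
    macro_carbon_threshold: int = MACROMOLECULE_CARBON_THRESHOLD,
) -> MetabolicModel:
    """Assign exactly one :class:`Status` to every entry.

    Order of precedence: generic (R-group markers) > macromolecule (carbon
    count above threshold) > structure_resolved (valid InChIKey) >
    no_xref (no cross-reference at all) > ambiguous_denomination (has some
    reference but no resolvable structure).
    """
    from .compound_graph import carbon_count

    for entry in model.metabolites:
        if entry.carbon_count is None:
            source = entry.formula or entry.xrefs.get("inchi")
            if source:
                entry.carbon_count = carbon_count(source)
        if _looks_generic(entry, generic_formula_tokens, generic_name_patterns):
            entry.status = Status.GENERIC
        elif entry.carbon_count is not None and entry.carbon_count > macro_carbon_threshold:
            entry.status = Status.MACROMOLECULE
        elif entry.first_block is not None:
            entry.status = Status.STRUCTURE_RESOLVED
        elif not entry.xrefs:
            entry.status = Status.NO_XREF
        else:
            entry.status = Status.AMBIGUOUS_DENOMINATION
    return model


# --- compartment merging --------------------------------------------------

_COMPARTMENT_SUFFIX = re.compile(r"(\[[a-z]{1,3}\]|_[a-z]{1,3})$", re.I)


def strip_compartment(model_id: str) -> str:
    """Drop a trailing ``[c]`` / ``_c`` style compartment tag."""
    return _COMPARTMENT_SUFFIX.sub("", model_id)


def merge_compartments(model: MetabolicModel) -> MetabolicModel:
    """Collapse compartment duplicates into one cell-scale model.

    Identity is the InChIKey first block when available (so protonation
    states and stereoisomer entries sharing a block collapse too), else the
    compartment-stripped model id.  Reactions are rewritten onto merged ids
    and transport reactions that become self-loops are dropped.  Idempotent.
    """
    if model.merged:
        return model
    groups: dict[str, list[MetaboliteEntry]] = {}
    for entry in model.metabolites:
        identity = entry.first_block or strip_compartment(entry.model_id)
        groups.setdefault(identity, []).append(entry)

    merged_entries: list[MetaboliteEntry] = []
    id_map: dict[str, str] = {}
    for identity, members in groups.items():
        rep = members[0]
        # prefer a structure-resolved representative for attributes
        for m in members:
            if m.first_block is not None:
                rep = m
                break
        new_id = rep.first_block or strip_compartment(rep.model_id)
        merged = replace(
            rep,
            model_id=new_id,
            compartment="",
            members=tuple(sorted(m.model_id for m in members)),
        )
        merged.xrefs = dict(rep.xrefs)
        merged_entries.append(merged)
        for m in members:
            id_map[m.model_id] = new_id

    merged_reactions: list[ReactionEntry] = []
    for rxn in model.reactions:
        subs = [id_map[s] for s in rxn.substrates if s in id_map]
        prods = [id_map[p] for p in rxn.products if p in id_map]
        if not subs or not prods:
            continue
        if set(subs) == set(prods):
            continue  # pure transport: same species on both sides after merge
        merged_reactions.append(
            ReactionEntry(rxn.reaction_id, subs, prods, rxn.reversible)
        )
    return MetabolicModel(
        metabolites=merged_entries,
        reactions=merged_reactions,
        merged=True,
        name=model.name,
    )


def classification_summary(model: MetabolicModel) -> dict[str, int]:
    counts: dict[str, int] = {s.value: 0 for s in Status}
    for entry in model.metabolites:
        if entry.status is not None:
            counts[entry.status.value] += 1
    counts["total"] = len(model.metabolites)
    return counts
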