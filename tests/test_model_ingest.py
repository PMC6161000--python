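from __future__ import annotations

import pandas as pd
import pytest

from metnetcov.model_ingest import (MetabolicModel, ReactionEntry, Status,
                                    classify_entries, merge_compartments,
                                    parse_model, resolve_identifiers,
                                    strip_compartment)
from conftest import make_entry

TOY_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
 <model id="toy">
  <listOfCompartments>
   <compartment id="c"/><compartment id="e"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="glc_c" name="glucose" compartment="c">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
      <p>FORMULA: C6H12O6</p><p>INCHIKEY: WQZGKKKJIJFFOK-GASJEMHNSA-N</p>
    </body></notes>
   </species>
   <species id="glc_e" name="glucose" compartment="e">
    <notes><body xmlns="http://www.w3.org/1999/xhtml">
      <p>FORMULA: C6H12O6</p><p>INCHIKEY: WQZGKKKJIJFFOK-GASJEMHNSA-N</p>
    </body></notes>
   </species>
   <species id="pyr_c" name="pyruvate" compartment="c">
    <notes><body xmlns="http://www.w3.org/1999/xhtml"><p>FORMULA: C3H4O3</p></body></notes>
    <annotation><rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
      xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
     <rdf:Description rdf:about="#pyr_c"><bqbiol:is><rdf:Bag>
      <rdf:li rdf:resource="http://identifiers.org/chebi/CHEBI:15361"/>
     </rdf:Bag></bqbiol:is></rdf:Description></rdf:RDF></annotation>
   </species>
   <species id="lac_c" name="lactate" compartment="c">
    <notes><body xmlns="http://www.w3.org/1999/xhtml"><p>FORMULA: C3H6O3</p>
      <p>HMDB: HMDB0000190</p></body></notes>
   </species>
   <species id="h2o_c" name="water" compartment="c">
    <notes><body xmlns="http://www.w3.org/1999/xhtml"><p>FORMULA: H2O</p>
      <p>KEGG: C00001</p></body></notes>
   </species>
   <species id="mystery_c" name="orphan compound" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="GLCt" reversible="true">
    <listOfReactants><speciesReference species="glc_e"/></listOfReactants>
    <listOfProducts><speciesReference species="glc_c"/></listOfProducts>
   </reaction>
   <reaction id="LDH" reversible="true">
    <listOfReactants><speciesReference species="pyr_c"/></listOfReactants>
    <listOfProducts><speciesReference species="lac_c"/></listOfProducts>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


@pytest.fixture
def toy_model_path(tmp_path):
    p = tmp_path / "toy.xml"
    p.write_text(TOY_SBML)
    return p


class TestParseModel:
    def test_counts_and_compartments(self, toy_model_path):
        model = parse_model(toy_model_path)
        assert len(model.metabolites) == 6
        assert len(model.reactions) == 2
        assert {m.compartment for m in model.metabolites} == {"c", "e"}

    def test_notes_and_miriam_harvested(self, toy_model_path):
        model = parse_model(toy_model_path)
        glc = model.entry("glc_c")
        assert glc.formula == "C6H12O6"
        assert glc.xrefs["inchikey"] == "WQZGKKKJIJFFOK-GASJEMHNSA-N"
        pyr = model.entry("pyr_c")
        assert "chebi" in pyr.xrefs and "inchikey" not in pyr.xrefs

    def test_invalid_xml_rejected(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<sbml><unclosed>")
        with pytest.raises(ValueError):
            parse_model(p)

    def test_zero_reactions_rejected(self, tmp_path):
        p = tmp_path / "norxn.xml"
        p.write_text(TOY_SBML.replace(
            TOY_SBML[TOY_SBML.index("<listOfReactions>"):
                     TOY_SBML.index("</listOfReactions>") + len("</listOfReactions>")],
            ""))
        with pytest.raises(ValueError):
            parse_model(p)


XREF_TABLE = pd.DataFrame(
    [
        {"source_db": "chebi", "source_id": "CHEBI:15361",
         "inchikey": "LCTONWCANYUPML-UHFFFAOYSA-N", "formula": "C3H4O3"},
        {"source_db": "hmdb", "source_id": "HMDB0000190",
         "inchikey": "JVTAAEKCZFNVCJ-UHFFFAOYSA-N", "formula": "C3H6O3"},
    ]
)


class TestResolveIdentifiers:
    def test_attach_through_any_xref(self, toy_model_path):
        model = resolve_identifiers(parse_model(toy_model_path), [XREF_TABLE])
        assert model.entry("pyr_c").first_block == "LCTONWCANYUPML"
        assert model.entry("lac_c").first_block == "JVTAAEKCZFNVCJ"

    def test_conflict_resolved_by_priority(self):
        entry = make_entry("m", "metab", "C2H6O", chebi="CHEBI:1", hmdb="HMDB1")
        tables = [
            pd.DataFrame([{"source_db": "hmdb", "source_id": "HMDB1",
                           "inchikey": "B" * 14 + "-AAAAAAAAAA-N", "formula": ""}]),
            pd.DataFrame([{"source_db": "chebi", "source_id": "CHEBI:1",
                           "inchikey": "A" * 14 + "-AAAAAAAAAA-N", "formula": ""}]),
        ]
        model = MetabolicModel([entry], [ReactionEntry("r", ["m"], ["m"])])
        resolve_identifiers(model, tables)
        # chebi outranks hmdb regardless of table order
        assert entry.first_block == "A" * 14

    def test_native_key_wins(self):
        entry = make_entry("m", "metab", "C2H6O",
                           inchikey="C" * 14 + "-AAAAAAAAAA-N", chebi="CHEBI:1")
        table = pd.DataFrame([{"source_db": "chebi", "source_id": "CHEBI:1",
                               "inchikey": "A" * 14 + "-AAAAAAAAAA-N", "formula": ""}])
        resolve_identifiers(MetabolicModel([entry], []), [table])
        assert entry.first_block == "C" * 14


class TestClassify:
    def test_examples(self, toy_model_path):
        model = classify_entries(resolve_identifiers(parse_model(toy_model_path), [XREF_TABLE]))
        assert model.entry("glc_c").status is Status.STRUCTURE_RESOLVED
        assert model.entry("mystery_c").status is Status.NO_XREF
        assert model.entry("h2o_c").status is Status.AMBIGUOUS_DENOMINATION

    def test_generic_and_macromolecule(self):
        generic = make_entry("g", "an alcohol", "CH3R")
        macro = make_entry("p", "glycogen", "C2400H4000O2000",
                           inchikey="A" * 14 + "-AAAAAAAAAA-N")
        model = classify_entries(MetabolicModel([generic, macro], []))
        assert generic.status is Status.GENERIC
        assert macro.status is Status.MACROMOLECULE

    def test_exhaustive_and_exclusive(self, toy_model_path):
        model = classify_entries(parse_model(toy_model_path))
        assert all(isinstance(m.status, Status) for m in model.metabolites)


class TestMergeCompartments:
    def test_duplicates_collapse_and_transport_dropped(self, toy_model_path):
        model = merge_compartments(classify_entries(
            resolve_identifiers(parse_model(toy_model_path), [XREF_TABLE])))
        ids = {m.model_id for m in model.metabolites}
        # the two glucose species collapse onto their shared first block
        assert "WQZGKKKJIJFFOK" in ids
        glc = model.entry("WQZGKKKJIJFFOK")
        assert set(glc.members) == {"glc_c", "glc_e"}
        # the transport reaction became a self-loop and was dropped
        assert {r.reaction_id for r in model.reactions} == {"LDH"}

    def test_idempotent_and_never_grows(self, toy_model_path):
        model = classify_entries(parse_model(toy_model_path))
        once = merge_compartments(model)
        twice = merge_compartments(once)
        assert len(once.metabolites) <= len(model.metabolites)
        assert {m.model_id for m in twice.metabolites} == {m.model_id for m in once.metabolites}
        assert len(twice.reactions) == len(once.reactions)

    def test_reactions_reference_existing_ids(self, toy_model_path):
        model = merge_compartments(classify_entries(parse_model(toy_model_path)))
        ids = {m.model_id for m in model.metabolites}
        for rxn in model.reactions:
            assert set(rxn.substrates) <= ids and set(rxn.products) <= ids

    def test_stereoisomers_share_block_collapse(self):
        a = make_entry("d_ala_c", "D-alanine", "C3H7NO2", "QNAYBMKLOCPYGJ-UWTATZPHSA-N")
        b = make_entry("l_ala_c", "L-alanine", "C3H7NO2", "QNAYBMKLOCPYGJ-REOHCLBHSA-N")
        model = merge_compartments(classify_entries(MetabolicModel([a, b], [])))
        assert len(model.metabolites) == 1
        assert set(model.metabolites[0].members) == {"d_ala_c", "l_ala_c"}


def test_strip_compartment_suffixes():
    assert strip_compartment("glc[c]") == "glc"
    assert strip_compartment("glc_e") == "glc"
    assert strip_compartment("M0001") == "M0001"
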