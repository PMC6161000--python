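from __future__ import annotations

import pytest

from metnetcov.model_ingest import (MetabolicModel, MetaboliteEntry,
                                    ReactionEntry, classify_entries)


def make_entry(model_id, name, formula, inchikey=None, compartment="c", **xrefs):
    x = dict(xrefs)
    if inchikey:
        x["inchikey"] = inchikey
    return MetaboliteEntry(
        model_id=model_id, name=name, compartment=compartment,
        xrefs=x, formula=formula,
    )


@pytest.fixture
def hexokinase_model():
    """The hexokinase reaction plus a side reaction producing water/CO2.

    Candidate substrate-product pairs of HEX1 are Glc-G6P, Glc-ADP,
    ATP-G6P, ATP-ADP; with the atom map only the first and last conserve
    carbon.  The side reaction exercises the carbon-free (water) and
    blacklist (CO2) exclusions.
    """
    entries = [
        make_entry("glc", "D-glucose", "C6H12O6", "WQZGKKKJIJFFOK-GASJEMHNSA-N"),
        make_entry("atp", "ATP", "C10H16N5O13P3", "ZKHQWZAMYRWXGA-KQYNXXCUSA-N"),
        make_entry("g6p", "D-glucose 6-phosphate", "C6H13O9P", "NBSCHQHZLSJFNQ-GASJEMHNSA-N"),
        make_entry("adp", "ADP", "C10H15N5O10P2", "XTWYTFMLZFPYCI-KQYNXXCUSA-N"),
        make_entry("h2o", "water", "H2O", "XLYOFNOQVPJJNP-UHFFFAOYSA-N"),
        make_entry("co2", "carbon dioxide", "CO2", "CURLTUGMZLYLDI-UHFFFAOYSA-N"),
    ]
    reactions = [
        ReactionEntry("HEX1", ["glc", "atp"], ["g6p", "adp"]),
        ReactionEntry("SIDE", ["g6p", "h2o"], ["glc", "co2"]),
    ]
    model = MetabolicModel(metabolites=entries, reactions=reactions, merged=True)
    return classify_entries(model)


@pytest.fixture
def hexokinase_atom_map():
    return {
        ("HEX1", "glc", "g6p"): 6,
        ("HEX1", "atp", "adp"): 10,
        ("HEX1", "glc", "adp"): 0,
        ("HEX1", "atp", "g6p"): 0,
        ("SIDE", "g6p", "glc"): 6,
        ("SIDE", "g6p", "co2"): 1,
        ("SIDE", "h2o", "glc"): 0,
        ("SIDE", "h2o", "co2"): 0,
    }


@pytest.fixture(scope="session")
def synthetic_bundle(tmp_path_factory):
    """Default-config synthetic input bundle shared across tests."""
    from metnetcov.synthetic_data import GeneratorConfig, generate

    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate(GeneratorConfig(seed=11), outdir)
    return outdir, truth
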