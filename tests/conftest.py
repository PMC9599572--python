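"""Shared fixtures: hand-solvable toy models and the default consortium."""

import pytest

from crossfeed.core import MediumSpec, Metabolite, Reaction, StoichiometricModel
from crossfeed.synth import ConsortiumDesign, default_design, gen_consortium


def make_chain_model() -> StoichiometricModel:
    """Four-reaction chain: EX_glc → transport → conversion (1:2) → biomass.

    With carbon uptake 10 the LP optimum is biomass flux 20 (hand-solved).
    """
    metabolites = {
        "glc_e": Metabolite(id="glc_e", compartment="extracellular",
                            carbon_atoms=6),
        "glc_c": Metabolite(id="glc_c", compartment="cytosol", carbon_atoms=6),
        "precursor_c": Metabolite(id="precursor_c", compartment="cytosol",
                                  carbon_atoms=3),
    }
    reactions = {
        "EX_glc": Reaction(id="EX_glc", stoichiometry={"glc_e": -1.0},
                           lower_bound=0.0, kind="exchange"),
        "TR_glc": Reaction(id="TR_glc",
                           stoichiometry={"glc_e": -1.0, "glc_c": 1.0},
                           kind="transport"),
        "CONV": Reaction(id="CONV",
                         stoichiometry={"glc_c": -1.0, "precursor_c": 2.0},
                         kind="internal"),
        "BIOMASS": Reaction(id="BIOMASS", stoichiometry={"precursor_c": -1.0},
                            kind="biomass"),
    }
    return StoichiometricModel(species_id="chain", metabolites=metabolites,
                               reactions=reactions, biomass_id="BIOMASS")


def make_sucrose_toy() -> StoichiometricModel:
    """Sucrose splits into glucose + fructose, both feeding one pathway, so
    the sucrose yield is exactly double the glucose yield."""
    mets = {}
    for mid, comp, c in [
        ("sucrose_e", "extracellular", 12), ("sucrose_c", "cytosol", 12),
        ("glucose_e", "extracellular", 6), ("glucose_c", "cytosol", 6),
        ("fructose_c", "cytosol", 6),
        ("precursor_c", "cytosol", 1),
    ]:
        mets[mid] = Metabolite(id=mid, compartment=comp, carbon_atoms=c)
    rxns = {
        "EX_sucrose": Reaction(id="EX_sucrose",
                               stoichiometry={"sucrose_e": -1.0},
                               lower_bound=0.0, kind="exchange"),
        "EX_glucose": Reaction(id="EX_glucose",
                               stoichiometry={"glucose_e": -1.0},
                               lower_bound=0.0, kind="exchange"),
        "TR_sucrose": Reaction(id="TR_sucrose",
                               stoichiometry={"sucrose_e": -1.0,
                                              "sucrose_c": 1.0},
                               kind="transport"),
        "TR_glucose": Reaction(id="TR_glucose",
                               stoichiometry={"glucose_e": -1.0,
                                              "glucose_c": 1.0},
                               kind="transport"),
        "SPLIT": Reaction(id="SPLIT",
                          stoichiometry={"sucrose_c": -1.0, "glucose_c": 1.0,
                                         "fructose_c": 1.0},
                          kind="internal"),
        "ISO": Reaction(id="ISO",
                        stoichiometry={"fructose_c": -1.0, "glucose_c": 1.0},
                        kind="internal"),
        "CAT": Reaction(id="CAT",
                        stoichiometry={"glucose_c": -1.0, "precursor_c": 6.0},
                        kind="internal"),
        "BIOMASS": Reaction(id="BIOMASS", stoichiometry={"precursor_c": -1.0},
                            kind="biomass"),
    }
    return StoichiometricModel(species_id="sucrose_toy", metabolites=mets,
                               reactions=rxns, biomass_id="BIOMASS")


def make_degrader_consumer():
    """Two-species chitin toy: the degrader cleaves chitin to NAG but cannot
    take NAG up; the consumer eats NAG but cannot cleave chitin."""
    design = ConsortiumDesign(
        substrate_sets={"degrader": {"glucose"}, "consumer": {"nag"}},
        carbon_panel=("chitin", "glucose", "nag"),
        roles={"degrader": {"chitinase", "chitobiase"}},
    )
    return gen_consortium(design)


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def sucrose_toy():
    return make_sucrose_toy()


@pytest.fixture
def degrader_consumer():
    return make_degrader_consumer()


@pytest.fixture(scope="session")
def default_consortium():
    design = default_design(seed=42)
    models, truth = gen_consortium(design)
    media = [MediumSpec(carbon_source=c) for c in design.carbon_panel]
    return design, models, truth, media
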