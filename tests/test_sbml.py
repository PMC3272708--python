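"""SBML round-trip fidelity, legacy-dialect import and error handling."""

import pytest

from snfba import (Metabolite, Model, Reaction, ReactionKind, read_sbml,
                   solve_fba, validate_model, write_sbml)
from snfba.gpr import gpr_to_string
from snfba.sbml import SbmlReadError


def tiny_model():
    m = Model(id="tiny")
    m.add_metabolite(Metabolite(id="a[e]", compartment="e"))
    m.add_metabolite(Metabolite(id="a[c]", compartment="c",
                                formula="C4H6O5"))
    m.add_reaction(Reaction(id="EX_a_e", stoichiometry={"a[e]": -1},
                            lower_bound=-10, upper_bound=0,
                            kind=ReactionKind.EXCHANGE))
    m.add_reaction(Reaction(id="T", stoichiometry={"a[e]": -1, "a[c]": 1},
                            upper_bound=100, gpr="(gA and gB) or gC",
                            subsystem="Transport"))
    m.add_reaction(Reaction(id="OF_sink", stoichiometry={"a[c]": -1},
                            upper_bound=100,
                            kind=ReactionKind.OBJECTIVE_PSEUDO))
    m.objective_reaction_ids = ["OF_sink"]
    return m


def assert_structurally_equal(a, b):
    assert sorted(m.id for m in a.metabolites) == \
        sorted(m.id for m in b.metabolites)
    assert {m.id: m.compartment for m in a.metabolites} == \
        {m.id: m.compartment for m in b.metabolites}
    assert sorted(r.id for r in a.reactions) == \
        sorted(r.id for r in b.reactions)
    for rxn in a.reactions:
        other = b.reaction(rxn.id)
        assert other.stoichiometry == pytest.approx(rxn.stoichiometry)
        assert other.lower_bound == pytest.approx(rxn.lower_bound)
        assert other.upper_bound == pytest.approx(rxn.upper_bound)
        assert other.kind == rxn.kind
        assert other.subsystem == rxn.subsystem
        g1 = gpr_to_string(rxn.gpr) if rxn.gpr else None
        g2 = gpr_to_string(other.gpr) if other.gpr else None
        assert g1 == g2
    assert sorted(a.genes) == sorted(b.genes)
    assert a.objective_reaction_ids == b.objective_reaction_ids


def test_tiny_round_trip(tmp_path):
    path = str(tmp_path / "tiny.xml")
    write_sbml(tiny_model(), path)
    assert_structurally_equal(tiny_model(), read_sbml(path))


def test_gpr_string_survives_round_trip(tmp_path):
    path = str(tmp_path / "tiny.xml")
    write_sbml(tiny_model(), path)
    back = read_sbml(path)
    assert gpr_to_string(back.reaction("T").gpr) == "(gA and gB) or gC"


def test_toy_model_round_trip(tmp_path, toy_model):
    path = str(tmp_path / "toy.xml")
    write_sbml(toy_model, path)
    back = read_sbml(path)
    assert validate_model(back) == []
    assert_structurally_equal(toy_model, back)
    assert solve_fba(back).objective_value == pytest.approx(
        solve_fba(toy_model).objective_value, rel=1e-9)


def test_invalid_model_refused_before_write(tmp_path):
    m = tiny_model()
    m.reactions.append(Reaction(id="BAD", stoichiometry={}))
    with pytest.raises(ValueError, match="empty stoichiometry"):
        write_sbml(m, str(tmp_path / "bad.xml"))


def test_malformed_xml_parse_error(tmp_path):
    path = tmp_path / "broken.xml"
    path.write_text("<sbml><model><unclosed></model></sbml>")
    with pytest.raises(SbmlReadError, match="parse error"):
        read_sbml(str(path))


def test_dangling_species_reference_listed(tmp_path):
    path = tmp_path / "dangling.xml"
    path.write_text("""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3"
      version="1">
  <model id="d">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_a_c" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R_r1" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="M_X_c" stoichiometry="1"
                            constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_a_c" stoichiometry="1"
                            constant="true"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
""")
    with pytest.raises(SbmlReadError, match="M_X_c"):
        read_sbml(str(path))


def test_legacy_cobra_notes_dialect(tmp_path):
    """Pre-fbc SBML: bounds in kinetic-law parameters, GPR in notes."""
    path = tmp_path / "legacy.xml"
    path.write_text("""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="legacy">
    <listOfCompartments>
      <compartment id="c"/>
      <compartment id="e"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_a_e" compartment="e"/>
      <species id="M_a_c" compartment="c"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R_EX_a_e" reversible="true">
        <listOfReactants>
          <speciesReference species="M_a_e" stoichiometry="1"/>
        </listOfReactants>
        <kineticLaw>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="-5"/>
            <parameter id="UPPER_BOUND" value="0"/>
            <parameter id="OBJECTIVE_COEFFICIENT" value="0"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="R_T" reversible="false">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>GENE_ASSOCIATION: (gA and gB) or gC</p>
            <p>SUBSYSTEM: Transport</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="M_a_e" stoichiometry="1"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_a_c" stoichiometry="1"/>
        </listOfProducts>
        <kineticLaw>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="0"/>
            <parameter id="UPPER_BOUND" value="100"/>
            <parameter id="OBJECTIVE_COEFFICIENT" value="1"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
""")
    model = read_sbml(str(path))
    assert model.reaction("EX_a_e").lower_bound == -5.0
    assert model.reaction("EX_a_e").kind is ReactionKind.EXCHANGE
    t = model.reaction("T")
    assert gpr_to_string(t.gpr) == "(gA and gB) or gC"
    assert t.subsystem == "Transport"
    assert t.upper_bound == 100.0
    assert model.objective_reaction_ids == ["T"]
    assert sorted(model.genes) == ["gA", "gB", "gC"]


def test_cobrapy_agrees_on_exported_model(tmp_path, toy_model):
    """Independent cross-check: COBRApy reads our SBML and reproduces the
    optimum of our own LP formulation."""
    cobra = pytest.importorskip("cobra")
    path = str(tmp_path / "toy.xml")
    write_sbml(toy_model, path)
    cm = cobra.io.read_sbml_model(path)
    assert cm.slim_optimize() == pytest.approx(
        solve_fba(toy_model).objective_value, rel=1e-6)
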