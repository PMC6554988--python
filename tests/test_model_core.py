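import textwrap

import numpy as np
import pytest

from methanoflux.model_core import (
    DEFAULT_BOUND,
    EquationParseError,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    format_equation,
    parse_equation,
    read_sbml,
    read_tsv_model,
    stoichiometric_matrix,
    unbalanced_reactions,
    write_sbml,
    write_tsv_model,
)


def tiny_model():
    mets = [Metabolite(id=f"{x}_c0") for x in "ABC"] + [Metabolite(id="A_e0")]
    rxns = [
        Reaction(id="EX_A", stoichiometry={"A_e0": -1.0}, lower_bound=-10, upper_bound=0,
                 is_exchange=True),
        Reaction(id="T_A", stoichiometry={"A_e0": -1.0, "A_c0": 1.0},
                 lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND),
        Reaction(id="R1", stoichiometry={"A_c0": -1.0, "B_c0": 2.0},
                 lower_bound=0, upper_bound=5),
        Reaction(id="R2", stoichiometry={"B_c0": -1.0, "C_c0": 1.0},
                 lower_bound=0, upper_bound=100),
        Reaction(id="EX_C", stoichiometry={"C_c0": -1.0}, lower_bound=0, upper_bound=100,
                 is_exchange=True),
    ]
    return MetabolicModel(id="tiny", metabolites=mets, reactions=rxns)


class TestEquationGrammar:
    @pytest.mark.parametrize("text, stoich, reversible", [
        ("A_c0 + 2 B_c0 -> C_c0", {"A_c0": -1, "B_c0": -2, "C_c0": 1}, False),
        ("A_c0 <=> B_c0", {"A_c0": -1, "B_c0": 1}, True),
        ("A_e0 ->", {"A_e0": -1}, False),
        ("(0.5) O2_c0 + X_c0 -> Y_c0", {"O2_c0": -0.5, "X_c0": -1, "Y_c0": 1}, False),
        ("A_c0 + B_c0 → C_c0 + 3 D_c0", {"A_c0": -1, "B_c0": -1, "C_c0": 1, "D_c0": 3},
         False),
    ])
    def test_parse(self, text, stoich, reversible):
        got, rev = parse_equation(text)
        assert got == stoich
        assert rev is reversible

    def test_no_arrow_is_error(self):
        with pytest.raises(EquationParseError):
            parse_equation("A_c0 + B_c0")

    @pytest.mark.parametrize("rxn", [
        Reaction(id="r", stoichiometry={"A_c0": -1.0, "B_c0": 2.5, "C_c0": 1.0},
                 lower_bound=0, upper_bound=10),
        Reaction(id="r", stoichiometry={"A_c0": -2.0, "B_c0": 1.0},
                 lower_bound=-5, upper_bound=5),
        Reaction(id="r", stoichiometry={"A_e0": 1.0}, lower_bound=-3, upper_bound=0),
    ])
    def test_format_parse_round_trip(self, rxn):
        stoich, rev = parse_equation(format_equation(rxn))
        assert stoich == rxn.stoichiometry
        assert rev is rxn.reversible


class TestValidation:
    def test_dangling_metabolite_rejected(self):
        m = tiny_model()
        m.reactions[2].stoichiometry["GHOST_c0"] = 1.0
        with pytest.raises(ModelValidationError, match="dangling"):
            m.validate()

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction(id="bad", stoichiometry={"A_c0": -1.0}, lower_bound=1, upper_bound=0)

    def test_exchange_touching_two_metabolites_rejected(self):
        m = tiny_model()
        m.reactions[0].stoichiometry["B_c0"] = 1.0
        with pytest.raises(ModelValidationError, match="exchange"):
            m.validate()

    def test_compartments_parsed_from_id_suffix(self):
        assert Metabolite(id="foo_e0").compartment == "e0"
        assert Metabolite(id="bar_c0").compartment == "c0"


class TestStoichiometricMatrix:
    def test_conversion_column(self):
        m = tiny_model()
        S = stoichiometric_matrix(m).toarray()
        j = m.reaction_ids.index("R2")
        col = {m.metabolite_ids[i]: S[i, j] for i in range(S.shape[0]) if S[i, j]}
        assert col == {"B_c0": -1.0, "C_c0": 1.0}

    def test_exchange_column_single_entry(self):
        m = tiny_model()
        S = stoichiometric_matrix(m).toarray()
        j = m.reaction_ids.index("EX_A")
        assert np.count_nonzero(S[:, j]) == 1
        assert S[m.metabolite_ids.index("A_e0"), j] == -1.0

    def test_column_sums_match_independent_summation(self, core_model):
        # independent oracle: sum coefficients per reaction from the dicts
        S = stoichiometric_matrix(core_model)
        col_sums = np.asarray(S.sum(axis=0)).ravel()
        expected = [sum(r.stoichiometry.values()) for r in core_model.reactions]
        assert np.allclose(col_sums, expected)

    def test_dimensions(self, core_model):
        S = stoichiometric_matrix(core_model)
        assert S.shape == (len(core_model.metabolites), len(core_model.reactions))


class TestTsvFormat:
    def test_minimal_dialect_irreversible_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("r1\tA_c0 + 2 B_c0 -> C_c0\tirrev\n")
        m = read_tsv_model(str(p))
        r = m.reaction("r1")
        assert r.stoichiometry == {"A_c0": -1, "B_c0": -2, "C_c0": 1}
        assert r.lower_bound == 0.0

    def test_reversible_arrow_opens_lower_bound(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("r1\tA_c0 <=> B_c0\n")
        assert read_tsv_model(str(p)).reaction("r1").lower_bound < 0

    def test_unparsable_equation_reports_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("r1\tA_c0 -> B_c0\nr2\tno arrow here\n")
        with pytest.raises(EquationParseError, match="row 2"):
            read_tsv_model(str(p))

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("r1\tA_c0 -> B_c0\nr1\tB_c0 -> C_c0\n")
        with pytest.raises(ModelValidationError, match="duplicate"):
            read_tsv_model(str(p))

    def test_round_trip_exact(self, core_model, tmp_path):
        p = tmp_path / "core.tsv"
        write_tsv_model(core_model, str(p))
        back = read_tsv_model(str(p))
        assert back.reaction_ids == core_model.reaction_ids
        for r in core_model.reactions:
            b = back.reaction(r.id)
            assert b.stoichiometry == r.stoichiometry
            assert (b.lower_bound, b.upper_bound) == (r.lower_bound, r.upper_bound)


class TestSbmlFormat:
    def test_round_trip_exact(self, core_model, tmp_path):
        p = tmp_path / "core.xml"
        write_sbml(core_model, str(p))
        back = read_sbml(str(p))
        assert back.reaction_ids == core_model.reaction_ids
        assert len(back.metabolites) == len(core_model.metabolites)
        assert back.objective_id == core_model.objective_id
        for r in core_model.reactions:
            b = back.reaction(r.id)
            assert b.stoichiometry == r.stoichiometry
            assert (b.lower_bound, b.upper_bound) == (r.lower_bound, r.upper_bound)
        for met in core_model.metabolites:
            assert back.metabolite(met.id).formula == met.formula

    def test_three_reaction_fixture(self, tmp_path):
        m = tiny_model()
        m.metabolites = m.metabolites[:3]
        m.reactions = [
            Reaction(id="r1", stoichiometry={"A_c0": -1.0, "B_c0": 1.0},
                     lower_bound=0, upper_bound=7.5),
            Reaction(id="r2", stoichiometry={"B_c0": -1.0, "C_c0": 1.0},
                     lower_bound=-2, upper_bound=2),
            Reaction(id="EX_C", stoichiometry={"C_c0": -1.0}, lower_bound=0,
                     upper_bound=4, is_exchange=True),
        ]
        m = MetabolicModel(id="three", metabolites=m.metabolites, reactions=m.reactions)
        p = tmp_path / "three.xml"
        write_sbml(m, str(p))
        back = read_sbml(str(p))
        assert len(back.reactions) == 3
        assert len(back.metabolites) == 3
        assert back.reaction("r1").upper_bound == 7.5
        assert back.reaction("r2").lower_bound == -2

    def test_level2_kinetic_law_bounds(self, tmp_path):
        sbml = textwrap.dedent("""\
            <?xml version="1.0" encoding="UTF-8"?>
            <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
              <model id="l2">
                <listOfCompartments><compartment id="c0" size="1"/></listOfCompartments>
                <listOfSpecies>
                  <species id="A_c0" compartment="c0" initialAmount="0"/>
                  <species id="B_c0" compartment="c0" initialAmount="0"/>
                </listOfSpecies>
                <listOfReactions>
                  <reaction id="r1" reversible="false">
                    <listOfReactants><speciesReference species="A_c0"/></listOfReactants>
                    <listOfProducts><speciesReference species="B_c0"/></listOfProducts>
                    <kineticLaw>
                      <math xmlns="http://www.w3.org/1998/Math/MathML">
                        <ci>FLUX_VALUE</ci>
                      </math>
                      <listOfParameters>
                        <parameter id="LOWER_BOUND" value="-3"/>
                        <parameter id="UPPER_BOUND" value="8"/>
                        <parameter id="FLUX_VALUE" value="0"/>
                      </listOfParameters>
                    </kineticLaw>
                  </reaction>
                </listOfReactions>
              </model>
            </sbml>
        """)
        p = tmp_path / "l2.xml"
        p.write_text(sbml)
        m = read_sbml(str(p))
        r = m.reaction("r1")
        assert (r.lower_bound, r.upper_bound) == (-3.0, 8.0)

    def test_malformed_xml_reports_line(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<?xml version='1.0'?>\n<sbml><unclosed>\n")
        with pytest.raises(Exception, match="line"):
            read_sbml(str(p))

    def test_tsv_and_sbml_give_identical_matrices(self, core_model, tmp_path):
        write_sbml(core_model, str(tmp_path / "m.xml"))
        write_tsv_model(core_model, str(tmp_path / "m.tsv"))
        ma = read_sbml(str(tmp_path / "m.xml"))
        mb = read_tsv_model(str(tmp_path / "m.tsv"))

        def aligned(m):
            S = stoichiometric_matrix(m).toarray()
            rows = np.argsort(m.metabolite_ids)
            cols = np.argsort(m.reaction_ids)
            return S[np.ix_(rows, cols)]

        assert sorted(ma.metabolite_ids) == sorted(mb.metabolite_ids)
        assert sorted(ma.reaction_ids) == sorted(mb.reaction_ids)
        assert np.array_equal(aligned(ma), aligned(mb))


def test_elemental_balance_helper_flags_imbalance():
    mets = [Metabolite(id="A_c0", formula="C2H4"), Metabolite(id="B_c0", formula="C2H2")]
    rxns = [Reaction(id="r", stoichiometry={"A_c0": -1.0, "B_c0": 1.0},
                     lower_bound=0, upper_bound=1)]
    m = MetabolicModel(id="x", metabolites=mets, reactions=rxns)
    bad = unbalanced_reactions(m)
    assert bad == {"r": {"H": -2.0}}
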