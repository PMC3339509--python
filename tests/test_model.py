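"""Model containers, matrix/SBML I/O, and mass/charge balance checking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxspan.model import (
    DEFAULT_BOUND,
    FormatError,
    Metabolite,
    Model,
    ModelError,
    Reaction,
    add_reaction,
    check_mass_charge_balance,
    parse_formula,
    read_matrix_tsv,
    read_sbml,
    write_matrix_tsv,
    write_sbml,
)
from fluxspan.synthetic import ToyNetworkSpec, make_toy_network


def models_equal(a: Model, b: Model) -> bool:
    return (
        a.metabolite_ids == b.metabolite_ids
        and a.reaction_ids == b.reaction_ids
        and np.array_equal(a.stoichiometric_matrix(), b.stoichiometric_matrix())
        and np.array_equal(a.bounds_arrays()[0], b.bounds_arrays()[0])
        and np.array_equal(a.bounds_arrays()[1], b.bounds_arrays()[1])
    )


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("H2O", {"H": 2, "O": 1}),
            ("NaCl", {"Na": 1, "Cl": 1}),
            ("C", {"C": 1}),
            ("CHO2Fe3", {"C": 1, "H": 1, "O": 2, "Fe": 3}),
        ],
    )
    def test_element_counts(self, formula, expected):
        assert parse_formula(formula) == expected

    @pytest.mark.parametrize("bad", ["", "c6h12", "(C5H8O4)n", "X*", "12C"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormatError):
            parse_formula(bad)


class TestContainers:
    def test_bounds_must_be_ordered(self):
        with pytest.raises(ModelError, match="lower bound"):
            Reaction("r", {"A": -1.0}, 5.0, -5.0)

    def test_zero_coefficients_rejected(self):
        with pytest.raises(ModelError, match="zero coefficient"):
            Reaction("r", {"A": 0.0, "B": 1.0})

    def test_exchange_is_single_participant(self):
        assert Reaction("ex", {"A": -1.0}).is_exchange
        assert not Reaction("r", {"A": -1.0, "B": 1.0}).is_exchange

    def test_unknown_metabolite_reference_rejected(self):
        with pytest.raises(ModelError, match="unknown metabolites"):
            Model((Metabolite("A"),), (Reaction("r", {"B": 1.0}),))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            Model((Metabolite("A"), Metabolite("A")), ())

    def test_every_loaded_toy_model_has_ordered_bounds(self):
        for kind in ("chain", "branch", "diamond"):
            model = make_toy_network(ToyNetworkSpec(kind=kind))
            lower, upper = model.bounds_arrays()
            assert (lower <= upper).all()


class TestAddReaction:
    def test_appends_column_and_preserves_original(self, chain_model):
        drain = Reaction("SNK_A", {"A": -1.0}, 0.0, DEFAULT_BOUND)
        bigger = add_reaction(chain_model, drain)
        assert len(bigger.reactions) == len(chain_model.reactions) + 1
        assert "SNK_A" not in chain_model.reaction_ids  # value semantics
        col = bigger.stoichiometric_matrix()[:, -1]
        assert sorted(col.tolist()) == [-1.0, 0.0]

    def test_duplicate_id_conflict(self, chain_model):
        with pytest.raises(ModelError, match="already present"):
            add_reaction(chain_model, Reaction("R_AB", {"A": -1.0}))

    def test_unknown_metabolite_requires_flag(self, chain_model):
        rxn = Reaction("r_new", {"Z": -1.0})
        with pytest.raises(ModelError, match="new_metabolites"):
            add_reaction(chain_model, rxn)
        ok = add_reaction(chain_model, rxn, new_metabolites=[Metabolite("Z")])
        assert "Z" in ok.metabolite_ids

    def test_add_then_remove_is_identity(self, chain_model):
        drain = Reaction("SNK_A", {"A": -1.0}, 0.0, DEFAULT_BOUND)
        roundtrip = add_reaction(chain_model, drain).without_reaction("SNK_A")
        assert models_equal(roundtrip, chain_model)


class TestMatrixTsv:
    def test_minimal_one_by_one(self, tmp_path):
        path = tmp_path / "S.tsv"
        path.write_text("\tR1\nA\t-1\n")
        model = read_matrix_tsv(path)
        assert model.metabolite_ids == ["A"] and model.reaction_ids == ["R1"]
        assert model.reaction("R1").stoichiometry == {"A": -1.0}
        assert model.reaction("R1").bounds == (-DEFAULT_BOUND, DEFAULT_BOUND)

    def test_round_trip_identity(self, tmp_path, chain_model):
        mpath, bpath = tmp_path / "S.tsv", tmp_path / "b.tsv"
        write_matrix_tsv(chain_model, mpath, bpath)
        assert models_equal(read_matrix_tsv(mpath, bpath), chain_model)

    def test_all_zero_column_is_format_error(self, tmp_path):
        path = tmp_path / "S.tsv"
        path.write_text("\tR1\tR2\nA\t-1\t0\nB\t1\t0\n")
        with pytest.raises(FormatError, match="all-zero"):
            read_matrix_tsv(path)

    def test_non_numeric_cell_is_format_error(self, tmp_path):
        path = tmp_path / "S.tsv"
        path.write_text("\tR1\nA\tbogus\n")
        with pytest.raises(FormatError):
            read_matrix_tsv(path)

    def test_bounds_for_unknown_reaction_is_format_error(self, tmp_path, chain_model):
        mpath, bpath = tmp_path / "S.tsv", tmp_path / "b.tsv"
        write_matrix_tsv(chain_model, mpath)
        bpath.write_text("reaction\tlower\tupper\nNOPE\t0\t1\n")
        with pytest.raises(FormatError, match="unknown reactions"):
            read_matrix_tsv(mpath, bpath)


MINIMAL_L2_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="mini">
    <listOfCompartments><compartment id="c"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c"/>
      <species id="B" compartment="c"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1" reversible="false">
        <listOfReactants><speciesReference species="A"/></listOfReactants>
        <listOfProducts><speciesReference species="B"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""


class TestSbml:
    def test_irreversible_default_bounds(self, tmp_path):
        path = tmp_path / "mini.xml"
        path.write_text(MINIMAL_L2_SBML)
        model = read_sbml(path)
        assert model.reaction("R1").bounds == (0.0, DEFAULT_BOUND)
        assert model.reaction("R1").stoichiometry == {"A": -1.0, "B": 1.0}

    def test_round_trip_identity(self, tmp_path, branch_model):
        path = tmp_path / "branch.xml"
        write_sbml(branch_model, path)
        assert models_equal(read_sbml(path), branch_model)

    def test_explicit_fbc_bounds_pass_through(self, tmp_path):
        model = Model(
            (Metabolite("A", compartment="c"),),
            (Reaction("EX_A", {"A": -1.0}, -5.0, 5.0),),
        )
        path = tmp_path / "fbc.xml"
        write_sbml(model, path)
        assert read_sbml(path).reaction("EX_A").bounds == (-5.0, 5.0)

    def test_malformed_xml_is_format_error(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml><not-closed>")
        with pytest.raises(FormatError):
            read_sbml(path)


class TestBalanceChecking:
    def _model(self, reactions, mets):
        return Model(tuple(mets), tuple(reactions))

    def test_identical_formulas_balance(self):
        mets = [Metabolite("A", formula="CH4"), Metabolite("B", formula="CH4")]
        report = check_mass_charge_balance(
            self._model([Reaction("iso", {"A": -1.0, "B": 1.0})], mets)
        )
        assert report["iso"].balanced

    def test_stoichiometric_split_balance_and_imbalance(self):
        mets = [
            Metabolite("glc", formula="C6H12O6"),
            Metabolite("lac", formula="C3H6O3"),
        ]
        good = Reaction("split2", {"glc": -1.0, "lac": 2.0})
        bad = Reaction("split1", {"glc": -1.0, "lac": 1.0})
        report = check_mass_charge_balance(self._model([good, bad], mets))
        assert report["split2"].balanced
        assert report["split1"].status == "unbalanced"
        assert report["split1"].element_imbalance == {"C": -3, "H": -6, "O": -3}

    def test_exchange_reactions_are_exempt(self):
        mets = [Metabolite("A", formula="C")]
        report = check_mass_charge_balance(self._model([Reaction("EX_A", {"A": -1.0})], mets))
        assert report["EX_A"].status == "exempt"

    def test_missing_formula_marks_unknown(self):
        mets = [Metabolite("A", formula="C"), Metabolite("B")]
        report = check_mass_charge_balance(self._model([Reaction("r", {"A": -1.0, "B": 1.0})], mets))
        assert report["r"].status == "unknown"

    def test_unparseable_formula_warns_and_marks_unknown(self):
        mets = [Metabolite("A", formula="C"), Metabolite("B", formula="(C5H8O4)n")]
        with pytest.warns(UserWarning, match="unparseable"):
            report = check_mass_charge_balance(
                self._model([Reaction("r", {"A": -1.0, "B": 1.0})], mets)
            )
        assert report["r"].status == "unknown"

    def test_charge_imbalance_detected(self):
        mets = [
            Metabolite("A", formula="C", charge=1),
            Metabolite("B", formula="C", charge=0),
        ]
        report = check_mass_charge_balance(self._model([Reaction("r", {"A": -1.0, "B": 1.0})], mets))
        assert report["r"].status == "unbalanced"
        assert report["r"].charge_imbalance == -1

    def test_summary_counts(self):
        mets = [Metabolite("A", formula="C"), Metabolite("B", formula="C"), Metabolite("C_")]
        rxns = [
            Reaction("ok", {"A": -1.0, "B": 1.0}),
            Reaction("EX", {"A": -1.0}),
            Reaction("mystery", {"A": -1.0, "C_": 1.0}),
        ]
        summary = check_mass_charge_balance(self._model(rxns, mets)).summary()
        assert summary == {"balanced": 1, "unbalanced": 0, "unknown": 1, "exempt": 1}

    elements = st.sampled_from(["C", "H", "O", "N", "P"])
    formulas = st.dictionaries(elements, st.integers(1, 9), min_size=1, max_size=5)

    @settings(max_examples=50, deadline=None)
    @given(
        formulas=st.lists(formulas, min_size=2, max_size=4),
        coeffs=st.lists(st.integers(-3, 3).filter(lambda c: c != 0), min_size=2, max_size=4),
    )
    def test_checker_agrees_with_atom_tally_oracle(self, formulas, coeffs):
        """Brute-force oracle: expand each molecule into an explicit atom list."""
        n = min(len(formulas), len(coeffs))
        mets = [
            Metabolite(f"m{i}", formula="".join(f"{el}{ct}" for el, ct in sorted(f.items())))
            for i, f in enumerate(formulas[:n])
        ]
        rxn = Reaction("r", {f"m{i}": float(c) for i, c in enumerate(coeffs[:n])})
        report = check_mass_charge_balance(Model(tuple(mets), (rxn,)))

        atoms: dict[str, float] = {}
        for i, f in enumerate(formulas[:n]):
            for element, count in f.items():
                for _ in range(count):  # one atom at a time
                    atoms[element] = atoms.get(element, 0.0) + coeffs[i]
        expected = {el: c for el, c in atoms.items() if c != 0}
        if expected:
            assert report["r"].status == "unbalanced"
            assert report["r"].element_imbalance == pytest.approx(expected)
        else:
            assert report["r"].balanced
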