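"""Molecule parsing, fingerprints, and tabular round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sensits.chemio import (
    Formulation,
    Ingredient,
    compute_fingerprint,
    parse_molecule,
    read_assay_table,
    read_formulation_table,
    read_smiles_list,
    write_formulation_table,
    write_report,
)
from sensits.errors import MoleculeParseError, SchemaError, TableRowError, ValidationError
from sensits.itscore import combine_and_classify
from sensits.synthdata import _FRAGMENTS, ALERT_SMILES


def test_parse_ethanol():
    mol = parse_molecule("CCO")
    assert mol.heavy_atom_count == 3
    assert mol.fingerprint.shape == (1024,)
    assert mol.fingerprint.sum() > 0


def test_invalid_smiles_names_offender():
    with pytest.raises(MoleculeParseError, match=r"C\("):
        parse_molecule("C(")


def test_empty_smiles_is_validation_error():
    with pytest.raises(ValidationError):
        parse_molecule("")
    with pytest.raises(ValidationError):
        parse_molecule("   ")


def test_canonicalization_idempotent():
    mol = parse_molecule("OC(=O)c1ccccc1")
    again = parse_molecule(mol.canonical_smiles)
    assert again.canonical_smiles == mol.canonical_smiles


def test_fingerprint_permutation_invariance():
    """Two SMILES spellings of the same molecule give identical fingerprints."""
    a = parse_molecule("OCC")
    b = parse_molecule("CCO")
    assert np.array_equal(a.fingerprint, b.fingerprint)
    assert a.canonical_smiles == b.canonical_smiles


def test_fingerprint_determinism_and_distinctness():
    m1 = parse_molecule("C")
    m2 = parse_molecule("C")
    assert np.array_equal(m1.fingerprint, m2.fingerprint)
    assert not np.array_equal(m1.fingerprint, parse_molecule("CCO").fingerprint)


def test_longer_path_molecule_sets_at_least_as_many_bits():
    # path-based fingerprint: decane contains every path methane has and more
    small = parse_molecule("C").fingerprint.sum()
    large = parse_molecule("CCCCCCCCCC").fingerprint.sum()
    assert small <= large


def test_fingerprint_width_configurable():
    assert parse_molecule("CCO", n_bits=256).fingerprint.shape == (256,)
    from rdkit import Chem

    with pytest.raises(ValidationError):
        compute_fingerprint(Chem.MolFromSmiles("C"), n_bits=0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    frags=st.lists(st.sampled_from(_FRAGMENTS), min_size=1, max_size=4),
    alert=st.booleans(),
)
def test_canonical_idempotence_over_fragment_grammar(frags, alert):
    smiles = "".join(frags) + (ALERT_SMILES if alert else "")
    mol = parse_molecule(smiles)
    assert parse_molecule(mol.canonical_smiles).canonical_smiles == mol.canonical_smiles


def test_ingredient_negative_concentration_rejected():
    with pytest.raises(ValidationError):
        Ingredient(name="x", molecule=None, concentration=-1.0)


def test_formulation_over_100_percent_warns_not_fails():
    ings = [Ingredient("a", None, 60.0), Ingredient("b", None, 55.0)]
    with pytest.warns(UserWarning, match="sum"):
        Formulation(id="f", ingredients=ings)


def test_formulation_requires_ingredients_and_valid_label():
    with pytest.raises(ValidationError):
        Formulation(id="f", ingredients=[])
    with pytest.raises(ValidationError):
        Formulation(id="f", ingredients=[Ingredient("a", None, 1.0)], ghs_label="2")


class TestFormulationTable:
    def _write(self, tmp_path, rows, columns=None):
        path = tmp_path / "f.csv"
        pd.DataFrame(
            rows,
            columns=columns
            or ["formulation_id", "ingredient_name", "smiles", "concentration_pct"],
        ).to_csv(path, index=False)
        return path

    def test_two_rows_two_formulations(self, tmp_path):
        path = self._write(
            tmp_path, [["F1", "a", "CCO", 10.0], ["F2", "b", "CCN", 5.0]]
        )
        frms = read_formulation_table(path)
        assert len(frms) == 2 and all(len(f.ingredients) == 1 for f in frms)

    def test_rows_grouped_by_formulation(self, tmp_path):
        path = self._write(
            tmp_path, [["F1", "a", "CCO", 10.0], ["F1", "b", "CCN", 5.0]]
        )
        (frm,) = read_formulation_table(path)
        assert [i.name for i in frm.ingredients] == ["a", "b"]

    def test_blank_smiles_yields_absent_molecule(self, tmp_path):
        path = self._write(tmp_path, [["F1", "mineral", "", 10.0]])
        (frm,) = read_formulation_table(path)
        assert frm.ingredients[0].molecule is None

    def test_unparseable_smiles_warns_and_yields_absent_molecule(self, tmp_path):
        path = self._write(tmp_path, [["F1", "junk", "C(", 10.0]])
        with pytest.warns(UserWarning, match="unparseable"):
            (frm,) = read_formulation_table(path)
        assert frm.ingredients[0].molecule is None

    def test_missing_column_raises_schema_error_listing_names(self, tmp_path):
        path = tmp_path / "f.csv"
        pd.DataFrame([["F1", "a"]], columns=["formulation_id", "ingredient_name"]).to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError) as err:
            read_formulation_table(path)
        assert "smiles" in str(err.value) and "concentration_pct" in str(err.value)

    def test_non_numeric_concentration_reports_row_index(self, tmp_path):
        path = self._write(
            tmp_path, [["F1", "a", "CCO", 10.0], ["F1", "b", "CCN", "lots"]]
        )
        with pytest.raises(TableRowError, match="row 1"):
            read_formulation_table(path)

    def test_round_trip_stable(self, tmp_path):
        path = self._write(
            tmp_path,
            [["F1", "a", "CCO", 10.0], ["F1", "b", "", 5.0], ["F2", "c", "CCN", 1.0]],
        )
        frms = read_formulation_table(path)
        out = tmp_path / "out.csv"
        write_formulation_table(frms, out)
        again = read_formulation_table(out)
        assert [(f.id, [(i.name, i.concentration) for i in f.ingredients]) for f in frms] == [
            (f.id, [(i.name, i.concentration) for i in f.ingredients]) for f in again
        ]


class TestAssayTable:
    def _write(self, tmp_path, rows, extra_cols=()):
        path = tmp_path / "a.csv"
        cols = [
            "formulation_id",
            "dpra_cys_depletion_pct",
            "dpra_lys_depletion_pct",
            "dpra_lys_coelution",
            "hclat_mit_ug_ml",
            *extra_cols,
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return path

    def test_reads_numbers_and_negative_marker(self, tmp_path):
        path = self._write(
            tmp_path,
            [["F1", 5.0, 5.0, 0, 2000.0], ["F2", 50.0, 40.0, 0, "negative"]],
        )
        panels = read_assay_table(path)
        assert panels["F1"].hclat.mit == 2000.0
        assert panels["F2"].hclat.negative

    def test_blank_cells_yield_missing_components(self, tmp_path):
        path = self._write(tmp_path, [["F1", "", "", "", ""]])
        panel = read_assay_table(path)["F1"]
        assert panel.dpra is None and panel.hclat is None

    def test_optional_label_and_call_columns(self, tmp_path):
        path = self._write(
            tmp_path,
            [["F1", 5.0, 5.0, 0, "negative", "1B", "positive"]],
            extra_cols=("ghs_label", "insilico_call"),
        )
        panel = read_assay_table(path)["F1"]
        assert panel.ghs_label == "1B" and panel.insilico_call == "positive"

    def test_bad_mit_reports_row(self, tmp_path):
        path = self._write(tmp_path, [["F1", 5.0, 5.0, 0, "maybe"]])
        with pytest.raises(TableRowError, match="row 0"):
            read_assay_table(path)

    def test_missing_columns_raise_schema_error(self, tmp_path):
        path = tmp_path / "a.csv"
        pd.DataFrame([["F1"]], columns=["formulation_id"]).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            read_assay_table(path)


def test_smiles_list_reader_skips_blank_lines(tmp_path):
    path = tmp_path / "s.smi"
    path.write_text("CCO\n\n  \nCCN\n")
    assert read_smiles_list(path) == ["CCO", "CCN"]


def test_write_report_round_trips_through_pandas(tmp_path):
    results = {"F1": combine_and_classify(1, 1, 0), "F2": combine_and_classify(0, None, 0)}
    path = tmp_path / "r.csv"
    write_report(results, path)
    df = pd.read_csv(path)
    assert list(df["formulation_id"]) == ["F1", "F2"]
    assert list(df["hazard"]) == ["sensitizer", "inconclusive"]
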