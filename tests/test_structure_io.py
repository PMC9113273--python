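"""Parsing PDB text into C-alpha models and writing results back out."""

import numpy as np
import pytest

from dci.errors import EmptySelectionError, ParseError
from dci.structure_io import (
    ResidueKey,
    assignments_table,
    parse_assignments,
    parse_structure,
    write_labeled_structure,
    write_trajectory,
)


def test_minimal_file_reads_back_in_order(minimal_pdb):
    model = parse_structure(minimal_pdb)
    assert len(model) == 3
    assert model.residues == [ResidueKey("A", i) for i in (1, 2, 3)]
    np.testing.assert_allclose(model.coordinates[:, 0], [0.0, 3.8, 7.6])


def test_absent_chain_selection_is_empty(minimal_pdb):
    with pytest.raises(EmptySelectionError, match="empty selection"):
        parse_structure(minimal_pdb, chains=["B"])


def test_residue_range_selection(minimal_pdb):
    model = parse_structure(minimal_pdb, residue_ranges={"A": [(2, 3)]})
    assert [r.residue_number for r in model.residues] == [2, 3]


def test_altloc_keeps_highest_occupancy():
    text = "\n".join([
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C",
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60  0.00           C",
        "ATOM      3  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C",
        "END",
    ]) + "\n"
    model = parse_structure(text)
    assert len(model) == 2
    assert model.coordinates[0, 0] == pytest.approx(1.0)  # altloc B, occ 0.60


def test_altloc_occupancy_tie_prefers_a():
    text = "\n".join([
        "ATOM      1  CA BALA A   1       1.000   0.000   0.000  0.50  0.00           C",
        "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C",
        "ATOM      3  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C",
        "END",
    ]) + "\n"
    model = parse_structure(text)
    assert model.coordinates[0, 0] == pytest.approx(0.0)


def test_hetatm_excluded_by_default_and_includable(minimal_pdb):
    het = (
        "HETATM    4  CA  MSE A   4      11.400   0.000   0.000  1.00  0.00           C\n"
        "HETATM    5  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O\n"
    )
    text = minimal_pdb.replace("END\n", het + "END\n")
    assert len(parse_structure(text)) == 3
    model = parse_structure(text, hetatm_include=["MSE"])
    assert len(model) == 4
    assert model.residues[-1] == ResidueKey("A", 4)


def test_malformed_coordinates_name_the_line(minimal_pdb):
    bad = minimal_pdb.replace("   3.800", "  xx.800")
    with pytest.raises(ParseError, match="line 2"):
        parse_structure(bad)


def test_multi_model_uses_first_model_only(minimal_pdb):
    model = parse_structure(minimal_pdb)
    shifted = model.coordinates + 5.0
    text = write_trajectory([model.coordinates, shifted], model)
    reread = parse_structure(text)
    assert len(reread) == 3
    np.testing.assert_allclose(reread.coordinates, model.coordinates, atol=1e-3)


def test_labeled_structure_carries_community_as_bfactor(minimal_pdb):
    model = parse_structure(minimal_pdb)
    out = write_labeled_structure(model, [1, 1, 2], minimal_pdb)
    b_factors = [line[60:66] for line in out.splitlines() if line.startswith("ATOM")]
    assert b_factors == ["  1.00", "  1.00", "  2.00"]


def test_labeled_structure_zero_bfactor_outside_model(minimal_pdb):
    model = parse_structure(minimal_pdb, residue_ranges={"A": [(1, 2)]})
    out = write_labeled_structure(model, [1, 2], minimal_pdb)
    b_factors = [line[60:66] for line in out.splitlines() if line.startswith("ATOM")]
    assert b_factors == ["  1.00", "  2.00", "  0.00"]


def test_label_length_mismatch_rejected(minimal_pdb):
    model = parse_structure(minimal_pdb)
    with pytest.raises(ValueError, match="length"):
        write_labeled_structure(model, [1, 2], minimal_pdb)


def test_write_parse_round_trip_preserves_model(minimal_pdb):
    model = parse_structure(minimal_pdb)
    labeled = write_labeled_structure(model, [1, 2, 3], minimal_pdb)
    again = parse_structure(labeled)
    assert again.residues == model.residues
    np.testing.assert_allclose(again.coordinates, model.coordinates, atol=1e-3)


def test_trajectory_model_blocks(minimal_pdb):
    model = parse_structure(minimal_pdb)
    frames = [model.coordinates.copy() for _ in range(5)]
    text = write_trajectory(frames, model)
    assert text.count("MODEL") - text.count("ENDMDL") == 0
    assert text.count("ENDMDL") == 5
    single = write_trajectory(frames[:1], model)
    assert len(parse_structure(single)) == 3


def test_trajectory_rejects_bad_frames(minimal_pdb):
    model = parse_structure(minimal_pdb)
    with pytest.raises(ValueError, match="empty"):
        write_trajectory([], model)
    with pytest.raises(ValueError, match="shape"):
        write_trajectory([np.zeros((2, 3))], model)


def test_assignment_table_round_trip(minimal_pdb):
    model = parse_structure(minimal_pdb)
    table = assignments_table(model, [2, 1, 2])
    keys, labels = parse_assignments(table)
    assert keys == model.residues
    assert labels == [2, 1, 2]
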