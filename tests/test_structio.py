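"""Structure loading, preprocessing and subunit partitioning."""

import numpy as np
import pytest

from glycosite.structio import (
    CarbVocabulary,
    StructureError,
    load_structure,
    partition_subunits,
    preprocess,
    write_structure,
)


def _pdb_line(serial, name, resname, chain, resnum, x, y, z, element, record="ATOM"):
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n"
    )


def test_load_small_pdb(ala_pdb):
    st = load_structure(ala_pdb)
    assert len(st) == 3
    assert st.model_count_merged == 1
    assert st.atoms[0].element == "N"
    assert st.atoms[1].residue_name == "ALA"
    assert st.atoms[1].residue_key == ("A", 1, "")


def test_multimodel_concatenated_into_one_entity(tmp_path):
    lines = ["MODEL        1\n"]
    for i in range(5):
        lines.append(_pdb_line(i + 1, "CA", "GLY", "A", i + 1, float(i), 0, 0, "C"))
    lines += ["ENDMDL\n", "MODEL        2\n"]
    for i in range(5):
        lines.append(_pdb_line(i + 1, "CA", "GLY", "A", i + 1, float(i), 5, 0, "C"))
    lines += ["ENDMDL\n", "END\n"]
    path = tmp_path / "two_models.pdb"
    path.write_text("".join(lines))
    st = load_structure(path)
    assert len(st) == 10
    assert st.model_count_merged == 2
    # residue keys stay unique across merged models
    keys = {a.residue_key for a in st.atoms}
    assert len(keys) == 10


def test_empty_file_raises(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(StructureError):
        load_structure(path)


def test_unknown_format_raises(ala_pdb):
    with pytest.raises(StructureError):
        load_structure(ala_pdb, fmt="xyz")


@pytest.fixture()
def ala_water_hydrogen_pdb(tmp_path):
    lines = []
    coords = [(0, 0, 0), (1.5, 0, 0), (2.2, 1.3, 0), (3.4, 1.3, 0.4), (1.9, -1.2, 0.8)]
    for i, (name, el) in enumerate(zip(["N", "CA", "C", "O", "CB"], "NCCOC")):
        lines.append(_pdb_line(i + 1, name, "ALA", "A", 1, *coords[i], el))
    for i in range(3):
        lines.append(_pdb_line(10 + i, f"H{i}", "ALA", "A", 1, i * 0.3, 2.0, 2.0, "H"))
    lines.append(_pdb_line(20, "O", "HOH", "A", 101, 8.0, 8.0, 8.0, "O", "HETATM"))
    lines.append(_pdb_line(21, "O", "HOH", "A", 102, 9.0, 9.0, 9.0, "O", "HETATM"))
    path = tmp_path / "ala_w_h.pdb"
    path.write_text("".join(lines) + "END\n")
    return path


def test_preprocess_removes_waters_and_hydrogens(ala_water_hydrogen_pdb):
    st = preprocess(load_structure(ala_water_hydrogen_pdb))
    assert len(st) == 5
    assert all(a.element not in ("H", "D") for a in st.atoms)
    assert all(a.residue_name != "HOH" for a in st.atoms)


def test_preprocess_is_idempotent(ala_water_hydrogen_pdb):
    st1 = preprocess(load_structure(ala_water_hydrogen_pdb))
    st2 = preprocess(st1)
    assert [a for a in st2.atoms] == [a for a in st1.atoms]


@pytest.fixture()
def protein_two_glc_pdb(tmp_path):
    """Protein chain A plus two spatially separate GLC monomers also on A."""
    lines = []
    for i in range(3):
        lines.append(_pdb_line(i + 1, "CA", "GLY", "A", i + 1, i * 3.8, 0, 0, "C"))
    # two GLC molecules far apart (not covalently linked)
    lines.append(_pdb_line(10, "C1", "GLC", "A", 201, 0.0, 10.0, 0.0, "C", "HETATM"))
    lines.append(_pdb_line(11, "O1", "GLC", "A", 201, 1.2, 10.3, 0.0, "O", "HETATM"))
    lines.append(_pdb_line(12, "C1", "GLC", "A", 202, 20.0, 10.0, 0.0, "C", "HETATM"))
    lines.append(_pdb_line(13, "O1", "GLC", "A", 202, 21.2, 10.3, 0.0, "O", "HETATM"))
    path = tmp_path / "protein_two_glc.pdb"
    path.write_text("".join(lines) + "END\n")
    return path


def test_nonpolymer_molecules_get_unique_chain_names(protein_two_glc_pdb):
    st = preprocess(load_structure(protein_two_glc_pdb))
    glc_chains = {a.residue_key[0] for a in st.atoms if a.residue_name == "GLC"}
    protein_chains = {a.residue_key[0] for a in st.atoms if a.is_polymer}
    assert len(glc_chains) == 2
    assert glc_chains.isdisjoint(protein_chains)


def test_linked_sugar_residues_form_one_molecule(tmp_path):
    """Two sugar residues bridged by a 1.4 Å contact share a chain name."""
    lines = [_pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")]
    lines.append(_pdb_line(10, "C1", "XYP", "A", 201, 0.0, 10.0, 0.0, "C", "HETATM"))
    lines.append(_pdb_line(11, "O4", "XYP", "A", 201, 1.4, 10.0, 0.0, "O", "HETATM"))
    lines.append(_pdb_line(12, "C1", "XYP", "A", 202, 2.1, 10.0, 0.0, "C", "HETATM"))
    path = tmp_path / "xylobiose.pdb"
    path.write_text("".join(lines) + "END\n")
    st = preprocess(load_structure(path))
    xyp_chains = {a.residue_key[0] for a in st.atoms if a.residue_name == "XYP"}
    assert len(xyp_chains) == 1


def test_partition_classes(protein_two_glc_pdb):
    st = preprocess(load_structure(protein_two_glc_pdb))
    part = partition_subunits(st)
    assert part.classes() == {"protein", "carbohydrate"}
    covered = sorted(i for s in part.subunits for i in s.atom_indices)
    assert covered == list(range(len(st)))


def test_cyclodextrin_class_takes_priority(tmp_path):
    lines = [_pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")]
    lines.append(_pdb_line(10, "C1", "BCD", "A", 301, 0, 12, 0, "C", "HETATM"))
    path = tmp_path / "bcd.pdb"
    path.write_text("".join(lines) + "END\n")
    st = preprocess(load_structure(path))
    part = partition_subunits(st)
    assert "cyclodextrin" in part.classes()
    assert "carbohydrate" not in part.classes()


def test_unknown_ligand_falls_through_to_other(tmp_path):
    lines = [_pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")]
    lines.append(_pdb_line(10, "C1", "XYZ", "A", 301, 0, 12, 0, "C", "HETATM"))
    path = tmp_path / "xyz.pdb"
    path.write_text("".join(lines) + "END\n")
    part = partition_subunits(preprocess(load_structure(path)))
    assert part.classes() == {"protein", "other"}


def test_vocabulary_invariants_and_roundtrip(tmp_path):
    vocab = CarbVocabulary({"GLC", "GAL"}, {"BCD"})
    assert vocab.cyclodextrin_codes <= vocab.carbohydrate_codes
    path = tmp_path / "vocab.yaml"
    vocab.to_file(path)
    again = CarbVocabulary.from_file(path)
    assert again.carbohydrate_codes == vocab.carbohydrate_codes
    assert again.cyclodextrin_codes == vocab.cyclodextrin_codes
    with pytest.raises(ValueError):
        CarbVocabulary(set(), {"BCD"})


def test_write_read_roundtrip(protein_two_glc_pdb, tmp_path):
    st = load_structure(protein_two_glc_pdb)
    out = tmp_path / "roundtrip.pdb"
    write_structure(st, out)
    again = load_structure(out)
    assert len(again) == len(st)
    assert [a.atom_name for a in again.atoms] == [a.atom_name for a in st.atoms]
    assert [a.residue_name for a in again.atoms] == [a.residue_name for a in st.atoms]
    np.testing.assert_allclose(again.coords, st.coords, atol=1e-3)


def test_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n",
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n",
        "END\n",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("".join(lines))
    st = load_structure(path)
    assert len(st) == 1
    assert st.atoms[0].coords[0] == pytest.approx(5.0)
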