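"""Structure I/O, reference numbering, and residue selections."""

import numpy as np
import pytest

import sercakit as sk
from sercakit.structure import (
    DOMAINS,
    DomainDefinition,
    EmptySelectionError,
    common_residues,
    map_to_reference_numbering,
    select_coordinates,
)
from sercakit.synthetic import HelixSpec, _build_atom_array, _helix_coords, make_ideal_helix


def test_domain_definition_validation():
    with pytest.raises(ValueError):
        DomainDefinition("bad", ((10, 5),))
    with pytest.raises(ValueError):
        DomainDefinition("bad", ((0, 5),))
    with pytest.raises(ValueError):
        DomainDefinition("bad", ((1, 10), (5, 20)))  # overlap
    d = DomainDefinition("ok", ((1, 3), (10, 12)))
    assert d.residues == (1, 2, 3, 10, 11, 12)
    assert 11 in d and 5 not in d


def test_anchor_definition_residue_count():
    # 25 + 21 + 16 + 29 C-alpha positions across the four anchor helices
    assert len(DOMAINS["anchor"]) == 91


@pytest.mark.parametrize("fmt,suffix,tol", [("pdb", ".pdb", 1e-3), ("mmcif", ".cif", 1e-3)])
def test_write_read_round_trip(tmp_path, ideal_helix, fmt, suffix, tol):
    path = tmp_path / f"helix{suffix}"
    sk.write_structure(ideal_helix, path, format=fmt)
    back = sk.load_structure(path, format=fmt)
    assert len(back.residue_ids()) == 20
    assert back.backbone_complete_residues() == set(range(1, 21))
    assert np.abs(back.coord - ideal_helix.coord).max() < tol


def test_load_resolves_altloc_to_highest_occupancy(tmp_path):
    pdb_text = (
        "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40 10.00           N\n"
        "ATOM      2  N  BALA A   1       9.000   9.000   9.000  0.60 10.00           N\n"
        "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C\n"
        "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00 10.00           C\n"
        "ATOM      5  O   ALA A   1       2.000   2.200   1.000  1.00 10.00           O\n"
        "END\n"
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(pdb_text)
    s = sk.load_structure(path)
    n_coord = s.atom_coord(1, "N")
    assert np.allclose(n_coord, [9.0, 9.0, 9.0], atol=1e-3)  # occupancy 0.60 wins
    assert (s.atoms.res_id == 1).sum() == 4  # one N retained


def test_longest_chain_becomes_pump(tmp_path):
    big = make_ideal_helix(HelixSpec(n_residues=20))
    small_coords, small_res, small_names = _helix_coords(HelixSpec(n_residues=6, origin=(30, 0, 0)))
    small = _build_atom_array(small_coords, small_res, small_names, chain_id="B")
    merged = big.atoms + small
    import biotite.structure.io.pdb as pdb_io

    f = pdb_io.PDBFile()
    pdb_io.set_structure(f, merged)
    path = tmp_path / "two_chains.pdb"
    f.write(str(path))
    s = sk.load_structure(path)
    assert len(s.residue_ids()) == 20  # pump = longest chain
    assert s.ligands is not None and s.ligands.array_length() == 6 * 4


def test_select_coordinates_backbone_and_ca(ideal_helix, helix_domain):
    bb = select_coordinates(ideal_helix, helix_domain, atoms="backbone")
    ca = select_coordinates(ideal_helix, helix_domain, atoms="CA")
    assert bb.coords.shape == (80, 3)
    assert ca.coords.shape == (20, 3)
    assert list(np.unique(ca.atom_names)) == ["CA"]
    assert bb.missing_residues == ()


def test_select_reports_incomplete_residues(ideal_helix, helix_domain):
    # strip the O atom of residue 10
    mask = ~((ideal_helix.atoms.res_id == 10) & (ideal_helix.atoms.atom_name == "O"))
    s = sk.Structure(
        id="gappy",
        atoms=ideal_helix.atoms[mask],
        source_format="synthetic",
        coord=ideal_helix.coord[mask],
    )
    bb = select_coordinates(s, helix_domain, atoms="backbone")
    assert bb.missing_residues == (10,)
    assert bb.coords.shape == (76, 3)
    # CA selection unaffected
    assert select_coordinates(s, helix_domain, atoms="CA").coords.shape == (20, 3)


def test_empty_selection_raises(ideal_helix):
    with pytest.raises(EmptySelectionError):
        select_coordinates(ideal_helix, DomainDefinition("far", ((500, 520),)))


def _drop_residues(s, residues):
    mask = ~np.isin(s.atoms.res_id, list(residues))
    return sk.Structure(id=s.id, atoms=s.atoms[mask], source_format="synthetic", coord=s.coord[mask])


def test_common_residues_brute_force(helix_domain):
    h = make_ideal_helix(HelixSpec(n_residues=20))
    a = _drop_residues(h, {3, 4})
    b = _drop_residues(h, {4, 5, 17})
    c = _drop_residues(h, {11})
    got = common_residues([a, b, c], helix_domain)
    # brute-force oracle over residue sets
    expected = sorted(
        set(range(1, 21)) - {3, 4} - {4, 5, 17} - {11}
    )
    assert list(got) == expected


def test_common_residues_empty_names_most_restrictive(helix_domain):
    h = make_ideal_helix(HelixSpec(n_residues=20))
    a = _drop_residues(h, set(range(1, 11)))
    b = _drop_residues(h, set(range(10, 21)))
    with pytest.raises(ValueError, match="most restrictive"):
        common_residues([a, b], helix_domain)


def test_mapping_drops_insertion_and_is_idempotent():
    ref_seq = "A" * 100 + "G" * 50
    coords, res_ids, names = _helix_coords(HelixSpec(n_residues=155))
    res_names = np.array(["ALA"] * 155)
    res_names[100:105] = "TRP"  # 5-residue insertion after reference position 100
    res_names[105:] = "GLY"
    atoms = _build_atom_array(coords, res_ids, names)
    atoms.res_name = np.repeat(res_names, 4)
    s = sk.Structure(id="ins", atoms=atoms, source_format="synthetic", coord=coords)

    mapped, report = map_to_reference_numbering(s, ref_seq)
    assert report["dropped_residues"] == (101, 102, 103, 104, 105)
    assert len(mapped.residue_ids()) == 150
    assert mapped.residue_ids().max() == 150

    again, report2 = map_to_reference_numbering(mapped, ref_seq)
    assert report2["dropped_residues"] == ()
    assert np.array_equal(again.residue_ids(), mapped.residue_ids())
    assert np.allclose(again.coord, mapped.coord)


def test_mapping_refuses_low_identity(ideal_helix):
    with pytest.raises(ValueError, match="identity"):
        map_to_reference_numbering(ideal_helix, "W" * 20)
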