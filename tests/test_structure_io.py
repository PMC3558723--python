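"""Structure parsing, space-group resolution and symmetry-mate generation."""

import numpy as np
import pytest

from tcrsurvey import expand_symmetry, read_structure
from tcrsurvey.errors import NoCrystalContextError, UnknownSpaceGroupError
from tcrsurvey.structure_io import invert_mate, transform_xyz

from conftest import brute_force_mates

# operator list for space group 19 (P 2_1 2_1 2_1) transcribed from the
# International Tables: x,y,z / x+1/2,-y+1/2,-z / -x,y+1/2,-z+1/2 / -x+1/2,-y,z+1/2
P212121_OPS = [
    (np.eye(3), (0.0, 0.0, 0.0)),
    (np.diag([1.0, -1.0, -1.0]), (0.5, 0.5, 0.0)),
    (np.diag([-1.0, 1.0, -1.0]), (0.0, 0.5, 0.5)),
    (np.diag([-1.0, -1.0, 1.0]), (0.5, 0.0, 0.5)),
]


def _minimal_pdb(tmp_path, cryst1_line, name="toy.pdb"):
    lines = [cryst1_line] if cryst1_line else []
    lines += [
        "ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00  0.00           C",
        "ATOM      2  CA  GLY A   2      13.400  10.000  10.000  1.00  0.00           C",
        "END",
    ]
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


def test_p1_toy_has_single_identity_operator(scenario_cache):
    st = scenario_cache("isolated")["structure"]
    assert len(st.spacegroup_ops) == 1
    assert st.spacegroup_ops[0].is_identity()


def test_p212121_operators_match_international_tables(tmp_path):
    path = _minimal_pdb(
        tmp_path,
        "CRYST1   50.000   60.000   70.000  90.00  90.00  90.00 P 21 21 21",
    )
    st = read_structure(path)
    assert len(st.spacegroup_ops) == 4
    expected = {
        (tuple(np.asarray(r).ravel()), t) for r, t in P212121_OPS
    }
    got = {
        (tuple(op.rot.ravel()), tuple(op.tran % 1.0)) for op in st.spacegroup_ops
    }
    assert got == expected


def test_unknown_spacegroup_symbol_is_hard_error(tmp_path):
    path = _minimal_pdb(
        tmp_path, "CRYST1   50.000   60.000   70.000  90.00  90.00  90.00 Q 5"
    )
    with pytest.raises(UnknownSpaceGroupError, match="Q 5"):
        read_structure(path)


def test_missing_cell_gives_no_crystal_context(tmp_path):
    path = _minimal_pdb(tmp_path, None)
    st = read_structure(path)
    assert not st.has_crystal_context
    # sequence-level content is still available
    assert len(st.atoms) == 2
    with pytest.raises(NoCrystalContextError):
        expand_symmetry(st, 5.0)


def test_waters_and_hydrogens_excluded(tmp_path):
    path = tmp_path / "het.pdb"
    path.write_text(
        "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00  0.00           C\n"
        "ATOM      2  H   ALA A   1      10.500  10.000  10.000  1.00  0.00           H\n"
        "HETATM    3  O   HOH A 101      12.000  10.000  10.000  1.00  0.00           O\n"
        "HETATM    4  C1  NAG A 201      14.000  10.000  10.000  1.00  0.00           C\n"
        "END\n"
    )
    st = read_structure(path)
    assert set(st.atoms["resname"]) == {"ALA", "NAG"}
    assert (~st.atoms[st.atoms["resname"] == "NAG"]["is_protein"]).all()


def test_altloc_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(
        "CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1\n"
        "ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.40  0.00           C\n"
        "ATOM      2  CA BALA A   1      11.000  10.000  10.000  0.60  0.00           C\n"
        "END\n"
    )
    st = read_structure(path)
    assert len(st.atoms) == 1
    assert st.atoms.iloc[0]["x"] == pytest.approx(11.0)


def test_fractional_cartesian_round_trip(scenario_cache):
    st = scenario_cache("lattice-contact-F-strand")["structure"]
    F, O = st.frac_matrix, st.orth_matrix
    xyz = st.xyz
    back = (xyz @ F.T) @ O.T
    assert np.allclose(back, xyz, rtol=1e-9, atol=1e-9)
    assert np.allclose(F @ O, np.eye(3), atol=1e-12)


@pytest.mark.parametrize("scenario", ["isolated", "lattice-contact-F-strand"])
def test_expand_symmetry_equals_bruteforce_enumeration(scenario_cache, scenario):
    data = scenario_cache(scenario)
    st = data["structure"]
    got = [(m.source_op_index, m.lattice_shift) for m in data["mates"]]
    assert got == brute_force_mates(st, 5.0)


def test_expand_symmetry_mate_transform_consistency(scenario_cache):
    data = scenario_cache("lattice-contact-F-strand")
    st = data["structure"]
    for mate in data["mates"]:
        direct = transform_xyz(st, mate.source_op_index, mate.lattice_shift, st.xyz)
        assert np.allclose(direct, mate.transformed_xyz, atol=1e-6)
        assert mate.min_distance <= 5.0


def test_expand_symmetry_monotone_in_radius(scenario_cache):
    st = scenario_cache("lattice-contact-F-strand")["structure"]
    small = {(m.source_op_index, m.lattice_shift) for m in expand_symmetry(st, 5.0)}
    large = {(m.source_op_index, m.lattice_shift) for m in expand_symmetry(st, 10.0)}
    assert small <= large


def test_expand_symmetry_invariant_under_atom_reordering(scenario_cache):
    data = scenario_cache("lattice-contact-F-strand")
    st = data["structure"]
    shuffled = st.atoms.sample(frac=1.0, random_state=7).reset_index(drop=True)
    st2 = type(st)(st.entry_id, shuffled, st.cell, st.spacegroup_symbol, st.spacegroup_ops)
    got = [(m.source_op_index, m.lattice_shift) for m in expand_symmetry(st2, 5.0)]
    ref = [(m.source_op_index, m.lattice_shift) for m in data["mates"]]
    assert got == ref


def test_isolated_molecule_has_no_nearby_mates(scenario_cache):
    assert scenario_cache("isolated")["mates"] == []


def test_invert_mate_round_trip(scenario_cache):
    st = scenario_cache("lattice-contact-F-strand")["structure"]
    for mate in scenario_cache("lattice-contact-F-strand")["mates"]:
        j, inv_shift = invert_mate(st, mate.source_op_index, mate.lattice_shift)
        fwd = transform_xyz(st, mate.source_op_index, mate.lattice_shift, st.xyz)
        back = transform_xyz(st, j, inv_shift, fwd)
        assert np.allclose(back, st.xyz, atol=1e-6)


def test_mmcif_read_matches_pdb_read(scenario_cache, tmp_path):
    import gemmi

    data = scenario_cache("isolated")
    pdb_path = data["out_dir"] / f"{data['bundle'].entry_id}.pdb"
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "entry.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    via_cif = read_structure(cif_path, fmt="mmcif")
    ref = data["structure"]
    assert len(via_cif.atoms) == len(ref.atoms)
    assert via_cif.has_crystal_context
    assert len(via_cif.spacegroup_ops) == len(ref.spacegroup_ops)
    assert np.allclose(
        via_cif.atoms[["x", "y", "z"]].to_numpy(),
        ref.atoms[["x", "y", "z"]].to_numpy(),
        atol=1e-3,
    )


def test_debug_mate_writer_round_trips(scenario_cache, tmp_path):
    from tcrsurvey.structure_io import write_mate_pdb

    data = scenario_cache("lattice-contact-F-strand")
    mate = data["mates"][0]
    out = tmp_path / "mate.pdb"
    write_mate_pdb(data["structure"], mate, out)
    again = read_structure(out)
    assert len(again.atoms) == len(data["structure"].atoms)
    assert np.allclose(
        again.atoms[["x", "y", "z"]].to_numpy(), mate.transformed_xyz, atol=2e-3
    )
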