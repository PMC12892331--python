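"""PDB parsing, atom typing, reference frame, and superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import sitevec as sv
from sitevec.structure_model import (BONDI_RADII, EmptyStructureError,
                                     FormatError, PairingError,
                                     RadiusLookupError, SelectionError)

from conftest import make_atom, make_structure

PDB_3ATOM = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.000   3.500   3.000  1.00  0.00           C
END
"""

PDB_HEME = """\
HETATM    1 FE   HEM A 501       0.000   0.000   0.000  1.00  0.00          FE
HETATM    2  NA  HEM A 501       2.000   0.000   0.000  1.00  0.00           N
HETATM    3  NB  HEM A 501       0.000   2.000   0.000  1.00  0.00           N
HETATM    4  NC  HEM A 501      -2.000   0.000   0.000  1.00  0.00           N
HETATM    5  ND  HEM A 501       0.000  -2.000   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   1       1.000   1.000   5.000  1.00  0.00           C
HETATM    7  O   HOH A 601       4.000   4.000   4.000  1.00  0.00           O
END
"""


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadStructure:
    def test_three_atom_roundtrip(self, tmp_path):
        st = sv.read_structure(write(tmp_path, "a.pdb", PDB_3ATOM))
        assert len(st.atoms) == 3
        np.testing.assert_allclose(st.atoms[0].coordinates, [1.0, 2.0, 3.0])
        assert st.atoms[1].name == "CA"
        assert st.atoms[1].element == "C"
        assert st.atoms[0].is_backbone

    def test_multi_model_selects_requested_model(self, tmp_path):
        models = []
        for m in range(1, 6):
            models.append(f"MODEL     {m}")
            models.append(f"ATOM      1  CA  ALA A   1    {float(m):8.3f}"
                          f"{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
            models.append("ENDMDL")
        models.append("END")
        path = write(tmp_path, "multi.pdb", "\n".join(models) + "\n")
        st = sv.read_structure(path, model_index=2)
        assert st.frame_index == 2
        assert st.atoms[0].coordinates[0] == pytest.approx(2.0)

    def test_heme_hetatm_preserved(self, tmp_path):
        st = sv.read_structure(write(tmp_path, "hem.pdb", PDB_HEME))
        hem = [a for a in st.atoms if a.residue_name == "HEM"]
        assert len(hem) == 5
        assert hem[0].element == "FE"
        assert {a.name for a in hem[1:]} == {"NA", "NB", "NC", "ND"}

    def test_drop_waters_flag(self, tmp_path):
        path = write(tmp_path, "hem.pdb", PDB_HEME)
        st = sv.read_structure(path, drop_waters_ions=True)
        assert all(a.residue_name != "HOH" for a in st.atoms)
        assert len(st.atoms) == 6

    def test_unparsable_file_names_offending_line(self, tmp_path):
        bad = PDB_3ATOM.replace("   2.500", "  xx.500")
        path = write(tmp_path, "bad.pdb", bad)
        with pytest.raises(FormatError, match="line 2"):
            sv.read_structure(path)

    def test_pdb_write_roundtrip(self, tmp_path):
        st = sv.read_structure(write(tmp_path, "hem.pdb", PDB_HEME))
        out = tmp_path / "out.pdb"
        sv.write_structure(st, out)
        back = sv.read_structure(out)
        np.testing.assert_allclose(back.coords(), st.coords(), atol=1e-3)
        assert [a.name for a in back.atoms] == [a.name for a in st.atoms]


class TestAssignment:
    def test_default_radius_table_carbon(self, tmp_path):
        st = sv.read_structure(write(tmp_path, "a.pdb", PDB_3ATOM))
        st = sv.assign_radii(st)
        assert st.atoms[1].vdw_radius == pytest.approx(1.70)
        assert st.atoms[0].vdw_radius == pytest.approx(BONDI_RADII["N"])

    def test_custom_table_applies_to_all(self):
        st = make_structure([((0, 0, 1), 1.0, 0.0), ((0, 0, 2), 1.0, 0.0)])
        for a in st.atoms:
            a.element = "X"
        st2 = sv.assign_radii(st, {"X": 2.0})
        assert all(a.vdw_radius == 2.0 for a in st2.atoms)

    def test_missing_element_without_fallback_raises(self):
        st = make_structure([((0, 0, 1), 1.0, 0.0)])
        st.atoms[0].element = "QQ"
        with pytest.raises(RadiusLookupError, match="QQ"):
            sv.assign_radii(st, {})
        st2 = sv.assign_radii(st, {}, fallback=1.5)
        assert st2.atoms[0].vdw_radius == 1.5

    def test_charge_table_and_fallback(self):
        st = make_structure([((0, 0, 1), 1.0, 0.0), ((0, 0, 2), 1.0, 0.0)])
        st.atoms[0].residue_name = "GLU"
        st.atoms[0].name = "OE1"
        st.atoms[1].residue_name = "GLU"
        st.atoms[1].name = "CB"
        out = sv.assign_charges(st, {("GLU", "OE1"): -0.5}, fallback=0.0)
        assert out.atoms[0].partial_charge == -0.5
        assert out.atoms[1].partial_charge == 0.0
        assert out.meta["n_unmatched_charges"] == 1

    def test_unmatched_count_by_set_difference(self):
        table = {("ALA", "CA"): 0.1}
        specs = [((0, 0, i + 1.0), 1.0, 0.0) for i in range(5)]
        st = make_structure(specs)
        for i, a in enumerate(st.atoms):
            a.residue_name = "ALA"
            a.name = "CA" if i < 2 else f"CB{i}"
        out = sv.assign_charges(st, table)
        expected_unmatched = sum(
            1 for a in st.atoms if ("ALA", a.name) not in table)
        assert out.meta["n_unmatched_charges"] == expected_unmatched

    def test_assignment_preserves_coordinates_and_order(self):
        st = make_structure([((1, 2, 3), 1.0, 0.0), ((4, 5, 6), 1.0, 0.0)])
        out = sv.assign_charges(sv.assign_radii(st, fallback=1.7))
        np.testing.assert_array_equal(out.coords(), st.coords())
        assert [a.name for a in out.atoms] == [a.name for a in st.atoms]


def tilted_heme_structure(rotation, shift):
    """Planar 4-N ring + Fe + one 'above' atom, rigidly transformed."""
    theta = np.linspace(0, 2 * np.pi, 4, endpoint=False)
    ring = np.column_stack([2 * np.cos(theta), 2 * np.sin(theta), np.zeros(4)])
    atoms = [make_atom(rotation @ np.zeros(3) + shift, name="FE", element="FE",
                       residue_name="HEM", residue_id=501)]
    for name, r in zip(("NA", "NB", "NC", "ND"), ring):
        atoms.append(make_atom(rotation @ r + shift, name=name, element="N",
                               residue_name="HEM", residue_id=501))
    atoms.append(make_atom(rotation @ np.array([0.5, 0.5, 5.0]) + shift,
                           name="CA", element="C", residue_name="ALA",
                           residue_id=1))
    return sv.Structure(id="heme", atoms=atoms)


class TestReferenceFrame:
    def test_inverts_known_transform(self):
        rot = Rotation.from_euler("xyz", [0.4, -0.3, 1.1]).as_matrix()
        st = tilted_heme_structure(rot, np.array([1.0, 2.0, 3.0]))
        rf = sv.compute_reference_frame(st)
        out = rf.apply_structure(st)
        np.testing.assert_allclose(out.atoms[0].coordinates, 0.0, atol=1e-6)
        ring_z = [a.coordinates[2] for a in out.atoms[1:5]]
        assert np.max(np.abs(ring_z)) < 1e-6
        assert out.atoms[5].coordinates[2] > 0  # centroid side is +z

    def test_identity_on_framed_structure(self):
        st = tilted_heme_structure(np.eye(3), np.zeros(3))
        rf0 = sv.compute_reference_frame(st)
        framed = rf0.apply_structure(st)
        rf = sv.compute_reference_frame(framed)
        np.testing.assert_allclose(rf.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(rf.translation, 0.0, atol=1e-6)

    def test_idempotent_application(self):
        rot = Rotation.from_euler("zyx", [0.9, 0.2, -0.5]).as_matrix()
        st = tilted_heme_structure(rot, np.array([-2.0, 4.0, 1.0]))
        once = sv.compute_reference_frame(st).apply_structure(st)
        twice = sv.compute_reference_frame(once).apply_structure(once)
        np.testing.assert_allclose(twice.coords(), once.coords(), atol=1e-6)

    def test_rotation_is_proper(self):
        st = tilted_heme_structure(np.eye(3), np.zeros(3))
        rf = sv.compute_reference_frame(st)
        assert np.linalg.det(rf.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_anchor_not_found(self):
        st = make_structure([((0, 0, 1), 1.0, 0.0)])
        with pytest.raises(SelectionError):
            sv.compute_reference_frame(st)

    def test_collinear_plane_atoms_rejected(self):
        atoms = [make_atom((0, 0, 0), name="FE", element="FE",
                           residue_name="HEM")]
        for i, name in enumerate(("NA", "NB", "NC")):
            atoms.append(make_atom((i + 1.0, 0, 0), name=name, element="N",
                                   residue_name="HEM"))
        st = sv.Structure(id="bad", atoms=atoms)
        with pytest.raises(Exception, match="collinear"):
            sv.compute_reference_frame(st)


class TestSuperpose:
    def _protein(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0, 5, (n, 3))
        atoms = [make_atom(c, name="CA", residue_name="ALA", residue_id=i + 1)
                 for i, c in enumerate(coords)]
        return sv.Structure(id="p", atoms=atoms)

    def test_exact_rigid_copy_recovered(self):
        ref = self._protein(50)
        rot = Rotation.from_euler("xyz", [0.3, 0.8, -1.2]).as_matrix()
        mob = ref.with_coords(ref.coords() @ rot.T + np.array([5, -3, 2.0]))
        out, rmsd = sv.superpose(mob, ref, {"atom_name": "CA"})
        assert rmsd < 1e-6
        np.testing.assert_allclose(out.coords(), ref.coords(), atol=1e-6)

    def test_gaussian_noise_rmsd_matches_theory(self):
        # minimal RMSD under isotropic noise sigma approaches sqrt(3)*sigma
        ref = self._protein(1000, seed=1)
        rng = np.random.default_rng(2)
        noisy = ref.with_coords(ref.coords() + rng.normal(0, 0.1, (1000, 3)))
        _, rmsd = sv.superpose(noisy, ref, {"atom_name": "CA"})
        assert rmsd == pytest.approx(np.sqrt(3) * 0.1, rel=0.15)

    def test_invariant_to_pre_rotation(self):
        ref = self._protein(200, seed=3)
        rng = np.random.default_rng(4)
        mob = ref.with_coords(ref.coords() + rng.normal(0, 0.2, (200, 3)))
        _, rmsd1 = sv.superpose(mob, ref, {"atom_name": "CA"})
        rot = Rotation.from_euler("xyz", [1.0, -0.4, 2.2]).as_matrix()
        mob2 = mob.with_coords(mob.coords() @ rot.T + 7.0)
        _, rmsd2 = sv.superpose(mob2, ref, {"atom_name": "CA"})
        assert rmsd1 == pytest.approx(rmsd2, abs=1e-9)

    def test_agrees_with_independent_implementation(self):
        # biotite's superimpose as the independent oracle
        import biotite.structure as struc
        ref = self._protein(80, seed=5)
        rng = np.random.default_rng(6)
        mob = ref.with_coords(ref.coords() + rng.normal(0, 0.3, (80, 3)))
        _, rmsd = sv.superpose(mob, ref, {"atom_name": "CA"})

        def as_array(st):
            arr = struc.AtomArray(len(st.atoms))
            arr.coord[:] = st.coords()
            return arr

        fitted, _ = struc.superimpose(as_array(ref), as_array(mob))
        oracle = float(struc.rmsd(as_array(ref), fitted))
        assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_too_few_atoms_is_pairing_error(self):
        ref = self._protein(2)
        with pytest.raises(PairingError):
            sv.superpose(ref, ref, {"atom_name": "CA"})

    def test_mismatched_selection_sizes(self):
        a = self._protein(10)
        b = self._protein(12)
        with pytest.raises(PairingError):
            sv.superpose(a, b, {"atom_name": "CA"})


def test_empty_structure_rejected():
    with pytest.raises(EmptyStructureError):
        sv.Structure(id="empty", atoms=[])
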