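"""Structure model, PDB I/O, superposition and RMSD/RMSF analytics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from enzdesign.core_structures import (Atom, DegenerateSelectionError,
                                       Ensemble, InsufficientFramesError,
                                       MalformedInputError, Selection,
                                       Structure, TopologyError,
                                       pairwise_rmsd_matrix, read_structure,
                                       rmsf_profile, superpose,
                                       write_structure)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00  0.00           C
END
"""

THREE_MODELS = "".join(
    f"MODEL {m}\n"
    f"ATOM      1  N   ALA A   1       {m}.000   0.000   0.000  1.00  0.00           N\n"
    f"ATOM      2  CA  ALA A   1       {m + 1}.500   0.000   0.000  1.00  0.00           C\n"
    "ENDMDL\n"
    for m in (1, 2, 3))

MISSING_ATOM = """\
MODEL 1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL 2
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ENDMDL
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
END
"""


class TestPDBIO:
    def test_minimal_parse_identity(self):
        ens = read_structure(MINIMAL_PDB)
        assert len(ens) == 1 and len(ens.members[0]) == 2
        np.testing.assert_allclose(ens.members[0].atoms[0].coords, [1, 2, 3])
        a = ens.members[0].atoms[1]
        assert (a.chain, a.res_id, a.name, a.res_name) == ("A", 1, "CA", "ALA")

    def test_three_models(self):
        ens = read_structure(THREE_MODELS)
        assert len(ens) == 3
        assert ens.members[2].atoms[0].coords[0] == 3.0

    def test_topology_error_across_models(self):
        with pytest.raises(TopologyError):
            read_structure(MISSING_ATOM)

    def test_duplicate_atom_rejected(self):
        bad = MINIMAL_PDB.replace(" CA ", " N  ", 1)
        with pytest.raises(MalformedInputError):
            read_structure(bad)

    def test_altloc_highest_occupancy_wins(self):
        s = read_structure(ALTLOC_PDB).members[0]
        assert len(s) == 2
        assert s.find_atom("A", 1, "CA").coords[0] == 2.0

    def test_round_trip_generated_ensemble(self, toy):
        rng = np.random.default_rng(0)
        members = [toy.copy()]
        for k in range(3):
            m = toy.copy()
            m.set_coords(toy.coords + rng.normal(0, 1, toy.coords.shape))
            members.append(m)
        ens = Ensemble(members)
        back = read_structure(write_structure(ens))
        assert len(back) == 4
        for a, b in zip(ens.members, back.members):
            np.testing.assert_allclose(a.coords, b.coords, atol=5.1e-4)
            assert [x.name for x in a.atoms] == [x.name for x in b.atoms]
            assert [x.res_id for x in a.atoms] == [x.res_id for x in b.atoms]

    def test_n_model_blocks(self, toy):
        ens = Ensemble([toy.copy() for _ in range(5)])
        assert write_structure(ens).count("MODEL ") == 5

    def test_empty_inputs_error(self):
        with pytest.raises(MalformedInputError):
            read_structure("END\n")
        with pytest.raises(Exception):
            Ensemble([])

    def test_biopython_cross_check(self, toy):
        """Independent oracle: Bio.PDB parses our writer's output identically."""
        from io import StringIO

        from Bio.PDB import PDBParser

        text = write_structure(Ensemble([toy]))
        parser = PDBParser(QUIET=True)
        bio = parser.get_structure("x", StringIO(text))
        bio_atoms = list(bio.get_atoms())
        assert len(bio_atoms) == len(toy)
        ours = toy.coords
        theirs = np.array([a.coord for a in bio_atoms])
        np.testing.assert_allclose(ours, theirs, atol=5.1e-4)


class TestSuperpose:
    def test_self_rmsd_zero(self, toy):
        r = superpose(toy, toy, Selection.ca())
        assert r.rmsd < 1e-10
        np.testing.assert_allclose(r.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_recovered(self, toy):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = toy.copy()
        moved.set_coords(toy.coords @ Rz.T + np.array([5.0, 0, 0]))
        r = superpose(moved, toy, Selection.ca())
        assert r.rmsd < 1e-8
        assert abs(np.linalg.det(r.rotation) - 1.0) < 1e-9

    def test_collinear_selection_degenerate(self):
        atoms = [Atom(i + 1, "CA", "C", "ALA", i + 1, "A",
                      np.array([float(i), 0, 0])) for i in range(4)]
        line = Structure(atoms)
        with pytest.raises(DegenerateSelectionError):
            superpose(line, line, Selection.ca())

    def test_too_few_pairs(self, toy):
        sel = Selection(lambda c, r, n: n == "CA" and r <= 2)
        with pytest.raises(DegenerateSelectionError):
            superpose(toy, toy, sel)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rmsd_rigid_invariance_property(self, toy, seed):
        """RMSD is invariant under arbitrary rigid motion of either input."""
        rng = np.random.default_rng(seed)
        other = toy.copy()
        other.set_coords(toy.coords + rng.normal(0, 0.5, toy.coords.shape))
        base = superpose(other, toy, Selection.ca()).rmsd
        R = Rotation.random(random_state=int(seed % (2 ** 31))).as_matrix()
        t = rng.normal(0, 10, 3)
        moved = other.copy()
        moved.set_coords(other.coords @ R.T + t)
        assert abs(superpose(moved, toy, Selection.ca()).rmsd - base) < 1e-8


class TestRMSDMatrix:
    def test_identical_copies_zero(self, toy):
        mat = pairwise_rmsd_matrix([toy, toy.copy(), toy.copy()],
                                   Selection.ca())
        assert np.allclose(mat, 0.0)

    def test_symmetry_and_diagonal(self, toy):
        rng = np.random.default_rng(3)
        structs = [toy]
        for _ in range(2):
            s = toy.copy()
            s.set_coords(toy.coords + rng.normal(0, 0.4, toy.coords.shape))
            structs.append(s)
        for sel in (Selection.ca(),
                    Selection.backbone(sorted(toy.meta["triad"].values()))):
            mat = pairwise_rmsd_matrix(structs, sel)
            assert np.allclose(mat, mat.T)
            assert np.allclose(np.diag(mat), 0.0)

    def test_rigidly_moved_row_zero(self, toy):
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = toy.copy()
        moved.set_coords(toy.coords @ R.T + np.array([1.0, 2.0, 3.0]))
        mat = pairwise_rmsd_matrix([toy, toy.copy(), moved], Selection.ca())
        assert np.abs(mat[2]).max() < 1e-8


class TestRMSF:
    def test_identical_frames_zero(self, toy):
        ens = Ensemble([toy.copy() for _ in range(5)])
        prof = rmsf_profile(ens, Selection.ca(), fit=False)
        assert max(prof.values()) < 1e-12

    def test_two_frame_analytic(self, toy):
        """One atom displaced 2 A in one of two frames -> RMSF exactly 1 A."""
        a = toy.copy()
        b = toy.copy()
        idx = Selection.ca().indices(toy)[0]
        coords = b.coords
        coords[idx, 0] += 2.0
        b.set_coords(coords)
        prof = rmsf_profile(Ensemble([a, b]), Selection.ca(), fit=False)
        res = toy.atoms[idx].res_id
        assert prof[res] == pytest.approx(1.0, abs=1e-12)
        others = [v for r, v in prof.items() if r != res]
        assert max(others) < 1e-12

    def test_frame_permutation_invariance(self, toy):
        rng = np.random.default_rng(5)
        members = []
        for _ in range(8):
            m = toy.copy()
            m.set_coords(toy.coords + rng.normal(0, 0.3, toy.coords.shape))
            members.append(m)
        p1 = rmsf_profile(Ensemble(members), Selection.ca(), fit=False)
        p2 = rmsf_profile(Ensemble(members[::-1]), Selection.ca(), fit=False)
        for r in p1:
            assert p1[r] == pytest.approx(p2[r], abs=1e-10)

    def test_single_member_error(self, toy):
        with pytest.raises(InsufficientFramesError):
            rmsf_profile(Ensemble([toy]), Selection.ca())
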