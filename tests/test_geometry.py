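"""Geometry: structure parsing, distances, torsions, H-bond predicate."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gemdiol import geometry
from gemdiol.geometry import (
    Atom,
    StructureModel,
    dihedral,
    distance,
    extract_frame_features,
    hydrogen_bond,
    read_structure,
    write_structure,
)
from gemdiol.synthetic import make_structure_frames

MINIMAL_PDB = """\
ATOM      1  CG  ASP B 257       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CG  ASP B 385       7.000   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_two_atom_parse(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert len(model) == 2
        assert model.get("B", 257, "CG").xyz == (0.0, 0.0, 0.0)
        assert model.get("B", 385, "CG").resname == "ASP"

    def test_multi_model_selector(self, tmp_path):
        frames = make_structure_frames(n_frames=3, seed=5)
        p = tmp_path / "multi.pdb"
        write_structure(frames, p)
        model = read_structure(p, frame_selector=1)
        assert len(model) == len(frames[1])
        # picks model 2's coordinates, not model 1's
        got = np.array(model.get("B", 257, "CG").xyz)
        want = np.array(frames[1].get("B", 257, "CG").xyz)
        assert np.allclose(got, want, atol=1e-3)

    def test_write_read_roundtrip(self, tmp_path):
        frames = make_structure_frames(n_frames=2, seed=9)
        p = tmp_path / "rt.pdb"
        write_structure(frames, p)
        for i, original in enumerate(frames):
            back = read_structure(p, frame_selector=i)
            assert len(back) == len(original)
            for atom in original.atoms:
                got = back.get(atom.chain, atom.resnum, atom.name)
                assert got.resname == atom.resname
                assert np.allclose(got.xyz, atom.xyz, atol=1.5e-3)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.pdb")

    def test_missing_model(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(MINIMAL_PDB)
        with pytest.raises(ValueError, match="model 3"):
            read_structure(p, frame_selector=3)


class TestDistance:
    def test_coincident(self):
        assert distance((0, 0, 0), (0, 0, 0)) == 0.0

    def test_345_triangle(self):
        assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_matches_componentwise_brute_force(self, rng):
        for _ in range(100):
            a, b = rng.normal(size=(2, 3))
            expected = math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))
            assert distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 3))
        assert distance(a, b) == distance(b, a)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral((1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, 1, 0)) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_planar_trans_is_180(self):
        assert dihedral((1, 1, 0), (1, 0, 0), (-1, 0, 0), (-1, -1, 0)) == pytest.approx(
            180.0, abs=1e-10
        )

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_matches_mdanalysis_oracle(self, rng):
        """Cross-check against MDAnalysis' independent torsion routine."""
        from MDAnalysis.lib.distances import calc_dihedrals

        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except ValueError:
                continue
            ref = math.degrees(
                float(
                    calc_dihedrals(
                        pts[0][None], pts[1][None], pts[2][None], pts[3][None]
                    )[0]
                )
            )
            # both conventions agree up to the wrap at ±180 (MDAnalysis
            # computes in float32, hence the tolerance)
            diff = (ours - ref + 180.0) % 360.0 - 180.0
            assert abs(diff) < 1e-3

    def test_chain_reversal_symmetry(self, rng):
        """The torsion is unchanged when the chain is traversed backwards
        (d,c,b,a) — a defining property of the standard convention."""
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 2
            try:
                fwd = dihedral(*pts)
            except ValueError:
                continue
            assert dihedral(*pts[::-1]) == pytest.approx(fwd, abs=1e-9)

    def test_mirror_antisymmetry(self, rng):
        """Reflecting the coordinates (an improper operation) negates the
        torsion."""
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 2
            try:
                fwd = dihedral(*pts)
            except ValueError:
                continue
            mirrored = pts * np.array([1.0, 1.0, -1.0])
            rev = dihedral(*mirrored)
            if abs(abs(fwd) - 180.0) < 1e-9:
                assert abs(rev) == pytest.approx(180.0)
            else:
                assert rev == pytest.approx(-fwd, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(4, 3)) * 2
        ref = dihedral(*pts)
        dref = distance(pts[0], pts[3])
        for _ in range(20):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(size=3) * 10
            moved = pts @ rot.T + shift
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)
            assert distance(moved[0], moved[3]) == pytest.approx(dref, abs=1e-9)


class TestHydrogenBond:
    def test_ideal_linear_geometry(self):
        # D at origin, H on the line to A; D-A 2.8 Å
        assert hydrogen_bond((0, 0, 0), (1.0, 0, 0), (2.8, 0, 0))

    def test_beyond_distance_cutoff(self):
        assert not hydrogen_bond((0, 0, 0), (1.0, 0, 0), (5.0, 0, 0))

    def test_sweep_matches_predicate_reevaluation(self, rng):
        cutoffs = (3.5, 135.0)
        for _ in range(300):
            d = rng.normal(size=3)
            h = d + rng.normal(scale=0.5, size=3)
            a = d + rng.normal(scale=2.0, size=3)
            got = hydrogen_bond(d, h, a, cutoffs)
            # independent straight-line evaluation of both conditions
            dda = np.linalg.norm(d - a)
            v1, v2 = d - h, a - h
            ang = math.degrees(
                math.acos(
                    np.clip(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1,
                        1,
                    )
                )
            )
            assert got == (dda <= cutoffs[0] and ang >= cutoffs[1])


class TestExtractFeatures:
    def _model_with(self, dd=7.0, dowc=3.0):
        frames = make_structure_frames(n_frames=1, seed=0, jitter=0.0)
        model = frames[0]
        atoms = [a for a in model.atoms if not (a.chain == "B" or a.chain == "W")]
        atoms.append(Atom("CG", "ASP", 257, "B", (0.0, 0.0, 0.0)))
        atoms.append(Atom("CG", "ASP", 385, "B", (dd, 0.0, 0.0)))
        carbonyl = np.array(model.get("S", 49, "C").xyz)
        atoms.append(Atom("O", "HOH", 1, "W", tuple(carbonyl + [dowc, 0.0, 0.0])))
        return StructureModel(atoms=atoms, frame_id=0)

    def test_constructed_dd_asp(self):
        frame = extract_frame_features(self._model_with(dd=7.0))
        assert frame.dd_asp == pytest.approx(7.0)

    def test_constructed_dowc(self):
        frame = extract_frame_features(self._model_with(dowc=3.0))
        assert frame.d_OwC == pytest.approx(3.0)

    def test_batch_equals_per_atom_recomposition(self):
        """Composition oracle: features equal distance/dihedral recomputed
        atom by atom from the same coordinates."""
        amap = geometry.DEFAULT_ATOM_MAP
        for model in make_structure_frames(n_frames=5, seed=3):
            frame = extract_frame_features(model)
            (s1, s2) = amap["dd_asp"]
            assert frame.dd_asp == pytest.approx(
                distance(model.get(*s1).xyz, model.get(*s2).xyz)
            )
            for (phi_lab, psi_lab), defs in amap["torsions"].items():
                assert frame.torsions[phi_lab] == pytest.approx(
                    dihedral(*(model.get(*s).xyz for s in defs["phi"]))
                )
                assert frame.torsions[psi_lab] == pytest.approx(
                    dihedral(*(model.get(*s).xyz for s in defs["psi"]))
                )

    def test_missing_atom_names_selector(self):
        model = StructureModel(
            atoms=[Atom("CG", "ASP", 257, "B", (0, 0, 0))], frame_id=0
        )
        with pytest.raises(KeyError, match="385"):
            extract_frame_features(model)

    def test_deterministic_for_fixed_map(self):
        model = make_structure_frames(n_frames=1, seed=7)[0]
        f1 = extract_frame_features(model)
        f2 = extract_frame_features(model)
        assert f1.dd_asp == f2.dd_asp and f1.torsions == f2.torsions


class TestFeatureTables:
    def test_roundtrip_through_tsv(self, tmp_path):
        from gemdiol.synthetic import make_geometry_frames

        frames = make_geometry_frames({"Asp257i_385i": 0.5}, n=20, seed=4)
        p = tmp_path / "features.tsv"
        geometry.write_feature_table(frames, p)
        back = geometry.table_to_frames(geometry.read_feature_table(p))
        assert len(back) == len(frames)
        assert back[3].dd_asp == pytest.approx(frames[3].dd_asp, abs=1e-9)
        assert back[3].hb_geometries[0][2] == frames[3].hb_geometries[0][2]
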