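"""Superposition, per-residue RMSD, and halogen-pi geometry tests."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from erksel.geometry import (
    Atom,
    SelectionSpec,
    StructureModel,
    apply_transform,
    cl_pi_distance,
    kabsch_superpose,
    read_structure,
    residue_rmsd,
)

from conftest import make_ca_model, pdb_atom_line, rigid_transform


@pytest.fixture
def cloud():
    rng = np.random.default_rng(42)
    return rng.normal(size=(20, 3)) * 6.0


@pytest.fixture
def resnums():
    return list(range(109, 129))


class TestReadStructure:
    def test_three_atom_pdb(self, tmp_path):
        lines = [
            pdb_atom_line(1, "N", "GLY", "A", 1, (0.0, 0.0, 0.0), element="N"),
            pdb_atom_line(2, "CA", "GLY", "A", 1, (1.5, 0.0, 0.0)),
            pdb_atom_line(3, "C", "GLY", "A", 1, (2.2, 1.3, 0.0)),
            "END",
        ]
        path = tmp_path / "tiny.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        assert len(model.atoms) == 3
        assert model.get("A", 1, "CA").coords == (1.5, 0.0, 0.0)

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "SER", "A", 5, (0.0, 0.0, 0.0), occ=0.4, altloc="A"),
            pdb_atom_line(2, "CA", "SER", "A", 5, (9.0, 9.0, 9.0), occ=0.6, altloc="B"),
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        assert len(model.atoms) == 1
        assert model.atoms[0].coords == (9.0, 9.0, 9.0)

    def test_hydrogens_dropped(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
            pdb_atom_line(2, "HA", "ALA", "A", 1, (0.5, 0.5, 0.5), element="H"),
            "END",
        ]
        path = tmp_path / "h.pdb"
        path.write_text("\n".join(lines) + "\n")
        assert len(read_structure(path).atoms) == 1

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "absent.pdb")


class TestKabsch:
    def test_identical_structures(self, cloud, resnums):
        model = make_ca_model(resnums, cloud)
        sel = SelectionSpec(residue_ranges=((109, 128),))
        result = kabsch_superpose(model, model, sel)
        assert result.rmsd_fit == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_known_rigid_transform_recovered(self, cloud, resnums):
        ref = make_ca_model(resnums, cloud)
        mob = make_ca_model(resnums, rigid_transform(cloud, 30.0))
        sel = SelectionSpec(residue_ranges=((109, 128),))
        result = kabsch_superpose(ref, mob, sel)
        assert result.rmsd_fit < 1e-9
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(result.rotation @ result.rotation.T, np.eye(3), atol=1e-9)

    def test_agrees_with_brute_force_minimum_on_four_points(self):
        """Four-point cloud with one displaced point: compare with a direct
        numerical minimisation over rotations and translations."""
        ref_xyz = np.array(
            [[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0], [0, 0, 3.0]]
        )
        mob_xyz = ref_xyz.copy()
        mob_xyz[3] += np.array([0.8, -0.4, 0.3])
        ref = make_ca_model([10, 11, 12, 13], ref_xyz)
        mob = make_ca_model([10, 11, 12, 13], mob_xyz)
        sel = SelectionSpec(residue_ranges=((10, 13),))
        result = kabsch_superpose(ref, mob, sel)

        def objective(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = mob_xyz @ rot.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - ref_xyz) ** 2, axis=1)))

        best = min(
            (
                minimize(objective, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
                for x0 in (np.zeros(6), np.r_[0.3, -0.2, 0.1, 1.0, -1.0, 0.5])
            ),
            key=lambda r: r.fun,
        )
        assert result.rmsd_fit == pytest.approx(best.fun, abs=1e-6)

    def test_agrees_with_scipy_align_vectors(self, cloud, resnums):
        rng = np.random.default_rng(7)
        mob_xyz = rigid_transform(cloud, 55.0, axis=(1, 2, 0.5)) + rng.normal(
            scale=0.3, size=cloud.shape
        )
        ref = make_ca_model(resnums, cloud)
        mob = make_ca_model(resnums, mob_xyz)
        sel = SelectionSpec(residue_ranges=((109, 128),))
        result = kabsch_superpose(ref, mob, sel)
        rot, rssd = Rotation.align_vectors(
            cloud - cloud.mean(axis=0), mob_xyz - mob_xyz.mean(axis=0)
        )
        assert np.allclose(result.rotation, rot.as_matrix(), atol=1e-8)
        assert result.rmsd_fit == pytest.approx(rssd / np.sqrt(len(cloud)), abs=1e-8)

    def test_rmsd_invariant_under_rigid_pretransform(self, cloud, resnums):
        rng = np.random.default_rng(3)
        noisy = cloud + rng.normal(scale=0.5, size=cloud.shape)
        sel = SelectionSpec(residue_ranges=((109, 128),))
        base = kabsch_superpose(
            make_ca_model(resnums, cloud), make_ca_model(resnums, noisy), sel
        )
        pre = kabsch_superpose(
            make_ca_model(resnums, rigid_transform(cloud, 70.0, axis=(0, 1, 1))),
            make_ca_model(resnums, rigid_transform(noisy, -25.0, shift=(4, 4, -2))),
            sel,
        )
        assert pre.rmsd_fit == pytest.approx(base.rmsd_fit, abs=1e-9)

    def test_missing_residues_reported(self, cloud, resnums):
        ref = make_ca_model(resnums, cloud)
        mob = make_ca_model(resnums[:-2], cloud[:-2])
        sel = SelectionSpec(residue_ranges=((109, 128),))
        with pytest.raises(ValueError, match="mobile missing"):
            kabsch_superpose(ref, mob, sel)


class TestResidueRMSD:
    def test_identical_residue_zero(self, cloud, resnums):
        model = make_ca_model(resnums, cloud)
        assert residue_rmsd(model, model, 110) == 0.0

    def test_single_displaced_atom_equals_displacement(self, cloud, resnums):
        ref = make_ca_model(resnums, cloud)
        moved_xyz = cloud.copy()
        moved_xyz[0] += np.array([0.3, -0.4, 1.2])
        mob = make_ca_model(resnums, moved_xyz)
        d = np.linalg.norm([0.3, -0.4, 1.2])
        assert residue_rmsd(ref, mob, resnums[0]) == pytest.approx(d, abs=1e-12)

    def test_ca_rmsds_aggregate_to_fit_rmsd(self, cloud, resnums):
        rng = np.random.default_rng(11)
        noisy = cloud + rng.normal(scale=0.4, size=cloud.shape)
        ref = make_ca_model(resnums, cloud)
        mob = make_ca_model(resnums, noisy)
        sel = SelectionSpec(residue_ranges=((109, 128),))
        fit = kabsch_superpose(ref, mob, sel)
        moved = apply_transform(mob, fit)
        per_res = [
            residue_rmsd(ref, moved, r, atom_subset="CA") for r in resnums
        ]
        aggregated = np.sqrt(np.mean(np.square(per_res)))
        assert aggregated == pytest.approx(fit.rmsd_fit, abs=1e-9)

    def test_sidechain_subset_excludes_backbone(self):
        atoms_ref = [
            Atom("A", 1, "SER", "N", "N", 1.0, (0, 0, 0)),
            Atom("A", 1, "SER", "CA", "C", 1.0, (1, 0, 0)),
            Atom("A", 1, "SER", "OG", "O", 1.0, (2, 0, 0)),
        ]
        atoms_mob = [
            Atom("A", 1, "SER", "N", "N", 1.0, (0, 0, 5.0)),
            Atom("A", 1, "SER", "CA", "C", 1.0, (1, 0, 5.0)),
            Atom("A", 1, "SER", "OG", "O", 1.0, (2, 0, 1.0)),
        ]
        ref, mob = StructureModel(atoms_ref), StructureModel(atoms_mob)
        assert residue_rmsd(ref, mob, 1, "SIDECHAIN_HEAVY") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            residue_rmsd(ref, mob, 1, "NO_SUCH_SUBSET")


class TestClPi:
    def tyrosine_ring(self, center=(0.0, 0.0, 0.0), chain="A", resnum=34):
        hexagon = [
            (1.0, 0.0), (0.5, np.sqrt(3) / 2), (-0.5, np.sqrt(3) / 2),
            (-1.0, 0.0), (-0.5, -np.sqrt(3) / 2), (0.5, -np.sqrt(3) / 2),
        ]
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        cx, cy, cz = center
        return [
            Atom(chain, resnum, "TYR", n, "C", 1.0, (cx + x, cy + y, cz))
            for n, (x, y) in zip(names, hexagon)
        ]

    def test_constructed_geometry(self):
        atoms = self.tyrosine_ring() + [
            Atom("A", 501, "LIG", "CL1", "Cl", 1.0, (0.0, 0.0, 3.5))
        ]
        model = StructureModel(atoms)
        assert cl_pi_distance(model, ("A", "LIG", "CL1"), 34) == pytest.approx(3.5)
        assert cl_pi_distance(model, ("A", 501, "CL1"), 34) == pytest.approx(3.5)

    def test_invariant_under_rigid_transform(self):
        atoms = self.tyrosine_ring() + [
            Atom("A", 501, "LIG", "CL1", "Cl", 1.0, (0.4, -0.2, 3.3))
        ]
        model = StructureModel(atoms)
        base = cl_pi_distance(model, ("A", "LIG", "CL1"), 34)
        xyz = np.array([a.coords for a in model.atoms])
        moved_xyz = rigid_transform(xyz, 40.0, axis=(1, 1, 0), shift=(-3, 7, 2))
        moved = StructureModel(
            [
                Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                     a.element, a.occupancy, tuple(c))
                for a, c in zip(model.atoms, moved_xyz)
            ]
        )
        assert cl_pi_distance(moved, ("A", "LIG", "CL1"), 34) == (
            pytest.approx(base, abs=1e-9)
        )

    def test_missing_ring_atom_and_halogen_errors(self):
        ring = self.tyrosine_ring()[:-1]  # drop CD2
        model = StructureModel(
            ring + [Atom("A", 501, "LIG", "CL1", "Cl", 1.0, (0, 0, 3.5))]
        )
        with pytest.raises(ValueError, match="ring atom"):
            cl_pi_distance(model, ("A", "LIG", "CL1"), 34)
        full = StructureModel(self.tyrosine_ring())
        with pytest.raises(ValueError, match="halogen"):
            cl_pi_distance(full, ("A", "LIG", "CL9"), 34)
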