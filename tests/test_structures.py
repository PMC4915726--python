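import gzip
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp

from graftsite.structures import (
    AtomNotFoundError,
    AtomSelector,
    RegionSpec,
    StructureError,
    Superposition,
    get_reference_atom,
    kabsch_superpose,
    read_structure,
    rmsd_between,
    select_region,
    write_pdb,
)

from conftest import pdb_atom_line


class TestReadStructure:
    def test_two_atom_file_one_model(self, two_atom_pdb):
        models = read_structure(two_atom_pdb)
        assert len(models) == 1
        assert len(models[0]) == 2
        assert models[0].atoms[0].res_num == 1

    def test_multi_model(self, multi_model_pdb):
        models = read_structure(multi_model_pdb)
        assert len(models) == 2
        names = lambda m: [a.atom_name for a in m.atoms]
        assert names(models[0]) == names(models[1])
        assert models[0].model_id == 1 and models[1].model_id == 2

    def test_altloc_highest_occupancy_kept(self, altloc_pdb):
        (model,) = read_structure(altloc_pdb)
        ca = [a for a in model.atoms if a.atom_name == "CA"]
        assert len(ca) == 1
        assert ca[0].alt_loc == "A"
        assert ca[0].occupancy == pytest.approx(0.6)

    def test_altloc_tie_breaks_alphabetically(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "SER", "A", 1, 0.0, 0.0, 0.0, altloc="B", occ=0.5),
            pdb_atom_line(2, "CA", "SER", "A", 1, 0.5, 0.0, 0.0, altloc="A", occ=0.5),
        ]
        p = tmp_path / "tie.pdb"
        p.write_text("\n".join(lines) + "\n")
        (model,) = read_structure(p)
        assert model.atoms[0].alt_loc == "A"

    def test_mse_relabelled_met(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "MSE", "A", 5, 0, 0, 0, record="HETATM"),
            pdb_atom_line(2, "SE", "MSE", "A", 5, 1, 1, 1, element="SE", record="HETATM"),
            pdb_atom_line(3, "CA", "GLY", "A", 6, 3, 0, 0),
        ]
        p = tmp_path / "mse.pdb"
        p.write_text("\n".join(lines) + "\n")
        (model,) = read_structure(p)
        mse = model.residue_atoms("A", 5)
        assert len(mse) == 2
        assert all(a.res_name == "MET" for a in mse)

    def test_waters_and_het_dropped_unless_kept(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            pdb_atom_line(2, "O", "HOH", "A", 200, 5, 5, 5, record="HETATM"),
            pdb_atom_line(3, "S", "SO4", "A", 201, 6, 6, 6, element="S", record="HETATM"),
        ]
        p = tmp_path / "het.pdb"
        p.write_text("\n".join(lines) + "\n")
        (model,) = read_structure(p)
        assert len(model) == 1
        (model_het,) = read_structure(p, keep_het=True)
        assert len(model_het) == 3

    def test_hydrogens_dropped_by_default(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            pdb_atom_line(2, "HA2", "GLY", "A", 1, 0.5, 0.5, 0, element="H"),
        ]
        p = tmp_path / "h.pdb"
        p.write_text("\n".join(lines) + "\n")
        assert len(read_structure(p)[0]) == 1
        assert len(read_structure(p, keep_hydrogens=True)[0]) == 2

    def test_chain_filter_and_absent_chain(self, tmp_path):
        lines = [
            pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            pdb_atom_line(2, "CA", "GLY", "B", 1, 5, 0, 0),
        ]
        p = tmp_path / "chains.pdb"
        p.write_text("\n".join(lines) + "\n")
        (model,) = read_structure(p, chain="B")
        assert [a.chain_id for a in model.atoms] == ["B"]
        with pytest.raises(StructureError, match="chain 'C' absent"):
            read_structure(p, chain="C")

    def test_no_atoms_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(StructureError, match="no ATOM records"):
            read_structure(p)

    def test_gzip_transparent(self, two_atom_pdb, tmp_path):
        gz = tmp_path / "two_atom.pdb.gz"
        gz.write_bytes(gzip.compress(two_atom_pdb.read_bytes()))
        models = read_structure(gz)
        assert len(models[0]) == 2

    def test_write_read_roundtrip(self, lysine_model, tmp_path):
        p = tmp_path / "rt.pdb"
        write_pdb([lysine_model], p)
        (back,) = read_structure(p)
        assert [a.atom_name for a in back.atoms] == [a.atom_name for a in lysine_model.atoms]
        np.testing.assert_allclose(back.coords_array(), lysine_model.coords_array(), atol=1e-3)


class TestReferenceAtom:
    def test_lysine_nz_found(self, lysine_model):
        spec = RegionSpec.for_lysine("A", 167)
        atom = get_reference_atom(lysine_model, spec)
        assert atom.atom_name == "NZ" and atom.res_name == "LYS"

    def test_missing_nz_errors(self, lysine_model):
        lysine_model.atoms = [a for a in lysine_model.atoms if a.atom_name != "NZ"]
        spec = RegionSpec.for_lysine("A", 167)
        with pytest.raises(AtomNotFoundError, match="reference atom absent"):
            get_reference_atom(lysine_model, spec)

    def test_default_selector_rejects_non_lysine(self, lysine_model):
        spec = RegionSpec.for_lysine("A", 20)  # VAL
        with pytest.raises(StructureError, match="expected LYS"):
            get_reference_atom(lysine_model, spec)

    def test_explicit_selector_overrides_lysine_check(self, lysine_model):
        spec = RegionSpec(reference_atom=AtomSelector("A", 20, "CB"))
        atom = get_reference_atom(lysine_model, spec)
        assert atom.atom_name == "CB" and atom.res_name == "VAL"


class TestSelectRegion:
    def test_boundary_inclusive(self, lysine_model):
        spec = RegionSpec.for_lysine("A", 167, radius=6.0)
        names = {(a.res_num, a.atom_name) for a in select_region(lysine_model, spec)}
        assert (20, "CA") in names  # 5.9 A
        assert (20, "CB") not in names  # 6.1 A

    def test_center_on_atom_included(self, lysine_model):
        spec = RegionSpec.for_lysine("A", 167, radius=6.0)
        atoms = select_region(lysine_model, spec)
        assert any(a.atom_name == "NZ" for a in atoms)  # distance 0 from itself

    def test_diameter_parameterization_equivalent(self, lysine_model):
        # a 12 A-diameter sphere is the same region as radius 6.0
        diameter = 12.0
        spec_r = RegionSpec.for_lysine("A", 167, radius=6.0)
        spec_d = RegionSpec.for_lysine("A", 167, radius=diameter / 2)
        assert [a.serial for a in select_region(lysine_model, spec_r)] == [
            a.serial for a in select_region(lysine_model, spec_d)
        ]

    def test_empty_region_warns(self, lysine_model):
        spec = RegionSpec.for_lysine("A", 167, center=np.array([100.0, 100.0, 100.0]), radius=1.0)
        with pytest.warns(UserWarning, match="no atoms"):
            assert select_region(lysine_model, spec) == []

    def test_idempotent_membership(self, lysine_model):
        spec = RegionSpec.for_lysine("A", 167, radius=6.0)
        first = select_region(lysine_model, spec)
        sub = lysine_model
        sub.atoms = list(first)
        second = select_region(sub, spec)
        assert [a.serial for a in first] == [a.serial for a in second]

    def test_explicit_center_vector(self, lysine_model):
        spec = RegionSpec.for_lysine("A", 167, center=np.array([0.0, 4.0, 0.0]), radius=0.5)
        atoms = select_region(lysine_model, spec)
        assert [a.res_num for a in atoms] == [30]

    def test_invalid_radius(self):
        with pytest.raises(ValueError, match="radius"):
            RegionSpec.for_lysine("A", 167, radius=0.0)


def _rotation_grid_oracle(mobile, target, window_deg=25.0):
    """Brute-force rotation search (coarse-to-fine, final step 0.125 deg).

    The optimal translation per rotation is the centroid match, which is
    closed-form; only the rotation is searched.
    """
    from scipy.spatial.transform import Rotation

    P = mobile - mobile.mean(axis=0)
    Q = target - target.mean(axis=0)

    def best_on_grid(center, half_width, step):
        axes = [np.arange(-half_width, half_width + step / 2, step) + c for c in center]
        best = (np.inf, center)
        for a in axes[0]:
            for b in axes[1]:
                for g in axes[2]:
                    R = Rotation.from_euler("xyz", [a, b, g], degrees=True).as_matrix()
                    r = math.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))
                    if r < best[0]:
                        best = (r, (a, b, g))
        return best

    rmsd, center = best_on_grid((0.0, 0.0, 0.0), window_deg, 5.0)
    rmsd, center = best_on_grid(center, 5.0, 1.0)
    rmsd, center = best_on_grid(center, 1.0, 0.5)
    rmsd, center = best_on_grid(center, 0.5, 0.125)
    return rmsd


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(-3, 3, (6, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).uniform(-3, 3, (5, 3))
        sup = kabsch_superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.translation, [5.0, 0.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_matches_rotation_grid_oracle(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(42)
        mobile = rng.uniform(-3, 3, (5, 3))
        true_rot = Rotation.from_euler("xyz", rng.uniform(-15, 15, 3), degrees=True)
        target = true_rot.apply(mobile) + rng.normal(0, 0.1, (5, 3)) + np.array([1.0, -2.0, 0.5])
        sup = kabsch_superpose(mobile, target)
        oracle_rmsd = _rotation_grid_oracle(mobile, target)
        assert sup.rmsd <= oracle_rmsd + 1e-12
        assert abs(sup.rmsd - oracle_rmsd) < 1e-3

    def test_proper_rotation_enforced(self):
        # a target that is a mirror image would tempt a reflection
        rng = np.random.default_rng(3)
        mobile = rng.uniform(-3, 3, (8, 3))
        target = mobile.copy()
        target[:, 0] = -target[:, 0]
        sup = kabsch_superpose(mobile, target)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)

    @settings(max_examples=25, deadline=None)
    @given(seed=st_hyp.integers(0, 10_000))
    def test_invariant_under_pre_translation(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-5, 5, (6, 3))
        b = rng.uniform(-5, 5, (6, 3))
        shift = rng.uniform(-50, 50, 3)
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(a + shift, b).rmsd, abs=1e-9
        )
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(a, b + shift).rmsd, abs=1e-9
        )

    @settings(max_examples=25, deadline=None)
    @given(seed=st_hyp.integers(0, 10_000))
    def test_fit_never_increases_rmsd(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-5, 5, (7, 3))
        b = a + rng.normal(0, 0.3, (7, 3))
        sup = kabsch_superpose(a, b)
        assert rmsd_between(sup.apply(a), b) <= rmsd_between(a, b) + 1e-9


class TestRmsdBetween:
    def test_identical(self):
        a = np.arange(12.0).reshape(4, 3)
        assert rmsd_between(a, a) == 0.0

    def test_single_pair(self):
        assert rmsd_between(np.zeros((1, 3)), np.array([[2.0, 0, 0]])) == pytest.approx(2.0)

    def test_two_pairs_hand_value(self):
        # pairs at distance 0 and 2 -> sqrt((0 + 4)/2) = sqrt 2
        a = np.zeros((2, 3))
        b = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert rmsd_between(a, b) == pytest.approx(math.sqrt(2.0), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rmsd_between(np.zeros((2, 3)), np.zeros((3, 3)))


class TestSuperpositionType:
    def test_rejects_improper_rotation(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            Superposition(rotation=refl, translation=np.zeros(3), rmsd=0.0, n_pairs=3)

    def test_rejects_too_few_pairs(self):
        with pytest.raises(ValueError, match="n_pairs"):
            Superposition(np.eye(3), np.zeros(3), 0.0, 2)
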