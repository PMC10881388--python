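import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from trsfx.metrics import (difference_distance_matrix, displacement_from_haem,
                           doming_coefficient, doming_mode_vector,
                           fe_his_distance, fe_out_of_plane, fit_plane,
                           radius_of_gyration)
from trsfx.models import AtomicModel
from trsfx.synthetic import TwoStateConfig, build_two_state_system


def rigid_move(model: AtomicModel, seed=0) -> AtomicModel:
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-2, 2, 3)
    out = model.copy()
    center = out.xyz.mean(axis=0)
    out.xyz = (out.xyz - center) @ rot.T + center + shift
    return out


class TestFitPlane:
    def test_symmetric_square(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        normal, centroid = fit_plane(pts)
        assert np.allclose(centroid, 0.0)
        assert np.allclose(np.abs(normal), [0, 0, 1])

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 3))
        pts[:, 2] *= 0.01
        n1, _ = fit_plane(pts, orient_toward=[0, 0, 10])
        rot = Rotation.from_euler("xyz", [0.3, -0.7, 1.1]).as_matrix()
        n2, _ = fit_plane(pts @ rot.T, orient_toward=rot @ [0, 0, 10])
        assert np.allclose(rot @ n1, n2, atol=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(30, 3)) * [3, 2, 0.05]
        normal, centroid = fit_plane(pts)
        # brute-force oracle: smallest right singular vector of centered cloud
        _, _, vt = np.linalg.svd(pts - pts.mean(axis=0))
        oracle = vt[-1]
        assert min(np.linalg.norm(normal - oracle),
                   np.linalg.norm(normal + oracle)) < 1e-10

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_plane(pts)


def make_haem_toy(fe_z=0.3, n_z=(0, 0, 0, 0), his_z=-2.0):
    """Minimal model: 4 pyrrole N, Fe, proximal NE2 (His side at -z)."""
    xyz = [[0, 0, fe_z], [2, 0, n_z[0]], [0, 2, n_z[1]], [-2, 0, n_z[2]],
           [0, -2, n_z[3]], [0, 0, his_z]]
    ids = ["FE", "NA", "NB", "NC", "ND", "NE2"]
    return AtomicModel(
        atom_id=np.array(ids, dtype=object),
        element=np.array(["FE", "N", "N", "N", "N", "N"], dtype=object),
        res_name=np.array(["HEM"] * 5 + ["HIS"], dtype=object),
        res_seq=np.array([154] * 5 + [93]),
        xyz=np.array(xyz, float) + 10.0,
        b=np.full(6, 10.0), occ=np.ones(6), cell=(20.0, 20.0, 20.0))


class TestFeOutOfPlane:
    def test_closed_form_sign_convention(self):
        # Fe displaced away from the His side -> negative; toward -> positive
        assert fe_out_of_plane(make_haem_toy(fe_z=0.3)) == pytest.approx(-0.3)
        assert fe_out_of_plane(make_haem_toy(fe_z=-0.3)) == pytest.approx(0.3)

    def test_fe_in_plane_is_zero(self):
        assert fe_out_of_plane(make_haem_toy(fe_z=0.0)) == pytest.approx(0.0, abs=1e-12)

    def test_ruffled_ring_matches_plane_oracle(self):
        m = make_haem_toy(fe_z=0.2, n_z=(0.1, -0.1, 0.1, -0.1))
        n_pts = m.xyz[1:5]
        _, _, vt = np.linalg.svd(n_pts - n_pts.mean(axis=0))
        normal = vt[-1]
        if np.dot(normal, m.xyz[5] - n_pts.mean(axis=0)) < 0:
            normal = -normal
        oracle = np.dot(m.xyz[0] - n_pts.mean(axis=0), normal)
        assert fe_out_of_plane(m) == pytest.approx(oracle, abs=1e-12)

    def test_missing_atoms_named_in_error(self):
        m = make_haem_toy()
        m.atom_id[1] = "XX"
        with pytest.raises(KeyError, match="NA"):
            fe_out_of_plane(m)

    def test_generator_delta_recovered(self):
        sys_ = build_two_state_system(TwoStateConfig(delta_fe=0.30))
        delta = fe_out_of_plane(sys_.excited) - fe_out_of_plane(sys_.dark)
        assert delta == pytest.approx(0.30, abs=1e-9)


class TestDoming:
    def test_identity_is_zero(self, system):
        assert doming_coefficient(system.dark, system.dark) == pytest.approx(0.0)

    def test_projection_identity(self, system):
        labels, weights = doming_mode_vector()
        moved = system.dark.copy()
        for lab, w in zip(labels, weights):
            moved.xyz[moved.index_of(lab), 2] -= 0.17 * w  # -z is toward the His
        assert doming_coefficient(moved, system.dark) == pytest.approx(0.17, abs=1e-9)

    def test_in_plane_breathing_is_orthogonal(self, system):
        moved = system.dark.copy()
        center = moved.position("FE")
        labels, _ = doming_mode_vector()
        for lab in labels:
            i = moved.index_of(lab)
            radial = moved.xyz[i] - center
            moved.xyz[i] += 0.05 * radial          # in-plane expansion
        assert doming_coefficient(moved, system.dark) == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_amplitude(self, system):
        labels, weights = doming_mode_vector()
        def displaced(a):
            m = system.dark.copy()
            for lab, w in zip(labels, weights):
                m.xyz[m.index_of(lab), 2] -= a * w
            return doming_coefficient(m, system.dark)
        assert displaced(0.2) == pytest.approx(2.0 * displaced(0.1), rel=1e-9)


class TestDifferenceDistanceMatrix:
    def test_identical_structures_zero(self, system):
        ddm = difference_distance_matrix(system.dark, system.dark)
        assert np.allclose(ddm, 0.0)

    def test_rigid_motion_invisible(self, system):
        ddm = difference_distance_matrix(rigid_move(system.dark), system.dark)
        assert np.allclose(ddm, 0.0, atol=1e-9)

    def test_single_atom_move_matches_hand_computation(self):
        def ca_model(xyz):
            n = len(xyz)
            return AtomicModel(
                atom_id=np.array(["CA"] * n, dtype=object),
                element=np.array(["C"] * n, dtype=object),
                res_name=np.array(["ALA"] * n, dtype=object),
                res_seq=np.arange(1, n + 1), xyz=np.array(xyz, float),
                b=np.full(n, 10.0), occ=np.ones(n), cell=(20., 20., 20.))
        dark = ca_model([[0, 0, 0], [3, 0, 0], [3, 4, 0], [0, 4, 0]])
        light = ca_model([[1, 0, 0], [3, 0, 0], [3, 4, 0], [0, 4, 0]])
        ddm = difference_distance_matrix(light, dark)
        assert np.allclose(np.diag(ddm), 0.0)
        assert np.allclose(ddm, ddm.T)
        assert ddm[0, 1] == pytest.approx(2.0 - 3.0)
        assert ddm[0, 2] == pytest.approx(np.sqrt(4 + 16) - 5.0)
        assert ddm[0, 3] == pytest.approx(np.sqrt(1 + 16) - 4.0)
        assert ddm[1, 2] == pytest.approx(0.0)

    def test_roster_mismatch_rejected(self, system):
        trimmed = system.dark.select(system.dark.res_seq != 90)
        with pytest.raises(ValueError, match="roster"):
            difference_distance_matrix(trimmed, system.dark)


class TestDisplacementFromHaem:
    def test_identical_series_all_zero(self, system):
        df = displacement_from_haem([(0.0, system.dark)], system.dark)
        assert np.allclose(df["delta_A"], 0.0)
        assert set(df["atom"]) == {"N", "CA", "C"}

    def test_radial_move_gives_its_magnitude(self, system):
        from trsfx.metrics import haem_centroid
        moved = system.dark.copy()
        c = haem_centroid(moved)
        i = moved.index_of("CA", 91)
        u = (moved.xyz[i] - c) / np.linalg.norm(moved.xyz[i] - c)
        moved.xyz[i] += 0.5 * u
        df = displacement_from_haem([(100.0, moved)], system.dark)
        row = df[(df.res_seq == 91) & (df.atom == "CA")]
        assert row["delta_A"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_global_rigid_motion_cancels(self, system):
        df = displacement_from_haem([(0.0, rigid_move(system.dark, 3))],
                                    system.dark)
        assert np.allclose(df["delta_A"], 0.0, atol=1e-9)


class TestRadiusOfGyration:
    def test_two_atoms(self):
        m = AtomicModel(
            atom_id=np.array(["A", "B"], dtype=object),
            element=np.array(["C", "C"], dtype=object),
            res_name=np.array(["ALA", "ALA"], dtype=object),
            res_seq=np.array([1, 2]),
            xyz=np.array([[1., 1, 1], [3., 1, 1]]),
            b=np.full(2, 10.0), occ=np.ones(2), cell=(10., 10., 10.))
        assert radius_of_gyration(m) == pytest.approx(1.0)

    def test_homogeneity_under_scaling(self, system):
        scaled = system.dark.copy()
        center = scaled.xyz.mean(axis=0)
        scaled.xyz = center + 1.7 * (scaled.xyz - center)
        assert radius_of_gyration(scaled) \
            == pytest.approx(1.7 * radius_of_gyration(system.dark), rel=1e-12)

    def test_matches_double_loop_oracle(self, system):
        m = system.dark
        heavy = [i for i in range(m.n_atoms) if m.element[i] != "H"]
        center = m.xyz[heavy].mean(axis=0)
        total = sum(np.sum((m.xyz[i] - center) ** 2) for i in heavy)
        oracle = np.sqrt(total / len(heavy))
        assert radius_of_gyration(m) == pytest.approx(oracle, rel=1e-12)

    def test_rigid_motion_invariance(self, system):
        assert radius_of_gyration(rigid_move(system.dark, 8)) \
            == pytest.approx(radius_of_gyration(system.dark), rel=1e-9)


def test_fe_his_distance(system):
    fe = system.dark.position("FE")
    ne2 = system.dark.position("NE2", 93)
    assert fe_his_distance(system.dark) == pytest.approx(np.linalg.norm(fe - ne2))
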