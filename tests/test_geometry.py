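import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcginv.geometry import (
    PlyParseError,
    make_ellipsoid_mesh,
    make_sensor_grid,
    nearest_node_map,
    read_ply,
    remesh_perturb,
    write_ply,
)


class TestEllipsoidMesh:
    def test_sphere_nodes_on_radius(self):
        mesh = make_ellipsoid_mesh((3, 3, 3), 12, seed=0)
        radii = np.linalg.norm(mesh.node_positions, axis=1)
        assert np.all(np.abs(radii - 3.0) < 1e-6)

    def test_deterministic_for_fixed_seed(self):
        a = make_ellipsoid_mesh((4, 3, 5), 257, seed=1)
        b = make_ellipsoid_mesh((4, 3, 5), 257, seed=1)
        assert np.array_equal(a.node_positions, b.node_positions)
        assert np.array_equal(a.triangles, b.triangles)
        assert np.array_equal(a.node_normals, b.node_normals)

    def test_sphere_normals_radial(self):
        mesh = make_ellipsoid_mesh((3, 3, 3), 200, seed=2)
        radial = mesh.node_positions / np.linalg.norm(
            mesh.node_positions, axis=1, keepdims=True
        )
        angles = np.arccos(
            np.clip(np.einsum("ij,ij->i", radial, mesh.node_normals), -1, 1)
        )
        assert np.max(angles) < 1e-3

    def test_closed_genus0_surface(self):
        mesh = make_ellipsoid_mesh((4, 3, 5), 257, seed=1)
        assert mesh.euler_characteristic() == 2
        assert mesh.n_nodes == 257
        mesh.validate()

    def test_sphere_area_converges(self):
        mesh = make_ellipsoid_mesh((3, 3, 3), 500, seed=4)
        exact = 4 * np.pi * 9.0
        assert abs(mesh.surface_area() - exact) / exact < 0.05

    @pytest.mark.parametrize(
        "axes,nodes", [((0, 3, 3), 50), ((-1, 3, 3), 50), ((3, 3, 3), 11)]
    )
    def test_rejects_bad_arguments(self, axes, nodes):
        with pytest.raises(ValueError):
            make_ellipsoid_mesh(axes, nodes)


class TestRemesh:
    def test_identity_resolution_reproduces_surface(self, heart_mesh):
        out = remesh_perturb(heart_mesh, heart_mesh.n_nodes, 0.0, seed=11)
        assert np.abs(out.node_positions - heart_mesh.node_positions).max() < 1e-6

    def test_node_count_and_nonalignment(self, heart_mesh):
        out = remesh_perturb(heart_mesh, 585, 0.0, seed=7)
        assert abs(out.n_nodes - 585) <= 0.05 * 585
        assert out.euler_characteristic() == 2
        # new node set is not index-aligned with the input
        shared = min(out.n_nodes, heart_mesh.n_nodes)
        d = np.linalg.norm(
            out.node_positions[:shared] - heart_mesh.node_positions[:shared], axis=1
        )
        assert np.median(d) > 1e-3

    def test_deterministic(self, heart_mesh):
        a = remesh_perturb(heart_mesh, 100, 0.1, seed=5)
        b = remesh_perturb(heart_mesh, 100, 0.1, seed=5)
        assert np.array_equal(a.node_positions, b.node_positions)

    def test_perturbation_bounded(self, heart_mesh):
        scale = 0.1
        out = remesh_perturb(heart_mesh, 150, scale, seed=9)
        # radial deviation from the fitted ellipsoid stays within the bound
        base = remesh_perturb(heart_mesh, 150, 0.0, seed=9)
        dev = np.linalg.norm(out.node_positions - base.node_positions, axis=1)
        mean_semi = np.mean([4.0, 3.5, 5.0])
        assert dev.max() <= scale * mean_semi * (1 + 1e-9)

    def test_rejects_out_of_range_scale(self, heart_mesh):
        with pytest.raises(ValueError):
            remesh_perturb(heart_mesh, 100, 0.3, seed=0)


class TestSensorGrid:
    def test_9x9_has_81_sensors_at_spacing(self):
        grid = make_sensor_grid(9, 9, 3.0)
        assert grid.n_sensors == 81
        d = np.linalg.norm(
            grid.positions[:, None] - grid.positions[None], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert abs(d.min() - 3.0) < 1e-9

    def test_single_point_grid(self):
        grid = make_sensor_grid(1, 1, 2.0, center=(1.0, 2.0, 3.0))
        assert np.allclose(grid.positions, [[1.0, 2.0, 3.0]])

    def test_2x2_lattice_distances(self):
        # hand enumeration: side 3 and diagonal 3*sqrt(2)
        grid = make_sensor_grid(2, 2, 3.0)
        d = np.linalg.norm(grid.positions[:, None] - grid.positions[None], axis=-1)
        vals = np.unique(np.round(d[np.triu_indices(4, 1)], 9))
        assert np.allclose(vals, [3.0, 3.0 * np.sqrt(2)])

    def test_non_unit_normal_normalized_with_warning(self):
        with pytest.warns(UserWarning):
            grid = make_sensor_grid(2, 2, 1.0, plane_normal=(0.0, 0.0, 2.0))
        assert abs(np.linalg.norm(grid.plane_normal) - 1.0) < 1e-12


class TestNearestNodeMap:
    def test_identity_on_same_mesh(self, heart_mesh):
        nm = nearest_node_map(heart_mesh, heart_mesh)
        assert np.array_equal(nm.indices, np.arange(heart_mesh.n_nodes))
        assert np.all(nm.distances == 0)

    def test_single_node_target(self, heart_mesh):
        import mcginv.geometry as g

        target = g.TriMesh(
            np.zeros((1, 3)), np.empty((0, 3), dtype=int), np.array([[0.0, 0.0, 1.0]])
        )
        nm = nearest_node_map(heart_mesh, target)
        assert np.all(nm.indices == 0)
        assert np.all(nm.distances >= 0)

    def test_matches_brute_force_on_toy(self):
        import mcginv.geometry as g

        src = g.TriMesh(
            np.array([[0.0, 0, 0], [1.0, 0, 0], [0.4, 0.1, 0]]),
            np.empty((0, 3), dtype=int),
            np.tile([[0.0, 0, 1]], (3, 1)),
        )
        tgt = g.TriMesh(
            np.array([[0.1, 0, 0], [0.9, 0, 0], [0.5, 0, 0]]),
            np.empty((0, 3), dtype=int),
            np.tile([[0.0, 0, 1]], (3, 1)),
        )
        nm = nearest_node_map(src, tgt)
        d = np.linalg.norm(
            src.node_positions[:, None] - tgt.node_positions[None], axis=-1
        )
        expect = np.argmin(d, axis=1)
        assert np.array_equal(nm.indices, expect)
        assert np.allclose(nm.distances, d[np.arange(3), expect])


class TestPlyIO:
    def test_round_trip(self, heart_mesh, tmp_path):
        p = tmp_path / "mesh.ply"
        write_ply(heart_mesh, p)
        back = read_ply(p)
        assert np.abs(back.node_positions - heart_mesh.node_positions).max() < 1e-6
        assert np.array_equal(back.triangles, heart_mesh.triangles)

    def test_normals_recomputed_when_absent(self, heart_mesh, tmp_path):
        p = tmp_path / "mesh.ply"
        write_ply(heart_mesh, p)
        # strip the normal columns
        lines = p.read_text().splitlines()
        out = []
        nvert = heart_mesh.n_nodes
        body_at = lines.index("end_header") + 1
        for i, line in enumerate(lines):
            if line.startswith("property float n"):
                continue
            if body_at <= i < body_at + nvert:
                out.append(" ".join(line.split()[:3]))
            else:
                out.append(line)
        # body start shifts by the removed header lines; recompute body index
        p2 = tmp_path / "no_normals.ply"
        p2.write_text("\n".join(out) + "\n")
        back = read_ply(p2)
        assert np.allclose(np.linalg.norm(back.node_normals, axis=1), 1.0, atol=1e-9)

    def test_quad_face_rejected_with_line_number(self, heart_mesh, tmp_path):
        p = tmp_path / "mesh.ply"
        write_ply(heart_mesh, p)
        lines = p.read_text().splitlines()
        # corrupt the first face row into a quad
        first_face = next(
            i for i, l in enumerate(lines) if l.startswith("3 ")
        )
        lines[first_face] = "4 0 1 2 3"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(PlyParseError, match=rf"line {first_face + 1}"):
            read_ply(p)

    def test_malformed_header_rejected(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("not a ply\n")
        with pytest.raises(PlyParseError, match="line 1"):
            read_ply(p)


@given(st.integers(min_value=12, max_value=400), st.integers(min_value=0, max_value=10))
def test_generated_meshes_always_closed_and_valid(n, seed):
    mesh = make_ellipsoid_mesh((4.0, 3.5, 5.0), n, seed=seed)
    mesh.validate()
    assert mesh.euler_characteristic() == 2
    assert mesh.n_nodes == n
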