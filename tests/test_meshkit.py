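"""Mesh model, I/O round-trips, discrete geometry kernels, fixtures, refinement."""

import numpy as np
import pytest

from elastishape import _ad as ad
from elastishape.meshkit import (
    MeshError,
    MeshParseError,
    TangentField,
    TriMesh,
    cotan_laplacian,
    delete_component,
    face_geometry,
    hex_fan,
    icosphere,
    make_fixture,
    merge,
    noisy,
    plane_grid,
    read_mesh,
    refine_mesh,
    rotation_matrix,
    single_triangle,
    torus,
    tube,
    two_triangle_square,
    upsample_time,
    uv_sphere,
    vertex_areas,
    write_mesh,
)


# ---------------------------------------------------------------------------
# data model


class TestTriMesh:
    def test_canonical_face_storage_preserves_orientation(self):
        m = TriMesh(np.eye(3), np.array([[2, 0, 1]]))
        assert m.faces.tolist() == [[0, 1, 2]]

    def test_rejects_out_of_range_and_repeated_indices(self):
        with pytest.raises(MeshError):
            TriMesh(np.zeros((2, 3)), np.array([[0, 1, 2]]))
        with pytest.raises(MeshError):
            TriMesh(np.eye(3), np.array([[0, 1, 1]]))

    def test_orientation_consistency_detection(self, sphere1):
        assert sphere1.is_oriented()
        bad_faces = sphere1.faces.copy()
        bad_faces[0] = bad_faces[0][::-1]
        assert not TriMesh(sphere1.vertices, bad_faces).is_oriented()


# ---------------------------------------------------------------------------
# I/O


class TestIO:
    @pytest.mark.parametrize("fmt", ["obj", "ply", "off"])
    def test_roundtrip_identity(self, tmp_path, fmt, sphere1):
        path = str(tmp_path / f"mesh.{fmt}")
        write_mesh(sphere1, path)
        back = read_mesh(path)
        np.testing.assert_array_equal(back.faces, sphere1.faces)
        np.testing.assert_allclose(back.vertices, sphere1.vertices, rtol=0, atol=0)

    def test_ply_binary_matches_ascii(self, tmp_path):
        mesh = noisy(icosphere(4), 0.01, seed=5)  # 2562 vertices
        p_ascii = str(tmp_path / "a.ply")
        p_bin = str(tmp_path / "b.ply")
        write_mesh(mesh, p_ascii, binary=False)
        write_mesh(mesh, p_bin, binary=True)
        a, b = read_mesh(p_ascii), read_mesh(p_bin)
        np.testing.assert_array_equal(a.faces, b.faces)
        np.testing.assert_allclose(a.vertices, b.vertices, rtol=0, atol=0)

    def test_off_quad_face_errors_without_triangulate_flag(self, tmp_path):
        path = tmp_path / "quad.off"
        path.write_text("OFF\n4 1 0\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n")
        with pytest.raises(MeshParseError, match="non-triangular"):
            read_mesh(str(path))
        quad = read_mesh(str(path), triangulate=True)
        assert quad.n_faces == 2

    def test_obj_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 x\n")
        with pytest.raises(MeshParseError, match=r"bad\.obj:4"):
            read_mesh(str(path))

    def test_obj_one_based_indices(self, tmp_path):
        path = tmp_path / "tri.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 3\n")
        m = read_mesh(str(path))
        assert m.faces.tolist() == [[0, 1, 2]]


# ---------------------------------------------------------------------------
# face geometry


class TestFaceGeometry:
    def test_unit_right_triangle(self, unit_triangle):
        fg = face_geometry(unit_triangle)
        np.testing.assert_allclose(fg.g[0], np.eye(2), atol=1e-15)
        assert fg.vol[0] == pytest.approx(0.5)
        np.testing.assert_allclose(fg.normal[0], [0, 0, 1], atol=1e-15)
        np.testing.assert_allclose(fg.center[0], [1 / 3, 1 / 3, 0], atol=1e-15)
        np.testing.assert_allclose(fg.dq[0], [[1, 0, 0], [0, 1, 0]], atol=1e-15)

    def test_equilateral_area(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        m = TriMesh(v, np.array([[0, 1, 2]]))
        assert face_geometry(m).vol[0] == pytest.approx(np.sqrt(3) / 4)

    def test_collinear_triangle_flagged_degenerate(self):
        m = TriMesh(
            np.array([[0, 0, 0.0], [1, 0, 0], [2, 0, 0]]), np.array([[0, 1, 2]])
        )
        fg = face_geometry(m)
        assert fg.degenerate[0]
        assert fg.vol[0] == 0.0

    def test_det_g_equals_four_area_squared(self, bumpy_sphere):
        fg = face_geometry(bumpy_sphere)
        np.testing.assert_allclose(
            np.linalg.det(fg.g), (2 * fg.vol) ** 2, rtol=1e-10
        )

    def test_orientation_flip_negates_normals_only(self, bumpy_sphere):
        fg = face_geometry(bumpy_sphere)
        flipped = TriMesh(bumpy_sphere.vertices, bumpy_sphere.faces[:, ::-1])
        fgf = face_geometry(flipped)
        # canonical storage may reorder rows; compare per-face via sorted key
        np.testing.assert_allclose(fgf.normal, -fg.normal, atol=1e-12)
        np.testing.assert_allclose(fgf.vol, fg.vol, rtol=1e-12)

    def test_rigid_equivariance(self, bumpy_sphere):
        R = rotation_matrix(3)
        tau = np.array([0.3, -1.2, 2.0])
        fg = face_geometry(bumpy_sphere)
        moved = bumpy_sphere.with_vertices(bumpy_sphere.vertices @ R.T + tau)
        fgm = face_geometry(moved)
        np.testing.assert_allclose(fgm.normal, fg.normal @ R.T, atol=1e-12)
        np.testing.assert_allclose(fgm.vol, fg.vol, atol=1e-12)
        np.testing.assert_allclose(fgm.g, fg.g, atol=1e-12)


# ---------------------------------------------------------------------------
# vertex areas


class TestVertexAreas:
    def test_two_triangle_square_distribution(self, unit_square):
        va = vertex_areas(unit_square)
        # diagonal vertices 0 and 2 touch both faces, 1 and 3 only one
        np.testing.assert_allclose(va, [1 / 3, 1 / 6, 1 / 3, 1 / 6], atol=1e-15)
        assert va.sum() == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("mesh_fn", [lambda: icosphere(2), lambda: torus(2, 0.5, 16, 8), lambda: plane_grid(5, 3)])
    def test_area_conservation(self, mesh_fn):
        mesh = mesh_fn()
        assert vertex_areas(mesh).sum() == pytest.approx(
            face_geometry(mesh).vol.sum(), rel=1e-14
        )

    def test_isolated_vertex_gets_zero(self, unit_triangle):
        m = TriMesh(
            np.vstack([unit_triangle.vertices, [[5.0, 5, 5]]]), unit_triangle.faces
        )
        assert vertex_areas(m)[3] == 0.0


# ---------------------------------------------------------------------------
# cotangent Laplacian


class TestCotanLaplacian:
    def test_constant_field_in_kernel(self, sphere1):
        h = TangentField(np.tile([1.0, -2.0, 0.5], (sphere1.n_vertices, 1)))
        out = cotan_laplacian(sphere1, h)
        np.testing.assert_allclose(out.values, 0, atol=1e-12)

    def test_linear_precision_on_planar_grid(self, grid):
        """The integrated cotan operator annihilates affine fields at interior vertices."""
        x, y = grid.vertices[:, 0], grid.vertices[:, 1]
        h = np.zeros_like(grid.vertices)
        h[:, 0] = 2 * x - 3 * y
        out = cotan_laplacian(grid, TangentField(h)).values
        onb = np.zeros(grid.n_vertices, dtype=bool)
        edge_count = {}
        for f in grid.faces:
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                k = (min(a, b), max(a, b))
                edge_count[k] = edge_count.get(k, 0) + 1
        for (a, b), c in edge_count.items():
            if c == 1:
                onb[a] = onb[b] = True
        assert np.abs(out[~onb]).max() < 1e-10

    def test_hexagonal_fan_value(self, fan):
        h = np.zeros((7, 3))
        h[0, 0] = 1.0
        out = cotan_laplacian(fan, TangentField(h))
        assert out.values[0, 0] == pytest.approx(4 * np.sqrt(3), rel=1e-12)

    def test_mass_normalized_variant(self, fan):
        h = np.zeros((7, 3))
        h[0, 0] = 1.0
        raw = cotan_laplacian(fan, TangentField(h))
        normed = cotan_laplacian(fan, TangentField(h), mass_normalized=True)
        va = vertex_areas(fan)
        assert normed.values[0, 0] == pytest.approx(raw.values[0, 0] / (2 * va[0]))

    def test_field_length_mismatch_raises(self, fan):
        with pytest.raises(MeshError):
            cotan_laplacian(fan, TangentField(np.zeros((3, 3))))


# ---------------------------------------------------------------------------
# fixtures


class TestFixtures:
    def test_icosahedron_combinatorics(self):
        m = make_fixture("icosphere", {"subdiv": 0})
        assert (m.n_vertices, m.n_faces) == (12, 20)

    def test_icosphere_subdiv1_combinatorics(self):
        m = make_fixture("icosphere", {"subdiv": 1})
        assert (m.n_vertices, m.n_faces) == (42, 80)

    def test_torus_euler_characteristic(self):
        m = make_fixture("torus", {"R": 2, "r": 0.5, "n_major": 32, "n_minor": 16})
        assert m.euler_characteristic() == 0

    def test_sphere_euler_characteristic(self):
        assert icosphere(2).euler_characteristic() == 2
        assert uv_sphere(16, 8).euler_characteristic() == 2

    def test_tube_has_boundary(self):
        m = tube(n_circ=8, n_len=3)
        assert m.euler_characteristic() == 0  # annulus
        assert m.is_oriented()

    def test_delete_component(self):
        a = single_triangle()
        b = TriMesh(a.vertices + np.array([10.0, 0, 0]), a.faces)
        both = merge(a, b)
        kept = delete_component(both, keep=0)
        assert kept.n_faces == 1

    def test_deterministic_given_seed(self):
        a = make_fixture("icosphere", {"subdiv": 1, "noise": 0.05}, seed=42)
        b = make_fixture("icosphere", {"subdiv": 1, "noise": 0.05}, seed=42)
        np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_invalid_params_error(self):
        with pytest.raises(MeshError):
            make_fixture("torus", {"R": 0.4, "r": 0.5})
        with pytest.raises(MeshError):
            make_fixture("klein_bottle")

    @pytest.mark.parametrize("kind,params", [
        ("icosphere", {"subdiv": 1}),
        ("uv_sphere", {"n_lon": 12, "n_lat": 6}),
        ("torus", {"n_major": 12, "n_minor": 6}),
        ("ellipsoid", {"subdiv": 1}),
    ])
    def test_closed_fixtures_are_oriented_and_closed(self, kind, params):
        m = make_fixture(kind, params)
        assert m.is_oriented()
        # closed: every undirected edge shared by exactly two faces
        edges = np.concatenate([m.faces[:, [0, 1]], m.faces[:, [1, 2]], m.faces[:, [2, 0]]])
        _, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
        assert np.all(counts == 2)


# ---------------------------------------------------------------------------
# refinement


class TestRefinement:
    def test_single_triangle_subdivision(self, unit_triangle):
        r = refine_mesh(unit_triangle)
        assert r.n_faces == 4
        assert face_geometry(r).vol.sum() == pytest.approx(0.5, abs=1e-15)

    def test_double_subdivision_face_count(self):
        m = icosphere(0)
        assert refine_mesh(m, 2).n_faces == 16 * m.n_faces

    def test_planar_area_preserved_exactly(self, grid):
        a0 = face_geometry(grid).vol.sum()
        a1 = face_geometry(refine_mesh(grid)).vol.sum()
        assert a1 == pytest.approx(a0, rel=1e-14)

    def test_time_upsample_inserts_midpoints(self):
        bp = np.stack([np.zeros((3, 3)), np.ones((3, 3))])
        up = upsample_time(bp)
        assert up.shape[0] == 3
        np.testing.assert_allclose(up[1], 0.5)
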