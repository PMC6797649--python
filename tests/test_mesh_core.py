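import numpy as np
import pytest

from lsmd.decimate import resample_to
from lsmd.io import load_mesh, save_mesh
from lsmd.mesh import (ContractViolation, MeshFormatError, TriangleMesh,
                       VectorField, discrete_laplacian, mean_edge_length,
                       vertex_adjacency)
from lsmd.metrics import hausdorff_distance
from conftest import bumpy_mesh


# ---------------------------------------------------------------------------
# construction and invariants

def test_tetrahedron_is_closed(tetrahedron):
    assert tetrahedron.n_vertices == 4
    assert tetrahedron.n_faces == 4
    assert tetrahedron.is_closed


def test_faces_out_of_range_rejected():
    with pytest.raises(MeshFormatError):
        TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 5]])


def test_orient_outward_on_construction(tetrahedron):
    flipped = TriangleMesh(tetrahedron.vertices,
                           tetrahedron.faces[:, ::-1])
    assert flipped.signed_volume() > 0


def test_normals_unit_length(random_mesh):
    norms = np.linalg.norm(random_mesh.vertex_normals, axis=1)
    np.testing.assert_allclose(norms, 1.0, atol=1e-12)


def test_vector_field_length_checked(tetrahedron):
    with pytest.raises(ContractViolation):
        VectorField(tetrahedron, np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# I/O

def test_ply_tetrahedron_roundtrip(tetrahedron, tmp_path):
    p = tmp_path / "tet.ply"
    save_mesh(tetrahedron, p)
    mesh = load_mesh(p)
    assert mesh.n_vertices == 4 and mesh.n_faces == 4
    assert mesh.is_closed


def test_stl_merges_duplicate_vertices(tetrahedron, tmp_path):
    p = tmp_path / "tet.stl"
    save_mesh(tetrahedron, p)  # writes 12 vertex records
    mesh = load_mesh(p)
    assert mesh.n_vertices == 4
    assert mesh.n_faces == 4


@pytest.mark.parametrize("fmt,binary", [("ply", False), ("ply", True),
                                        ("stl", False), ("stl", True)])
def test_random_mesh_roundtrip(random_mesh, tmp_path, fmt, binary):
    p = tmp_path / f"m.{fmt}"
    save_mesh(random_mesh, p, binary=binary)
    back = load_mesh(p)
    assert back.n_faces == random_mesh.n_faces
    atol = 1e-4 if fmt == "stl" else 1e-12  # STL stores float32
    # vertex order may differ for STL; compare sorted coordinate sets
    a = np.sort(random_mesh.vertices, axis=0)
    b = np.sort(back.vertices, axis=0)
    np.testing.assert_allclose(a, b, atol=atol)


def test_ply_displacement_properties(random_mesh, tmp_path):
    u = np.random.default_rng(0).normal(size=random_mesh.vertices.shape)
    p = tmp_path / "d.ply"
    save_mesh(random_mesh, p, displacement=u)
    back = load_mesh(p)
    got = np.column_stack([back.vertex_data[k] for k in ("ux", "uy", "uz")])
    np.testing.assert_allclose(got, u, atol=1e-12)


def test_missing_file_raises(tmp_path):
    with pytest.raises(IOError):
        load_mesh(tmp_path / "nope.ply")


# ---------------------------------------------------------------------------
# adjacency

def test_tetrahedron_adjacency(tetrahedron):
    adj = vertex_adjacency(tetrahedron)
    assert all(len(a) == 3 for a in adj)


def test_icosahedron_five_neighbours(icosahedron):
    assert all(len(a) == 5 for a in vertex_adjacency(icosahedron))


def test_handshake_identity(random_mesh):
    adj = vertex_adjacency(random_mesh)
    assert sum(len(a) for a in adj) == 2 * len(random_mesh.edges)


def test_adjacency_symmetric_no_self(random_mesh):
    adj = vertex_adjacency(random_mesh)
    for i, nbrs in enumerate(adj):
        assert i not in nbrs
        assert all(i in adj[j] for j in nbrs)
        assert np.all(np.diff(nbrs) > 0)  # ascending


# ---------------------------------------------------------------------------
# discrete Laplacian

def test_laplacian_constant_field_vanishes(random_mesh):
    const = np.tile([1.0, -2.0, 3.0], (random_mesh.n_vertices, 1))
    np.testing.assert_allclose(discrete_laplacian(random_mesh, const), 0.0,
                               atol=1e-12)


def test_laplacian_single_vertex_example():
    # vertex 0 at apex with 4 neighbours in a plane: L(v0) = 4*v0 - sum(vj)
    v = np.array([[0, 0, 1], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                  [0, 0, -1]], dtype=float)
    f = np.array([[0, 1, 3], [0, 3, 2], [0, 2, 4], [0, 4, 1],
                  [5, 3, 1], [5, 2, 3], [5, 4, 2], [5, 1, 4]])
    octa = TriangleMesh(v, f)
    lap = discrete_laplacian(octa, octa.vertices)
    np.testing.assert_allclose(lap[0], [0, 0, 4], atol=1e-12)


def test_laplacian_matches_dense_degree_minus_adjacency(random_mesh):
    rng = np.random.default_rng(1)
    field = rng.normal(size=(random_mesh.n_vertices, 3))
    n = random_mesh.n_vertices
    A = np.zeros((n, n))
    for i, j in random_mesh.edges:
        A[i, j] = A[j, i] = 1.0
    dense = np.diag(A.sum(1)) - A
    np.testing.assert_allclose(discrete_laplacian(random_mesh, field),
                               dense @ field, atol=1e-9)


def test_laplacian_linearity(random_mesh):
    rng = np.random.default_rng(2)
    f = rng.normal(size=(random_mesh.n_vertices, 3))
    g = rng.normal(size=(random_mesh.n_vertices, 3))
    a, b = 2.5, -0.7
    lhs = discrete_laplacian(random_mesh, a * f + b * g)
    rhs = a * discrete_laplacian(random_mesh, f) \
        + b * discrete_laplacian(random_mesh, g)
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)


def test_laplacian_translation_invariant(random_mesh):
    t = np.array([5.0, -3.0, 2.0])
    lap0 = discrete_laplacian(random_mesh, random_mesh.vertices)
    lap1 = discrete_laplacian(random_mesh, random_mesh.vertices + t)
    np.testing.assert_allclose(lap0, lap1, atol=1e-9)


def test_laplacian_sums_to_zero_on_closed_mesh(random_mesh):
    lap = discrete_laplacian(random_mesh, random_mesh.vertices)
    np.testing.assert_allclose(lap.sum(axis=0), 0.0, atol=1e-9)


def test_laplacian_field_length_mismatch(random_mesh):
    with pytest.raises(ContractViolation):
        discrete_laplacian(random_mesh, np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# mean edge length

def test_regular_tetrahedron_edge_length():
    s = 1.0 / np.sqrt(2)
    v = np.array([[1, 0, -s], [-1, 0, -s], [0, 1, s], [0, -1, s]]) * 0.5
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    tet = TriangleMesh(v, f)
    edge = np.linalg.norm(v[0] - v[1])
    for i in range(4):
        assert mean_edge_length(tet, i) == pytest.approx(edge)


def test_mean_edge_length_two_distances():
    # vertex 0 with neighbours at distances 1 and 3 (plus shared edge)
    v = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 3, 0]])
    m = TriangleMesh(v, [[0, 1, 2]], orient=False)
    d01, d02 = 1.0, 3.0
    assert mean_edge_length(m, 0) == pytest.approx((d01 + d02) / 2)


def test_mean_edge_length_matches_bruteforce(random_mesh):
    lengths = random_mesh.mean_edge_lengths()
    adj = vertex_adjacency(random_mesh)
    for i in range(0, random_mesh.n_vertices, 13):
        expected = np.mean([np.linalg.norm(random_mesh.vertices[i]
                                           - random_mesh.vertices[j])
                            for j in adj[i]])
        assert lengths[i] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# resampling

def test_resample_sphere_to_400(sphere3):
    out = resample_to(sphere3, 400)
    assert out.n_vertices == 400
    assert out.n_faces == 796
    assert out.is_closed


def test_resample_euler_formula_various(sphere3):
    for n in (50, 123, 300):
        out = resample_to(sphere3, n)
        assert out.n_faces == 2 * n - 4
        assert out.is_closed


def test_resample_identity_count_near_identity(sphere2):
    out = resample_to(sphere2, sphere2.n_vertices)
    assert hausdorff_distance(sphere2, out) < 0.05 * sphere2.bounding_box_diagonal()


def test_resample_sphere_radius_preserved(sphere3):
    scaled = sphere3.with_vertices(sphere3.vertices * 10.0)
    out = resample_to(TriangleMesh(scaled.vertices, scaled.faces), 200)
    radii = np.linalg.norm(out.vertices, axis=1)
    assert np.all(np.abs(radii - 10.0) < 0.6)


def test_resample_error_tolerance_enforced(sphere3):
    with pytest.raises(ContractViolation):
        resample_to(sphere3, 12, max_error_fraction=1e-6)


def test_resample_below_tetrahedron_rejected(sphere2):
    with pytest.raises(ContractViolation):
        resample_to(sphere2, 3)


def test_resample_random_meshes_stay_closed():
    for seed in range(3):
        m = bumpy_mesh(seed, subdivisions=3)
        out = resample_to(m, 150)
        assert out.is_closed
        assert out.n_vertices == 150
        assert hausdorff_distance(m, out) < 0.1 * m.bounding_box_diagonal()
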