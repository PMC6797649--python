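"""Triangle-mesh container and the discrete differential operators used everywhere else.

Coordinates are millimetres throughout.  The discrete Laplacian is the
uniform-weight umbrella operator

    L(f)_i = sum_{j in N(i)} w_ij (f_i - f_j)

with ``w_ij = 1`` by default; applied to vertex positions it approximates the
mean-curvature normal, applied to a displacement field it measures the
roughness of the deformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


class MeshFormatError(ValueError):
    """Raised for malformed mesh files or non-triangular faces."""


class ContractViolation(ValueError):
    """Raised when an operation's preconditions are not met."""


def _as_vertices(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ContractViolation(f"vertices must be (N, 3), got {v.shape}")
    return v


def _as_faces(faces) -> np.ndarray:
    f = np.asarray(faces, dtype=np.int64)
    if f.ndim != 2 or f.shape[1] != 3:
        raise MeshFormatError(f"faces must be triangles (M, 3), got {f.shape}")
    return f


class TriangleMesh:
    """A triangulated surface: vertex array (N, 3) and face-index array (M, 3).

    Derived quantities (normals, adjacency, edge lists, Laplacian matrices)
    are computed lazily and cached; mutate vertices only through
    :meth:`with_vertices`, which returns a new mesh sharing topology.
    """

    def __init__(self, vertices, faces, *, orient: bool = True):
        self.vertices = _as_vertices(vertices)
        self.faces = _as_faces(faces)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshFormatError("face indices out of range")
        self._cache: dict = {}
        if orient and self.is_closed and self.signed_volume() < 0:
            self.faces = self.faces[:, ::-1].copy()
            self._cache = {}

    # -- basic counts ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new vertex positions (no re-orientation pass)."""
        v = _as_vertices(vertices)
        if len(v) != self.n_vertices:
            raise ContractViolation("vertex count mismatch")
        m = TriangleMesh.__new__(TriangleMesh)
        m.vertices = v
        m.faces = self.faces
        m._cache = {}
        return m

    def copy(self) -> "TriangleMesh":
        return self.with_vertices(self.vertices.copy())

    # -- topology ----------------------------------------------------------
    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as (E, 2) sorted index pairs."""
        if "edges" not in self._cache:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
            e.sort(axis=1)
            self._cache["edges"] = np.unique(e, axis=0)
        return self._cache["edges"]

    @property
    def is_closed(self) -> bool:
        """True iff every edge borders exactly two faces and V - E + F = 2."""
        if "closed" not in self._cache:
            e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                           self.faces[:, [2, 0]]])
            e.sort(axis=1)
            _, counts = np.unique(e, axis=0, return_counts=True)
            two_manifold = bool(counts.size) and bool(np.all(counts == 2))
            euler = self.n_vertices - len(counts) + self.n_faces
            self._cache["closed"] = two_manifold and euler == 2
        return self._cache["closed"]

    def vertex_adjacency(self) -> list[np.ndarray]:
        """One-ring neighbour indices per vertex, each ascending."""
        if "adjacency" not in self._cache:
            e = self.edges
            order = np.argsort(np.concatenate([e[:, 0], e[:, 1]]), kind="stable")
            endpoints = np.concatenate([e[:, 1], e[:, 0]])[order]
            heads = np.concatenate([e[:, 0], e[:, 1]])[order]
            splits = np.searchsorted(heads, np.arange(self.n_vertices + 1))
            adj = [np.sort(endpoints[splits[i]:splits[i + 1]])
                   for i in range(self.n_vertices)]
            self._cache["adjacency"] = adj
        return self._cache["adjacency"]

    # -- geometry ----------------------------------------------------------
    def face_normals(self, *, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalized:
            lng = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.where(lng > 0, lng, 1.0)
        return n

    @property
    def vertex_normals(self) -> np.ndarray:
        """Unit normals: area-weighted average of incident face normals."""
        if "normals" not in self._cache:
            fn = self.face_normals(normalized=False)  # length 2*area
            n = np.zeros_like(self.vertices)
            for k in range(3):
                np.add.at(n, self.faces[:, k], fn)
            lng = np.linalg.norm(n, axis=1, keepdims=True)
            self._cache["normals"] = n / np.where(lng > 0, lng, 1.0)
        return self._cache["normals"]

    def signed_volume(self) -> float:
        """Signed volume in mm^3 by the divergence theorem (origin tetrahedra)."""
        v = self.vertices
        f = self.faces
        return float(np.einsum("ij,ij->i", v[f[:, 0]],
                               np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)

    def bounding_box_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))

    def mean_edge_lengths(self) -> np.ndarray:
        """Per-vertex arithmetic mean of incident edge lengths."""
        if "mean_edge" not in self._cache:
            e = self.edges
            lng = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                                 axis=1)
            tot = np.zeros(self.n_vertices)
            cnt = np.zeros(self.n_vertices)
            np.add.at(tot, e[:, 0], lng)
            np.add.at(tot, e[:, 1], lng)
            np.add.at(cnt, e[:, 0], 1.0)
            np.add.at(cnt, e[:, 1], 1.0)
            if np.any(cnt == 0):
                raise ContractViolation("mesh has isolated vertices")
            self._cache["mean_edge"] = tot / cnt
        return self._cache["mean_edge"]

    # -- operators ---------------------------------------------------------
    def laplacian_matrix(self, weights: str | np.ndarray = "uniform") -> sp.csr_matrix:
        """Sparse operator such that (L @ f)[i] = sum_j w_ij (f_i - f_j).

        ``weights`` is ``"uniform"`` (w_ij = 1, the default protocol),
        ``"cotangent"``, or an explicit per-edge array aligned with
        :attr:`edges`.
        """
        key = ("lap", weights if isinstance(weights, str) else id(weights))
        if key not in self._cache:
            e = self.edges
            if isinstance(weights, str):
                if weights == "uniform":
                    w = np.ones(len(e))
                elif weights == "cotangent":
                    w = self._cotangent_edge_weights()
                else:
                    raise ValueError(f"unknown weighting {weights!r}")
            else:
                w = np.asarray(weights, dtype=np.float64)
                if len(w) != len(e):
                    raise ContractViolation("per-edge weight length mismatch")
            n = self.n_vertices
            rows = np.concatenate([e[:, 0], e[:, 1]])
            cols = np.concatenate([e[:, 1], e[:, 0]])
            vals = np.concatenate([w, w])
            A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
            D = sp.diags(np.asarray(A.sum(axis=1)).ravel())
            self._cache[key] = (D - A).tocsr()
        return self._cache[key]

    def _cotangent_edge_weights(self) -> np.ndarray:
        v, f = self.vertices, self.faces
        e = self.edges
        lookup = {tuple(pair): idx for idx, pair in enumerate(map(tuple, e))}
        w = np.zeros(len(e))
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            p, q, r = v[f[:, a]], v[f[:, b]], v[f[:, c]]
            u1, u2 = p - r, q - r
            cross = np.linalg.norm(np.cross(u1, u2), axis=1)
            cot = np.einsum("ij,ij->i", u1, u2) / np.where(cross > 0, cross, 1.0)
            for fi in range(len(f)):
                i, j = sorted((f[fi, a], f[fi, b]))
                w[lookup[(i, j)]] += 0.5 * cot[fi]
        return w


@dataclass
class VectorField:
    """One 3-vector per mesh vertex (mm), bound to the mesh it lives on."""

    mesh: TriangleMesh
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.mesh.n_vertices, 3):
            raise ContractViolation(
                f"field shape {self.values.shape} does not match mesh "
                f"({self.mesh.n_vertices} vertices)")

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=1)


# ---------------------------------------------------------------------------
# module-level operation wrappers

def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    return mesh.vertex_adjacency()


def discrete_laplacian(mesh: TriangleMesh, values: np.ndarray | VectorField,
                       weights: str | np.ndarray = "uniform") -> np.ndarray:
    """Apply the umbrella operator to a per-vertex field (scalar or vector)."""
    if isinstance(values, VectorField):
        values = values.values
    values = np.asarray(values, dtype=np.float64)
    if len(values) != mesh.n_vertices:
        raise ContractViolation("field length does not match vertex count")
    return mesh.laplacian_matrix(weights) @ values


def mean_edge_length(mesh: TriangleMesh, vertex: int) -> float:
    return float(mesh.mean_edge_lengths()[vertex])
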