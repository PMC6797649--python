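"""Surface-distance, smoothness, displacement-error and volume metrics.

Mean and Hausdorff distances are symmetrized and use true point-to-triangle
proximity, so a coarse mesh compared against a fine one is scored by the
distance to the other *surface*, not to its nearest vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .mesh import ContractViolation, TriangleMesh, VectorField, discrete_laplacian


@dataclass
class EvaluationPoint:
    """A labelled landmark pair: position on the source (inflated) surface and
    its true corresponding position on the target (deflated) surface."""

    label: str
    position_inflated: np.ndarray
    position_deflated: np.ndarray

    def __post_init__(self):
        self.position_inflated = np.asarray(self.position_inflated, dtype=np.float64)
        self.position_deflated = np.asarray(self.position_deflated, dtype=np.float64)
        if not (np.all(np.isfinite(self.position_inflated))
                and np.all(np.isfinite(self.position_deflated))):
            raise ContractViolation("evaluation point positions must be finite")

    @property
    def true_displacement(self) -> np.ndarray:
        return self.position_deflated - self.position_inflated


@dataclass
class MetricReport:
    mean_distance: float
    hausdorff_distance: float
    laplacian_mean: float
    laplacian_max: float
    target_displacement_errors: list[float] = field(default_factory=list)
    sd_convention: str = "sample (n-1)"

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# point-to-surface distance

def _triangle_arrays(mesh: TriangleMesh):
    tri = mesh.vertices[mesh.faces]  # (M, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e0, e1 = b - a, c - a
    a00 = np.einsum("ij,ij->i", e0, e0)
    a01 = np.einsum("ij,ij->i", e0, e1)
    a11 = np.einsum("ij,ij->i", e1, e1)
    det = np.maximum(a00 * a11 - a01 * a01, 1e-30)
    n = np.cross(e0, e1)
    n_hat = n / np.maximum(np.linalg.norm(n, axis=1), 1e-30)[:, None]
    edges = [(a, e0, a00), (a, e1, a11),
             (b, c - b, np.einsum("ij,ij->i", c - b, c - b))]
    return a, e0, e1, a00, a01, a11, det, n_hat, edges


def _chunk_distances(p, a, e0, e1, a00, a01, a11, det, n_hat, edges):
    """Per (point, triangle) squared distance and the data to rebuild the
    closest point for the winners."""
    w = p[:, None, :] - a[None, :, :]  # (P, M, 3)
    b0 = np.einsum("pmj,mj->pm", w, e0)
    b1 = np.einsum("pmj,mj->pm", w, e1)
    s = (a11 * b0 - a01 * b1) / det
    t = (a00 * b1 - a01 * b0) / det
    inside = (s >= 0) & (t >= 0) & (s + t <= 1)
    plane = np.einsum("pmj,mj->pm", w, n_hat)
    d2 = np.where(inside, plane ** 2, np.inf)
    for q0, d, dd in edges:
        wq = p[:, None, :] - q0[None, :, :]
        u = np.clip(np.einsum("pmj,mj->pm", wq, d) / np.maximum(dd, 1e-30),
                    0.0, 1.0)
        diff = wq - u[:, :, None] * d[None, :, :]
        d2 = np.minimum(d2, np.einsum("pmj,pmj->pm", diff, diff))
    return d2


def _closest_on_winner(p, tri_idx, mesh):
    """Exact closest point of each query on its pre-selected triangle."""
    tri = mesh.vertices[mesh.faces[tri_idx]]  # (P, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    e0, e1 = b - a, c - a
    a00 = np.einsum("ij,ij->i", e0, e0)
    a01 = np.einsum("ij,ij->i", e0, e1)
    a11 = np.einsum("ij,ij->i", e1, e1)
    det = np.maximum(a00 * a11 - a01 * a01, 1e-30)
    w = p - a
    b0 = np.einsum("ij,ij->i", w, e0)
    b1 = np.einsum("ij,ij->i", w, e1)
    s = (a11 * b0 - a01 * b1) / det
    t = (a00 * b1 - a01 * b0) / det
    inside = (s >= 0) & (t >= 0) & (s + t <= 1)
    n = np.cross(e0, e1)
    n_hat = n / np.maximum(np.linalg.norm(n, axis=1), 1e-30)[:, None]
    plane_pt = p - np.einsum("ij,ij->i", w, n_hat)[:, None] * n_hat

    best = np.full(len(p), np.inf)
    best_pt = np.zeros_like(p)
    for q0, d in ((a, e0), (a, e1), (b, c - b)):
        dd = np.maximum(np.einsum("ij,ij->i", d, d), 1e-30)
        u = np.clip(np.einsum("ij,ij->i", p - q0, d) / dd, 0.0, 1.0)
        cand = q0 + u[:, None] * d
        dist = np.einsum("ij,ij->i", p - cand, p - cand)
        better = dist < best
        best[better] = dist[better]
        best_pt[better] = cand[better]
    best_pt[inside] = plane_pt[inside]
    return best_pt


def closest_points_on_surface(points: np.ndarray, mesh: TriangleMesh,
                              chunk: int = 256, return_faces: bool = False):
    """Closest surface points and distances for a set of queries.

    Exact point-to-triangle proximity: the plane projection when its
    barycentric coordinates lie inside the triangle, otherwise the closest
    point on one of the three edges.  With ``return_faces`` the winning
    triangle index of each query is also returned.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    arrays = _triangle_arrays(mesh)
    dist = np.empty(len(points))
    closest = np.empty_like(points)
    faces = np.empty(len(points), dtype=np.int64)
    for lo in range(0, len(points), chunk):
        p = points[lo:lo + chunk]
        d2 = _chunk_distances(p, *arrays)
        win = np.argmin(d2, axis=1)
        dist[lo:lo + chunk] = np.sqrt(d2[np.arange(len(p)), win])
        closest[lo:lo + chunk] = _closest_on_winner(p, win, mesh)
        faces[lo:lo + chunk] = win
    if return_faces:
        return closest, dist, faces
    return closest, dist


def point_surface_distance(points: np.ndarray, mesh: TriangleMesh,
                           chunk: int = 256) -> np.ndarray:
    """Distance from each query point to the closest point on the mesh surface."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    arrays = _triangle_arrays(mesh)
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        d2 = _chunk_distances(points[lo:lo + chunk], *arrays)
        out[lo:lo + chunk] = np.sqrt(d2.min(axis=1))
    return out


def mean_distance(a: TriangleMesh, b: TriangleMesh) -> float:
    """Symmetric mean of per-vertex nearest-surface distances (mm)."""
    d_ab = point_surface_distance(a.vertices, b)
    d_ba = point_surface_distance(b.vertices, a)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def hausdorff_distance(a: TriangleMesh, b: TriangleMesh) -> float:
    """Symmetric Hausdorff distance: the largest nearest-surface distance (mm)."""
    d_ab = point_surface_distance(a.vertices, b)
    d_ba = point_surface_distance(b.vertices, a)
    return float(max(d_ab.max(), d_ba.max()))


# ---------------------------------------------------------------------------
# displacement-field metrics

def displacement_laplacian_stats(mesh: TriangleMesh,
                                 u: np.ndarray | VectorField) -> tuple[float, float]:
    """Mean and max of ``|L(u)_i|`` over vertices — deformation smoothness."""
    lu = discrete_laplacian(mesh, u)
    mags = np.linalg.norm(lu, axis=1)
    return float(mags.mean()), float(mags.max())


def target_displacement_error(u_true, u_est) -> float:
    """Euclidean norm of the displacement error at one evaluation point (mm)."""
    u_true = np.asarray(u_true, dtype=np.float64)
    u_est = np.asarray(u_est, dtype=np.float64)
    return float(np.linalg.norm(u_est - u_true))


def evaluate_target_displacements(m_inflated: TriangleMesh,
                                  m_deflated: TriangleMesh,
                                  points: list[EvaluationPoint]) -> list[float]:
    """TDE per evaluation point.

    The estimated displacement at a point is read off the registered pair's
    per-vertex correspondence at the closest point of the inflated model's
    surface, interpolated barycentrically — the continuous analogue of
    taking the corresponding registered vertex, fair across template
    resolutions.
    """
    if m_inflated.n_vertices != m_deflated.n_vertices:
        raise ContractViolation("registered pair must share topology")
    disp = m_deflated.vertices - m_inflated.vertices
    queries = np.array([pt.position_inflated for pt in points])
    closest, _, face_idx = closest_points_on_surface(queries, m_inflated,
                                                     return_faces=True)
    errors = []
    for k, pt in enumerate(points):
        tri = m_inflated.faces[face_idx[k]]
        bary = _barycentric(closest[k], m_inflated.vertices[tri])
        u_est = bary @ disp[tri]
        errors.append(target_displacement_error(pt.true_displacement, u_est))
    return errors


def _barycentric(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Clamped barycentric coordinates of a point already on the triangle."""
    e0, e1 = tri[1] - tri[0], tri[2] - tri[0]
    w = p - tri[0]
    a00, a01, a11 = e0 @ e0, e0 @ e1, e1 @ e1
    det = max(a00 * a11 - a01 * a01, 1e-30)
    s = (a11 * (w @ e0) - a01 * (w @ e1)) / det
    t = (a00 * (w @ e1) - a01 * (w @ e0)) / det
    s, t = float(np.clip(s, 0, 1)), float(np.clip(t, 0, 1))
    if s + t > 1:
        excess = (s + t - 1) / 2
        s, t = s - excess, t - excess
    return np.array([1 - s - t, s, t])


# ---------------------------------------------------------------------------
# volumes

def lobe_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume of a closed mesh in cc (mm^3 / 1000), orientation-free."""
    if not mesh.is_closed:
        raise ContractViolation("volume requires a closed mesh")
    return abs(mesh.signed_volume()) / 1000.0


def volume_ratio(v_inflated: float, v_deflated: float) -> float:
    """Deflated/inflated volume ratio in percent."""
    if v_inflated <= 0:
        raise ContractViolation("inflated volume must be positive")
    return 100.0 * v_deflated / v_inflated


def summarize_table(values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of a per-case column.

    The sample convention reproduces the reference volume table's printed
    mean +/- SD row; see :mod:`lsmd.datasets`.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ContractViolation("need at least two values to summarize")
    return float(values.mean()), float(values.std(ddof=1))


def metric_report(template_result_mesh: TriangleMesh, target: TriangleMesh,
                  displacement: np.ndarray,
                  points: list[EvaluationPoint] | None = None,
                  deflated_mesh: TriangleMesh | None = None) -> MetricReport:
    """Bundle the standard per-registration metrics into one report."""
    md = mean_distance(template_result_mesh, target)
    hd = hausdorff_distance(template_result_mesh, target)
    ld_mean, ld_max = displacement_laplacian_stats(template_result_mesh,
                                                   displacement)
    tdes: list[float] = []
    if points and deflated_mesh is not None:
        tdes = evaluate_target_displacements(template_result_mesh,
                                             deflated_mesh, points)
    return MetricReport(md, hd, ld_mean, ld_max, tdes)
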