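"""Synthetic lobe-like meshes and ground-truth deflation deformations.

Shapes are smoothly perturbed half-ellipsoid-like closed surfaces with one
high-curvature apex and a ridge band, sized to realistic lobe volumes
(order 100-300 cc).  The deflation map is analytic — bending, rotation about
an axis through the hilum, then radial contraction toward the hilum — so
every vertex carries an exact ground-truth displacement.  The deformed
surface is independently remeshed to a different vertex count, so source and
target share no topology, mimicking surfaces segmented from two separate
scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import ContractViolation, TriangleMesh, VectorField
from .metrics import EvaluationPoint


# ---------------------------------------------------------------------------
# icosphere scaffold

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1 + np.sqrt(5)) / 2
    v = np.array([[-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
                  [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
                  [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]],
                 dtype=np.float64)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
                  [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
                  [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
                  [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]],
                 dtype=np.int64)
    return v, f


def icosphere(subdivisions: int = 4) -> TriangleMesh:
    """Unit sphere by repeated midpoint subdivision of an icosahedron."""
    v, f = _icosahedron()
    verts = [tuple(p) for p in v]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        new_faces = []

        def midpoint(i, j):
            key = (i, j) if i < j else (j, i)
            if key not in cache:
                p = np.asarray(verts[i]) + np.asarray(verts[j])
                p /= np.linalg.norm(p)
                verts.append(tuple(p))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        f = np.asarray(new_faces, dtype=np.int64)
    return TriangleMesh(np.asarray(verts), f)


# ---------------------------------------------------------------------------
# lobe shapes

_SEMI_AXES = np.array([28.0, 36.0, 52.0])  # mm; apex along +z


def _lobe_radius(directions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Radius per unit direction: ellipsoid base + apex bump + ridge band
    + smooth seeded jitter."""
    d = directions
    base = 1.0 / np.sqrt(((d / _SEMI_AXES) ** 2).sum(axis=1))
    # the apex and ridge vary between subjects (tilt, sharpness, amplitude,
    # position) like real anatomical features do — a global transform cannot
    # absorb these differences, a non-rigid registration can
    tilt = rng.normal(0.0, 0.06, size=2)
    a_dir = np.array([tilt[0], tilt[1], 1.0])
    a_dir /= np.linalg.norm(a_dir)
    apex_amp = 0.25 * (1.0 + rng.normal(0.0, 0.125))
    apex_width = 0.10 * (1.0 + rng.normal(0.0, 0.125))
    apex = 1.0 + apex_amp * np.exp(-(1.0 - d @ a_dir) / max(apex_width, 0.04))
    ridge_amp = 0.12 * (1.0 + rng.normal(0.0, 0.175))
    ridge_y = rng.normal(0.0, 0.035)
    ridge_z = -0.25 + rng.normal(0.0, 0.05)
    ridge = 1.0 + ridge_amp * np.exp(-((d[:, 1] - ridge_y) / 0.22) ** 2) \
        * np.exp(-((d[:, 2] - ridge_z) / 0.55) ** 2)
    # decisive asymmetry on every axis (lobes are egg- not ellipsoid-like);
    # keeps the solid's third moments well away from zero so orientation is
    # never ambiguous
    skew = (1.0 + 0.14 * d[:, 0]) * (1.0 - 0.12 * d[:, 1]) \
        * (1.0 + 0.06 * d[:, 2] ** 3)
    jitter = np.ones(len(d))
    for _ in range(6):
        q = rng.normal(size=3)
        q /= np.linalg.norm(q)
        amp = rng.normal(0.0, 0.02)
        power = rng.integers(2, 4)
        jitter += amp * (d @ q) ** power
    # localized bumps: non-affine inter-subject variation a global transform
    # cannot absorb
    for _ in range(8):
        q = rng.normal(size=3)
        q /= np.linalg.norm(q)
        amp = rng.normal(0.0, 0.03)
        width = rng.uniform(0.3, 0.7)
        jitter += amp * np.exp(-(1.0 - d @ q) / width)
    return base * apex * ridge * skew * jitter


def make_fine_lobe(seed: int, subdivisions: int = 4) -> TriangleMesh:
    """High-resolution lobe surface (2562 vertices at the default level)."""
    rng = np.random.default_rng(seed)
    sphere = icosphere(subdivisions)
    r = _lobe_radius(sphere.vertices, rng)
    return TriangleMesh(sphere.vertices * r[:, None], sphere.faces)


def _fibonacci_directions(n: int, seed: int) -> np.ndarray:
    """n near-uniform unit directions, randomly rotated (seeded)."""
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    dirs = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return dirs @ q.T


def _ray_radii(mesh: TriangleMesh, origin: np.ndarray,
               dirs: np.ndarray, chunk: int = 256) -> np.ndarray:
    """First-hit ray lengths from an interior origin along each direction
    (Moller-Trumbore, vectorized)."""
    tri = mesh.vertices[mesh.faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    r = np.empty(len(dirs))
    for lo in range(0, len(dirs), chunk):
        d = dirs[lo:lo + chunk]
        h = np.cross(d[:, None, :], e2[None, :, :])
        a = np.einsum("mj,pmj->pm", e1, h)
        safe = np.where(a == 0, 1.0, a)
        f = np.where(np.abs(a) > 1e-12, 1.0 / safe, 0.0)
        s = np.broadcast_arrays((origin - v0)[None, :, :], h)[0]
        u = f * np.einsum("pmj,pmj->pm", s, h)
        q = np.cross(s, e1[None, :, :])
        v = f * np.einsum("pj,pmj->pm", d, q)
        t = f * np.einsum("mj,pmj->pm", e2, q)
        hit = (np.abs(a) > 1e-12) & (u >= -1e-9) & (v >= -1e-9) \
            & (u + v <= 1 + 1e-9) & (t > 1e-9)
        r[lo:lo + chunk] = np.where(hit, t, np.inf).min(axis=1)
    if not np.all(np.isfinite(r)):
        raise ContractViolation("ray remeshing failed: surface not "
                                "star-shaped about its centroid")
    return r


def surface_remesh(mesh: TriangleMesh, n_vertices: int,
                   seed: int = 0) -> TriangleMesh:
    """Independent retriangulation with vertices exactly on the surface.

    Casts rays from the centroid along a seeded, randomly rotated Fibonacci
    direction set and triangulates via the convex hull of the directions
    (a spherical Delaunay), so the output shares no topology with the input.
    Requires the surface to be star-shaped about its centroid.
    """
    from scipy.spatial import ConvexHull
    if n_vertices < 4:
        raise ContractViolation("need at least 4 vertices")
    dirs = _fibonacci_directions(n_vertices, seed)
    origin = mesh.vertices.mean(axis=0)
    radii = _ray_radii(mesh, origin, dirs)
    hull = ConvexHull(dirs)
    faces = hull.simplices.copy()
    # orient every hull face outward (positive det about the origin)
    flip = np.einsum("ij,ij->i", dirs[faces[:, 0]],
                     np.cross(dirs[faces[:, 1]], dirs[faces[:, 2]])) < 0
    faces[flip] = faces[flip][:, ::-1]
    return TriangleMesh(origin + radii[:, None] * dirs, faces)


def make_lobe_mesh(seed: int, n_vertices: int = 400) -> TriangleMesh:
    """Closed genus-0 lobe-like mesh with exactly ``n_vertices`` vertices."""
    if n_vertices < 100:
        raise ContractViolation("lobe meshes need at least 100 vertices")
    fine = make_fine_lobe(seed)
    return surface_remesh(fine, n_vertices, seed=seed + 1)


def default_hilum(mesh: TriangleMesh) -> np.ndarray:
    """Reference contraction centre: low on the axis opposite the apex."""
    lo, hi = mesh.vertices.min(0), mesh.vertices.max(0)
    centre = 0.5 * (lo + hi)
    return np.array([centre[0], centre[1], lo[2] + 0.15 * (hi[2] - lo[2])])


# ---------------------------------------------------------------------------
# deflation map

@dataclass
class DeflationParams:
    """Analytic deflation: bend, rotate about an axis through the hilum,
    then contract radially toward the hilum; optional normal noise."""

    hilum: np.ndarray
    contraction: float | np.ndarray = 0.78  # scalar or per-axis, in (0, 1]
    rotation_deg: float = 0.0          # about `axis` through the hilum
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    bending_mm: float = 0.0            # transverse quadratic offset amplitude
    bend_direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    tip_compression: float = 0.0       # extra apical collapse, quadratic in z
    radial_gain: float = 0.0           # >0: distal regions contract more
    noise_sd: float = 0.0              # mm, along deformed normals
    target_n_vertices: int = 420       # independent remesh count
    rng_seed: int = 0

    def __post_init__(self):
        self.hilum = np.asarray(self.hilum, dtype=np.float64)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        self.axis = self.axis / np.linalg.norm(self.axis)
        self.bend_direction = np.asarray(self.bend_direction, dtype=np.float64)
        self.bend_direction = self.bend_direction / np.linalg.norm(self.bend_direction)
        c = np.atleast_1d(np.asarray(self.contraction, dtype=np.float64))
        if c.size not in (1, 3) or np.any(c <= 0) or np.any(c > 1):
            raise ContractViolation(
                "contraction must be a scalar or 3-vector in (0, 1]")
        if self.noise_sd < 0:
            raise ContractViolation("noise SD must be >= 0")


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


def deflation_map(points: np.ndarray, params: DeflationParams,
                  scale_reference: float) -> np.ndarray:
    """Exact deformed position of each point (no noise).

    ``scale_reference`` is the max hilum distance of the *source* mesh,
    fixed once per case so the map is identical wherever it is evaluated.
    """
    w = np.atleast_2d(points) - params.hilum
    if params.bending_mm != 0.0:
        t = np.linalg.norm(w, axis=1) / max(scale_reference, 1e-12)
        w = w + params.bending_mm * (t ** 2)[:, None] * params.bend_direction
    if params.tip_compression != 0.0:
        # apical collapse: axial (hilum-to-tip) contraction growing
        # quadratically toward the tip; non-affine and surface-normal-visible
        # at the apex
        w = w.copy()
        z = np.maximum(w[:, 2], 0.0) / max(scale_reference, 1e-12)
        w[:, 2] = w[:, 2] * (1.0 - params.tip_compression * z ** 2)
    if params.rotation_deg != 0.0:
        R = _rotation_matrix(params.axis, np.deg2rad(params.rotation_deg))
        w = w @ R.T
    c = np.atleast_1d(np.asarray(params.contraction, dtype=np.float64))
    w = w * c  # isotropic or per-axis (anisotropic) contraction
    if params.radial_gain != 0.0:
        # distal collapse: contraction strengthens with hilum distance,
        # a smooth non-affine component no global transform can absorb
        t = np.linalg.norm(w, axis=1) / max(scale_reference, 1e-12)
        w = w * (1.0 - params.radial_gain * (t - 0.5))[:, None]
    return params.hilum + w


def apply_deflation(mesh: TriangleMesh, params: DeflationParams,
                    n_evaluation_points: int = 6
                    ) -> tuple[TriangleMesh, VectorField, list[EvaluationPoint]]:
    """Deform a source mesh, returning the independently remeshed target,
    the exact ground-truth displacement on the source vertices, and
    auto-placed tip/ridge evaluation point pairs."""
    scale_ref = float(np.linalg.norm(mesh.vertices - params.hilum,
                                     axis=1).max())
    if params.bending_mm > 0.5 * scale_ref:
        raise ContractViolation(
            f"bending amplitude {params.bending_mm} mm risks self-intersection; "
            f"keep it below half the lobe extent ({0.5 * scale_ref:.1f} mm)")
    deformed_pos = deflation_map(mesh.vertices, params, scale_ref)
    truth = VectorField(mesh, deformed_pos - mesh.vertices)
    deformed = mesh.with_vertices(deformed_pos)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.rng_seed)
        noisy = deformed_pos + params.noise_sd \
            * rng.standard_normal(len(deformed_pos))[:, None] \
            * deformed.vertex_normals
        deformed = mesh.with_vertices(noisy)
    target = surface_remesh(TriangleMesh(deformed.vertices, deformed.faces),
                            params.target_n_vertices, seed=params.rng_seed + 1)
    points = place_evaluation_points(mesh, params.hilum, n_evaluation_points)
    eval_pairs = [
        EvaluationPoint(lbl, pos,
                        deflation_map(pos, params, scale_ref)[0])
        for lbl, pos in points]
    return target, truth, eval_pairs


def place_evaluation_points(mesh: TriangleMesh, hilum,
                            n_points: int = 6) -> list[tuple[str, np.ndarray]]:
    """Programmatic stand-in for manual landmarking.

    Mirrors the tip/ridge protocol using the generator's structural
    features: the apex (farthest vertex from the hilum) plus the sharpest
    vertices of the built-in ridge band (the high-curvature strip near the
    y-midplane on the lower half), spread along the ridge.  Structural
    features are used rather than arbitrary curvature maxima so that the
    points denote stable, identifiable locations, as manual landmarks would.
    """
    hilum = np.asarray(hilum, dtype=np.float64)
    v = mesh.vertices
    lap = mesh.laplacian_matrix() @ v
    curvature = np.linalg.norm(lap, axis=1) / mesh.mean_edge_lengths()
    dist = np.linalg.norm(v - hilum, axis=1)
    apex = int(np.argmax(dist))

    lo, hi = v.min(0), v.max(0)
    centre, span = 0.5 * (lo + hi), np.maximum(hi - lo, 1e-9)
    dn = (v - centre) / (0.5 * span)  # normalized [-1, 1] coordinates
    band = (np.abs(dn[:, 1]) < 0.3) & (dn[:, 2] < 0.25) & (dn[:, 2] > -0.8)
    candidates = np.flatnonzero(band)
    if candidates.size == 0:
        candidates = np.arange(len(v))
    # spread along the ridge: one sharpest vertex per x-bin, staying clear
    # of the lateral extremes where the band leaves the ridge crest
    n_ridge = max(n_points - 1, 1)
    order = dn[candidates, 0]
    edges = np.quantile(order, np.linspace(0.08, 0.92, n_ridge + 1))
    chosen = [apex]
    for k in range(n_ridge):
        in_bin = candidates[(order >= edges[k]) & (order <= edges[k + 1])]
        in_bin = [i for i in in_bin if i not in chosen]
        if in_bin:
            chosen.append(int(in_bin[int(np.argmax(curvature[in_bin]))]))
    labels = ["tip-1"] + [f"ridge-{k}" for k in range(1, len(chosen))]
    return [(lbl, v[i].copy()) for lbl, i in zip(labels, chosen)]


# ---------------------------------------------------------------------------
# populations

@dataclass
class VariationSpec:
    """Distributions for per-case deflation parameter draws."""

    contraction_mean: float = 0.74
    contraction_sd: float = 0.08
    # bounds chosen to match the observed per-lobe volume-ratio range of the
    # reference study (excluding its pressure-control failure case)
    contraction_bounds: tuple[float, float] = (0.56, 0.86)
    rotation_sd_deg: float = 22.0
    bending_mean_mm: float = 3.5
    bending_sd_mm: float = 1.2
    # per-axis spread around the drawn c; zero by default — the reference
    # volume table reports a single scalar ratio per lobe, and principal-axes
    # moment alignment is exact only for isotropic-plus-rotation maps
    anisotropy_sd: float = 0.0
    tip_compression_mean: float = 0.10
    tip_compression_sd: float = 0.04
    radial_gain_mean: float = 0.0
    radial_gain_sd: float = 0.0
    noise_sd_mm: float = 0.1
    source_n_vertices: int = 1500
    target_n_vertices: int = 1400
    shape_jitter: bool = True


@dataclass
class SyntheticCase:
    case_id: str
    inflated: TriangleMesh
    deflated: TriangleMesh
    truth: VectorField            # on the inflated mesh
    evaluation_points: list[EvaluationPoint]
    params: DeflationParams


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def make_population(n_cases: int, base_seed: int,
                    variation: VariationSpec | None = None
                    ) -> list[SyntheticCase]:
    """Seeded population of inflated/deflated pairs with exact truth fields."""
    if n_cases < 2:
        raise ContractViolation("a population needs at least two cases")
    variation = variation or VariationSpec()
    cases = []
    root = np.random.SeedSequence(base_seed)
    for k, child in enumerate(root.spawn(n_cases)):
        rng = np.random.default_rng(child)
        shape_seed = int(rng.integers(2 ** 31)) if variation.shape_jitter \
            else base_seed
        fine = make_fine_lobe(shape_seed)
        inflated = surface_remesh(fine, variation.source_n_vertices,
                                  seed=shape_seed + 1)
        c_base = _truncated_normal(
            rng, variation.contraction_mean, variation.contraction_sd,
            *variation.contraction_bounds)
        contraction = np.clip(
            c_base * (1.0 + rng.normal(0.0, variation.anisotropy_sd, size=3)),
            0.4, 0.99)
        gain = 0.0
        if variation.radial_gain_mean > 0 or variation.radial_gain_sd > 0:
            gain = float(abs(rng.normal(variation.radial_gain_mean,
                                        variation.radial_gain_sd)))
        params = DeflationParams(
            hilum=default_hilum(inflated),
            contraction=contraction,
            rotation_deg=float(rng.normal(0.0, variation.rotation_sd_deg)),
            bending_mm=float(abs(rng.normal(variation.bending_mean_mm,
                                            variation.bending_sd_mm))),
            tip_compression=float(abs(rng.normal(
                variation.tip_compression_mean, variation.tip_compression_sd))),
            radial_gain=gain,
            noise_sd=variation.noise_sd_mm,
            target_n_vertices=variation.target_n_vertices,
            rng_seed=int(rng.integers(2 ** 31)))
        deflated, truth, points = apply_deflation(inflated, params)
        cases.append(SyntheticCase(f"case-{k + 1:02d}", inflated, deflated,
                                   truth, points, params))
    return cases
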