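"""Non-rigid surface registration by progressive Laplacian shape matching.

The main routine :func:`register_lsmd` deforms a template mesh onto a target
surface by iterating four steps:

1. compute discrete Laplacians and vertex normals on template and target;
2. find, for every template vertex, the target vertex minimizing the local
   similarity ``Q = |v_s - v_t| + gamma (1 - n_s . n_t)``;
3. turn the matches into soft positional constraints — vertices that already
   sit on the target (low Q) are anchored in place, badly matched vertices
   (high Q) are pulled a sub-edge-length step toward the tangent plane of
   their match, and the pull origin is first smoothed by subtracting the
   Laplacian of the accumulated displacement field, which is what keeps the
   recovered deformation smooth;
4. solve the sparse quadratic
   ``min sum |L(v') - L(v)|^2 + delta sum |p_i - v'_i|^2``
   for the updated vertex positions.

:func:`register_lsm` is the ablation without the displacement-field
smoothing; :func:`register_piecewise_affine` and :func:`register_affine` are
the classical baselines.  All methods run an affine ICP pre-alignment first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .decimate import resample_to
from .mesh import ContractViolation, TriangleMesh, VectorField

FLAG_FREE, FLAG_ANCHOR, FLAG_PULL = 0, 1, 2


class DegenerateGeometryError(RuntimeError):
    """Raised when an affine fit hits a rank-deficient vertex configuration."""


@dataclass
class RegistrationConfig:
    """Parameters of the progressive Laplacian registration."""

    delta: float = 10.0          # positional-constraint weight in the solve
    gamma: float = 1.0           # normal-compatibility weight in Q
    lam: float = 1.0             # displacement-smoothing step (v' = v - lam L(u))
    # progressive step divisor: the pull constraint moves a fraction
    # min(l_s / m, 1) of the way to its destination.  m must exceed the mean
    # edge length (mm) for the search to be progressive at all; 20 gives
    # quarter-edge steps on a 400-vertex lobe template.
    m: float = 20.0
    q_high_fraction: float = 0.10
    q_low_fraction: float = 0.02
    max_iterations: int = 3000
    stall_window: int = 10
    rng_seed: int = 0
    weights: str = "uniform"

    def __post_init__(self):
        if self.delta <= 0 or self.gamma < 0 or self.lam < 0 or self.m < 1:
            raise ContractViolation("invalid registration weights")
        if not (0 < self.q_low_fraction < self.q_high_fraction < 1):
            raise ContractViolation("need 0 < q_low_fraction < q_high_fraction < 1")


@dataclass
class Correspondence:
    """Per-template-vertex best target match."""

    target_index: np.ndarray   # (n,) int
    q: np.ndarray              # (n,) similarity value, mm
    flags: np.ndarray | None = None  # FLAG_* after thresholding


@dataclass
class ConstraintSet:
    """Sparse positional constraints: template vertex index -> target point."""

    indices: np.ndarray    # (k,) int
    positions: np.ndarray  # (k, 3) mm

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class RegistrationResult:
    mesh: TriangleMesh                 # registered model, template topology
    displacement: np.ndarray           # final - affine-aligned start, (n, 3)
    affine: np.ndarray                 # 3x4 pre-alignment map
    trace: list[dict]                  # per-iteration convergence record
    iterations: int
    converged: bool
    method: str

    @property
    def displacement_field(self) -> VectorField:
        return VectorField(self.mesh, self.displacement)


# ---------------------------------------------------------------------------
# affine pre-alignment

def _fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 3x4 affine minimizing |A x + t - y|^2 over given pairs."""
    X = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(X) < 4:
        raise DegenerateGeometryError("affine fit: coplanar/degenerate points")
    sol, *_ = np.linalg.lstsq(X, dst, rcond=None)
    return sol.T  # (3, 4)


def apply_affine(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    return points @ affine[:, :3].T + affine[:, 3]


def _solid_moments(mesh: TriangleMesh):
    """Exact volume, centroid and covariance of the enclosed solid
    (divergence-theorem sums over origin tetrahedra)."""
    v, f = mesh.vertices, mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    vol = det.sum() / 6.0
    if abs(vol) < 1e-12:
        raise DegenerateGeometryError("mesh encloses no volume")
    ctr = (det[:, None] * (a + b + c)).sum(0) / (24.0 * vol)
    S = np.zeros((3, 3))
    for x in (a, b, c):
        S += np.einsum("i,ij,ik->jk", det, x, x)
    s = a + b + c
    S += np.einsum("i,ij,ik->jk", det, s, s)
    S /= 120.0
    return vol, ctr, S / vol - np.outer(ctr, ctr)


# degree-3 Keast quadrature on the tetrahedron (exact for cubics)
_TET_Q_BARY = np.array([[0.25, 0.25, 0.25, 0.25],
                        [0.5, 1 / 6, 1 / 6, 1 / 6],
                        [1 / 6, 0.5, 1 / 6, 1 / 6],
                        [1 / 6, 1 / 6, 0.5, 1 / 6],
                        [1 / 6, 1 / 6, 1 / 6, 0.5]])
_TET_Q_W = np.array([-0.8, 0.45, 0.45, 0.45, 0.45])


def _solid_skewness(mesh: TriangleMesh, centre: np.ndarray,
                    axes: np.ndarray) -> np.ndarray:
    """Exact third central moments of the enclosed solid along given axes:
    s_k = integral of ((x - centre) . axes[:, k])^3 dV."""
    v, f = mesh.vertices, mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    det = np.einsum("ij,ij->i", a, np.cross(b, c))  # 6 * signed tet volume
    corners = np.stack([np.zeros_like(a), a, b, c])  # (4, M, 3)
    s = np.zeros(axes.shape[1])
    for lam, w in zip(_TET_Q_BARY, _TET_Q_W):
        x = np.einsum("q,qmj->mj", lam, corners) - centre
        proj = x @ axes  # (M, k)
        s += w * np.einsum("m,mk->k", det / 6.0, proj ** 3)
    return s


_SKEW_RELIABLE = 0.03  # dimensionless skewness below which a sign is untrusted


def _moment_affine(source: TriangleMesh, target: TriangleMesh,
                   target_tree: cKDTree | None = None) -> np.ndarray:
    """Affine from solid-moment matching.

    Covariances of the enclosed solids transform exactly under affine maps,
    so principal-axes whitening recovers the map up to axis signs.  Signs
    are fixed by matching the sign of the solid's third moment (skewness)
    along each principal axis; axes whose normalized skewness is too small
    to trust are resolved by scoring both signs with the mean
    nearest-neighbour distance.
    """
    vol_s, cs, Cs = _solid_moments(source)
    vol_t, ct, Ct = _solid_moments(target)
    ws, Us = np.linalg.eigh(Cs)
    wt, Ut = np.linalg.eigh(Ct)
    if ws.min() <= 0 or wt.min() <= 0:
        raise DegenerateGeometryError("degenerate solid covariance")
    skew_s = _solid_skewness(source, cs, Us) / (abs(vol_s) * ws ** 1.5)
    skew_t = _solid_skewness(target, ct, Ut) / (abs(vol_t) * wt ** 1.5)

    def build(signs):
        lin = Ut @ np.diag(signs) @ np.diag(np.sqrt(wt / ws)) @ Us.T
        return np.hstack([lin, (ct - lin @ cs)[:, None]])

    def polar_angle(lin):
        u, _, vt = np.linalg.svd(lin)
        rot = u @ vt
        if np.linalg.det(rot) < 0:
            return np.pi
        return float(np.arccos(np.clip((np.trace(rot) - 1) / 2, -1, 1)))

    base = np.where(skew_s * skew_t >= 0, 1.0, -1.0)
    unreliable = np.flatnonzero(
        np.minimum(np.abs(skew_s), np.abs(skew_t)) < _SKEW_RELIABLE)
    candidates = []
    for bits in range(1 << len(unreliable)):
        signs = base.copy()
        for j, ax in enumerate(unreliable):
            if bits >> j & 1:
                signs[ax] *= -1
        lin = Ut @ np.diag(signs) @ np.diag(np.sqrt(wt / ws)) @ Us.T
        if np.linalg.det(lin) < 0:
            continue
        candidates.append((signs, polar_angle(lin)))
    if not candidates:
        k = int(np.argmin(np.abs(skew_s * skew_t)))
        base[k] *= -1
        candidates = [(base, polar_angle(
            Ut @ np.diag(base) @ np.diag(np.sqrt(wt / ws)) @ Us.T))]
    # gross orientation is shared between states (same scanning pose), so
    # any candidate amounting to a near-half-turn is a principal-axis flip
    filtered = [c for c in candidates if c[1] < np.pi / 2]
    if not filtered:
        filtered = [min(candidates, key=lambda c: c[1])]

    if len(filtered) == 1:
        return build(filtered[0][0])
    if target_tree is None:
        target_tree = cKDTree(target.vertices)
    best, best_score = None, np.inf
    for signs, _ in filtered:
        aff = build(signs)
        d, _ = target_tree.query(apply_affine(aff, source.vertices))
        score = float(d.mean())
        if score < best_score:
            best, best_score = aff, score
    return best


def affine_align(source: TriangleMesh, target: TriangleMesh,
                 max_iterations: int = 100,
                 tol: float = 1e-10) -> tuple[np.ndarray, TriangleMesh]:
    """Classical affine ICP: iterate nearest-neighbour pairing and
    least-squares affine fitting until the mean pairing distance stops
    improving.  Deterministic given its inputs.

    This is the stand-alone affine baseline (and the global stage of the
    piecewise-affine one).  The progressive Laplacian methods pre-align
    with :func:`moment_align` instead, which preserves correspondence far
    better when the deformation is close to affine.
    """
    tree = cKDTree(target.vertices)
    pts = source.vertices.copy()
    prev = np.inf
    for _ in range(max_iterations):
        _, nn = tree.query(pts)
        aff = _fit_affine(pts, target.vertices[nn])
        pts = apply_affine(aff, pts)
        err = float(np.mean(np.linalg.norm(pts - target.vertices[nn], axis=1)))
        if abs(prev - err) < tol * max(prev, 1.0):
            break
        prev = err
    total = _fit_affine(source.vertices, pts)
    return total, source.with_vertices(pts)


def moment_align(source: TriangleMesh,
                 target: TriangleMesh) -> tuple[np.ndarray, TriangleMesh]:
    """Affine pre-alignment from solid moments (posture + volume matching)."""
    aff = _moment_affine(source, target)
    return aff, source.with_vertices(apply_affine(aff, source.vertices))


# ---------------------------------------------------------------------------
# similarity and correspondence

def local_similarity(v_s, n_s, v_t, n_t, gamma: float = 1.0) -> float:
    """Q = |v_s - v_t| + gamma (1 - n_s . n_t); zero iff coincident points
    with identical normals."""
    v_s, v_t = np.asarray(v_s, float), np.asarray(v_t, float)
    return float(np.linalg.norm(v_s - v_t)
                 + gamma * (1.0 - float(np.dot(n_s, n_t))))


def correspondence_search(template: TriangleMesh, target: TriangleMesh,
                          gamma: float = 1.0) -> Correspondence:
    """Exact argmin of Q over all template x target vertex pairs.

    Ties resolve to the lowest target index (numpy argmin convention).
    """
    if target.n_vertices == 0:
        raise ContractViolation("empty target")
    qmat = cdist(template.vertices, target.vertices)
    if gamma != 0.0:
        qmat = qmat + gamma * (1.0 - template.vertex_normals
                               @ target.vertex_normals.T)
    idx = np.argmin(qmat, axis=1)
    q = qmat[np.arange(len(idx)), idx]
    return Correspondence(idx, q)


def similarity_thresholds(q_values, q_high_fraction: float = 0.10,
                          q_low_fraction: float = 0.02) -> tuple[float, float]:
    """(Q_high, Q_low): means of the ceil(frac*n) largest / smallest Q."""
    q = np.sort(np.asarray(q_values, dtype=np.float64))
    n = q.size
    if n == 0:
        raise ContractViolation("no similarity values")
    k_high = int(np.ceil(q_high_fraction * n))
    k_low = int(np.ceil(q_low_fraction * n))
    return float(q[-k_high:].mean()), float(q[:k_low].mean())


def classify_vertices(corr: Correspondence, q_high: float,
                      q_low: float) -> np.ndarray:
    flags = np.full(len(corr.q), FLAG_FREE, dtype=np.int8)
    flags[corr.q < q_low] = FLAG_ANCHOR
    flags[corr.q > q_high] = FLAG_PULL
    return flags


# ---------------------------------------------------------------------------
# constraints and the quadratic solve

def build_constraints(template: TriangleMesh, target: TriangleMesh,
                      corr: Correspondence, u: np.ndarray,
                      cfg: RegistrationConfig, *,
                      smooth_field: bool = True) -> ConstraintSet:
    """Positional constraints from the current correspondence.

    With ``smooth_field`` (the differential-field variant), the pull origin
    is the smoothed position ``v' = v - lam L(u)`` and the pull destination
    is its orthogonal projection onto the matched target tangent plane; the
    constraint is the internal division point a fraction ``min(l_s/m, 1)``
    of the way there.  Without it (the ablation), the raw vertex and the raw
    matched vertex position are used.
    """
    if corr.flags is None:
        raise ContractViolation("correspondence must be classified first")
    v_s = template.vertices
    matched = target.vertices[corr.target_index]
    if smooth_field:
        lu = template.laplacian_matrix(cfg.weights) @ np.asarray(u, float)
        v_prime = v_s - cfg.lam * lu
        n_t = target.vertex_normals[corr.target_index]
        offset = np.einsum("ij,ij->i", v_prime - matched, n_t)
        destination = v_prime - offset[:, None] * n_t  # tangent-plane projection
    else:
        v_prime = v_s
        destination = matched
    l_s = template.mean_edge_lengths()

    # internal division point: literal multiplier l_s / m on the difference
    # vector, clipped to 1 so the constraint never overshoots the destination
    frac = np.minimum(l_s / cfg.m, 1.0)[:, None]
    pull_pos = v_prime + frac * (destination - v_prime)

    idx_anchor = np.flatnonzero(corr.flags == FLAG_ANCHOR)
    idx_pull = np.flatnonzero(corr.flags == FLAG_PULL)
    indices = np.concatenate([idx_anchor, idx_pull])
    if indices.size == 0:
        raise ContractViolation("degenerate state: all vertices free")
    positions = np.vstack([v_prime[idx_anchor], pull_pos[idx_pull]])
    order = np.argsort(indices)
    return ConstraintSet(indices[order], positions[order])


def laplacian_solve(template: TriangleMesh, constraints: ConstraintSet,
                    delta: float, weights: str = "uniform") -> np.ndarray:
    """Minimize ``|L v' - L v|^2 + delta |S v' - p|^2`` via the sparse
    normal equations; returns the new (n, 3) vertex positions."""
    if len(constraints) == 0:
        raise ContractViolation("constraint set is empty: singular system")
    L = template.laplacian_matrix(weights)
    n = template.n_vertices
    mask = np.zeros(n)
    mask[constraints.indices] = 1.0
    A = (L.T @ L + delta * sp.diags(mask)).tocsc()
    rhs = L.T @ (L @ template.vertices)
    rhs[constraints.indices] += delta * constraints.positions
    solve = spla.factorized(A)
    return np.column_stack([solve(rhs[:, k]) for k in range(3)])


def registration_objective(template: TriangleMesh, new_positions: np.ndarray,
                           constraints: ConstraintSet, delta: float,
                           weights: str = "uniform") -> float:
    """The quadratic objective value at ``new_positions`` (for diagnostics)."""
    L = template.laplacian_matrix(weights)
    shape_term = np.sum((L @ new_positions - L @ template.vertices) ** 2)
    diff = new_positions[constraints.indices] - constraints.positions
    return float(shape_term + delta * np.sum(diff ** 2))


# ---------------------------------------------------------------------------
# full registration loops

def _progressive_register(template: TriangleMesh, target: TriangleMesh,
                          cfg: RegistrationConfig, *, smooth_field: bool,
                          method: str) -> RegistrationResult:
    if not (template.is_closed and target.is_closed):
        raise ContractViolation("registration requires closed meshes")
    # pre-align with the correspondence-preserving moment affine; the ICP
    # polish of affine_align only optimizes surface proximity, which the
    # progressive phase handles itself, at the cost of tangential drift
    try:
        affine = _moment_affine(template, target)
        aligned = template.with_vertices(apply_affine(affine, template.vertices))
    except DegenerateGeometryError:
        affine, aligned = affine_align(template, target)
    base = aligned.vertices.copy()
    current = aligned
    tree = cKDTree(target.vertices)
    trace: list[dict] = []
    best = np.inf
    stall = 0
    converged = True
    iterations = 0
    for it in range(cfg.max_iterations):
        u = current.vertices - base
        corr = correspondence_search(current, target, cfg.gamma)
        q_high, q_low = similarity_thresholds(
            corr.q, cfg.q_high_fraction, cfg.q_low_fraction)
        corr.flags = classify_vertices(corr, q_high, q_low)
        try:
            constraints = build_constraints(current, target, corr, u, cfg,
                                            smooth_field=smooth_field)
        except ContractViolation:
            converged = False
            break
        new_pos = laplacian_solve(current, constraints, cfg.delta, cfg.weights)
        current = current.with_vertices(new_pos)
        iterations = it + 1
        d, _ = tree.query(current.vertices)
        max_d, mean_d = float(d.max()), float(d.mean())
        trace.append({
            "iteration": iterations, "max_distance": max_d,
            "mean_distance": mean_d,
            "n_anchor": int(np.sum(corr.flags == FLAG_ANCHOR)),
            "n_pull": int(np.sum(corr.flags == FLAG_PULL)),
            "n_free": int(np.sum(corr.flags == FLAG_FREE))})
        if max_d < best - 1e-9:
            best = max_d
            stall = 0
        else:
            stall += 1
            if stall >= cfg.stall_window:
                break
    return RegistrationResult(current, current.vertices - base, affine,
                              trace, iterations, converged, method)


def register_lsmd(template: TriangleMesh, target: TriangleMesh,
                  cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Laplacian shape matching with differential-field smoothing (the full
    method)."""
    return _progressive_register(template, target, cfg or RegistrationConfig(),
                                 smooth_field=True, method="lsmd")


def register_lsm(template: TriangleMesh, target: TriangleMesh,
                 cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Plain progressive Laplacian shape matching (no displacement smoothing)."""
    return _progressive_register(template, target, cfg or RegistrationConfig(),
                                 smooth_field=False, method="lsm")


def register_affine(template: TriangleMesh, target: TriangleMesh,
                    cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Baseline: affine ICP only."""
    affine, aligned = affine_align(template, target)
    tree = cKDTree(target.vertices)
    d, _ = tree.query(aligned.vertices)
    trace = [{"iteration": 1, "max_distance": float(d.max()),
              "mean_distance": float(d.mean()),
              "n_anchor": 0, "n_pull": 0, "n_free": template.n_vertices}]
    return RegistrationResult(aligned, np.zeros_like(aligned.vertices),
                              affine, trace, 1, True, "affine")


def register_piecewise_affine(template: TriangleMesh, target: TriangleMesh,
                              n_pieces: int = 8,
                              cfg: RegistrationConfig | None = None
                              ) -> RegistrationResult:
    """Baseline: seeded k-means cells, one affine ICP each, inverse-distance
    blending across cell boundaries."""
    if n_pieces < 1:
        raise ContractViolation("n_pieces must be >= 1")
    cfg = cfg or RegistrationConfig()
    affine, aligned = affine_align(template, target)
    if n_pieces == 1:
        res = register_affine(template, target, cfg)
        return replace(res, method="pwa")

    labels, centroids = _kmeans_cells(aligned.vertices, n_pieces, cfg.rng_seed)
    tree = cKDTree(target.vertices)
    transforms = {}
    for c in np.unique(labels):
        pts = aligned.vertices[labels == c]
        transforms[c] = _cell_affine_icp(pts, target, tree)
    # blend with inverse-distance weights to cell centroids; the sharp
    # power keeps each vertex dominated by its own cell while staying
    # continuous across boundaries
    d4 = cdist(aligned.vertices, centroids[sorted(transforms)]) ** 4 + 1e-9
    w = 1.0 / d4
    w /= w.sum(axis=1, keepdims=True)
    blended = np.zeros_like(aligned.vertices)
    for k, c in enumerate(sorted(transforms)):
        blended += w[:, [k]] * apply_affine(transforms[c], aligned.vertices)
    result = aligned.with_vertices(blended)
    d, _ = tree.query(result.vertices)
    trace = [{"iteration": 1, "max_distance": float(d.max()),
              "mean_distance": float(d.mean()),
              "n_anchor": 0, "n_pull": 0, "n_free": template.n_vertices}]
    return RegistrationResult(result, blended - aligned.vertices, affine,
                              trace, 1, True, "pwa")


def _kmeans_cells(points: np.ndarray, k: int, seed: int):
    from scipy.cluster.vq import kmeans2
    centroids, labels = kmeans2(points, k, minit="++", seed=seed, iter=50)
    # merge cells too small for a stable affine fit into the nearest cell
    for c in range(k):
        if np.sum(labels == c) < 4:
            others = [o for o in range(k) if o != c and np.sum(labels == o) >= 4]
            if not others:
                raise DegenerateGeometryError("all k-means cells degenerate")
            dist = [np.linalg.norm(centroids[c] - centroids[o]) for o in others]
            labels[labels == c] = others[int(np.argmin(dist))]
    return labels, centroids


def _cell_affine_icp(points: np.ndarray, target: TriangleMesh,
                     tree: cKDTree, max_iterations: int = 50) -> np.ndarray:
    """Per-cell affine ICP paired against the closest target *surface*
    point: cells are small, so vertex-to-vertex pairing would be dominated
    by target sampling noise."""
    from .metrics import closest_points_on_surface
    pts = points.copy()
    total = np.hstack([np.eye(3), np.zeros((3, 1))])
    prev = np.inf
    for _ in range(max_iterations):
        matched, dist = closest_points_on_surface(pts, target)
        try:
            aff = _fit_affine(pts, matched)
        except DegenerateGeometryError:
            break
        pts = apply_affine(aff, pts)
        total = np.hstack([aff[:, :3] @ total[:, :3],
                           (aff[:, :3] @ total[:, 3] + aff[:, 3])[:, None]])
        err = float(dist.mean())
        if abs(prev - err) < 1e-10 * max(prev, 1.0):
            break
        prev = err
    return total


# ---------------------------------------------------------------------------
# template generation

def build_template(surfaces: list[TriangleMesh], seed_case: int = 0,
                   n_vertices: int = 400,
                   cfg: RegistrationConfig | None = None) -> TriangleMesh:
    """Average shape template: resample one case, register it to every
    surface, return the vertex-wise mean mesh (shared topology)."""
    if len(surfaces) < 2:
        raise ContractViolation("need at least two surfaces")
    cfg = cfg or RegistrationConfig()
    seed_mesh = resample_to(surfaces[seed_case], n_vertices)
    acc = np.zeros_like(seed_mesh.vertices)
    for k, surf in enumerate(surfaces):
        try:
            res = register_lsmd(seed_mesh, surf, cfg)
        except Exception as exc:  # noqa: BLE001 - annotate failing case
            raise RuntimeError(f"template registration failed on case {k}") from exc
        acc += res.mesh.vertices
    return seed_mesh.with_vertices(acc / len(surfaces))
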