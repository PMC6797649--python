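"""Inter-subject statistical deformation model.

Per-case displacement fields (deflated minus inflated registered models,
stacked as 3N vectors) are centred and decomposed by SVD; eigenvalues are
squared singular values over n-1 (sample covariance).  Modes are visualized
by adding ``w * sqrt(eigenvalue) * eigenvector`` to the mean field, and the
distance-from-hilum linearity of a field is summarized by an ordinary
least-squares line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import ContractViolation, TriangleMesh, VectorField


@dataclass
class DeformationSample:
    case_id: str
    values: np.ndarray  # flat (3N,) displacement, mm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size % 3:
            raise ContractViolation("sample length must be a multiple of 3")


@dataclass
class DeformationModel:
    mean: np.ndarray          # (3N,)
    eigenvalues: np.ndarray   # descending, mm^2
    eigenvectors: np.ndarray  # (n_modes, 3N), orthonormal rows
    n_samples: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, eigenvalues=self.eigenvalues,
                 eigenvectors=self.eigenvectors,
                 n_samples=np.array([self.n_samples]))

    @classmethod
    def load(cls, path) -> "DeformationModel":
        with np.load(path) as z:
            return cls(z["mean"], z["eigenvalues"], z["eigenvectors"],
                       int(z["n_samples"][0]))


def displacement_field(m_inflated: TriangleMesh, m_deflated: TriangleMesh,
                       case_id: str = "") -> DeformationSample:
    """Per-vertex deformation of a registered pair: deflated minus inflated."""
    if m_inflated.n_vertices != m_deflated.n_vertices or \
            not np.array_equal(m_inflated.faces, m_deflated.faces):
        raise ContractViolation("registered pair must share mesh topology")
    return DeformationSample(case_id,
                             (m_deflated.vertices - m_inflated.vertices).ravel())


def fit_deformation_model(samples: list[DeformationSample]) -> DeformationModel:
    """Mean and SVD eigenmodes of the centred displacement matrix."""
    if len(samples) < 2:
        raise ContractViolation("need at least two samples")
    X = np.stack([s.values for s in samples])  # (n, 3N)
    if len({s.values.size for s in samples}) != 1:
        raise ContractViolation("samples differ in length")
    mean = X.mean(axis=0)
    centred = X - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = svals ** 2 / (len(samples) - 1)
    # drop numerically-zero trailing modes (rank <= n-1 after centring)
    keep = eigenvalues > max(eigenvalues.max(), 1e-300) * 1e-12
    eigenvalues, vt = eigenvalues[keep], vt[keep]
    # deterministic sign: largest-magnitude component of each mode positive
    for row in vt:
        k = int(np.argmax(np.abs(row)))
        if row[k] < 0:
            row *= -1.0
    return DeformationModel(mean, eigenvalues, vt, len(samples))


def project_sample(model: DeformationModel, sample: DeformationSample) -> np.ndarray:
    """Mode coefficients of a sample (its centred projection on each mode)."""
    return model.eigenvectors @ (sample.values - model.mean)


def synthesize_mode(model: DeformationModel, mode: int,
                    weight: float) -> np.ndarray:
    """Field ``mean + weight * sqrt(eigenvalue_mode) * mode`` as (N, 3)."""
    if not 0 <= mode < model.n_modes:
        raise ContractViolation(f"mode {mode} out of range "
                                f"(model has {model.n_modes})")
    flat = model.mean + weight * np.sqrt(model.eigenvalues[mode]) \
        * model.eigenvectors[mode]
    return flat.reshape(-1, 3)


def variance_explained(model: DeformationModel, k: int) -> float:
    """Percent of total variance captured by the first k modes."""
    if k > model.n_modes:
        raise ContractViolation("k exceeds the number of stored modes")
    total = model.eigenvalues.sum()
    if total <= 0:
        raise ContractViolation("model has zero total variance")
    return float(100.0 * model.eigenvalues[:k].sum() / total)


def interpolate_states(m_inflated: TriangleMesh, field: np.ndarray | VectorField,
                       t: float) -> TriangleMesh:
    """Blend between the inflated mesh (t=0) and its deformed state (t=1)."""
    if isinstance(field, VectorField):
        field = field.values
    field = np.asarray(field, dtype=np.float64)
    if field.shape != m_inflated.vertices.shape:
        raise ContractViolation("field shape must match the mesh")
    if not 0.0 <= t <= 1.0:
        import warnings
        warnings.warn(f"t={t} outside [0, 1]: extrapolating", stacklevel=2)
    return m_inflated.with_vertices(m_inflated.vertices + t * field)


def hilum_linearity(m_inflated: TriangleMesh, field: np.ndarray | VectorField,
                    hilum) -> dict:
    """Distance-from-hilum vs displacement-magnitude scatter with an OLS fit.

    Returns distances, magnitudes, slope, intercept and R^2; a purely radial
    contraction about the hilum gives an exact line through the origin.
    """
    if isinstance(field, VectorField):
        field = field.values
    field = np.asarray(field, dtype=np.float64)
    hilum = np.asarray(hilum, dtype=np.float64)
    distances = np.linalg.norm(m_inflated.vertices - hilum, axis=1)
    magnitudes = np.linalg.norm(field, axis=1)
    A = np.column_stack([distances, np.ones_like(distances)])
    (slope, intercept), *_ = np.linalg.lstsq(A, magnitudes, rcond=None)
    pred = slope * distances + intercept
    ss_res = float(np.sum((magnitudes - pred) ** 2))
    ss_tot = float(np.sum((magnitudes - magnitudes.mean()) ** 2))
    tiny = 1e-12 * len(magnitudes) * max(float(magnitudes.mean()) ** 2, 1e-30)
    r2 = 0.0 if ss_tot <= tiny else 1.0 - ss_res / ss_tot
    return {"distance": distances, "magnitude": magnitudes,
            "slope": float(slope), "intercept": float(intercept), "r2": float(r2)}
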