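"""Cohort shape analysis: generalized Procrustes alignment and shape PCA.

Generalized Procrustes analysis (GPA) aligns landmark configurations by
translation, rotation and (optionally) scaling, iterating alignment to the
evolving mean shape until convergence.  With scaling disabled the aligned
configurations are Boas coordinates, which preserve size variation -- the
variant used for embryonic cohorts where absolute growth matters.
Rotations are proper (determinant +1): reflections are disallowed because
anatomical chirality (left vs right arches) is meaningful.

PCA of the Procrustes residuals summarizes cohort shape variation; the
mean shape can be warped along principal components for visualization, and
robust (median/MAD) distances in PC space flag outlier specimens such as
embryos with a missing arch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class MorphometricsError(ValueError):
    pass


@dataclass
class LandmarkCohort:
    """``specimens``: (n_s, n_lm, 3) homologous landmarks (mm)."""
    specimens: np.ndarray
    ids: list = field(default_factory=list)
    outlier: np.ndarray | None = None     # generator-declared ground truth
    labels: np.ndarray | None = None      # per-landmark anatomical label

    def __post_init__(self):
        self.specimens = np.asarray(self.specimens, float)
        if self.specimens.ndim != 3 or self.specimens.shape[2] != 3:
            raise MorphometricsError("specimens must be (n_s, n_lm, 3)")
        if len(self.specimens) < 2:
            raise MorphometricsError("need at least 2 specimens")
        if not np.isfinite(self.specimens).all():
            raise MorphometricsError("non-finite landmark coordinates")
        if not self.ids:
            self.ids = [f"specimen_{i:03d}" for i in range(len(self.specimens))]

    @property
    def n_specimens(self) -> int:
        return self.specimens.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.specimens.shape[1]


@dataclass
class GPAResult:
    aligned: np.ndarray           # (n_s, n_lm, 3)
    mean_shape: np.ndarray        # (n_lm, 3)
    residuals: np.ndarray         # (n_s, 3 n_lm), row-centered at mean
    centroid_sizes: np.ndarray    # original sizes, per specimen
    with_scaling: bool
    n_iterations: int
    ids: list = field(default_factory=list)

    @property
    def coordinates_name(self) -> str:
        return "Procrustes" if self.with_scaling else "Boas"


@dataclass
class ShapePCA:
    loadings: np.ndarray          # (k, 3 n_lm), orthonormal rows
    scores: np.ndarray            # (n_s, k)
    variance: np.ndarray          # (k,) eigenvalues
    variance_ratio: np.ndarray    # (k,)
    mean_shape: np.ndarray
    ids: list = field(default_factory=list)


def centroid_size(x: np.ndarray) -> float:
    """Square root of the summed squared distances to the centroid."""
    c = x - x.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def _proper_procrustes_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing |x R - target|_F; both centered."""
    U, _, Vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, 1.0, d])
    return U @ S @ Vt


def gpa(cohort: LandmarkCohort, with_scaling: bool = False,
        tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Iterative generalized Procrustes alignment.

    ``with_scaling=False`` (default) produces Boas coordinates (sizes
    preserved); ``True`` scales every specimen to unit centroid size.
    """
    X = cohort.specimens.astype(float).copy()
    n_s, n_lm, _ = X.shape
    sizes = np.empty(n_s)
    for i in range(n_s):
        c = X[i] - X[i].mean(axis=0)
        s = np.sqrt((c ** 2).sum())
        if s < 1e-12 or np.linalg.matrix_rank(c, tol=1e-10 * max(s, 1.0)) < 2:
            raise MorphometricsError(
                f"specimen {cohort.ids[i]!r} is degenerate "
                "(coincident or collinear landmarks)")
        sizes[i] = s
        X[i] = c / s if with_scaling else c

    mean = X[0].copy()
    mean -= mean.mean(axis=0)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(n_s):
            R = _proper_procrustes_rotation(X[i], mean)
            X[i] = X[i] @ R
        new_mean = X.mean(axis=0)
        if with_scaling:
            new_mean /= max(centroid_size(new_mean), 1e-300)
        shift = np.linalg.norm(new_mean - mean) / max(
            np.linalg.norm(new_mean), 1e-300)
        mean = new_mean
        if shift < tol:
            break
    resid = (X - mean[None]).reshape(n_s, 3 * n_lm)
    return GPAResult(aligned=X, mean_shape=mean, residuals=resid,
                     centroid_sizes=sizes, with_scaling=with_scaling,
                     n_iterations=n_iter, ids=list(cohort.ids))


def pca_shapes(result: GPAResult, k: int | None = None) -> ShapePCA:
    """PCA of the Procrustes/Boas residuals.

    Eigendecomposition of the residual covariance across specimens;
    loadings carry a deterministic sign (largest-magnitude entry positive).
    """
    resid = result.residuals
    n_s = len(resid)
    rank = min(n_s - 1, resid.shape[1])
    if k is None:
        k = rank
    if k > rank:
        warnings.warn(f"requested {k} components exceeds rank {rank}; "
                      "truncating")
        k = rank
    # SVD of residuals == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(resid, full_matrices=False)
    var = s ** 2 / (n_s - 1)
    total = (resid ** 2).sum() / (n_s - 1)
    loadings = Vt[:k]
    scores = resid @ loadings.T
    for j in range(k):
        i = np.argmax(np.abs(loadings[j]))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return ShapePCA(loadings=loadings, scores=scores, variance=var[:k],
                    variance_ratio=var[:k] / max(total, 1e-300),
                    mean_shape=result.mean_shape, ids=list(result.ids))


def warp_mean_by_pc(pca: ShapePCA, component: int, score: float) -> np.ndarray:
    """Mean shape displaced by ``score`` along one principal component."""
    if not (0 <= component < len(pca.loadings)):
        raise MorphometricsError(
            f"component {component} out of range [0, {len(pca.loadings)})")
    disp = score * pca.loadings[component]
    return pca.mean_shape + disp.reshape(-1, 3)


def landmark_variance(result: GPAResult):
    """Per-landmark 3x3 covariance across aligned specimens and the
    variance-ellipsoid radii (eigenvalues, i.e. per-axis variances in the
    covariance eigenframe) with their axes.

    Returns (cov (n_lm, 3, 3), radii (n_lm, 3) descending, axes (n_lm, 3, 3)
    with eigenvectors in columns).
    """
    X = result.aligned
    n_s = X.shape[0]
    if n_s < 3:
        raise MorphometricsError("need >= 3 specimens for landmark variance")
    d = X - X.mean(axis=0)[None]
    cov = np.einsum('slx,sly->lxy', d, d) / (n_s - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals, axis=1)[:, ::-1]
    radii = np.take_along_axis(evals, order, axis=1)
    axes = np.stack([evecs[l][:, order[l]] for l in range(len(cov))])
    return cov, radii, axes


def detect_outliers(pca: ShapePCA, k: int = 2,
                    threshold: float = 3.5) -> np.ndarray:
    """Robust outlier flags from the first ``k`` PC scores.

    Scores are standardized per component by median and MAD (scaled to be
    consistent with the normal SD); specimens whose Euclidean distance in
    standardized PC space exceeds ``threshold`` are flagged.  Zero MAD
    falls back to the standard deviation with a warning.
    """
    if pca.scores.shape[0] < 4:
        raise MorphometricsError("need >= 4 specimens for outlier detection")
    k = min(k, pca.scores.shape[1])
    z = np.empty((pca.scores.shape[0], k))
    for j in range(k):
        s = pca.scores[:, j]
        med = np.median(s)
        mad = np.median(np.abs(s - med)) * 1.4826
        if mad < 1e-300:
            sd = s.std()
            if sd < 1e-300:
                z[:, j] = 0.0
                continue
            warnings.warn(f"PC {j + 1}: zero MAD, falling back to SD")
            mad = sd
        z[:, j] = (s - med) / mad
    dist = np.linalg.norm(z, axis=1)
    return dist > threshold


def project_out_similarity(mode: np.ndarray, reference: np.ndarray,
                           with_scaling: bool = False) -> np.ndarray:
    """Project a displacement field onto the Procrustes tangent space.

    GPA alignment removes rigid motions (and optionally scale), so a
    planted variation mode can only be recovered up to its component
    orthogonal to translations, infinitesimal rotations about the
    reference shape (and uniform scaling, when scaling is removed).  Used
    when comparing generator modes against fitted PC loadings.
    """
    x = np.asarray(reference, float)
    x = x - x.mean(axis=0)
    n_lm = len(x)
    basis = []
    for d in range(3):
        t = np.zeros((n_lm, 3))
        t[:, d] = 1.0
        basis.append(t.reshape(-1))
    for d in range(3):
        e = np.zeros(3)
        e[d] = 1.0
        basis.append(np.cross(np.broadcast_to(e, x.shape), x).reshape(-1))
    if with_scaling:
        basis.append(x.reshape(-1))
    v = np.asarray(mode, float).reshape(-1).copy()
    Q, _ = np.linalg.qr(np.stack(basis, axis=1))
    v = v - Q @ (Q.T @ v)
    n = np.linalg.norm(v)
    if n < 1e-300:
        raise MorphometricsError("mode lies entirely in the similarity "
                                 "group; it cannot appear in shape space")
    return (v / n).reshape(n_lm, 3)


def principal_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the row spaces of A and B;
    used to verify recovery of planted variation modes."""
    Qa, _ = np.linalg.qr(np.asarray(A, float).T)
    Qb, _ = np.linalg.qr(np.asarray(B, float).T)
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.arccos(np.clip(s, -1, 1))
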