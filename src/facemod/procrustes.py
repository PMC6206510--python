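"""Generalized Procrustes superimposition, symmetrization and image-level QC.

Landmark configurations are ``(L, 3)`` arrays in mm (or stacks ``(n, L, 3)``).
Superimposition removes translation, scale (to unit centroid size) and
rotation (orthogonal Procrustes, reflections excluded); the consensus is the
coordinate-wise mean of the aligned configurations at convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignedSet",
    "GpaConvergenceError",
    "centroid_size",
    "gpa",
    "symmetrize",
    "qc_outliers",
    "rotate_to_reference",
]


class GpaConvergenceError(RuntimeError):
    """Raised when GPA fails to converge; carries the last consensus change."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"GPA did not converge in {max_iter} iterations "
            f"(last consensus change {residual:.3e})"
        )


@dataclass
class AlignedSet:
    """Result of a generalized Procrustes superimposition.

    aligned          (n, L, 3), centered at the origin, unit centroid size
    consensus        (L, 3) mean shape (unit centroid size)
    centroid_sizes   (n,) pre-scaling centroid sizes, in the input units (mm)
    n_iterations     iterations until the consensus stabilized
    objective        final sum of squared distances of aligned configs to consensus
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    objective: float
    qc_zscores: np.ndarray | None = field(default=None)

    @property
    def n_subjects(self) -> int:
        return self.aligned.shape[0]


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks to their centroid.

    The standard geometric-morphometrics size measure; used as the "facial
    size" covariate (measured before any rescaling).
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[1] != 3 or config.shape[0] < 3:
        raise ValueError("config must be an (L, 3) array with L >= 3")
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _centroid_sizes(stack: np.ndarray) -> np.ndarray:
    centered = stack - stack.mean(axis=1, keepdims=True)
    return np.sqrt(np.sum(centered**2, axis=(1, 2)))


def rotate_to_reference(stack: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate every (centered) configuration in ``stack`` onto ``reference``.

    Solves the orthogonal Procrustes problem per subject with the reflection
    excluded (determinant-corrected SVD). Batched over the leading axis.
    """
    stack = np.asarray(stack, dtype=float)
    reference = np.asarray(reference, dtype=float)
    m = np.einsum("nli,lj->nij", stack, reference)
    u, _, vt = np.linalg.svd(m)
    det = np.linalg.det(u @ vt)
    u = u.copy()
    u[:, :, -1] *= np.sign(det)[:, None]
    rot = u @ vt
    return np.einsum("nli,nij->nlj", stack, rot)


def gpa(
    configs: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 200,
    scale: bool = True,
) -> AlignedSet:
    """Generalized Procrustes superimposition of ``(n, L, 3)`` configurations.

    Iterates: center each configuration, scale to unit centroid size, rotate
    onto the current consensus, recompute the consensus (renormalized to unit
    centroid size) until the consensus moves by less than ``tol`` (RMS per
    coordinate).
    """
    x = np.asarray(configs, dtype=float)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("configs must be an (n, L, 3) array")
    n = x.shape[0]
    if n < 2:
        raise ValueError("GPA requires at least two configurations")
    x = x - x.mean(axis=1, keepdims=True)
    sizes = np.sqrt(np.sum(x**2, axis=(1, 2)))
    if np.any(sizes <= 0) or not np.all(np.isfinite(sizes)):
        bad = np.flatnonzero(~(sizes > 0))
        raise ValueError(f"degenerate configuration(s) at index {bad.tolist()}")
    if scale:
        x = x / sizes[:, None, None]

    consensus = x[0] / (np.sqrt(np.sum(x[0] ** 2)) if not scale else 1.0)
    last_residual = np.inf
    for iteration in range(1, max_iter + 1):
        x = rotate_to_reference(x, consensus)
        new_consensus = x.mean(axis=0)
        new_consensus = new_consensus - new_consensus.mean(axis=0)
        norm = np.sqrt(np.sum(new_consensus**2))
        if norm <= 0:
            raise ValueError("consensus collapsed to a point")
        new_consensus = new_consensus / norm
        last_residual = float(
            np.sqrt(np.mean((new_consensus - consensus) ** 2))
        )
        consensus = new_consensus
        if last_residual < tol:
            break
    else:
        raise GpaConvergenceError(last_residual, max_iter)

    # canonical orientation: principal axes of the consensus with a fixed
    # sign convention, so the result does not depend on the (arbitrary)
    # orientation of the inputs or the initialisation
    consensus, x = _canonicalize_orientation(consensus, x)

    objective = float(np.sum((x - consensus) ** 2))
    return AlignedSet(
        aligned=x,
        consensus=consensus,
        centroid_sizes=sizes,
        n_iterations=iteration,
        objective=objective,
    )


def _canonicalize_orientation(
    consensus: np.ndarray, stack: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the consensus (and the whole aligned set with it) onto its
    principal axes with deterministic signs: GPA is otherwise only defined up
    to a global rotation inherited from the inputs."""
    _, vecs = np.linalg.eigh(consensus.T @ consensus)
    rot = vecs[:, ::-1]  # principal axes, descending variance
    rotated = consensus @ rot
    for j in range(3):
        peak = np.abs(rotated[:, j]).argmax()
        if rotated[peak, j] < 0:
            rot[:, j] *= -1
            rotated[:, j] *= -1
    if np.linalg.det(rot) < 0:
        rot[:, 2] *= -1
        rotated[:, 2] *= -1
    return rotated, np.einsum("nli,ij->nlj", stack, rot)


def _check_involution(mirror_map: np.ndarray, n_landmarks: int) -> np.ndarray:
    mm = np.asarray(mirror_map, dtype=int)
    if mm.shape != (n_landmarks,):
        raise ValueError("mirror_map length must equal the landmark count")
    if not np.array_equal(mm[mm], np.arange(n_landmarks)):
        raise ValueError("mirror_map is not an involution")
    return mm


def symmetrize(config: np.ndarray, mirror_map: np.ndarray) -> np.ndarray:
    """Average a configuration with its reflected, relabeled mirror image.

    Reflection flips the sign of the x coordinate; ``mirror_map`` pairs each
    landmark with its bilateral partner (midline landmarks map to themselves).
    The output is exactly invariant under reflect-and-relabel, and midline
    landmarks land exactly on the x = 0 plane. Accepts a single ``(L, 3)``
    configuration or a stack ``(n, L, 3)``.
    """
    x = np.asarray(config, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    mm = _check_involution(mirror_map, x.shape[1])
    reflected = x.copy()
    reflected[..., 0] *= -1.0
    relabeled = reflected[:, mm, :]
    out = 0.5 * (x + relabeled)
    return out[0] if single else out


def qc_outliers(
    aligned: AlignedSet,
    z_threshold: float = 2.0,
    var_explained: float = 0.98,
) -> np.ndarray:
    """Flag outlier faces by Mahalanobis distance from the mean face.

    The full-space covariance of flattened shapes is singular (3L > n is
    typical), so the distance is computed in the principal-component subspace
    retaining ``var_explained`` of the variance. Distances are standardized
    across subjects; subjects with z above ``z_threshold`` are flagged for
    inspection (never auto-deleted). Z-scores are stored on the AlignedSet.
    """
    n = aligned.n_subjects
    flat = aligned.aligned.reshape(n, -1)
    centered = flat - flat.mean(axis=0)
    # PCs via SVD; eigenvalues of the covariance with n-1 denominator
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eig = svals**2 / (n - 1)
    keep = eig > eig[0] * 1e-12 if eig.size else np.array([], bool)
    eig, vt = eig[keep], vt[keep]
    frac = np.cumsum(eig) / eig.sum()
    k = int(np.searchsorted(frac, var_explained) + 1)
    k = min(k, n - 2, eig.size)
    if k < 1:
        raise ValueError("not enough subjects for a Mahalanobis metric")
    scores = centered @ vt[:k].T
    d = np.sqrt(np.sum(scores**2 / eig[:k], axis=1))
    sd = d.std(ddof=1)
    z = (d - d.mean()) / sd if sd > 0 else np.zeros(n)
    aligned.qc_zscores = z
    return z > z_threshold
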