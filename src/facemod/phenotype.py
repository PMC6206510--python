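"""Per-module multivariate shape phenotypes.

Each module's landmarks are re-superimposed with their own generalized
Procrustes fit, flattened, centered and decomposed by PCA; Horn-style
parallel analysis (permutation null) picks the number of components that
carry more variance than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .procrustes import gpa

__all__ = ["ModulePhenotype", "module_shape_space", "parallel_analysis"]


@dataclass
class ModulePhenotype:
    """PCA shape space of one facial module.

    scores       (n, K) full PC scores (unitless); truncate to ``k`` for testing
    loadings     (3m, K) orthonormal basis over flattened module coordinates
    eigenvalues  (K,) non-increasing variances
    mean         (3m,) mean of the flattened aligned module shapes
    consensus    (m, 3) module consensus shape
    aligned      (n, m, 3) module-level GPA output
    k            retained dimension (set by parallel analysis; None before)
    """

    module_id: int | None
    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray
    consensus: np.ndarray
    aligned: np.ndarray
    k: int | None = None

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def truncated_scores(self) -> np.ndarray:
        if self.k is None:
            raise ValueError("retained dimension k not set")
        return self.scores[:, : self.k]


def module_shape_space(
    shapes: np.ndarray,
    module_indices: np.ndarray | None = None,
    module_id: int | None = None,
) -> ModulePhenotype:
    """GPA + PCA shape space for a module's landmarks.

    ``shapes`` is (n, L, 3); ``module_indices`` selects the module's landmarks
    (all landmarks when None). The module subset is aligned with its own GPA,
    flattened to (n, 3m), column-centered and eigendecomposed. PC signs follow
    the convention that each column's largest-magnitude loading is positive.
    """
    shapes = np.asarray(shapes, dtype=float)
    n = shapes.shape[0]
    if n <= 3:
        raise ValueError("need more than 3 subjects")
    if module_indices is None:
        sub = shapes
    else:
        module_indices = np.asarray(module_indices, dtype=int)
        if module_indices.size < 3:
            raise ValueError(
                f"module {module_id}: {module_indices.size} landmarks; "
                "GPA needs at least 3"
            )
        sub = shapes[:, module_indices, :]
    aligned_set = gpa(sub)
    flat = aligned_set.aligned.reshape(n, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > max(eigval[0], 0) * 1e-12
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    # sign convention: largest |loading| positive
    peaks = np.abs(eigvec).argmax(axis=0)
    signs = np.sign(eigvec[peaks, np.arange(eigvec.shape[1])])
    signs[signs == 0] = 1.0
    eigvec = eigvec * signs
    scores = centered @ eigvec
    return ModulePhenotype(
        module_id=module_id,
        scores=scores,
        loadings=eigvec,
        eigenvalues=eigval,
        mean=mean,
        consensus=aligned_set.consensus,
        aligned=aligned_set.aligned,
    )


def _top_eigenvalues(x: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Leading ``r`` covariance eigenvalues of centered ``x`` by randomized
    subspace iteration (two power passes; adequate for percentile nulls)."""
    n, p = x.shape
    q = min(r + 8, p)
    y = x.T @ (x @ rng.normal(size=(p, q)))
    for _ in range(2):
        y, _ = np.linalg.qr(y)
        y = x.T @ (x @ y)
    y, _ = np.linalg.qr(y)
    b = x @ y
    eig = np.linalg.eigvalsh(b.T @ b)[::-1]
    return eig[:r] / (n - 1)


def _null_eigenvalues(x: np.ndarray, rng: np.random.Generator, max_rank: int) -> np.ndarray:
    """Top eigenvalues of a column-permuted copy of ``x`` (independent
    permutations per column destroy all between-column covariance)."""
    n, p = x.shape
    xp = rng.permuted(x, axis=0)
    xp = xp - xp.mean(axis=0)
    if max_rank < p // 2 and p > 64:
        return _top_eigenvalues(xp, max_rank, rng)
    eig = np.linalg.eigvalsh(xp.T @ xp / (n - 1))[::-1]
    return eig[:max_rank]


def parallel_analysis(
    data: np.ndarray,
    n_iter: int = 200,
    percentile: float = 95.0,
    seed: int | np.random.Generator | None = None,
    max_rank: int | None = None,
    subsample: int | None = None,
) -> int:
    """Retained dimension by parallel analysis on a centered data matrix.

    Observed eigenvalues are compared rank-by-rank with the given percentile
    of eigenvalues from column-permuted null matrices; k counts the leading
    run of observed values exceeding the null and is forced >= 1.

    ``subsample`` caps the number of rows used (the same subsample feeds both
    the observed and the null spectra, so the comparison stays matched);
    ``max_rank`` truncates the spectra (large modules never retain more).
    """
    if n_iter < 50:
        raise ValueError("n_iter must be >= 50")
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if subsample is not None and n > subsample:
        rows = rng.choice(n, size=subsample, replace=False)
        x = x[rows]
        n = subsample
    x = x - x.mean(axis=0)
    r = min(max_rank or p, p, n - 1)
    obs = np.linalg.eigvalsh(x.T @ x / (n - 1))[::-1][:r]
    null = np.empty((n_iter, r))
    for i in range(n_iter):
        null[i] = _null_eigenvalues(x, rng, r)
    thresh = np.percentile(null, percentile, axis=0)
    exceeds = obs > thresh
    k = int(np.argmin(exceeds)) if not exceeds.all() else r
    return max(k, 1)
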