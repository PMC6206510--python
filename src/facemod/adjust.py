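"""Covariate adjustment of shape and genotype via partial least squares.

Both the shape coordinates and the SNP dosages are residualized, per cohort,
on age, age^2, sex, weight, height, facial (centroid) size and the first four
ancestry axes. With the default component count equal to the rank of the
covariate block, the PLS fit spans the covariate column space and the
residuals coincide with ordinary-least-squares residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = ["CovariateBlock", "plsr_residualize"]

COVARIATE_COLUMNS = (
    "age",
    "age2",
    "sex",
    "weight",
    "height",
    "size",
    "anc1",
    "anc2",
    "anc3",
    "anc4",
)


@dataclass
class CovariateBlock:
    """n x 10 covariate design: age, age^2, sex, weight, height, facial size,
    four ancestry axes. ``age2`` is computed internally from age."""

    design: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COVARIATE_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        self.design = self.design[list(COVARIATE_COLUMNS)].astype(float)
        values = self.design.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite covariate values")
        sd = values.std(axis=0)
        # sex may legitimately be constant in single-sex subgroup reruns
        zero_ok = np.array([c == "sex" for c in COVARIATE_COLUMNS])
        if np.any((sd == 0) & (values[0] == 0) & ~zero_ok):
            raise ValueError("constant-zero covariate column")
        self._values = values
        mu, sdev = values.mean(axis=0), sd.copy()
        sdev[sdev == 0] = 1.0
        self._standardized = (values - mu) / sdev

    @classmethod
    def from_covariates(
        cls, covariates: pd.DataFrame, centroid_sizes: np.ndarray
    ) -> "CovariateBlock":
        """Assemble the block from a cohort covariate table plus facial size."""
        df = covariates.copy()
        df["age2"] = df["age"].astype(float) ** 2
        df["size"] = np.asarray(centroid_sizes, dtype=float)
        return cls(df)

    @property
    def n(self) -> int:
        return len(self.design)

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def standardized(self) -> np.ndarray:
        return self._standardized

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self._standardized))

    def subset(self, mask: np.ndarray) -> "CovariateBlock":
        return CovariateBlock(self.design.loc[np.asarray(mask)].reset_index(drop=True))


def plsr_residualize(
    y: np.ndarray,
    covariates: CovariateBlock | np.ndarray | pd.DataFrame,
    n_components: int | None = None,
) -> np.ndarray:
    """Residuals of ``y`` after a PLS regression on the covariate block.

    ``y`` is (n,) or (n, p); the intercept is handled by centering. With
    ``n_components`` at the covariate rank (the default), this removes the
    full covariate column space and equals OLS residualization. Constant
    columns of ``y`` are passed through unchanged.
    """
    if isinstance(covariates, CovariateBlock):
        x = covariates.standardized
    else:
        x = np.asarray(
            covariates.to_numpy() if isinstance(covariates, pd.DataFrame) else covariates,
            dtype=float,
        )
        x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1, x.std(axis=0))
    y = np.asarray(y, dtype=float)
    flat_input = y.ndim == 1
    if flat_input:
        y = y[:, None]
    n, p = y.shape
    if x.shape[0] != n:
        raise ValueError("y and covariates disagree on n")
    rank = int(np.linalg.matrix_rank(x))
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    if n <= x.shape[1]:
        raise ValueError("need more subjects than covariates")

    col_sd = y.std(axis=0)
    active = col_sd > 0
    resid = y.copy()
    if active.any():
        pls = PLSRegression(n_components=n_components, scale=False, tol=1e-12,
                            max_iter=2000)
        ya = y[:, active]
        pls.fit(x, ya)
        resid[:, active] = ya - pls.predict(x)
    return resid[:, 0] if flat_input else resid
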