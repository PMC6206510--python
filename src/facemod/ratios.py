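"""Facial ratios from named landmarks and per-SNP linear association.

Five width-to-height-style ratios (each a quotient of two inter-landmark
Euclidean distances) are computed per subject, adjusted for sex, age and body
size, and tested against each SNP with an ordinary linear model that includes
the four ancestry axes. The Bonferroni cutoff divides alpha by the number of
SNPs tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatioDefinition",
    "DEFAULT_RATIOS",
    "compute_ratios",
    "compute_ratio_table",
    "ratio_association",
    "RatioAssociation",
]


@dataclass(frozen=True)
class RatioDefinition:
    name: str
    numerator: tuple[str, str]     # landmark-name pair, Euclidean distance
    denominator: tuple[str, str]


# Literature-standard defaults; endpoint choices are configuration, not
# constants, and can be overridden per study.
DEFAULT_RATIOS = (
    RatioDefinition("fwhr_total", ("zygion_l", "zygion_r"), ("nasion", "gnathion")),
    RatioDefinition("fwhr_upper", ("zygion_l", "zygion_r"), ("nasion", "prosthion")),
    RatioDefinition(
        "lower_face_height", ("stomion", "gnathion"), ("nasion", "gnathion")
    ),
    RatioDefinition(
        "width_lower_height", ("zygion_l", "zygion_r"), ("stomion", "gnathion")
    ),
    RatioDefinition(
        "cheekbone_prominence", ("zygion_l", "zygion_r"), ("gonion_l", "gonion_r")
    ),
)


def _distance(config: np.ndarray, names: dict[str, int],
              pair: tuple[str, str]) -> np.ndarray:
    a, b = pair
    for name in pair:
        if name not in names:
            raise ValueError(f"landmark name {name!r} not in the named-landmark map")
    diff = config[..., names[a], :] - config[..., names[b], :]
    return np.linalg.norm(diff, axis=-1)


def compute_ratios(
    config: np.ndarray,
    definitions=DEFAULT_RATIOS,
    names: dict[str, int] | None = None,
) -> np.ndarray:
    """Ratio vector for one configuration (or a stack): numerator distance /
    denominator distance, unitless and invariant to similarity transforms."""
    if names is None:
        raise ValueError("a named-landmark map is required")
    config = np.asarray(config, dtype=float)
    out = []
    for d in definitions:
        num = _distance(config, names, d.numerator)
        den = _distance(config, names, d.denominator)
        if np.any(den <= 1e-12):
            raise ValueError(f"ratio {d.name!r}: zero denominator distance")
        out.append(num / den)
    return np.stack(out, axis=-1)


def compute_ratio_table(
    configurations: np.ndarray,
    definitions=DEFAULT_RATIOS,
    names: dict[str, int] | None = None,
    subject_ids=None,
) -> pd.DataFrame:
    values = compute_ratios(configurations, definitions, names)
    df = pd.DataFrame(values, columns=[d.name for d in definitions])
    if subject_ids is not None:
        df.insert(0, "subject_id", list(subject_ids))
    return df


@dataclass
class RatioAssociation:
    slope: float
    se: float
    t_stat: float
    p_value: float      # two-sided
    n: int


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS with intercept; returns (beta, resid, dof). Rejects collinearity."""
    design = np.column_stack([np.ones(len(x)), x])
    cond = np.linalg.cond(design)
    if cond > 1e10:
        raise ValueError(f"collinear covariates (condition number {cond:.3g})")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, resid, len(y) - design.shape[1]


def ratio_association(
    ratios: np.ndarray,
    dosage: np.ndarray,
    covariates: pd.DataFrame,
    body_size_column: str = "height",
) -> RatioAssociation:
    """Two-stage ratio association.

    Stage 1 residualizes the ratio on sex, age and body size (height by
    default); stage 2 regresses the residual on dosage plus the four ancestry
    axes and reports the additive dosage slope with its two-sided p-value.
    """
    y = np.asarray(ratios, dtype=float)
    g = np.asarray(dosage, dtype=float)
    n = y.size
    if n <= 9:
        raise ValueError("need n > 9")
    if g.shape != y.shape:
        raise ValueError("ratio and dosage lengths differ")
    stage1 = covariates[["sex", "age", body_size_column]].to_numpy(dtype=float)
    stage1 = stage1[:, stage1.std(axis=0) > 0]  # sex is constant in single-sex subsets
    _, resid, _ = _ols(y, stage1)
    anc = covariates[["anc1", "anc2", "anc3", "anc4"]].to_numpy(dtype=float)
    design = np.column_stack([g, anc])
    beta, r2resid, dof = _ols(resid, design)
    sigma2 = float(np.sum(r2resid**2) / dof)
    xtx_inv = np.linalg.inv(
        np.column_stack([np.ones(n), design]).T @ np.column_stack([np.ones(n), design])
    )
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se)
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return RatioAssociation(slope=float(beta[1]), se=se, t_stat=t, p_value=p, n=n)


def ratio_association_table(
    ratio_table: pd.DataFrame,
    genotypes: np.ndarray,
    snp_ids: list[str],
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    subgroup: str = "all",
    body_size_column: str = "height",
) -> pd.DataFrame:
    """Every (SNP, ratio) association in one subgroup; Bonferroni flag at
    alpha / n_snps. Subgroups: all, male, female, postpubertal (age > 14)."""
    mask = {
        "all": np.ones(len(covariates), dtype=bool),
        "male": covariates["sex"].to_numpy() == 1,
        "female": covariates["sex"].to_numpy() == 0,
        "postpubertal": covariates["age"].to_numpy() > 14,
    }[subgroup]
    cov = covariates.loc[mask].reset_index(drop=True)
    cutoff = alpha / len(snp_ids)
    rows = []
    ratio_cols = [c for c in ratio_table.columns if c != "subject_id"]
    for j, snp in enumerate(snp_ids):
        for col in ratio_cols:
            res = ratio_association(
                ratio_table.loc[mask, col].to_numpy(),
                genotypes[mask, j],
                cov,
                body_size_column=body_size_column,
            )
            rows.append(
                {
                    "snp_id": snp, "ratio": col, "subgroup": subgroup,
                    "n": res.n, "slope": res.slope, "se": res.se,
                    "p_value": res.p_value,
                    "significant": res.p_value < cutoff,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["cutoff"] = cutoff
    return out
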