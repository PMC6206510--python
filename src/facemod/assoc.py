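"""Single-SNP multivariate association and round-robin meta-analysis.

A SNP is tested against a module's PC scores by canonical correlation; with
a single genetic variable the canonical correlation is the multiple
correlation of dosage on scores, and Rao's F approximation to Wilks'
Lambda = 1 - CC^2 reduces to the exact overall-regression F with
(k, n - k - 1 - c) degrees of freedom (c residualized covariates).

Replication projects a new cohort's module scores (expressed in the
discovery PC basis) onto the discovery canonical loadings, producing a
genetic effect score that is tested against dosage with an upper-tailed
slope t-test. The three p-values (one discovery, two replications) per
round-robin rotation are combined with Stouffer's method; study-wide
significance divides alpha by the Li-Ji effective numbers of modules and
SNPs and by the number of rotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "CcaResult",
    "MetaResult",
    "LiJiResult",
    "cca_single_snp",
    "project_effect_score",
    "replication_test",
    "stouffer_combine",
    "li_ji_meff",
    "study_threshold",
    "round_robin_meta",
    "meta_analyze_module",
    "P_CLAMP",
]

P_CLAMP = 1e-300


@dataclass
class CcaResult:
    cc: float                 # canonical correlation, in [0, 1]
    loadings: np.ndarray      # unit-norm canonical direction over module PCs
    p_value: float            # right tail of Rao's F
    f_stat: float
    n: int
    k: int
    n_covariates: int

    @property
    def dof(self) -> tuple[int, int]:
        return self.k, self.n - self.k - 1 - self.n_covariates


@dataclass
class MetaResult:
    snp_id: str
    module_id: int
    rotation: str             # discovery cohort label
    cc: float
    p_discovery: float
    p_replication: tuple[float, float]
    p_meta: float
    z_meta: float = float("nan")  # Stouffer Z; resolves ties when p underflows
    significant: bool | None = None


@dataclass
class LiJiResult:
    meff: int                 # rounded effective number of tests
    raw: float                # un-rounded sum


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def _f_logsf(r2: np.ndarray, k: int, df2: int) -> np.ndarray:
    """log right tail of the overall-regression F, via R^2 ~ Beta(k/2, df2/2).

    Falls back to the leading-order incomplete-beta asymptote where scipy's
    tail underflows to -inf (astronomically significant results must still
    rank correctly)."""
    a, b = 0.5 * k, 0.5 * df2
    logp = stats.beta.logsf(r2, a, b)
    bad = ~np.isfinite(logp)
    if np.any(bad):
        x = np.clip(r2[bad], 1e-300, 1 - 1e-15)
        logp[bad] = (
            (a - 1.0) * np.log(x)
            + b * np.log1p(-x)
            - np.log(b)
            - special.betaln(a, b)
        )
    return logp


def _t_logsf(t: np.ndarray, dof: int) -> np.ndarray:
    """log upper tail of Student's t with an asymptotic fallback."""
    logp = stats.t.logsf(t, dof)
    bad = ~np.isfinite(logp)
    if np.any(bad):
        a = 0.5 * dof
        x = dof / (dof + t[bad] ** 2)
        logp[bad] = (
            np.log(0.5) + a * np.log(x) - np.log(a) - special.betaln(a, 0.5)
        )
    return logp


def _cca_batch(
    scores: np.ndarray, dosages: np.ndarray, n_covariates: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CCA of each dosage column against one score matrix.

    Returns (cc, p, logp, f, loadings[k x S]); the log-space tail survives
    p-value underflow. Shared implementation behind ``cca_single_snp`` and
    the pipeline's per-module sweep.
    """
    n, k = scores.shape
    df2 = n - k - 1 - n_covariates
    if df2 <= 0:
        raise ValueError(f"n={n} too small for k={k} scores + {n_covariates} covariates")
    sc = _center(scores)
    dc = _center(np.atleast_2d(dosages.T).T)
    ss_tot = np.sum(dc**2, axis=0)
    if np.any(ss_tot <= 0):
        raise ValueError("constant dosage")
    beta, _, rank, _ = np.linalg.lstsq(sc, dc, rcond=None)
    if rank < k:
        raise ValueError(f"singular score matrix (rank {rank} < k={k})")
    fitted = sc @ beta
    r2 = np.sum(fitted**2, axis=0) / ss_tot
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    f = (r2 / k) / ((1.0 - r2) / df2)
    logp = _f_logsf(r2, k, df2)
    p = np.exp(logp)
    norms = np.linalg.norm(beta, axis=0)
    norms[norms == 0] = 1.0
    loadings = beta / norms
    return np.sqrt(r2), p, logp, f, loadings


def cca_single_snp(
    dosage_residual: np.ndarray, scores: np.ndarray, n_covariates: int = 0
) -> CcaResult:
    """CCA of one (residualized) dosage vector against module PC scores.

    The canonical direction is the regression direction of dosage on the
    scores (normalized), oriented so the canonical variate correlates
    positively with dosage; the p-value is the right tail of Rao's F
    approximation to Wilks' Lambda, which for a single genetic variable is
    the exact overall-regression F.
    """
    dosage_residual = np.asarray(dosage_residual, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or dosage_residual.shape != (scores.shape[0],):
        raise ValueError("dosage must be (n,), scores (n, k)")
    n, k = scores.shape
    if n <= k + 2:
        raise ValueError("need n > k + 2")
    cc, p, _, f, loadings = _cca_batch(scores, dosage_residual[:, None], n_covariates)
    return CcaResult(
        cc=float(cc[0]),
        loadings=loadings[:, 0],
        p_value=float(p[0]),
        f_stat=float(f[0]),
        n=n,
        k=k,
        n_covariates=n_covariates,
    )


def project_effect_score(scores: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Genetic effect score: inner product of each subject's PC vector with
    the discovery canonical loadings. ``scores`` must already be expressed in
    the discovery module's PC basis."""
    scores = np.asarray(scores, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if scores.ndim != 2 or loadings.shape != (scores.shape[1],):
        raise ValueError(
            f"dimension mismatch: scores {scores.shape}, loadings {loadings.shape}"
        )
    return scores @ loadings


def replication_test(
    effect_score: np.ndarray, dosage_residual: np.ndarray, n_covariates: int = 0
) -> float:
    """Upper-tailed p of the slope t-statistic of effect score on dosage.

    One-sided because the discovery canonical direction fixes the positive
    sense of the effect; a concordant replication has a positive slope.
    """
    e = np.asarray(effect_score, dtype=float)
    g = np.asarray(dosage_residual, dtype=float)
    if e.shape != g.shape or e.ndim != 1:
        raise ValueError("effect score and dosage must be equal-length vectors")
    n = e.size
    if n < 4:
        raise ValueError("need n >= 4")
    p, _, _ = _replication_batch(e[:, None], g[:, None], n_covariates)
    return float(p[0])


def _replication_batch(
    effects: np.ndarray, dosages: np.ndarray, n_covariates: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise one-sided slope tests; returns (p, logp, t)."""
    n = effects.shape[0]
    dof = n - 2 - n_covariates
    if dof <= 0:
        raise ValueError("not enough subjects for the replication test")
    ec = _center(effects)
    gc = _center(dosages)
    sxx = np.sum(gc**2, axis=0)
    syy = np.sum(ec**2, axis=0)
    if np.any(sxx <= 0) or np.any(syy <= 0):
        raise ValueError("zero-variance effect score or dosage")
    slope = np.sum(gc * ec, axis=0) / sxx
    resid = ec - gc * slope
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 / sxx)
    t = slope / se
    logp = _t_logsf(t, dof)
    return np.exp(logp), logp, t


def stouffer_combine(
    p_values, weights=None
) -> float:
    """Stouffer's combined p: z_i = Phi^-1(1 - p_i), Z = sum(w z)/sqrt(sum w^2)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p-values must lie strictly in (0, 1); clamp first")
    z = stats.norm.isf(p)
    if weights is None:
        weights = np.ones_like(p)
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape or np.any(w <= 0):
        raise ValueError("weights must be positive and match p_values")
    zc = np.sum(w * z) / np.sqrt(np.sum(w**2))
    return float(stats.norm.sf(zc))


def li_ji_meff(correlation: np.ndarray) -> LiJiResult:
    """Effective number of independent tests (Li & Ji) from a correlation
    matrix: Meff = sum over eigenvalues of 1(|lam| >= 1) + (|lam| - floor|lam|)."""
    c = np.asarray(correlation, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.abs(np.linalg.eigvalsh(0.5 * (c + c.T)))
    # guard the integer split against floating error (e.g. an exact eigenvalue
    # t materialising as t - 1e-14, whose fractional part would add a spurious 1)
    lam = np.round(lam, 10)
    raw = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return LiJiResult(meff=int(round(raw)), raw=raw)


def study_threshold(
    meff_modules: float, meff_snps: float, n_meta: int, alpha: float = 0.05
) -> float:
    """Bonferroni cutoff alpha / (Meff_modules * Meff_snps * n_meta)."""
    if meff_modules <= 0 or meff_snps <= 0 or n_meta <= 0 or alpha <= 0:
        raise ValueError("all arguments must be positive")
    return alpha / (meff_modules * meff_snps * n_meta)


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, P_CLAMP, 1.0 - 1e-16)


def meta_analyze_module(
    scores_by_cohort: list[np.ndarray],
    proj_scores: dict[tuple[int, int], np.ndarray],
    dosage_residuals: list[np.ndarray],
    snp_ids: list[str],
    module_id: int,
    cohort_labels: list[str] | None = None,
    n_covariates: int = 0,
    weights_mode: str = "unweighted",
) -> list[MetaResult]:
    """Round-robin meta-analysis of every SNP against one module.

    ``scores_by_cohort[c]`` are cohort c's truncated PC scores in its own
    discovery basis; ``proj_scores[(d, r)]`` are replication cohort r's scores
    expressed in discovery cohort d's basis; ``dosage_residuals[c]`` is the
    (n_c, S) residualized dosage matrix. Vectorized over SNPs; the per-SNP
    ``round_robin_meta`` wraps this with a single dosage column.
    """
    n_cohorts = len(scores_by_cohort)
    labels = cohort_labels or [f"cohort{i + 1}" for i in range(n_cohorts)]
    dosages = [np.atleast_2d(d.T).T for d in dosage_residuals]
    results: list[MetaResult] = []
    for d in range(n_cohorts):
        cc, p_disc, logp_disc, _, loadings = _cca_batch(
            scores_by_cohort[d], dosages[d], n_covariates
        )
        reps = [r for r in range(n_cohorts) if r != d]
        p_reps, logp_reps = [], []
        for r in reps:
            eff = proj_scores[(d, r)] @ loadings  # (n_r, S) effect scores
            p_r, logp_r, _ = _replication_batch(eff, dosages[r], n_covariates)
            p_reps.append(p_r)
            logp_reps.append(logp_r)
        p_all = _clamp(np.vstack([p_disc] + p_reps))  # (3, S), for reporting
        logp_all = np.minimum(np.vstack([logp_disc] + logp_reps), -1e-16)
        if weights_mode == "sqrt_n":
            ns = [scores_by_cohort[d].shape[0]] + [
                proj_scores[(d, r)].shape[0] for r in reps
            ]
            w = np.sqrt(np.asarray(ns, dtype=float))
        elif weights_mode == "unweighted":
            w = np.ones(p_all.shape[0])
        else:
            raise ValueError(f"unknown weights_mode {weights_mode!r}")
        # z from log-space tails: immune to p-value underflow
        z = -special.ndtri_exp(logp_all)
        zc = (w[:, None] * z).sum(axis=0) / np.sqrt(np.sum(w**2))
        p_meta = np.maximum(stats.norm.sf(zc), 0.0)
        for s, snp in enumerate(snp_ids):
            results.append(
                MetaResult(
                    snp_id=snp,
                    module_id=module_id,
                    rotation=labels[d],
                    cc=float(cc[s]),
                    p_discovery=float(p_all[0, s]),
                    p_replication=(float(p_all[1, s]), float(p_all[2, s])),
                    p_meta=float(max(p_meta[s], P_CLAMP)),
                    z_meta=float(zc[s]),
                )
            )
    return results


def round_robin_meta(
    scores_by_cohort: list[np.ndarray],
    proj_scores: dict[tuple[int, int], np.ndarray],
    dosage_residuals: list[np.ndarray],
    snp_id: str = "snp",
    module_id: int = 1,
    cohort_labels: list[str] | None = None,
    n_covariates: int = 0,
    weights_mode: str = "unweighted",
) -> list[MetaResult]:
    """Three meta-analyses for one SNP and one module, each cohort once the
    discovery set. ``dosage_residuals`` holds one residualized dosage vector
    per cohort."""
    return meta_analyze_module(
        scores_by_cohort,
        proj_scores,
        [np.asarray(d, dtype=float).reshape(-1, 1) for d in dosage_residuals],
        [snp_id],
        module_id,
        cohort_labels=cohort_labels,
        n_covariates=n_covariates,
        weights_mode=weights_mode,
    )
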