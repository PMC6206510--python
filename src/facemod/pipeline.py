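"""End-to-end orchestration: simulate/load -> QC -> adjust -> segment ->
phenotype -> associate -> correct -> report.

The stages are plain functions over in-memory objects so tests and scripts
can drive any slice of the pipeline; :func:`run_pipeline` wires them to disk
(TSV tables plus a JSON manifest) from a single validated config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, synthdata
from .adjust import CovariateBlock, plsr_residualize
from .phenotype import module_shape_space, parallel_analysis
from .procrustes import AlignedSet, gpa, qc_outliers, rotate_to_reference, symmetrize
from .segment import ModuleTree, hierarchical_segment, knn_adjacency
from .shapeio import CohortDataset, maf_filter

logger = logging.getLogger("facemod")

__all__ = [
    "PipelineConfig",
    "PreparedCohort",
    "ModuleAssocData",
    "prepare_cohorts",
    "segment_cohorts",
    "phenotype_module",
    "associate_all",
    "effect_displacement_field",
    "module_energy_fraction",
    "run_pipeline",
    "report",
]

_SIMULATION_KEYS = {
    "n_subjects", "n_landmarks", "noise_sd", "kernel_scale", "seed",
    "size_factor", "dosage_mode", "tree_depth", "snps",
}


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    simulation: dict = field(default_factory=dict)  # forwarded to SimulationSpec
    qc_z_threshold: float = 2.0
    qc_strict: bool = False            # drop flagged subjects instead of reporting
    plsr_components: int | None = None # None = rank of the covariate block
    depth: int = 5
    contiguity: bool = False           # adjacency-masked similarity
    min_module_size: int = 3
    pa_iterations: int = 200
    pa_percentile: float = 95.0
    pa_subsample: int | None = None
    pa_max_rank: int | None = None
    maf_threshold: float = 0.05
    weights_mode: str = "unweighted"
    alpha: float = 0.05
    subgroup: str = "all"              # all | male | female | postpubertal
    postpubertal_age: float = 15.0
    force: bool = False

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.subgroup not in ("all", "male", "female", "postpubertal"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if self.weights_mode not in ("unweighted", "sqrt_n"):
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        unknown = set(self.simulation) - _SIMULATION_KEYS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        n_landmarks = self.simulation.get("n_landmarks", 128)
        if n_landmarks < 2**self.depth:
            raise ValueError(
                f"depth {self.depth} needs at least {2**self.depth} landmarks, "
                f"got {n_landmarks}; lower the depth"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def simulation_spec(self) -> synthdata.SimulationSpec:
        sim = dict(self.simulation)
        snps = [
            synthdata.SnpSpec(**entry) if isinstance(entry, dict) else entry
            for entry in sim.pop("snps", [])
        ]
        sim.setdefault("seed", self.seed)
        return synthdata.SimulationSpec(snp_specs=snps, **sim)


@dataclass
class PreparedCohort:
    """A cohort after symmetrization, superimposition, QC and adjustment."""

    cohort_id: str
    aligned: AlignedSet
    adjusted_configs: np.ndarray       # (n, L, 3): consensus + PLSR residual
    covariate_block: CovariateBlock
    dosage_residuals: np.ndarray       # (n, S)
    qc_flags: np.ndarray
    n_covariates: int


def _subgroup_mask(dataset: CohortDataset, subgroup: str, age_cut: float) -> np.ndarray:
    cov = dataset.covariates
    if subgroup == "all":
        return np.ones(dataset.n, dtype=bool)
    if subgroup == "male":
        return cov["sex"].to_numpy() == 1
    if subgroup == "female":
        return cov["sex"].to_numpy() == 0
    return cov["age"].to_numpy() > age_cut


def prepare_cohort(
    dataset: CohortDataset,
    mirror_map: np.ndarray,
    cfg: PipelineConfig,
) -> PreparedCohort:
    """Symmetrize, superimpose, QC-flag and covariate-adjust one cohort.

    Adjusted configurations are rebuilt as consensus + PLSR residual so the
    per-module Procrustes fits downstream operate on valid shapes.
    """
    sym = symmetrize(dataset.configurations, mirror_map)
    aligned = gpa(sym)
    flags = qc_outliers(aligned, z_threshold=cfg.qc_z_threshold)
    block = CovariateBlock.from_covariates(dataset.covariates, aligned.centroid_sizes)
    n = dataset.n
    flat = aligned.aligned.reshape(n, -1)
    resid = plsr_residualize(flat, block, n_components=cfg.plsr_components)
    adjusted = (resid + aligned.consensus.ravel()).reshape(n, -1, 3)
    dosage_res = plsr_residualize(
        dataset.genotypes, block, n_components=cfg.plsr_components
    )
    return PreparedCohort(
        cohort_id=dataset.cohort_id,
        aligned=aligned,
        adjusted_configs=adjusted,
        covariate_block=block,
        dosage_residuals=dosage_res,
        qc_flags=flags,
        n_covariates=block.values.shape[1],
    )


def prepare_cohorts(
    cohorts: list[CohortDataset],
    mirror_map: np.ndarray,
    cfg: PipelineConfig,
) -> tuple[list[PreparedCohort], pd.DataFrame]:
    """MAF-filter, subgroup-filter and prepare every cohort."""
    cohorts, maf_report = maf_filter(cohorts, cfg.maf_threshold)
    if cfg.subgroup != "all":
        cohorts = [
            c.subset_subjects(_subgroup_mask(c, cfg.subgroup, cfg.postpubertal_age))
            for c in cohorts
        ]
    prepared = []
    for c in cohorts:
        pc = prepare_cohort(c, mirror_map, cfg)
        if cfg.qc_strict and pc.qc_flags.any():
            keep = ~pc.qc_flags
            logger.info(
                "%s: dropping %d QC-flagged subjects", c.cohort_id, int(pc.qc_flags.sum())
            )
            pc = prepare_cohort(c.subset_subjects(keep), mirror_map, cfg)
        prepared.append(pc)
        logger.info(
            "%s: n=%d, %d QC flags, aligned %s",
            pc.cohort_id, pc.aligned.n_subjects, int(pc.qc_flags.sum()),
            pc.aligned.aligned.shape,
        )
    return prepared, maf_report


def segment_cohorts(
    prepared: list[PreparedCohort],
    cfg: PipelineConfig,
    template: np.ndarray | None = None,
) -> ModuleTree:
    """Module tree from the adjusted shapes of all cohorts pooled."""
    pooled = np.concatenate([p.adjusted_configs for p in prepared], axis=0)
    n_landmarks = pooled.shape[1]
    min_size = cfg.min_module_size
    if n_landmarks < min_size * 2**cfg.depth:
        min_size = 1
    adjacency = None
    if cfg.contiguity:
        ref = template if template is not None else prepared[0].aligned.consensus
        adjacency = knn_adjacency(ref)
    tree = hierarchical_segment(
        pooled, depth=cfg.depth, min_size=min_size, adjacency=adjacency
    )
    logger.info("segmentation: %d modules, level counts %s", len(tree), tree.level_counts())
    return tree


@dataclass
class ModuleAssocData:
    """Per-module inputs for the round-robin meta-analysis.

    ``scores[c]`` are cohort c's PC scores in its own discovery basis
    (truncated to the parallel-analysis dimension k[c]); ``proj[(d, r)]`` are
    cohort r's module shapes expressed in cohort d's GPA frame and PC basis.
    """

    module_id: int
    k: list[int]
    scores: list[np.ndarray]
    proj: dict[tuple[int, int], np.ndarray]
    skipped: bool = False


def phenotype_module(
    prepared: list[PreparedCohort],
    module_indices: np.ndarray,
    module_id: int,
    cfg: PipelineConfig,
    rng: np.random.Generator,
) -> ModuleAssocData:
    """Per-cohort module shape spaces plus cross-cohort projections.

    Each cohort's module landmarks get their own GPA + PCA; parallel analysis
    picks k per cohort. For replication, a cohort's aligned module shapes are
    rotated onto the discovery consensus and projected onto the discovery
    loadings, expressing the discovery trait in the replication subjects.
    """
    phenos = [
        module_shape_space(p.adjusted_configs, module_indices, module_id)
        for p in prepared
    ]
    ks = []
    for p, ph in zip(prepared, phenos):
        # PA needs the flattened coordinate data: a permutation null in PC
        # space would preserve the observed eigenvalues and select nothing
        centered = ph.aligned.reshape(ph.n, -1) - ph.mean
        k = parallel_analysis(
            centered,
            n_iter=cfg.pa_iterations,
            percentile=cfg.pa_percentile,
            seed=rng,
            max_rank=cfg.pa_max_rank,
            subsample=cfg.pa_subsample,
        )
        k = min(k, ph.scores.shape[1])
        ph.k = k
        ks.append(k)
    scores = [ph.truncated_scores() for ph in phenos]
    proj: dict[tuple[int, int], np.ndarray] = {}
    n_cohorts = len(prepared)
    for d in range(n_cohorts):
        basis = phenos[d].loadings[:, : ks[d]]
        for r in range(n_cohorts):
            if r == d:
                continue
            rotated = rotate_to_reference(phenos[r].aligned, phenos[d].consensus)
            flat = rotated.reshape(rotated.shape[0], -1) - phenos[d].mean
            proj[(d, r)] = flat @ basis
    return ModuleAssocData(module_id=module_id, k=ks, scores=scores, proj=proj)


def associate_all(
    prepared: list[PreparedCohort],
    tree: ModuleTree,
    snp_ids: list[str],
    cfg: PipelineConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Round-robin CCA meta-analysis of every SNP against every module.

    Returns the long results table and a dict with the Li-Ji effective test
    counts and the study-wide threshold. Modules with fewer than 3 landmarks
    cannot be phenotyped and are recorded as skipped.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    labels = [p.cohort_id for p in prepared]
    dosres = [p.dosage_residuals for p in prepared]
    n_cov = prepared[0].n_covariates
    rows: list[assoc.MetaResult] = []
    skipped: list[int] = []
    first_pc: dict[int, list[np.ndarray]] = {}
    for module in tree.modules:
        if module.size < 3:
            skipped.append(module.module_id)
            continue
        mad = phenotype_module(prepared, module.landmark_indices, module.module_id, cfg, rng)
        first_pc[module.module_id] = [s[:, 0] for s in mad.scores]
        rows.extend(
            assoc.meta_analyze_module(
                mad.scores, mad.proj, dosres, snp_ids, module.module_id,
                cohort_labels=labels, n_covariates=n_cov,
                weights_mode=cfg.weights_mode,
            )
        )
    results = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in rows],
            "module_id": [r.module_id for r in rows],
            "rotation": [r.rotation for r in rows],
            "cc": [r.cc for r in rows],
            "p_discovery": [r.p_discovery for r in rows],
            "p_rep1": [r.p_replication[0] for r in rows],
            "p_rep2": [r.p_replication[1] for r in rows],
            "p_meta": [r.p_meta for r in rows],
            "z_meta": [r.z_meta for r in rows],
        }
    )

    meff_modules = _meff_modules(first_pc, len(prepared))
    meff_snps = _meff_snps(dosres)
    n_meta = len(prepared)
    cutoff = assoc.study_threshold(meff_modules.meff, meff_snps.meff, n_meta, cfg.alpha)
    results["significant"] = results["p_meta"] < cutoff
    info = {
        "meff_modules": meff_modules.meff,
        "meff_modules_raw": meff_modules.raw,
        "meff_snps": meff_snps.meff,
        "meff_snps_raw": meff_snps.raw,
        "n_meta": n_meta,
        "alpha": cfg.alpha,
        "threshold": cutoff,
        "skipped_modules": skipped,
    }
    if skipped:
        logger.info("skipped %d modules with < 3 landmarks: %s", len(skipped), skipped)
    return results, info


def _meff_modules(first_pc: dict[int, list[np.ndarray]], n_cohorts: int):
    """Li-Ji effective module count from first-PC score correlations,
    averaged over cohorts."""
    ids = sorted(first_pc)
    mats = []
    for c in range(n_cohorts):
        block = np.column_stack([first_pc[i][c] for i in ids])
        mats.append(np.abs(np.corrcoef(block, rowvar=False)))
    return assoc.li_ji_meff(np.mean(mats, axis=0))


def _meff_snps(dosage_residuals: list[np.ndarray]):
    if dosage_residuals[0].shape[1] < 2:
        return assoc.LiJiResult(meff=dosage_residuals[0].shape[1], raw=float(
            dosage_residuals[0].shape[1]))
    mats = [np.abs(np.corrcoef(d, rowvar=False)) for d in dosage_residuals]
    return assoc.li_ji_meff(np.mean(mats, axis=0))


def effect_displacement_field(
    prepared: list[PreparedCohort], snp_index: int, return_se: bool = False
):
    """Per-landmark displacement (L, 3) regressed on residualized dosage,
    pooled across cohorts: the heat-map field of a SNP's shape effect.

    With ``return_se`` the per-coordinate standard error of the slope is also
    returned, enabling a debiased energy decomposition (raw squared slopes
    carry a sampling-variance floor on every coordinate).

    Each cohort is aligned with its own GPA, whose canonical frame can differ
    between cohorts (principal axes of a face are close to degenerate), so
    every cohort is first rotated onto the first cohort's consensus.
    """
    ref = prepared[0].aligned.consensus
    aligned_sets = []
    for p in prepared:
        m = p.aligned.consensus.T @ ref
        u, _, vt = np.linalg.svd(m)
        u[:, -1] *= np.sign(np.linalg.det(u @ vt))
        rot = u @ vt
        aligned_sets.append(p.adjusted_configs @ rot)
    xs = np.concatenate(aligned_sets, axis=0)
    g = np.concatenate([p.dosage_residuals[:, snp_index] for p in prepared])
    n = xs.shape[0]
    flat = xs.reshape(n, -1)
    flat = flat - flat.mean(axis=0)
    gc = g - g.mean()
    sxx = float(gc @ gc)
    slope = flat.T @ gc / sxx
    if not return_se:
        return slope.reshape(-1, 3)
    resid = flat - np.outer(gc, slope)
    se2 = (resid**2).sum(axis=0) / (n - 2) / sxx
    return slope.reshape(-1, 3), np.sqrt(se2).reshape(-1, 3)


def module_energy_fraction(
    field: np.ndarray,
    module_indices: np.ndarray,
    se_field: np.ndarray | None = None,
) -> float:
    """Fraction of a displacement field's squared energy carried by a module.

    When the slope standard errors are supplied, the inside/outside energies
    are debiased at the aggregate level (sum of b^2 - SE^2 over each region,
    floored at zero): raw squared slopes carry a sampling-variance floor on
    every coordinate that would otherwise dilute the fraction over the many
    unaffected landmarks.
    """
    field = np.asarray(field, dtype=float)
    inside_mask = np.zeros(field.shape[0], dtype=bool)
    inside_mask[np.asarray(module_indices, dtype=int)] = True
    energy = field**2
    if se_field is not None:
        energy = energy - np.asarray(se_field, dtype=float) ** 2
    inside = max(float(energy[inside_mask].sum()), 0.0)
    outside = max(float(energy[~inside_mask].sum()), 0.0)
    total = inside + outside
    if total <= 0:
        return 0.0
    return inside / total


# ------------------------------------------------------------------ reporting

def report(results: pd.DataFrame, info: dict, top: int = 20) -> str:
    """Per-SNP, per-module summary sorted by meta p with the study threshold."""
    lines = [
        "Round-robin CCA meta-analysis",
        f"  effective modules (Li-Ji): {info['meff_modules']} "
        f"(raw {info['meff_modules_raw']:.3f})",
        f"  effective SNPs   (Li-Ji): {info['meff_snps']} "
        f"(raw {info['meff_snps_raw']:.3f})",
        f"  rotations: {info['n_meta']}   alpha: {info['alpha']}",
        f"  study-wide threshold: {info['threshold']:.3e}",
        "",
    ]
    if results.empty:
        lines.append("  no associations computed")
        return "\n".join(lines)
    ordered = results.sort_values("p_meta").head(top)
    lines.append(
        f"{'snp':<14}{'module':>7}{'rotation':>12}{'CC':>8}"
        f"{'p_disc':>11}{'p_meta':>11}  sig"
    )
    for r in ordered.itertuples():
        lines.append(
            f"{r.snp_id:<14}{r.module_id:>7}{r.rotation:>12}{r.cc:>8.3f}"
            f"{r.p_discovery:>11.2e}{r.p_meta:>11.2e}  {'*' if r.significant else ''}"
        )
    n_sig = int(results["significant"].sum())
    lines.append("")
    lines.append(f"  {n_sig} significant (SNP, module, rotation) results")
    return "\n".join(lines)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate, analyse and write the full result bundle.

    Deterministic given the config seed; a manifest records the config hash,
    so a completed run is a no-op unless ``force`` is set.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = cfg.config_hash()
    if manifest_path.exists() and not cfg.force:
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") == cfg_hash:
            logger.info("pipeline already complete for this config; use force to rerun")
            previous["skipped"] = True
            return previous

    spec = cfg.simulation_spec()
    study = synthdata.simulate_study(spec)
    logger.info(
        "simulated %s cohorts, L=%d, %d SNPs",
        [c.n for c in study.cohorts], spec.n_landmarks, len(spec.snp_specs),
    )
    prepared, maf_report = prepare_cohorts(study.cohorts, study.template.mirror_map, cfg)
    tree = segment_cohorts(prepared, cfg, template=study.template.coordinates)
    # surviving SNPs after the MAF filter
    dropped = set(maf_report["snp_id"]) if len(maf_report) else set()
    snp_ids = [s for s in study.cohorts[0].snp_ids if s not in dropped]
    rng = np.random.default_rng(cfg.seed + 1)
    results, info = associate_all(prepared, tree, snp_ids, cfg, rng)

    tree.to_tsv(out / "module_tree.tsv")
    maf_report.to_csv(out / "maf_exclusions.tsv", sep="\t", index=False)
    results.to_csv(out / "associations.tsv", sep="\t", index=False, float_format="%.4g")
    qc = pd.DataFrame(
        {
            "cohort": np.concatenate(
                [[p.cohort_id] * p.aligned.n_subjects for p in prepared]
            ),
            "qc_z": np.concatenate([p.aligned.qc_zscores for p in prepared]),
            "flagged": np.concatenate([p.qc_flags for p in prepared]),
        }
    )
    qc.to_csv(out / "qc_report.tsv", sep="\t", index=False, float_format="%.4f")
    summary = report(results, info)
    (out / "report.txt").write_text(summary + "\n")

    manifest = {
        "config_hash": cfg_hash,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "cohort_sizes": [p.aligned.n_subjects for p in prepared],
        "n_modules": len(tree),
        "level_counts": tree.level_counts(),
        "snp_ids": snp_ids,
        "maf_excluded": sorted(dropped),
        **{k: (v if not isinstance(v, float) else float(v)) for k, v in info.items()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote results to %s", out)
    manifest["results"] = results
    manifest["report"] = summary
    manifest["tree"] = tree
    manifest["prepared"] = prepared
    manifest["study"] = study
    return manifest
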