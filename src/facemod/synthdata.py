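"""Synthetic multi-cohort facial-shape + genotype generator.

Emulates the statistical structure the downstream analysis assumes: three
cohorts of unequal size; Hardy-Weinberg genotypes at stated minor-allele
frequencies; covariate effects on shape (age, age^2, sex, height, weight and
size allometry) plus small ancestry-axis loadings; a spatially correlated
residual field that gives the segmentation non-trivial modules; and small
additive SNP effects whose displacement field is restricted to one module of
a template-derived hierarchy (the "mandibular" module by default). Rigid
nuisance transforms (rotation, translation, global scale) are applied last so
Procrustes superimposition has real work to do.

Everything is reproducible from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import segment as _segment
from .shapeio import CohortDataset, SnpInfo, folded_maf

__all__ = [
    "TemplateFace",
    "SnpSpec",
    "SimulationSpec",
    "SimulatedStudy",
    "generate_template_face",
    "simulate_cohorts",
    "simulate_study",
    "mandible_module_id",
    "residual_kernel",
]

NAMED_LANDMARKS = (
    "glabella",
    "nasion",
    "prosthion",
    "stomion",
    "gnathion",
    "zygion_l",
    "zygion_r",
    "gonion_l",
    "gonion_r",
)

# anatomically ordered positions, mm; y is up, z is out of the face, x = 0 is
# the midsagittal plane. Bizygomatic width 130 mm, nasion-gnathion 110 mm.
_NAMED_COORDS = {
    "glabella": (0.0, 70.0, 88.0),
    "nasion": (0.0, 50.0, 95.0),
    "prosthion": (0.0, -25.0, 98.0),
    "stomion": (0.0, -38.0, 96.0),
    "gnathion": (0.0, -60.0, 95.0),
    "zygion_l": (-65.0, 20.0, 40.0),
    "zygion_r": (65.0, 20.0, 40.0),
    "gonion_l": (-50.0, -45.0, 55.0),
    "gonion_r": (50.0, -45.0, 55.0),
}

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class TemplateFace:
    """Bilaterally symmetric face-like landmark template.

    ``mirror_map`` is an involution pairing left/right landmarks across the
    x = 0 plane (midline landmarks map to themselves); reflecting x and
    relabeling reproduces the coordinates exactly.
    """

    coordinates: np.ndarray          # (L, 3), mm
    mirror_map: np.ndarray           # (L,) int involution
    named_landmarks: dict[str, int]

    @property
    def n_landmarks(self) -> int:
        return self.coordinates.shape[0]

    def named_coordinate(self, name: str) -> np.ndarray:
        return self.coordinates[self.named_landmarks[name]]


def generate_template_face(n_landmarks: int) -> TemplateFace:
    """Deterministic, symmetric, ellipsoid-like landmark layout.

    Nine named landmarks sit at fixed anatomical positions (nasion above
    prosthion above gnathion; zygions widest); the remaining points fill the
    facial surface with a midline arc plus a mirrored golden-angle spiral.
    """
    n_named = len(NAMED_LANDMARKS)
    if n_landmarks < 16:
        raise ValueError(
            f"L={n_landmarks} too small: need at least 16 landmarks to "
            f"accommodate the {n_named} named landmarks"
        )
    if n_landmarks % 2 != 0:
        raise ValueError("landmark count must be even (mirror-paired layout)")
    remaining = n_landmarks - n_named  # odd, since L is even and n_named is odd
    n_mid = max(1, (remaining // 7) | 1)  # odd count of extra midline points
    n_pairs = (remaining - n_mid) // 2
    assert n_mid + 2 * n_pairs == remaining

    coords = [np.array(_NAMED_COORDS[name]) for name in NAMED_LANDMARKS]
    names = {name: i for i, name in enumerate(NAMED_LANDMARKS)}

    # midline arc from forehead to chin, avoiding the named midline points
    t = (np.arange(n_mid) + 0.5) / n_mid
    y_mid = 84.0 - 150.0 * t
    z_mid = 97.0 - (y_mid / 84.0) ** 2 * 18.0
    mid_idx = list(range(n_named, n_named + n_mid))
    for y, z in zip(y_mid, z_mid):
        coords.append(np.array([0.0, y, z]))

    # mirrored spiral over the right hemiface (x > 0 strictly)
    right, left = [], []
    for i in range(n_pairs):
        u = (i + 0.5) / n_pairs
        radius = 0.93 * np.sqrt(u)
        angle = i * _GOLDEN_ANGLE
        x = 58.0 * radius * (0.15 + 0.85 * np.abs(np.cos(angle)))
        y = 80.0 * radius * np.sin(angle)
        z = 96.0 - ((x / 65.0) ** 2 + (y / 80.0) ** 2) * 45.0
        right.append(np.array([x, y, z]))
        left.append(np.array([-x, y, z]))
    r_idx = list(range(n_named + n_mid, n_named + n_mid + n_pairs))
    l_idx = list(range(n_named + n_mid + n_pairs, n_landmarks))
    coords.extend(right)
    coords.extend(left)

    mirror = np.arange(n_landmarks)
    mirror[names["zygion_l"]], mirror[names["zygion_r"]] = (
        names["zygion_r"],
        names["zygion_l"],
    )
    mirror[names["gonion_l"]], mirror[names["gonion_r"]] = (
        names["gonion_r"],
        names["gonion_l"],
    )
    for a, b in zip(r_idx, l_idx):
        mirror[a], mirror[b] = b, a
    _ = mid_idx  # midline points map to themselves

    return TemplateFace(
        coordinates=np.array(coords), mirror_map=mirror, named_landmarks=names
    )


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    maf: float
    beta: float = 0.0                 # mm total module displacement per alt allele
    target_module: int | str | None = None  # module id, or "mandible"

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: MAF must lie in (0, 0.5]")
        if self.beta < 0:
            raise ValueError(f"{self.snp_id}: effect size must be >= 0")


def _default_covariate_effects() -> dict[str, float]:
    # mm-scale coefficients; age per year, height/weight per cm/kg around
    # cohort means, sex as a dimorphism field amplitude, allometry as log-size
    # response per covariate SD
    return {
        "age": 0.12,
        "age2": -0.0015,
        "sex": 1.5,
        "height": 0.03,
        "weight": 0.02,
        "allometry": 0.05,
        "ancestry": 0.25,
    }


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic cohorts.

    Defaults mirror the three real cohorts: sizes 2297/1555/3566 scaled by
    ``size_factor``, cohort age ranges (3-40, 18-83, 14-17 years), residual
    landmark noise ``noise_sd`` mm with a distance-decaying spatial kernel.
    """

    n_subjects: tuple[int, int, int] = (2297, 1555, 3566)
    n_landmarks: int = 128
    snp_specs: list[SnpSpec] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    noise_sd: float = 2.0             # mm, per coordinate
    kernel_scale: float = 25.0        # mm, residual spatial correlation length
    seed: int = 0
    size_factor: float = 1.0
    dosage_mode: str = "hard"         # 'hard' {0,1,2} or 'dosage' [0,2]
    age_ranges: tuple = ((3.0, 40.0), (18.0, 83.0), (14.0, 17.0))
    tree_depth: int = 5
    cohort_ids: tuple = ("cohortA", "cohortB", "cohortC")

    def __post_init__(self):
        sizes = tuple(int(round(n * self.size_factor)) for n in self.n_subjects)
        if any(n <= 0 for n in sizes):
            raise ValueError("cohort sizes must be positive")
        self.n_subjects = sizes
        if self.n_landmarks < 16:
            raise ValueError("need at least 16 landmarks")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.dosage_mode not in ("hard", "dosage"):
            raise ValueError("dosage_mode must be 'hard' or 'dosage'")
        # a shallow tree is the best a small template can support
        self.tree_depth = min(self.tree_depth, int(np.log2(self.n_landmarks)) - 1)
        for s in self.snp_specs:
            if not isinstance(s, SnpSpec):
                raise TypeError("snp_specs must contain SnpSpec entries")


@dataclass
class SimulatedStudy:
    cohorts: list[CohortDataset]
    template: TemplateFace
    module_tree: _segment.ModuleTree
    planted_landmarks: dict[str, np.ndarray]   # snp_id -> landmark indices
    effect_fields: dict[str, np.ndarray]       # snp_id -> (L, 3) unit field
    spec: SimulationSpec


def residual_kernel(template: TemplateFace, scale: float) -> np.ndarray:
    """Distance-decaying landmark correlation kernel (unit diagonal)."""
    t = template.coordinates
    d2 = np.sum((t[:, None] - t[None, :]) ** 2, axis=2)
    k = np.exp(-d2 / (2.0 * scale**2))
    return k + 1e-8 * np.eye(len(t))


def symmetrized_kernel(template: TemplateFace, scale: float) -> np.ndarray:
    """Residual correlation structure after symmetrization.

    Downstream analysis averages each face with its reflected, relabeled
    mirror image, which ties every landmark to its bilateral partner; the
    resulting similarity is the mirror-average of the raw kernel, and mirror
    pairs become perfectly covarying.
    """
    k = residual_kernel(template, scale)
    mm = template.mirror_map
    k_sym = 0.25 * (k + k[:, mm] + k[mm, :] + k[np.ix_(mm, mm)])
    d = np.sqrt(np.diag(k_sym))
    k_sym = k_sym / np.outer(d, d)  # to correlations: mirror pairs hit 1
    return np.clip(k_sym, 0.0, 1.0)


def _template_tree(template: TemplateFace, spec: SimulationSpec) -> _segment.ModuleTree:
    """Reference module hierarchy from the symmetrized residual kernel (the
    generator's own notion of which landmarks co-vary after symmetrization);
    modules come out bilaterally mirror-closed, as in the analysis."""
    kernel = symmetrized_kernel(template, spec.kernel_scale)
    depth = spec.tree_depth
    min_size = 3 if template.n_landmarks >= 3 * 2**depth else 1
    return _segment.segment_similarity(kernel, depth=depth, min_size=min_size)


def mandible_module_id(template: TemplateFace, tree: _segment.ModuleTree,
                       level: int = 3) -> int:
    """Module at ``level`` containing the gnathion (chin) landmark."""
    gnathion = template.named_landmarks["gnathion"]
    for m in tree.at_level(level):
        if gnathion in m.landmark_indices:
            return m.module_id
    raise ValueError("no module at that level contains the gnathion")


def _similarity_tangent_basis(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3m x 7) of the similarity-group tangent space at a
    module configuration: 3 translations, 3 rotations, 1 scaling."""
    c = points - points.mean(axis=0)
    m = len(points)
    basis = []
    for ax in range(3):
        v = np.zeros((m, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for gen in (
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ):
        basis.append((c @ gen.T).ravel())
    basis.append(c.ravel())
    q, _ = np.linalg.qr(np.column_stack(basis))
    return q


def _effect_field(
    template: TemplateFace,
    indices: np.ndarray,
    child_sets: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Unit-norm displacement field supported on one module.

    When the module's two sub-modules are supplied, the field is a relative
    pose contrast: one child translates along the module's mean outward
    normal, the other counter-translates (weighted so the module's net
    translation vanishes). Restricted to either child the effect is a pure
    similarity transform — invisible after the child's own Procrustes fit —
    so the effect belongs to the module itself, not to its descendants;
    anatomically this is a relative protrusion of one sub-region against the
    other. Without sub-modules the field is a wide Gaussian-amplitude bump
    along outward normals (length scale twice the module's RMS radius).

    Either way the field is made bilaterally symmetric (the analysis works on
    symmetrized faces, so only the symmetric component of any effect
    survives), orthogonalized against the module's similarity-transform
    tangent space so per-module Procrustes cannot absorb it, and normalized
    to unit Frobenius norm: the SNP effect size is the total displacement
    (mm) of the module per alternate allele.
    """
    coords = template.coordinates
    module = coords[indices]
    field = np.zeros_like(coords)
    if child_sets is not None and len(child_sets) == 2:
        direction = (module - coords.mean(axis=0)).mean(axis=0)
        direction[0] = 0.0  # mirror-invariant push
        norm = np.linalg.norm(direction)
        if norm <= 1e-9:
            direction = np.array([0.0, 0.0, 1.0])
        else:
            direction = direction / norm
        a, b = child_sets
        field[a] = direction
        field[b] = -direction * (len(a) / len(b))
    else:
        centroid = module.mean(axis=0)
        center = module[np.argmin(np.linalg.norm(module - centroid, axis=1))]
        d2 = np.sum((module - center) ** 2, axis=1)
        sigma2 = 4.0 * max(d2.mean(), 1e-6)
        amp = np.exp(-d2 / (2.0 * sigma2))
        normals = module - coords.mean(axis=0)
        normals /= np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-9)
        field[indices] = amp[:, None] * normals
    # bilateral symmetry: keep the mirror-invariant component
    reflected = field.copy()
    reflected[:, 0] *= -1.0
    field = 0.5 * (field + reflected[template.mirror_map])
    outside = np.sum(field[np.setdiff1d(np.arange(len(coords)), indices)] ** 2)
    if outside > 1e-12 * max(np.sum(field**2), 1e-12):
        raise ValueError(
            "target module is not mirror-closed; plant effects on modules of "
            "the symmetrized template tree"
        )
    # project out translations/rotations/scale of the module
    local = field[indices]
    q = _similarity_tangent_basis(module)
    flat = local.ravel()
    flat = flat - q @ (q.T @ flat)
    norm = np.linalg.norm(flat)
    if norm <= 1e-9:
        raise ValueError("degenerate effect field on module")
    field = np.zeros_like(coords)
    field[indices] = flat.reshape(-1, 3) / norm
    return field


def _resolve_target(spec_entry: SnpSpec, template: TemplateFace,
                    tree: _segment.ModuleTree) -> tuple[int, np.ndarray] | None:
    if spec_entry.target_module is None or spec_entry.beta == 0:
        return None
    target = spec_entry.target_module
    if isinstance(target, str):
        if target != "mandible":
            raise ValueError(f"unknown named target module {target!r}")
        module_id = mandible_module_id(template, tree)
    else:
        module_id = int(target)
    try:
        module = tree.get(module_id)
    except KeyError as exc:
        raise ValueError(
            f"target module {module_id} not present in the generated tree"
        ) from exc
    return module_id, module.landmark_indices


def _random_rotations(rng: np.random.Generator, n: int, sd_deg: float = 5.0):
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, np.deg2rad(sd_deg), size=n)
    k = np.zeros((n, 3, 3))
    k[:, 0, 1], k[:, 0, 2] = -axes[:, 2], axes[:, 1]
    k[:, 1, 0], k[:, 1, 2] = axes[:, 2], -axes[:, 0]
    k[:, 2, 0], k[:, 2, 1] = -axes[:, 1], axes[:, 0]
    eye = np.eye(3)[None]
    sin, cos = np.sin(angles)[:, None, None], np.cos(angles)[:, None, None]
    return eye + sin * k + (1 - cos) * (k @ k)


def _smooth_field(rng: np.random.Generator, chol: np.ndarray) -> np.ndarray:
    """Random spatially smooth (L, 3) field with ~unit per-coordinate scale."""
    return chol @ rng.normal(size=(chol.shape[0], 3))


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Simulate the three cohorts plus the generator's provenance.

    Per cohort: covariates from documented distributions; genotypes under
    Hardy-Weinberg at the stated MAF; shape = template + covariate fields +
    beta * dosage * module-restricted unit field + spatially correlated
    residual; then a random rigid transform and allometric/global scale.
    """
    template = generate_template_face(spec.n_landmarks)
    tree = _template_tree(template, spec)
    kernel = residual_kernel(template, spec.kernel_scale)
    chol = np.linalg.cholesky(kernel)
    eff = spec.covariate_effects

    root = np.random.SeedSequence(spec.seed)
    field_rng = np.random.default_rng(root.spawn(1)[0])
    cohort_seeds = root.spawn(len(spec.n_subjects) + 1)[1:]

    centroid = template.coordinates.mean(axis=0)
    radial = template.coordinates - centroid
    radial_unit = radial / np.linalg.norm(radial, axis=1, keepdims=True)

    # deterministic covariate displacement fields (shared across cohorts)
    age_field = radial_unit.copy()                      # growth: outward
    sex_field = _effect_field(
        template,
        tree.get(mandible_module_id(template, tree, level=2)).landmark_indices,
    )  # dimorphism concentrated on the lower face
    height_field = _smooth_field(field_rng, chol)
    weight_field = _smooth_field(field_rng, chol)
    ancestry_fields = [_smooth_field(field_rng, chol) for _ in range(4)]

    planted: dict[str, np.ndarray] = {}
    effect_fields: dict[str, np.ndarray] = {}
    for s in spec.snp_specs:
        resolved = _resolve_target(s, template, tree)
        if resolved is not None:
            module_id, indices = resolved
            child_sets = [
                c.landmark_indices for c in tree.children(module_id)
            ] or None
            planted[s.snp_id] = indices
            effect_fields[s.snp_id] = _effect_field(template, indices, child_sets)

    cohorts: list[CohortDataset] = []
    for c, (n, age_range, cohort_id, cseed) in enumerate(
        zip(spec.n_subjects, spec.age_ranges, spec.cohort_ids, cohort_seeds)
    ):
        rng = np.random.default_rng(cseed)
        age = rng.uniform(*age_range, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)  # 1 = male
        height = np.where(
            sex > 0, rng.normal(177.0, 7.0, n), rng.normal(164.0, 7.0, n)
        )
        weight = np.where(
            sex > 0, rng.normal(78.0, 12.0, n), rng.normal(65.0, 11.0, n)
        )
        ancestry = rng.normal(size=(n, 4))
        covariates = pd.DataFrame(
            {
                "age": age, "sex": sex, "height": height, "weight": weight,
                "anc1": ancestry[:, 0], "anc2": ancestry[:, 1],
                "anc3": ancestry[:, 2], "anc4": ancestry[:, 3],
            }
        )

        genotypes = np.empty((n, len(spec.snp_specs)))
        for j, s in enumerate(spec.snp_specs):
            g = rng.binomial(2, s.maf, size=n).astype(float)
            if spec.dosage_mode == "dosage":
                g = np.clip(g + rng.normal(0.0, 0.08, size=n), 0.0, 2.0)
            genotypes[:, j] = g

        shapes = np.broadcast_to(
            template.coordinates, (n, spec.n_landmarks, 3)
        ).copy()
        age_c = age - np.mean(age_range)
        shapes += age_c[:, None, None] * eff["age"] * age_field
        shapes += (age_c**2 - np.mean(age_c**2))[:, None, None] * eff["age2"] * age_field
        shapes += (sex - 0.5)[:, None, None] * eff["sex"] * sex_field
        shapes += ((height - height.mean()) * eff["height"])[:, None, None] * height_field
        shapes += ((weight - weight.mean()) * eff["weight"])[:, None, None] * weight_field
        for a in range(4):
            shapes += (ancestry[:, a] * eff["ancestry"])[:, None, None] * ancestry_fields[a]
        for j, s in enumerate(spec.snp_specs):
            if s.snp_id in effect_fields:
                shapes += (s.beta * genotypes[:, j])[:, None, None] * effect_fields[s.snp_id]

        # spatially correlated residual, independent per axis (asymmetric)
        noise = rng.normal(size=(n, spec.n_landmarks, 3))
        shapes += spec.noise_sd * np.einsum("lk,nkj->nlj", chol, noise)

        # allometry + nuisance similarity transform
        log_scale = eff["allometry"] * (
            0.6 * (age_c / max(np.std(age_c), 1e-9))
            + 0.4 * ((height - height.mean()) / height.std())
        )
        scale = np.exp(log_scale + rng.normal(0.0, 0.02, n))
        rot = _random_rotations(rng, n)
        trans = rng.normal(0.0, 10.0, size=(n, 1, 3))
        shapes = scale[:, None, None] * np.einsum("nij,nlj->nli", rot, shapes) + trans

        emp_maf = folded_maf(genotypes)
        snp_meta = [
            SnpInfo(
                snp_id=s.snp_id, chrom="17", pos=7_600_000 + 1000 * j,
                ref="G", alt="T", maf=float(emp_maf[j]),
            )
            for j, s in enumerate(spec.snp_specs)
        ]
        cohorts.append(
            CohortDataset(
                cohort_id=cohort_id,
                configurations=shapes,
                covariates=covariates,
                genotypes=genotypes,
                snp_meta=snp_meta,
            )
        )

    return SimulatedStudy(
        cohorts=cohorts,
        template=template,
        module_tree=tree,
        planted_landmarks=planted,
        effect_fields=effect_fields,
        spec=spec,
    )


def simulate_cohorts(spec: SimulationSpec) -> list[CohortDataset]:
    """The three synthetic cohorts (see :func:`simulate_study` for provenance)."""
    return simulate_study(spec).cohorts


def null_spec(**overrides) -> SimulationSpec:
    """Convenience spec with no planted effects."""
    return replace(SimulationSpec(), **overrides)


def write_study(study: SimulatedStudy, out_dir, genotype_format: str = "vcf") -> None:
    """Write each cohort (landmarks, covariates, genotypes) plus a manifest
    recording the spec and seeds; the template and module tree ride along."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    from . import shapeio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cohort in study.cohorts:
        stem = out / cohort.cohort_id
        shapeio.write_landmarks(f"{stem}.landmarks.tsv", cohort.configurations,
                                cohort.subject_ids)
        shapeio.write_covariates(f"{stem}.covariates.tsv", cohort.covariates,
                                 cohort.subject_ids)
        if genotype_format == "vcf":
            shapeio.write_vcf(f"{stem}.vcf", cohort.genotypes, cohort.snp_meta,
                              cohort.subject_ids)
        else:
            shapeio.write_dosage_matrix(f"{stem}.dosages.tsv", cohort.genotypes,
                                        cohort.snp_meta, cohort.subject_ids)
    study.module_tree.to_tsv(out / "template_module_tree.tsv")
    np.savetxt(out / "template.tsv", study.template.coordinates, delimiter="\t")
    spec_dict = asdict(study.spec)
    spec_dict["snp_specs"] = [asdict(s) for s in study.spec.snp_specs]
    (out / "manifest.json").write_text(json.dumps(spec_dict, indent=2, default=str))
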