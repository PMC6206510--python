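"""On-disk formats and validation for cohorts, genotypes and results.

Landmark configurations travel as wide TSV (one row per subject, columns
x0, y0, z0, x1, ...), covariates and dosages as TSV keyed by subject id,
genotypes alternatively as minimal VCF 4.2 (GT and DS fields, read back
through cyvcf2). Subject order is canonicalized (sorted ids) on read so all
arrays of a cohort stay aligned.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SnpInfo",
    "CohortDataset",
    "read_landmarks",
    "write_landmarks",
    "read_covariates",
    "write_covariates",
    "read_genotypes",
    "write_dosage_matrix",
    "write_vcf",
    "maf_filter",
    "folded_maf",
]

COVARIATE_FILE_COLUMNS = ["age", "sex", "height", "weight", "anc1", "anc2", "anc3", "anc4"]


@dataclass(frozen=True)
class SnpInfo:
    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float

    @property
    def location(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class CohortDataset:
    """One cohort: landmark configurations, covariates, SNP dosages, metadata.

    All tables share the subject axis (same ordering, same n); dosages lie in
    [0, 2]; for hard calls the stored MAF must match the dosage-derived MAF.
    """

    cohort_id: str
    configurations: np.ndarray          # (n, L, 3), mm
    covariates: pd.DataFrame            # age, sex, height, weight, anc1..anc4
    genotypes: np.ndarray               # (n, S) additive dosages in [0, 2]
    snp_meta: list[SnpInfo]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = self.configurations.shape[0]
        if not self.subject_ids:
            self.subject_ids = [f"{self.cohort_id}_{i:05d}" for i in range(n)]
        self.validate()

    @property
    def n(self) -> int:
        return self.configurations.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.configurations.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snp_meta]

    def validate(self) -> None:
        n = self.configurations.shape[0]
        if self.configurations.ndim != 3 or self.configurations.shape[2] != 3:
            raise ValueError("configurations must be (n, L, 3)")
        if len(self.covariates) != n or self.genotypes.shape[0] != n:
            raise ValueError("tables disagree on subject count")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length mismatch")
        if self.genotypes.shape[1] != len(self.snp_meta):
            raise ValueError("genotype columns do not match snp_meta")
        if np.any(self.genotypes < -1e-9) or np.any(self.genotypes > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        missing = [c for c in COVARIATE_FILE_COLUMNS if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariate table missing columns {missing}")
        hard = np.all(np.isin(np.round(self.genotypes, 9), (0.0, 1.0, 2.0)))
        if hard and len(self.snp_meta):
            emp = folded_maf(self.genotypes)
            stored = np.array([s.maf for s in self.snp_meta])
            if np.any(np.abs(emp - stored) > 1e-6):
                raise ValueError(
                    "stored MAF does not match the dosage-derived MAF (hard calls)"
                )

    def empirical_maf(self) -> np.ndarray:
        return folded_maf(self.genotypes)

    def subset_subjects(self, mask: np.ndarray) -> "CohortDataset":
        mask = np.asarray(mask, dtype=bool)
        genotypes = self.genotypes[mask]
        # stored MAF describes the accompanying subjects: recompute on subset
        emp = folded_maf(genotypes)
        meta = [
            SnpInfo(s.snp_id, s.chrom, s.pos, s.ref, s.alt, float(emp[j]))
            for j, s in enumerate(self.snp_meta)
        ]
        return CohortDataset(
            cohort_id=self.cohort_id,
            configurations=self.configurations[mask],
            covariates=self.covariates.loc[mask].reset_index(drop=True),
            genotypes=genotypes,
            snp_meta=meta,
            subject_ids=[s for s, m in zip(self.subject_ids, mask) if m],
        )

    def drop_snps(self, snp_ids: set[str]) -> "CohortDataset":
        keep = [i for i, s in enumerate(self.snp_meta) if s.snp_id not in snp_ids]
        return CohortDataset(
            cohort_id=self.cohort_id,
            configurations=self.configurations,
            covariates=self.covariates,
            genotypes=self.genotypes[:, keep],
            snp_meta=[self.snp_meta[i] for i in keep],
            subject_ids=list(self.subject_ids),
        )


def folded_maf(dosages: np.ndarray) -> np.ndarray:
    """Allele frequency from mean dosage / 2, folded to the minor allele."""
    freq = np.asarray(dosages, dtype=float).mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


# ---------------------------------------------------------------- landmarks

def write_landmarks(path, configurations: np.ndarray, subject_ids) -> None:
    n, n_lm, _ = configurations.shape
    cols = [f"{ax}{i}" for i in range(n_lm) for ax in ("x", "y", "z")]
    df = pd.DataFrame(configurations.reshape(n, -1), columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_landmarks(path) -> tuple[np.ndarray, list[str]]:
    """Read a wide landmark table; returns ((n, L, 3) array, subject ids).

    Rows are sorted by subject id (canonical order); ragged rows, non-numeric
    cells and NaN coordinates are rejected with row/column diagnostics.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty landmark file")
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc
    if "subject_id" in df.columns:
        ids = df.pop("subject_id").astype(str).tolist()
    else:
        ids = [f"s{i:05d}" for i in range(len(df))]
    n_cols = df.shape[1]
    if n_cols == 0 or n_cols % 3 != 0:
        raise ValueError(
            f"{path}: {n_cols} coordinate columns, not divisible by 3"
        )
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at row {r}, column {df.columns[c]}"
        )
    order = np.argsort(ids, kind="stable")
    values = values[order]
    ids = [ids[i] for i in order]
    return values.reshape(len(df), n_cols // 3, 3), ids


# --------------------------------------------------------------- covariates

def write_covariates(path, covariates: pd.DataFrame, subject_ids) -> None:
    df = covariates.copy()
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_covariates(path) -> tuple[pd.DataFrame, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: covariate table needs a subject_id column")
    df = df.sort_values("subject_id", kind="stable").reset_index(drop=True)
    ids = df.pop("subject_id").astype(str).tolist()
    missing = [c for c in COVARIATE_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing covariate columns {missing}")
    return df, ids


# ---------------------------------------------------------------- genotypes

def write_dosage_matrix(path, dosages: np.ndarray, snp_meta: list[SnpInfo],
                        subject_ids) -> None:
    df = pd.DataFrame(dosages, columns=[s.snp_id for s in snp_meta])
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    meta = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snp_meta],
            "chrom": [s.chrom for s in snp_meta],
            "pos": [s.pos for s in snp_meta],
            "ref": [s.ref for s in snp_meta],
            "alt": [s.alt for s in snp_meta],
            "maf": [s.maf for s in snp_meta],
        }
    )
    meta.to_csv(str(path) + ".meta", sep="\t", index=False)


def write_vcf(path, dosages: np.ndarray, snp_meta: list[SnpInfo], subject_ids,
              hard_calls: bool | None = None) -> None:
    """Write a minimal VCF 4.2 with GT and DS per sample."""
    dosages = np.asarray(dosages, dtype=float)
    if hard_calls is None:
        hard_calls = bool(np.all(np.isin(np.round(dosages, 9), (0.0, 1.0, 2.0))))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Additive dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(subject_ids),
    ]
    for j, snp in enumerate(snp_meta):
        fields = [snp.chrom, str(snp.pos), snp.snp_id, snp.ref, snp.alt,
                  ".", "PASS", ".", "GT:DS"]
        for value in dosages[:, j]:
            gt = gt_map[int(round(value))] if hard_calls else "./."
            fields.append(f"{gt}:{value:.6g}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_vcf(path) -> tuple[np.ndarray, list[SnpInfo], list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols, meta = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record {variant.ID or variant.POS} not supported"
            )
        ds = variant.format("DS")
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(variant.gt_types)  # 0=hom_ref,1=het,2=unknown,3=hom_alt
            if np.any(gts == 2):
                raise ValueError(f"missing genotypes in {variant.ID}")
            col = np.where(gts == 3, 2.0, gts.astype(float))
        dosage_cols.append(col)
        meta.append(
            SnpInfo(
                snp_id=variant.ID or f"{variant.CHROM}:{variant.POS}",
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref=str(variant.REF),
                alt=str(variant.ALT[0]),
                maf=float(np.minimum(col.mean() / 2, 1 - col.mean() / 2)),
            )
        )
    if not dosage_cols:
        raise ValueError(f"{path}: no variant records")
    return np.column_stack(dosage_cols), meta, samples


def read_genotypes(
    path, mode: str = "matrix", sample_ids: list[str] | None = None
) -> tuple[np.ndarray, list[SnpInfo], list[str]]:
    """Read dosages from a VCF (``mode='vcf'``) or TSV matrix (``'matrix'``).

    GT fields map 0/0 -> 0, 0/1 -> 1, 1/1 -> 2; a DS field takes precedence.
    When ``sample_ids`` is given, samples are checked and reordered against
    it; unresolvable ids are reported.
    """
    if mode == "vcf":
        dosages, meta, samples = _read_vcf(path)
    elif mode == "matrix":
        df = pd.read_csv(path, sep="\t")
        if "subject_id" not in df.columns:
            raise ValueError(f"{path}: dosage matrix needs a subject_id column")
        samples = df.pop("subject_id").astype(str).tolist()
        dosages = df.to_numpy(dtype=float)
        meta_path = Path(str(path) + ".meta")
        if meta_path.exists():
            mdf = pd.read_csv(meta_path, sep="\t")
            meta = [
                SnpInfo(str(r.snp_id), str(r.chrom), int(r.pos), str(r.ref),
                        str(r.alt), float(r.maf))
                for r in mdf.itertuples()
            ]
        else:
            emp = folded_maf(dosages)
            meta = [
                SnpInfo(c, "0", i + 1, "A", "B", float(emp[i]))
                for i, c in enumerate(df.columns)
            ]
    else:
        raise ValueError("mode must be 'vcf' or 'matrix'")
    if np.any(dosages < 0) or np.any(dosages > 2):
        raise ValueError("dosages outside [0, 2]")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in set(samples)]
        if missing:
            raise ValueError(f"sample ids not found in genotype file: {missing[:10]}")
        index = {s: i for i, s in enumerate(samples)}
        order = [index[s] for s in sample_ids]
        dosages = dosages[order]
        samples = list(sample_ids)
    else:
        order = np.argsort(samples, kind="stable")
        dosages = dosages[order]
        samples = [samples[i] for i in order]
    return dosages, meta, samples


# --------------------------------------------------------------- MAF filter

def maf_filter(
    cohorts: list[CohortDataset], threshold: float
) -> tuple[list[CohortDataset], pd.DataFrame]:
    """Drop SNPs whose minor-allele frequency falls below ``threshold`` in
    any cohort; the exclusion report names the offending cohort and frequency.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must lie in (0, 0.5)")
    shared = set(cohorts[0].snp_ids)
    for c in cohorts[1:]:
        if set(c.snp_ids) != shared:
            raise ValueError("cohorts carry different SNP sets")
    excluded: dict[str, tuple[str, float]] = {}
    for c in cohorts:
        freqs = c.empirical_maf()
        for snp, f in zip(c.snp_ids, freqs):
            if f < threshold and snp not in excluded:
                excluded[snp] = (c.cohort_id, float(f))
    report = pd.DataFrame(
        {
            "snp_id": list(excluded),
            "cohort": [v[0] for v in excluded.values()],
            "maf": [v[1] for v in excluded.values()],
            "threshold": threshold,
        }
    )
    dropped = set(excluded)
    return [c.drop_snps(dropped) for c in cohorts], report
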