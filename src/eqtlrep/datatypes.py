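"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* genomic intervals are 0-based half-open (BED style); VCF positions are
  converted on read and kept 1-based only in per-SNP metadata (``pos``);
* dosages are expected alternate-allele counts in [0, 2];
* expression values are log2 intensities, probes (rows) by samples (columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "Demographics",
    "StudyPanel",
    "TruthTable",
    "ReporterPlate",
    "QcReport",
    "EqtlAssociation",
    "ScanResult",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    ``dosages`` holds mean-imputed allele counts in [0, 2]; ``mask`` (optional)
    marks entries that were missing before imputation.  ``snp_meta`` is indexed
    by snp_id with columns chrom, pos (1-based), ref, alt, maf, imputed.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_snps)
    snp_meta: pd.DataFrame
    mask: Optional[np.ndarray] = None  # True where originally missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if list(self.snp_meta.index) != list(self.snp_ids):
            self.snp_meta = self.snp_meta.loc[self.snp_ids]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency computed from the dosage matrix."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return GenotypeMatrix(
            sample_ids=list(keep),
            snp_ids=list(self.snp_ids),
            dosages=self.dosages[idx, :].copy(),
            snp_meta=self.snp_meta.copy(),
            mask=None if self.mask is None else self.mask[idx, :].copy(),
        )

    def subset_snps(self, keep: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=list(keep),
            dosages=self.dosages[:, idx].copy(),
            snp_meta=self.snp_meta.loc[keep].copy(),
            mask=None if self.mask is None else self.mask[:, idx].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensity matrix.

    ``probe_meta`` is indexed by probe_id with columns gene_id, exon_id,
    chrom, start, end (0-based half-open), strand, n_probe_snps.
    ``replicate_ids``, when present, gives one column label per data column of
    the form understood by :func:`replicate_map` (technical replicates of the
    same sample share a sample_id).
    """

    probe_ids: list[str]
    sample_ids: list[str]  # one entry per column; repeats = technical reps
    values: np.ndarray  # (n_probes, n_columns)
    probe_meta: pd.DataFrame
    replicate_ids: Optional[list[str]] = None  # unique column labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.probe_ids):
            raise ValueError("values rows must match probe_ids")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("values columns must match sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def replicate_map(self) -> dict[str, list[int]]:
        """Column indices per individual sample (replicates grouped)."""
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.sample_ids):
            out.setdefault(s, []).append(j)
        return out

    def collapse_replicates(self) -> "ExpressionMatrix":
        """Average technical replicates into one column per sample."""
        groups = self.replicate_map()
        samples = list(groups)
        vals = np.column_stack(
            [self.values[:, groups[s]].mean(axis=1) for s in samples]
        )
        return ExpressionMatrix(
            probe_ids=list(self.probe_ids),
            sample_ids=samples,
            values=vals,
            probe_meta=self.probe_meta.copy(),
        )


@dataclass
class Demographics:
    """One row per sample: age, sex, ancestry covariate(s), population."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        required = {"age", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"demographics missing columns: {sorted(missing)}")
        if (self.table["age"] < 0).any():
            raise ValueError("ages must be non-negative")
        bad = set(self.table["sex"]) - {"male", "female"}
        if bad:
            raise ValueError(f"unrecognised sex labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def ancestry_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("ancestry")]

    def sex_indicator(self) -> np.ndarray:
        """male = 1, female = 0."""
        return (self.table["sex"] == "male").to_numpy(dtype=float)


@dataclass
class StudyPanel:
    """One cohort: genotypes + expression + demographics + platform label."""

    name: str
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    demographics: Demographics
    platform: str = "array"

    def __post_init__(self) -> None:
        g = set(self.genotypes.sample_ids)
        e = set(self.expression.sample_ids)
        d = set(self.demographics.sample_ids)
        if not (g == d and e <= g):
            raise ValueError(
                f"panel {self.name}: sample ids inconsistent across components"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples


@dataclass
class TruthTable:
    """Planted ground truth for a simulated multi-study design.

    ``genes`` is indexed by gene_id with columns cis_snp_id, cis_beta,
    trans_snp_id, trans_beta, age_beta, sex_beta and the generator's expected
    variance-fraction bookkeeping (var_frac_* columns summing to 1).
    ``probes`` is indexed by probe_id with columns artifact (bool),
    artifact_snp_id, artifact_delta.  ``confounders`` maps panel name to a
    (loadings, scores) pair.
    """

    genes: pd.DataFrame
    probes: pd.DataFrame
    confounders: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )


@dataclass
class ReporterPlate:
    """Normalized luciferase measurements for one or more regions.

    Long-format rows: region_id, haplotype_id, prep_id, replicate_index,
    luminescence.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"region_id", "haplotype_id", "prep_id", "replicate_index",
                    "luminescence"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reporter plate missing columns: {sorted(missing)}")


@dataclass
class QcReport:
    """Bookkeeping from genotype filtering; counts reconcile exactly.

    A SNP is counted once, in the first filter it fails, applied in order
    call-rate -> HWE -> MAF.
    """

    n_snps_in: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_removed_maf: int
    n_snps_out: int
    removed_callrate: list[str]
    removed_hwe: list[str]
    removed_maf: list[str]
    parameters: dict

    def __post_init__(self) -> None:
        if self.n_snps_out != self.n_snps_in - (
            self.n_removed_callrate + self.n_removed_hwe + self.n_removed_maf
        ):
            raise ValueError("QcReport counts do not reconcile")

    def to_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_removed_callrate": self.n_removed_callrate,
            "n_removed_hwe": self.n_removed_hwe,
            "n_removed_maf": self.n_removed_maf,
            "n_snps_out": self.n_snps_out,
            "removed_callrate": self.removed_callrate,
            "removed_hwe": self.removed_hwe,
            "removed_maf": self.removed_maf,
            "parameters": self.parameters,
        }


@dataclass
class EqtlAssociation:
    """One gene x SNP association record."""

    gene_id: str
    snp_id: str
    log10_bf: float
    beta: float
    se: float
    t: float
    p: float
    maf: float
    imputed: bool
    tss_distance: int
    cis: bool


@dataclass
class ScanResult:
    """Best-SNP-per-gene table (+ optional full per-SNP table)."""

    best: pd.DataFrame  # indexed by gene_id; missing association -> NaN row
    mode: str  # "cis" or "trans"
    full: Optional[pd.DataFrame] = None

    BEST_COLUMNS = [
        "snp_id", "chrom", "pos", "log10_bf", "beta", "se", "t", "p",
        "maf", "imputed", "tss_distance",
    ]
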