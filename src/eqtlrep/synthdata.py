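"""Multi-study synthetic genotype/expression generator with known ground truth.

The generator emulates the statistical structure of a multi-panel liver
expression study: two or three cohorts of unequal size genotyped on a shared
SNP set, expression measured on platform-specific probe maps, shared cis and
trans genetic effects, demographic (age/sex/ancestry) effects, panel-specific
hidden confounders, technical replicates, and in-probe polymorphisms that
produce allele-specific hybridization artifacts.

Every operation is a pure function of its arguments including ``seed``.

Variance bookkeeping
--------------------
Each gene's per-sample biological value has unit variance by construction,
decomposed into cis + trans + age + sex + ancestry + confounder + residual
fractions that the generator records in the :class:`~eqtlrep.datatypes.TruthTable`
(columns ``var_frac_*``, summing to 1).  Technical replicate noise
(``noise_sd``) is measurement noise added per expression column on top of the
shared per-sample value, so it does not enter the unit-variance budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    Demographics,
    ExpressionMatrix,
    GenotypeMatrix,
    ReporterPlate,
    StudyPanel,
    TruthTable,
)

__all__ = [
    "SimulationConfig",
    "SnpLayout",
    "make_layout",
    "simulate_genotypes",
    "simulate_demographics",
    "simulate_expression",
    "simulate_multi_study",
    "simulate_reporter",
    "expected_dosage_correlation",
]

PROBE_LENGTH = 60  # bp, typical long-oligo array probe


@dataclass
class SimulationConfig:
    """Parameters of the multi-study simulation.

    Proportions are in [0, 1]; heritabilities are fractions of the unit
    per-gene biological variance; effect SDs are in log2 expression units.
    """

    panel_sizes: tuple[int, ...] = (206, 60, 266)
    n_genes: int = 300
    n_snps_per_gene: int = 15
    cis_window: int = 250_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_cis_genes: float = 0.3
    cis_h2_range: tuple[float, float] = (0.1, 0.4)
    n_trans_regulators: int = 2
    n_trans_targets: int = 10
    trans_h2: float = 0.25
    age_effect_sd: float = 0.15
    sex_effect_sd: float = 0.3
    ancestry_effect_sd: float = 0.2
    frac_age_genes: float = 0.3
    frac_sex_genes: float = 0.1
    frac_ancestry_genes: float = 0.1
    n_confounders_per_panel: int = 3
    confounder_var_frac: float = 0.3
    confounder_gene_frac: float = 0.4
    frac_probe_snp: tuple[float, ...] = (0.274, 0.191, 0.191)
    probe_artifact_delta: float = 0.6
    ld_decay: float = 0.8
    frac_imputed: float = 0.3
    noise_sd: float = 0.3
    n_replicates: tuple[int, ...] = (2, 2, 1)
    n_probes_per_gene: int = 3
    n_chromosomes: int = 4
    frac_non_european: tuple[float, ...] = (23 / 206, 5 / 60, 0.0)
    sex_genes_on_chrx: bool = False
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.panel_sizes):
            raise ValueError("panel_sizes must all be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in (
            "frac_cis_genes", "frac_age_genes", "frac_sex_genes",
            "frac_ancestry_genes", "confounder_var_frac",
            "confounder_gene_frac", "frac_imputed", "trans_h2",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must be in [0, 1)")
        if not 0 <= self.cis_h2_range[0] <= self.cis_h2_range[1] <= 1:
            raise ValueError("cis_h2_range must be ordered within [0, 1]")
        if self.cis_h2_range[1] + self.confounder_var_frac >= 1:
            raise ValueError(
                "cis_h2 + confounder variance fractions must leave room "
                "for residual variance"
            )


@dataclass
class SnpLayout:
    """Genomic layout shared by all panels.

    ``genes``: gene_id-indexed frame with chrom, tss, strand.
    ``snps``: snp_id-indexed frame with chrom, pos (1-based), maf (target),
    gene_id (the gene whose cis window contains it).
    """

    genes: pd.DataFrame
    snps: pd.DataFrame


def make_layout(config: SimulationConfig, seed: int) -> SnpLayout:
    """Place genes on chromosomes and SNPs in each gene's cis window."""
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    if config.sex_genes_on_chrx:
        chroms.append("chrX")
    gene_rows = []
    spacing = 2 * config.cis_window + 100_000  # non-overlapping cis windows
    per_chrom_count = {c: 0 for c in chroms}
    for g in range(config.n_genes):
        chrom = chroms[g % len(chroms)]
        k = per_chrom_count[chrom]
        per_chrom_count[chrom] += 1
        tss = config.cis_window + 10_000 + k * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((f"G{g:04d}", chrom, tss, strand))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss", "strand"]
    ).set_index("gene_id")

    snp_rows = []
    lo, hi = config.maf_range
    for gene_id, row in genes.iterrows():
        offs = rng.choice(
            np.arange(-config.cis_window + 1, config.cis_window),
            size=config.n_snps_per_gene, replace=False,
        )
        offs.sort()
        for j, off in enumerate(offs):
            snp_rows.append((
                f"{gene_id}_snp{j:02d}", row["chrom"],
                int(row["tss"] + off), rng.uniform(lo, hi), gene_id,
            ))
    snps = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", "maf", "gene_id"]
    ).set_index("snp_id")
    # positions strictly increasing within chromosome
    snps = snps.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        bumped = np.maximum.accumulate(pos + np.arange(len(pos)) * 0)
        # resolve duplicates by bumping by 1 bp
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + 1
        snps.loc[sub.index, "pos"] = pos
    return SnpLayout(genes=genes, snps=snps)


def simulate_genotypes(
    n_samples: int,
    layout: SnpLayout,
    ld_decay: float = 0.8,
    frac_imputed: float = 0.0,
    seed: int = 0,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Draw HWE hard-call genotypes with first-order haplotype-copying LD.

    Each haplotype allele at SNP k is copied from SNP k-1 with probability
    ``ld_decay``, else redrawn as Bernoulli(maf_k); adjacent-SNP correlation
    therefore decays geometrically with ``ld_decay``.  A fraction
    ``frac_imputed`` of SNPs is converted to fractional dosages (flagged
    ``imputed``) by shrinking the hard call toward 2*MAF with a per-SNP
    quality factor drawn from U(0.7, 1).
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    if not 0 <= ld_decay < 1:
        raise ValueError("ld_decay must be in [0, 1)")
    mafs = layout.snps["maf"].to_numpy()
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("SNP MAFs must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    n_snps = len(layout.snps)
    haplos = np.empty((2 * n_samples, n_snps), dtype=np.int8)
    chrom_codes = layout.snps["chrom"].to_numpy()
    prev_chrom = None
    for k in range(n_snps):
        fresh = rng.random(2 * n_samples) < mafs[k]
        if chrom_codes[k] != prev_chrom:
            haplos[:, k] = fresh
            prev_chrom = chrom_codes[k]
        else:
            copy = rng.random(2 * n_samples) < ld_decay
            haplos[:, k] = np.where(copy, haplos[:, k - 1], fresh)
    hard = (haplos[0::2] + haplos[1::2]).astype(float)

    imputed = rng.random(n_snps) < frac_imputed
    dosages = hard.copy()
    if imputed.any():
        quality = rng.uniform(0.7, 1.0, size=n_snps)
        centre = 2 * mafs
        for k in np.flatnonzero(imputed):
            dosages[:, k] = centre[k] + quality[k] * (hard[:, k] - centre[k])
    dosages = np.clip(dosages, 0.0, 2.0)

    p = dosages.mean(axis=0) / 2.0
    meta = pd.DataFrame(
        {
            "chrom": layout.snps["chrom"].to_numpy(),
            "pos": layout.snps["pos"].to_numpy(),
            "ref": "A",
            "alt": "G",
            "maf": np.minimum(p, 1 - p),
            "imputed": imputed,
        },
        index=layout.snps.index,
    )
    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=list(layout.snps.index),
        dosages=dosages,
        snp_meta=meta,
    )


def simulate_demographics(
    sample_ids: list[str],
    frac_non_european: float = 0.1,
    seed: int = 0,
) -> Demographics:
    """Ages ~ N(50, 12) truncated to the donor range [20, 75], balanced
    sexes, and a binary population label plus one continuous admixture
    covariate."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    age = np.clip(rng.normal(50, 12, size=n), 20, 75).round(1)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    non_eur = rng.random(n) < frac_non_european
    pop = np.where(non_eur, "AFR", "EUR")
    admix = np.where(
        non_eur, rng.normal(0.8, 0.1, n), rng.normal(0.02, 0.02, n)
    )
    table = pd.DataFrame(
        {"age": age, "sex": sex, "ancestry1": admix, "population": pop},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return Demographics(table)


def effective_allele_freq(layout: SnpLayout, ld_decay: float) -> pd.Series:
    """Marginal alternate-allele frequency under the haplotype-copying chain.

    Copying from the previous SNP pulls each SNP's realized frequency toward
    its left neighbour: p*_k = ld * p*_(k-1) + (1 - ld) * p_k, restarting at
    each chromosome.  Used so planted effect sizes hit their target variance
    fractions under the realized dosage variance.
    """
    out = np.empty(len(layout.snps))
    chroms = layout.snps["chrom"].to_numpy()
    target = layout.snps["maf"].to_numpy()
    prev_chrom = None
    for k in range(len(out)):
        if chroms[k] != prev_chrom:
            out[k] = target[k]
            prev_chrom = chroms[k]
        else:
            out[k] = ld_decay * out[k - 1] + (1 - ld_decay) * target[k]
    return pd.Series(out, index=layout.snps.index)


def _draw_gene_effects(config: SimulationConfig, layout: SnpLayout,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Assign cis/trans/demographic effects and variance fractions per gene."""
    genes = layout.genes
    n = len(genes)
    eff_freq = effective_allele_freq(layout, config.ld_decay)
    is_cis = rng.random(n) < config.frac_cis_genes
    is_age = rng.random(n) < config.frac_age_genes
    is_sex = rng.random(n) < config.frac_sex_genes
    if config.sex_genes_on_chrx:
        # sex-affected genes planted on the X chromosome for enrichment tests
        is_sex = (genes["chrom"] == "chrX").to_numpy()
    is_anc = rng.random(n) < config.frac_ancestry_genes
    is_conf = rng.random(n) < config.confounder_gene_frac

    rows = []
    snps_by_gene = layout.snps.groupby("gene_id", sort=False).groups
    gene_ids = list(genes.index)
    # trans regulators: SNPs from some genes regulate genes elsewhere
    trans_map: dict[str, tuple[str, float]] = {}
    if config.n_trans_regulators > 0:
        reg_genes = rng.choice(n, size=config.n_trans_regulators, replace=False)
        for rg in reg_genes:
            reg_gene = gene_ids[rg]
            snp_ids = list(snps_by_gene[reg_gene])
            reg_snp = snp_ids[rng.integers(len(snp_ids))]
            reg_chrom = genes.loc[reg_gene, "chrom"]
            other = [g for g in gene_ids if genes.loc[g, "chrom"] != reg_chrom]
            targets = rng.choice(
                len(other), size=min(config.n_trans_targets, len(other)),
                replace=False,
            )
            for t in targets:
                trans_map[other[t]] = (reg_snp, config.trans_h2)

    for i, gene_id in enumerate(gene_ids):
        f_cis = 0.0
        cis_snp = None
        cis_beta = 0.0
        if is_cis[i]:
            f_cis = rng.uniform(*config.cis_h2_range)
            snp_ids = list(snps_by_gene[gene_id])
            cis_snp = snp_ids[rng.integers(len(snp_ids))]
            p_eff = eff_freq[cis_snp]
            var_g = 2 * p_eff * (1 - p_eff)  # HWE dosage variance
            cis_beta = rng.choice([-1.0, 1.0]) * math.sqrt(f_cis / var_g)
        trans_snp, f_trans, trans_beta = None, 0.0, 0.0
        if gene_id in trans_map:
            trans_snp, f_trans = trans_map[gene_id]
            p_eff = eff_freq[trans_snp]
            var_g = 2 * p_eff * (1 - p_eff)
            trans_beta = rng.choice([-1.0, 1.0]) * math.sqrt(f_trans / var_g)
        age_beta = rng.normal(0, config.age_effect_sd) if is_age[i] else 0.0
        sex_beta = rng.normal(0, config.sex_effect_sd) if is_sex[i] else 0.0
        anc_beta = rng.normal(0, config.ancestry_effect_sd) if is_anc[i] else 0.0
        # effects are applied to standardized covariates, so the variance
        # contribution of each beta is beta^2 (sex: beta^2/4 on the 0/1 scale
        # is avoided by centring+scaling the indicator)
        f_age, f_sex, f_anc = age_beta ** 2, sex_beta ** 2, anc_beta ** 2
        f_conf = config.confounder_var_frac \
            if is_conf[i] and config.n_confounders_per_panel > 0 else 0.0
        signal = f_cis + f_trans + f_age + f_sex + f_anc + f_conf
        if signal > 0.95:
            # rescale all signal components so residual variance stays >= 5%
            shrink = 0.95 / signal
            root = math.sqrt(shrink)
            cis_beta *= root
            trans_beta *= root
            age_beta *= root
            sex_beta *= root
            anc_beta *= root
            f_cis *= shrink
            f_trans *= shrink
            f_age, f_sex, f_anc = (f_age * shrink, f_sex * shrink,
                                   f_anc * shrink)
            f_conf *= shrink
        f_resid = 1.0 - (f_cis + f_trans + f_age + f_sex + f_anc + f_conf)
        rows.append((
            gene_id, cis_snp, cis_beta, trans_snp, trans_beta,
            age_beta, sex_beta, anc_beta, bool(f_conf > 0),
            f_cis, f_trans, f_age, f_sex, f_anc, f_conf, f_resid,
        ))
    cols = [
        "gene_id", "cis_snp_id", "cis_beta", "trans_snp_id", "trans_beta",
        "age_beta", "sex_beta", "ancestry_beta", "confounded",
        "var_frac_cis", "var_frac_trans", "var_frac_age", "var_frac_sex",
        "var_frac_ancestry", "var_frac_confounder", "var_frac_residual",
    ]
    out = pd.DataFrame(rows, columns=cols).set_index("gene_id")
    frac_cols = [c for c in cols if c.startswith("var_frac")]
    assert np.allclose(out[frac_cols].sum(axis=1), 1.0, atol=1e-9)
    return out


def _make_probe_map(
    layout: SnpLayout,
    gene_truth: pd.DataFrame,
    frac_probe_snp: float,
    artifact_delta: float,
    platform: str,
    n_probes_per_gene: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Platform-specific probe coordinates, offsets and artifact assignments.

    Returns (probe_meta, probe_truth).  Artifact probes are placed directly
    over one of the gene's cis-window SNPs; intensity DECREASES with
    artifact-allele dosage (a mismatch lowers hybridization efficiency).
    """
    snps_by_gene = layout.snps.groupby("gene_id", sort=False).groups
    meta_rows, truth_rows = [], []
    for gene_id, grow in layout.genes.iterrows():
        snp_ids = list(snps_by_gene[gene_id])
        for j in range(n_probes_per_gene):
            probe_id = f"{platform}_{gene_id}_p{j}"
            offset = rng.normal(0, 0.5)
            artifact = rng.random() < frac_probe_snp
            if artifact:
                snp = snp_ids[rng.integers(len(snp_ids))]
                pos = int(layout.snps.loc[snp, "pos"])
                inside = int(rng.integers(PROBE_LENGTH))
                start = pos - 1 - inside  # 0-based, SNP inside probe
                art_snp, delta = snp, artifact_delta
            else:
                start = int(grow["tss"]) + 100 + j * (PROBE_LENGTH + 10)
                art_snp, delta = None, 0.0
            meta_rows.append((
                probe_id, gene_id, f"{gene_id}_e{j % 2}", grow["chrom"],
                max(0, start), max(0, start) + PROBE_LENGTH, grow["strand"],
                int(artifact), offset,
            ))
            truth_rows.append((probe_id, bool(artifact), art_snp, delta))
    probe_meta = pd.DataFrame(
        meta_rows,
        columns=["probe_id", "gene_id", "exon_id", "chrom", "start", "end",
                 "strand", "n_probe_snps", "probe_offset"],
    ).set_index("probe_id")
    probe_truth = pd.DataFrame(
        truth_rows,
        columns=["probe_id", "artifact", "artifact_snp_id", "artifact_delta"],
    ).set_index("probe_id")
    return probe_meta, probe_truth


def simulate_expression(
    genotypes: GenotypeMatrix,
    demographics: Demographics,
    gene_truth: pd.DataFrame,
    probe_meta: pd.DataFrame,
    probe_truth: pd.DataFrame,
    confounder_loadings: np.ndarray,
    confounder_scores: np.ndarray,
    noise_sd: float = 0.3,
    n_replicates: int = 1,
    seed: int = 0,
) -> ExpressionMatrix:
    """Forward-simulate log2 probe intensities from planted effects.

    Per probe j of gene g and sample i::

        value = baseline_g + probe_offset_j
                + cis_beta_g * dosage + trans_beta_g * dosage_trans
                + age_beta_g * z(age) + sex_beta_g * z(sex) + anc_beta * z(anc)
                + loadings_g . scores_i
                - artifact_delta_j * dosage(artifact SNP)   [artifact probes]
                + residual_i(g) + replicate noise
    """
    if list(demographics.sample_ids) != list(genotypes.sample_ids):
        raise ValueError("genotype and demographic sample ids differ")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    genes = list(gene_truth.index)
    snp_index = {s: k for k, s in enumerate(genotypes.snp_ids)}

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_age = z(demographics.table["age"].to_numpy(dtype=float))
    z_sex = z(demographics.sex_indicator())
    z_anc = z(demographics.table["ancestry1"].to_numpy(dtype=float))

    baseline = {g: 7.0 + rng.normal(0, 1) for g in genes}
    gene_value = np.zeros((len(genes), n))
    for gi, g in enumerate(genes):
        row = gene_truth.loc[g]
        y = np.full(n, baseline[g])
        if row["cis_snp_id"] is not None and not pd.isna(row["cis_snp_id"]):
            y = y + row["cis_beta"] * genotypes.dosages[:, snp_index[row["cis_snp_id"]]]
        if row["trans_snp_id"] is not None and not pd.isna(row["trans_snp_id"]):
            y = y + row["trans_beta"] * genotypes.dosages[:, snp_index[row["trans_snp_id"]]]
        y = y + row["age_beta"] * z_age + row["sex_beta"] * z_sex
        y = y + row["ancestry_beta"] * z_anc
        if confounder_loadings.size:
            y = y + confounder_scores @ confounder_loadings[gi]
        y = y + rng.normal(0, math.sqrt(max(row["var_frac_residual"], 0.0)), n)
        gene_value[gi] = y

    gene_pos = {g: i for i, g in enumerate(genes)}
    probe_ids = list(probe_meta.index)
    n_cols = n * n_replicates
    values = np.empty((len(probe_ids), n_cols))
    sample_cols: list[str] = []
    replicate_cols: list[str] = []
    for i, s in enumerate(genotypes.sample_ids):
        for r in range(n_replicates):
            sample_cols.append(s)
            replicate_cols.append(f"{s}_r{r + 1}")
    col_of_sample = np.repeat(np.arange(n), n_replicates)

    for pi, probe in enumerate(probe_ids):
        prow = probe_meta.loc[probe]
        base = gene_value[gene_pos[prow["gene_id"]]] + prow["probe_offset"]
        trow = probe_truth.loc[probe]
        if trow["artifact"]:
            d = genotypes.dosages[:, snp_index[trow["artifact_snp_id"]]]
            base = base - trow["artifact_delta"] * d
        values[pi] = base[col_of_sample] + rng.normal(0, noise_sd, n_cols)

    return ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_cols,
        values=values,
        probe_meta=probe_meta.drop(columns=["probe_offset"]),
        replicate_ids=replicate_cols,
    )


def simulate_multi_study(
    config: SimulationConfig,
) -> tuple[list[StudyPanel], TruthTable, SnpLayout]:
    """Generate disjoint study panels sharing one genetic truth table.

    Panels share the gene list and planted cis/trans/demographic effects but
    have disjoint samples, panel-specific confounders, and platform-specific
    probe maps whose in-probe-SNP (artifact) fractions differ by platform.
    """
    config.validate()
    if len(config.panel_sizes) < 2:
        raise ValueError("replication-mode configs need at least 2 panels")
    rng = np.random.default_rng(config.seed)
    layout = make_layout(config, seed=int(rng.integers(2 ** 31)))
    gene_truth = _draw_gene_effects(config, layout, rng)

    panels: list[StudyPanel] = []
    probe_truths = []
    confounders: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_genes = len(gene_truth)
    platforms = ["agilent-44k", "illumina-dasl", "agilent-merck"]
    for p, size in enumerate(config.panel_sizes):
        name = f"panel{p + 1}"
        geno = simulate_genotypes(
            size, layout, ld_decay=config.ld_decay,
            frac_imputed=config.frac_imputed,
            seed=int(rng.integers(2 ** 31)), sample_prefix=f"P{p + 1}_S",
        )
        frac_ne = config.frac_non_european[p % len(config.frac_non_european)]
        dem = simulate_demographics(
            geno.sample_ids, frac_non_european=frac_ne,
            seed=int(rng.integers(2 ** 31)),
        )
        k = config.n_confounders_per_panel
        scores = rng.standard_normal((size, k)) if k else np.zeros((size, 0))
        loadings = np.zeros((n_genes, k))
        if k:
            loaded = gene_truth["confounded"].to_numpy()
            # split each gene's confounder variance budget across components
            lam = np.sqrt(
                gene_truth["var_frac_confounder"].to_numpy() / k)
            signs = rng.choice([-1.0, 1.0], size=(n_genes, k))
            loadings[loaded] = (lam[loaded, None] * signs[loaded])
        confounders[name] = (loadings, scores)

        platform = platforms[p % len(platforms)]
        frac_ps = config.frac_probe_snp[p % len(config.frac_probe_snp)]
        probe_meta, probe_truth = _make_probe_map(
            layout, gene_truth, frac_ps, config.probe_artifact_delta,
            platform, config.n_probes_per_gene, rng,
        )
        n_reps = config.n_replicates[p % len(config.n_replicates)]
        expr = simulate_expression(
            geno, dem, gene_truth, probe_meta, probe_truth,
            loadings, scores, noise_sd=config.noise_sd,
            n_replicates=n_reps, seed=int(rng.integers(2 ** 31)),
        )
        panels.append(StudyPanel(
            name=name, genotypes=geno, expression=expr,
            demographics=dem, platform=platform,
        ))
        probe_truth = probe_truth.copy()
        probe_truth["panel"] = name
        probe_truths.append(probe_truth)

    truth = TruthTable(
        genes=gene_truth,
        probes=pd.concat(probe_truths),
        confounders=confounders,
    )
    return panels, truth, layout


def simulate_reporter(
    haplotype_effects: dict[str, float],
    n_preps: int = 3,
    n_reps: int = 4,
    prep_sd: float = 0.2,
    residual_sd: float = 0.3,
    seed: int = 0,
    region_id: str = "region1",
) -> ReporterPlate:
    """Simulate a luciferase plate: haplotype mean + per-prep random
    intercept + residual.  The default 3 preps x 4 replicates yields 12
    measurements per haplotype."""
    if n_preps < 1 or n_reps < 1:
        raise ValueError("n_preps and n_reps must be >= 1")
    if prep_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for hap, mu in haplotype_effects.items():
        for prep in range(n_preps):
            prep_eff = rng.normal(0, prep_sd) if prep_sd > 0 else 0.0
            for rep in range(n_reps):
                resid = rng.normal(0, residual_sd) if residual_sd > 0 else 0.0
                rows.append((
                    region_id, hap, f"{hap}_prep{prep + 1}", rep + 1,
                    mu + prep_eff + resid,
                ))
    return ReporterPlate(pd.DataFrame(
        rows,
        columns=["region_id", "haplotype_id", "prep_id", "replicate_index",
                 "luminescence"],
    ))


def expected_dosage_correlation(
    beta: float, var_g: float, var_y: float
) -> float:
    """Closed-form corr(probe value, SNP dosage) from the variance budget.

    ``beta`` is the total linear coefficient of the SNP's dosage in the probe
    value (cis effect plus any artifact contribution on that probe), ``var_g``
    the dosage variance and ``var_y`` the total probe-value variance
    (including the beta^2 * var_g term and replicate noise).
    """
    if var_y <= 0 or var_g <= 0:
        raise ValueError("variances must be positive")
    return beta * math.sqrt(var_g) / math.sqrt(var_y)
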