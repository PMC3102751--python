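"""Single-SNP association scans.

Each gene's residual phenotype is tested against SNP dosages one at a time,
by a conjugate Bayesian regression Bayes factor (reported as log10) and by
ordinary least squares with a two-sided t-test.  Cis scans test SNPs within a
window of the transcription start site; trans scans test SNPs on other
chromosomes.  The best SNP per gene is the log10 BF argmax with a
deterministic tie-break (lowest genomic coordinate, then snp_id).

Bayes factor model
------------------
For phenotype y and dosage g (n samples),

    y = mu * 1 + a * g + e,   e ~ N(0, sigma^2 I),
    a ~ N(0, sigma_a^2 * sigma^2),

with an improper flat prior on mu and Jeffreys prior on sigma^2.  Writing
centered sums syy, sgg, sgy, the marginal-likelihood ratio against the
intercept-only model is

    BF(sigma_a) = (1 + sigma_a^2 sgg)^(-1/2) * (syy / S1)^((n-1)/2),
    S1 = syy - sigma_a^2 sgy^2 / (1 + sigma_a^2 sgg),

averaged over a small grid of prior effect scales sigma_a with fixed weights.
Because the effect prior scales with sigma, the BF is invariant to affine
transformations of y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .covariates import AdjustedPhenotypes
from .datatypes import GenotypeMatrix, ScanResult

__all__ = [
    "BfPriorSpec",
    "single_snp_bf",
    "single_snp_lm",
    "cis_scan",
    "trans_scan",
]


@dataclass
class BfPriorSpec:
    """Grid of prior effect scales (relative to residual SD) and weights."""

    sigma_a: tuple[float, ...] = (0.05, 0.2, 0.4)
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_a):
            raise ValueError("prior scales must be positive")
        if self.weights is None:
            self.weights = tuple(1.0 / len(self.sigma_a)
                                 for _ in self.sigma_a)
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("prior weights must sum to 1")


def _log10_bf_from_sums(
    syy: float | np.ndarray,
    sgg: np.ndarray,
    sgy: np.ndarray,
    n: int,
    priors: BfPriorSpec,
) -> np.ndarray:
    """Vectorized closed-form log10 BF over SNP columns."""
    sgg = np.asarray(sgg, float)
    sgy = np.asarray(sgy, float)
    logbfs = []
    for s_a in priors.sigma_a:
        lam = s_a ** 2
        shrink = 1.0 + lam * sgg
        s1 = syy - lam * sgy ** 2 / shrink
        logbf = -0.5 * np.log(shrink) + 0.5 * (n - 1) * (
            np.log(syy) - np.log(s1)
        )
        logbfs.append(logbf)
    logbfs = np.stack(logbfs)  # (n_priors, n_snps)
    logw = np.log(np.asarray(priors.weights))[:, None]
    return logsumexp(logbfs + logw, axis=0) / np.log(10.0)


def single_snp_bf(
    y: np.ndarray, g: np.ndarray, priors: BfPriorSpec | None = None
) -> float:
    """log10 Bayes factor for a single phenotype/dosage pair."""
    priors = priors or BfPriorSpec()
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n = len(y)
    if n < 3 or len(g) != n:
        raise ValueError("need n >= 3 paired observations")
    gc = g - g.mean()
    sgg = float(gc @ gc)
    if sgg == 0:
        raise ValueError("genotype is monomorphic in sample")
    yc = y - y.mean()
    syy = float(yc @ yc)
    sgy = float(gc @ yc)
    return float(_log10_bf_from_sums(syy, np.array([sgg]),
                                     np.array([sgy]), n, priors)[0])


def single_snp_lm(
    y: np.ndarray, g: np.ndarray
) -> tuple[float, float, float, float]:
    """OLS slope of y on g with a two-sided t-test: (beta, se, t, p)."""
    y = np.asarray(y, float)
    g = np.asarray(g, float)
    n = len(y)
    if n < 3 or len(g) != n:
        raise ValueError("need n >= 3 paired observations")
    gc = g - g.mean()
    sgg = float(gc @ gc)
    if sgg == 0:
        raise ValueError("genotype is monomorphic in sample")
    yc = y - y.mean()
    beta = float(gc @ yc) / sgg
    rss = float(yc @ yc) - beta ** 2 * sgg
    dof = n - 2
    sigma2 = max(rss, 0.0) / dof
    se = float(np.sqrt(sigma2 / sgg))
    if se == 0:
        return beta, 0.0, np.inf if beta != 0 else 0.0, 0.0 if beta else 1.0
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), dof))
    return beta, se, t, max(p, np.finfo(float).tiny)


def _scan_gene(
    y: np.ndarray,
    G: np.ndarray,
    n: int,
    priors: BfPriorSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene statistics over SNP columns of G."""
    yc = y - y.mean()
    syy = float(yc @ yc)
    Gc = G - G.mean(axis=0, keepdims=True)
    sgg = (Gc ** 2).sum(axis=0)
    sgy = Gc.T @ yc
    log10_bf = _log10_bf_from_sums(syy, sgg, sgy, n, priors)
    beta = sgy / sgg
    rss = np.maximum(syy - beta ** 2 * sgg, 0.0)
    dof = n - 2
    se = np.sqrt(rss / dof / sgg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    p = np.maximum(2 * stats.t.sf(np.abs(t), dof), np.finfo(float).tiny)
    return log10_bf, beta, se, t, p


def _signed_tss_distance(pos: np.ndarray, tss: int, strand: str) -> np.ndarray:
    return pos - tss if strand == "+" else tss - pos


def _intersect_samples(
    adjusted: AdjustedPhenotypes, genotypes: GenotypeMatrix
) -> tuple[list[str], np.ndarray, np.ndarray]:
    shared = [s for s in adjusted.sample_ids if s in set(genotypes.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between phenotypes and genotypes")
    frac_lost = 1 - len(shared) / max(
        len(adjusted.sample_ids), genotypes.n_samples)
    if frac_lost > 0.10:
        warnings.warn(
            f"sample intersection dropped {frac_lost:.0%} of samples"
        )
    a_idx = np.array([adjusted.sample_ids.index(s) for s in shared])
    g_idx = np.array([genotypes.sample_ids.index(s) for s in shared])
    return shared, a_idx, g_idx


def _run_scan(
    adjusted: AdjustedPhenotypes,
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    mode: str,
    window: int,
    maf_min: float,
    priors: BfPriorSpec,
    keep_full: bool,
) -> ScanResult:
    shared, a_idx, g_idx = _intersect_samples(adjusted, genotypes)
    n = len(shared)
    Y = adjusted.residuals[:, a_idx]
    D = genotypes.dosages[g_idx, :]
    meta = genotypes.snp_meta
    snp_chrom = meta["chrom"].to_numpy()
    snp_pos = meta["pos"].to_numpy(dtype=int)
    snp_maf = meta["maf"].to_numpy(dtype=float)
    snp_imp = meta["imputed"].to_numpy(dtype=bool) \
        if "imputed" in meta.columns else np.zeros(len(meta), bool)
    snp_ids = np.array(genotypes.snp_ids)
    maf_ok = snp_maf >= maf_min

    best_rows = []
    full_rows = [] if keep_full else None
    for gi, gene in enumerate(adjusted.gene_ids):
        if gene not in genes.index:
            continue
        grow = genes.loc[gene]
        tssd_all = _signed_tss_distance(snp_pos, int(grow["tss"]),
                                        grow["strand"])
        if mode == "cis":
            elig = (snp_chrom == grow["chrom"]) & \
                (np.abs(tssd_all) < window) & maf_ok
        else:
            elig = (snp_chrom != grow["chrom"]) & maf_ok
        idx = np.flatnonzero(elig)
        if idx.size:
            G = D[:, idx]
            poly = G.std(axis=0) > 0
            idx = idx[poly]
        if idx.size == 0:
            best_rows.append({
                "gene_id": gene, "snp_id": None, "chrom": None,
                "pos": np.nan, "log10_bf": np.nan, "beta": np.nan,
                "se": np.nan, "t": np.nan, "p": np.nan, "maf": np.nan,
                "imputed": False, "tss_distance": np.nan,
            })
            continue
        log10_bf, beta, se, t, p = _scan_gene(Y[gi], D[:, idx], n, priors)
        # argmax with deterministic tie-break: bf desc, pos asc, id asc
        order = np.lexsort((snp_ids[idx], snp_pos[idx], -log10_bf))
        b = order[0]
        k = idx[b]
        best_rows.append({
            "gene_id": gene, "snp_id": snp_ids[k], "chrom": snp_chrom[k],
            "pos": int(snp_pos[k]), "log10_bf": float(log10_bf[b]),
            "beta": float(beta[b]), "se": float(se[b]), "t": float(t[b]),
            "p": float(p[b]), "maf": float(snp_maf[k]),
            "imputed": bool(snp_imp[k]),
            "tss_distance": int(tssd_all[k]),
        })
        if keep_full:
            for b2, k2 in enumerate(idx):
                full_rows.append({
                    "gene_id": gene, "snp_id": snp_ids[k2],
                    "chrom": snp_chrom[k2], "pos": int(snp_pos[k2]),
                    "log10_bf": float(log10_bf[b2]),
                    "beta": float(beta[b2]), "se": float(se[b2]),
                    "t": float(t[b2]), "p": float(p[b2]),
                    "maf": float(snp_maf[k2]),
                    "imputed": bool(snp_imp[k2]),
                    "tss_distance": int(tssd_all[k2]),
                })
    best = pd.DataFrame(best_rows).set_index("gene_id")
    full = pd.DataFrame(full_rows) if keep_full else None
    return ScanResult(best=best, mode=mode, full=full)


def cis_scan(
    adjusted: AdjustedPhenotypes,
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    window: int = 250_000,
    maf_min: float = 0.01,
    priors: BfPriorSpec | None = None,
    keep_full: bool = False,
) -> ScanResult:
    """Scan SNPs with |TSS distance| < ``window`` and MAF >= ``maf_min`` for
    every gene; record per-gene best associations by log10 BF.

    ``genes`` is a frame indexed by gene_id with columns chrom, tss, strand.
    Genes with no eligible SNP appear in the output with missing statistics.
    """
    return _run_scan(adjusted, genotypes, genes, "cis", window, maf_min,
                     priors or BfPriorSpec(), keep_full)


def trans_scan(
    adjusted: AdjustedPhenotypes,
    genotypes: GenotypeMatrix,
    genes: pd.DataFrame,
    maf_min: float = 0.01,
    priors: BfPriorSpec | None = None,
    keep_full: bool = False,
) -> ScanResult:
    """Genome-wide scan restricted to SNPs on other chromosomes than the
    gene (unlinked), recording the best trans association per gene."""
    return _run_scan(adjusted, genotypes, genes, "trans", 0, maf_min,
                     priors or BfPriorSpec(), keep_full)
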