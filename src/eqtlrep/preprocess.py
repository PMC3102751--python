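"""Genotype and expression quality control.

Implements the marker filters (call rate, Hardy-Weinberg exact test, minor
allele frequency), probe-to-probeset construction by hierarchical clustering,
in-probe polymorphism annotation, K-means sex confirmation, Dixon's outlier
test for arrays, and signed TSS-distance computation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .datatypes import ExpressionMatrix, GenotypeMatrix, QcReport, StudyPanel

__all__ = [
    "hwe_exact_test",
    "filter_genotypes",
    "infer_sex",
    "ProbeSnpAnnotation",
    "annotate_probe_snps",
    "ProbesetMap",
    "cluster_probes_to_probesets",
    "collapse_to_probesets",
    "dixon_outlier_flag",
    "tss_distance",
]


def hwe_exact_test(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact two-sided Hardy-Weinberg test on genotype counts.

    Conditional on the observed allele counts, the heterozygote count h has

        P(h) ∝ n! / (n_AA! n_AB! n_BB!) * 2**h

    over all h with the same parity as the rare-allele count.  The two-sided
    p-value sums P(h) over every h whose probability does not exceed that of
    the observed configuration.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("at least one genotype observation required")
    n_a = 2 * n_AA + n_AB
    n_b = 2 * n_BB + n_AB
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic: a single possible outcome

    def log_weight(h: int) -> float:
        # homozygote counts implied by h given fixed allele counts
        hom_rare = (rare - h) // 2
        hom_common = (max(n_a, n_b) - h) // 2
        return (
            h * math.log(2.0)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
        )

    hs = list(range(rare % 2, rare + 1, 2))
    logw = np.array([log_weight(h) for h in hs])
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    obs = probs[hs.index(n_AB)]
    # relative tolerance so float ties match exact-arithmetic enumeration
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def filter_genotypes(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.10,
    hwe_alpha: float = 0.001,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the marker filters in order: call rate -> HWE -> MAF.

    A SNP is counted against the first filter it fails.  The HWE exact test is
    applied only to hard-call (integer-dosage) SNPs; fractional (imputed)
    dosages are exempt.  Survivors are mean-imputed per SNP.
    """
    mask = g.mask if g.mask is not None else np.zeros(g.dosages.shape, bool)
    if mask.shape != g.dosages.shape:
        raise ValueError("missingness mask shape must match dosages")
    dos = np.where(mask, np.nan, g.dosages)
    n = g.n_samples

    removed_cr: list[str] = []
    removed_hwe: list[str] = []
    removed_maf: list[str] = []
    keep: list[str] = []
    imputed_flags = g.snp_meta["imputed"].to_numpy() \
        if "imputed" in g.snp_meta.columns else np.zeros(g.n_snps, bool)
    for k, snp in enumerate(g.snp_ids):
        col = dos[:, k]
        miss_frac = np.isnan(col).mean()
        if miss_frac > miss_max:
            removed_cr.append(snp)
            continue
        obs = col[~np.isnan(col)]
        hard_call = (not imputed_flags[k]) and np.allclose(obs, np.round(obs))
        if hard_call and len(obs):
            counts = np.bincount(np.round(obs).astype(int), minlength=3)
            if hwe_exact_test(int(counts[0]), int(counts[1]),
                              int(counts[2])) < hwe_alpha:
                removed_hwe.append(snp)
                continue
        p = obs.mean() / 2.0 if len(obs) else 0.0
        if min(p, 1 - p) < maf_min:
            removed_maf.append(snp)
            continue
        keep.append(snp)

    if not keep:
        raise ValueError("no SNPs survive quality-control filters")

    out = g.subset_snps(keep)
    kidx = [g.snp_ids.index(s) for s in keep]
    kept_dos = dos[:, kidx]
    col_means = np.nanmean(kept_dos, axis=0)
    filled = np.where(np.isnan(kept_dos), col_means, kept_dos)
    out.dosages = filled
    out.mask = np.isnan(kept_dos)
    p = filled.mean(axis=0) / 2.0
    out.snp_meta = out.snp_meta.copy()
    out.snp_meta["maf"] = np.minimum(p, 1 - p)
    report = QcReport(
        n_snps_in=g.n_snps,
        n_removed_callrate=len(removed_cr),
        n_removed_hwe=len(removed_hwe),
        n_removed_maf=len(removed_maf),
        n_snps_out=len(keep),
        removed_callrate=removed_cr,
        removed_hwe=removed_hwe,
        removed_maf=removed_maf,
        parameters={"maf_min": maf_min, "miss_max": miss_max,
                    "hwe_alpha": hwe_alpha},
    )
    return out, report


def infer_sex(
    panel: StudyPanel,
    y_linked_probes: list[str],
    x_linked_snps: list[str],
) -> pd.DataFrame:
    """Impute sample sex by 2-means clustering of Y-linked expression and
    X-linked heterozygosity; flag samples whose call disagrees with the
    annotation.

    Returns a frame indexed by sample with columns inferred_sex
    ('male'/'female'/'indeterminate'), annotated_sex, mismatch.
    """
    samples = panel.genotypes.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    features = []
    if y_linked_probes:
        expr = panel.expression.collapse_replicates()
        pidx = [expr.probe_ids.index(p) for p in y_linked_probes]
        col = {s: j for j, s in enumerate(expr.sample_ids)}
        y_mean = expr.values[pidx][:, [col[s] for s in samples]].mean(axis=0)
        features.append(y_mean)
    if x_linked_snps:
        sidx = [panel.genotypes.snp_ids.index(s) for s in x_linked_snps]
        het = (np.abs(panel.genotypes.dosages[:, sidx] - 1.0) < 0.5).mean(axis=1)
        features.append(het)
    if not features:
        raise ValueError("need Y-linked probes or X-linked SNPs")
    X = np.column_stack(features)

    annotated = panel.demographics.table.loc[samples, "sex"].to_numpy()
    if np.allclose(X.std(axis=0), 0):
        return pd.DataFrame(
            {"inferred_sex": "indeterminate", "annotated_sex": annotated,
             "mismatch": True},
            index=pd.Index(samples, name="sample_id"),
        )
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(Xs)
    labels = km.labels_
    if y_linked_probes:
        key = features[0]  # higher Y expression cluster -> male
        male_cluster = int(key[labels == 1].mean() > key[labels == 0].mean())
    else:
        key = features[-1]  # lower X heterozygosity cluster -> male
        male_cluster = int(key[labels == 1].mean() < key[labels == 0].mean())
    inferred = np.where(labels == male_cluster, "male", "female")
    return pd.DataFrame(
        {"inferred_sex": inferred, "annotated_sex": annotated,
         "mismatch": inferred != annotated},
        index=pd.Index(samples, name="sample_id"),
    )


@dataclass
class ProbeSnpAnnotation:
    """Per-probe in-probe variant lists and counts.

    ``hits`` maps probe_id to a list of (variant_id, offset from the probe's
    5' end in bp, (ref, alt)); ``n_probe_snps`` gives the count per probe.
    """

    hits: dict[str, list[tuple[str, int, tuple[str, str]]]]
    n_probe_snps: pd.Series


def annotate_probe_snps(
    probes: pd.DataFrame,
    variants: pd.DataFrame,
    flank: int = 0,
) -> ProbeSnpAnnotation:
    """Overlap-join probes (0-based half-open intervals with strand) against a
    variant catalog (VCF-style 1-based ``pos``).

    Offsets are measured from the probe's 5' end: the leftmost base for +
    strand probes, the rightmost for - strand.  ``flank`` extends each probe
    interval on both sides.
    """
    for col in ("chrom", "start", "end", "strand"):
        if col not in probes.columns:
            raise ValueError(f"probes frame needs column {col!r}")
    for col in ("chrom", "pos"):
        if col not in variants.columns:
            raise ValueError(f"variants frame needs column {col!r}")
    pchroms = set(probes["chrom"])
    vchroms = set(variants["chrom"])
    if len(probes) and len(variants) and not (pchroms & vchroms):
        raise ValueError(
            f"no shared chromosome names between probes {sorted(pchroms)[:5]} "
            f"and variants {sorted(vchroms)[:5]}"
        )

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in variants.groupby("chrom"):
        tree = IntervalTree()
        for vid, row in sub.iterrows():
            start0 = int(row["pos"]) - 1  # VCF 1-based -> 0-based point
            ref = row.get("ref", "N")
            alt = row.get("alt", "N")
            tree.addi(start0, start0 + 1, (str(vid), ref, alt))
        trees[chrom] = tree

    hits: dict[str, list[tuple[str, int, tuple[str, str]]]] = {}
    for probe_id, row in probes.iterrows():
        found = []
        tree = trees.get(row["chrom"])
        if tree is not None:
            lo = int(row["start"]) - flank
            hi = int(row["end"]) + flank
            for iv in sorted(tree.overlap(lo, hi)):
                vpos0 = iv.begin
                if row["strand"] == "-":
                    offset = (int(row["end"]) - 1) - vpos0
                else:
                    offset = vpos0 - int(row["start"])
                vid, ref, alt = iv.data
                found.append((vid, int(offset), (ref, alt)))
        hits[str(probe_id)] = found
    counts = pd.Series(
        {p: len(v) for p, v in hits.items()}, name="n_probe_snps"
    ).reindex([str(p) for p in probes.index])
    return ProbeSnpAnnotation(hits=hits, n_probe_snps=counts)


@dataclass
class ProbesetMap:
    """Partition of probes into co-correlated probesets.

    ``members`` maps probeset_id to the ordered probe list; ``gene_of`` maps
    probeset_id to gene_id; ``min_internal_r`` records the minimum pairwise
    Pearson correlation within each multi-probe probeset.
    """

    members: dict[str, list[str]]
    gene_of: dict[str, str]
    min_internal_r: dict[str, float]


def cluster_probes_to_probesets(
    expr: ExpressionMatrix, gene_map: dict[str, str] | None = None
) -> ProbesetMap:
    """Group each gene's probes by complete-linkage clustering with distance
    1 - Pearson r, cutting the dendrogram at height 0.5.

    Complete linkage at cut height 0.5 guarantees every within-probeset
    pairwise correlation is >= 0.5.  Zero-variance probes become singleton
    probesets with a warning.
    """
    if expr.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to correlate probes")
    if gene_map is None:
        gene_map = dict(zip(expr.probe_ids, expr.probe_meta["gene_id"]))
    by_gene: dict[str, list[str]] = {}
    for p in expr.probe_ids:
        by_gene.setdefault(gene_map[p], []).append(p)

    members: dict[str, list[str]] = {}
    gene_of: dict[str, str] = {}
    min_r: dict[str, float] = {}
    ridx = {p: i for i, p in enumerate(expr.probe_ids)}
    for gene, probes in by_gene.items():
        vals = expr.values[[ridx[p] for p in probes]]
        sd = vals.std(axis=1)
        flat = [p for p, s in zip(probes, sd) if s == 0]
        live = [p for p, s in zip(probes, sd) if s > 0]
        if flat:
            warnings.warn(
                f"gene {gene}: {len(flat)} constant probe(s) assigned "
                "singleton probesets"
            )
        cluster_lists: list[list[str]] = [[p] for p in flat]
        if len(live) == 1:
            cluster_lists.append(live)
        elif len(live) > 1:
            lv = expr.values[[ridx[p] for p in live]]
            r = np.corrcoef(lv)
            d = np.clip(1.0 - r, 0.0, 2.0)
            np.fill_diagonal(d, 0.0)
            Z = linkage(squareform(d, checks=False), method="complete")
            labels = fcluster(Z, t=0.5, criterion="distance")
            for lab in np.unique(labels):
                cluster_lists.append(
                    [p for p, l in zip(live, labels) if l == lab])
        for ci, plist in enumerate(sorted(cluster_lists)):
            ps_id = f"{gene}_ps{ci}"
            members[ps_id] = plist
            gene_of[ps_id] = gene
            if len(plist) > 1:
                sub = np.corrcoef(expr.values[[ridx[p] for p in plist]])
                min_r[ps_id] = float(sub[np.triu_indices_from(sub, 1)].min())
            else:
                min_r[ps_id] = 1.0
    return ProbesetMap(members=members, gene_of=gene_of, min_internal_r=min_r)


def collapse_to_probesets(
    expr: ExpressionMatrix, pmap: ProbesetMap
) -> ExpressionMatrix:
    """Summarize each probeset as the per-column mean of its member probes."""
    ridx = {p: i for i, p in enumerate(expr.probe_ids)}
    ps_ids = sorted(pmap.members)
    values = np.vstack([
        expr.values[[ridx[p] for p in pmap.members[ps]]].mean(axis=0)
        for ps in ps_ids
    ])
    meta_rows = []
    for ps in ps_ids:
        first = expr.probe_meta.loc[pmap.members[ps][0]]
        n_ps = int(expr.probe_meta.loc[pmap.members[ps], "n_probe_snps"].sum()) \
            if "n_probe_snps" in expr.probe_meta.columns else 0
        meta_rows.append({
            "gene_id": pmap.gene_of[ps], "exon_id": first.get("exon_id", ""),
            "chrom": first["chrom"], "start": first["start"],
            "end": first["end"], "strand": first["strand"],
            "n_probe_snps": n_ps, "n_probes": len(pmap.members[ps]),
        })
    return ExpressionMatrix(
        probe_ids=ps_ids,
        sample_ids=list(expr.sample_ids),
        values=values,
        probe_meta=pd.DataFrame(meta_rows, index=ps_ids),
        replicate_ids=expr.replicate_ids,
    )


# One-sided alpha = 0.05 critical values for Dixon's r10 (Q) statistic,
# n = 3..30 (classical table; equals the two-tailed 10% column).
_DIXON_Q_05 = {
    3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468, 9: 0.437,
    10: 0.412, 11: 0.392, 12: 0.376, 13: 0.361, 14: 0.349, 15: 0.338,
    16: 0.329, 17: 0.320, 18: 0.313, 19: 0.306, 20: 0.300, 21: 0.295,
    22: 0.290, 23: 0.285, 24: 0.281, 25: 0.277, 26: 0.273, 27: 0.269,
    28: 0.266, 29: 0.263, 30: 0.260,
}


def dixon_outlier_flag(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Dixon's Q (r10) outlier test applied to both tails of one per-array
    metric; returns a boolean flag per array.

    For n < 4 the test is not applied (no flags).  For n > 30 the critical
    value is held at the n = 30 entry, a conservative fallback beyond the
    classical table.  Only alpha = 0.05 is tabulated.
    """
    if alpha != 0.05:
        raise ValueError("only alpha = 0.05 critical values are tabulated")
    x = np.asarray(values, dtype=float)
    n = len(x)
    flags = np.zeros(n, dtype=bool)
    if n < 4:
        return flags
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    rng_ = xs[-1] - xs[0]
    if rng_ == 0:
        return flags
    crit = _DIXON_Q_05.get(n, _DIXON_Q_05[30])
    q_low = (xs[1] - xs[0]) / rng_
    q_high = (xs[-1] - xs[-2]) / rng_
    if q_low > crit:
        flags[order[0]] = True
    if q_high > crit:
        flags[order[-1]] = True
    return flags


def tss_distance(snp_pos: int, tss: int, strand: str,
                 snp_chrom: str | None = None,
                 gene_chrom: str | None = None) -> int:
    """Signed SNP-to-TSS distance: negative means 5' of the gene in its
    transcriptional orientation."""
    if snp_chrom is not None and gene_chrom is not None \
            and snp_chrom != gene_chrom:
        raise ValueError(
            f"TSS distance undefined across chromosomes "
            f"({snp_chrom} vs {gene_chrom})"
        )
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    return snp_pos - tss if strand == "+" else tss - snp_pos
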