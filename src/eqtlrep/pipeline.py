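"""End-to-end orchestration: simulate -> QC -> adjust -> scan -> replicate.

`run_pipeline` executes the full discovery/replication analysis on synthetic
panels (or panels supplied by the caller), with one panel acting as the
discovery cohort and the remaining panels as replication sets, and returns a
JSON-serializable report of the headline quantities: discovery counts at the
Bayes-factor threshold, per-panel / either / both replication rates,
concordance rates with their false-positive adjustment, matched-resampling
baseline rates, and the determinant model.  Every output carries the config
hash, and outputs are a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .covariates import (
    AdjustedPhenotypes,
    CovariateModelSpec,
    build_design,
    estimate_surrogate_variables,
    fit_covariate_model,
    quantile_normal_transform,
)
from .datatypes import StudyPanel, TruthTable
from .preprocess import annotate_probe_snps, filter_genotypes
from .replication import (
    assess_replication,
    concordance_adjustment,
    effect_correlation,
    matched_resample,
    probe_artifact_attribution,
    replication_determinants,
    replication_rate_curve,
    replication_stats,
    resampling_baseline,
)
from .scan import BfPriorSpec, cis_scan, trans_scan
from .synthdata import SimulationConfig, SnpLayout, simulate_multi_study

__all__ = ["PipelineConfig", "PipelineResult", "adjust_panel",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study's canonical defaults."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    discovery_panel: str = "panel1"
    cis_window: int = 250_000
    maf_min: float = 0.01
    miss_max: float = 0.10
    hwe_alpha: float = 0.001
    p_thresh: float = 0.05
    bf_threshold: float = 5.0
    bf_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0)
    fdr: float = 0.05
    prior_sigma_a: tuple[float, ...] = (0.05, 0.2, 0.4)
    use_sva: bool = True
    compare_sva: bool = False
    sva_n_perm: int = 50
    sva_alpha: float = 0.05
    quantile_transform: bool = True
    run_trans: bool = False
    run_resampling: bool = True
    n_resample_sets: int = 100
    age_tol: float = 3.0
    reporter_alpha: float = 0.001
    outdir: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: dict
    manifest: dict
    records: pd.DataFrame | None
    curves: pd.DataFrame | None
    scans: dict[str, pd.DataFrame]
    panels: list[StudyPanel]
    truth: TruthTable | None
    layout: SnpLayout | None


def adjust_panel(
    panel: StudyPanel,
    config: PipelineConfig,
    use_sva: bool | None = None,
    seed: int = 0,
) -> AdjustedPhenotypes:
    """Produce residual phenotypes for one panel.

    Fits the demographic fixed-effect model, optionally estimates surrogate
    variables on its residuals and refits with them, then (optionally)
    applies the within-population inverse-normal transform to the residuals
    of panels with more than one population.
    """
    use_sva = config.use_sva if use_sva is None else use_sva
    base_spec = CovariateModelSpec()
    adjusted = fit_covariate_model(panel.expression, panel.demographics,
                                   base_spec)
    if use_sva:
        X, _ = build_design(panel.demographics, adjusted.sample_ids,
                            base_spec)
        svs = estimate_surrogate_variables(
            adjusted.residuals, known_covariates=X[:, 1:],
            n_perm=config.sva_n_perm, alpha=config.sva_alpha, seed=seed,
        )
        if svs.shape[1]:
            adjusted = fit_covariate_model(
                panel.expression, panel.demographics,
                CovariateModelSpec(surrogate_variables=svs),
            )
    if config.quantile_transform:
        pops = panel.demographics.table.loc[
            adjusted.sample_ids, "population"].to_numpy()
        counts = pd.Series(pops).value_counts()
        if (counts < 2).any():
            # singleton populations cannot be rank-transformed on their own
            pops = np.full(len(pops), "all")
        if len(set(pops)) > 1 or pops[0] == "all":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                adjusted.residuals = np.vstack([
                    quantile_normal_transform(row, pops)
                    for row in adjusted.residuals
                ])
            adjusted.transformed = True
    return adjusted


def _gene_determinants(panel: StudyPanel, genes: pd.DataFrame,
                       best: pd.DataFrame) -> pd.DataFrame:
    """Per-gene covariates used in the determinant models."""
    expr = panel.expression.collapse_replicates()
    by_gene: dict[str, list[int]] = {}
    for i, p in enumerate(expr.probe_ids):
        by_gene.setdefault(expr.probe_meta["gene_id"][p], []).append(i)
    variants = panel.genotypes.snp_meta.reset_index(names="snp_id").set_index(
        "snp_id")[["chrom", "pos", "ref", "alt"]]
    ann = annotate_probe_snps(
        panel.expression.probe_meta[["chrom", "start", "end", "strand"]],
        variants,
    )
    probe_gene = panel.expression.probe_meta["gene_id"]
    ps_per_gene = ann.n_probe_snps.groupby(
        [probe_gene[p] for p in ann.n_probe_snps.index]).sum()
    rows = []
    for gene in best.index:
        idx = by_gene.get(gene, [])
        vals = expr.values[idx] if idx else np.zeros((0, 1))
        mean_e = float(vals.mean()) if vals.size else np.nan
        sd_e = float(vals.mean(axis=0).std()) if vals.size else np.nan
        rows.append({
            "gene_id": gene,
            "mean_expression": mean_e,
            "expression_cv": sd_e / abs(mean_e) if mean_e else np.nan,
            "probe_snps": int(ps_per_gene.get(gene, 0)),
            "abs_tss_distance": abs(best.loc[gene, "tss_distance"])
            if pd.notna(best.loc[gene, "tss_distance"]) else np.nan,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def _scan_and_replicate(
    panels: list[StudyPanel],
    adjusted: dict[str, AdjustedPhenotypes],
    genes: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Cis scans per panel plus replication records for the discovery set."""
    priors = BfPriorSpec(sigma_a=config.prior_sigma_a)
    by_name = {p.name: p for p in panels}
    scans = {
        name: cis_scan(adjusted[name], by_name[name].genotypes, genes,
                       window=config.cis_window, maf_min=config.maf_min,
                       priors=priors).best
        for name in adjusted
    }
    disc = config.discovery_panel
    best = scans[disc].dropna(subset=["snp_id"])
    rep_panels = {
        name: replication_stats(best, adjusted[name],
                                by_name[name].genotypes)
        for name in adjusted if name != disc
    }
    records = assess_replication(best, rep_panels, p_thresh=config.p_thresh)
    det = _gene_determinants(by_name[disc], genes, best)
    records = records.join(det)
    curves = replication_rate_curve(records, np.asarray(config.bf_grid),
                                    list(rep_panels))
    return records, curves, scans


def _headline(records: pd.DataFrame, config: PipelineConfig,
              truth: TruthTable | None, rep_names: list[str]) -> dict:
    t = config.bf_threshold
    above = records[(records["log10_bf"] > t) & ~records["indeterminate"]]
    out: dict = {"n_discoveries_bf": int(len(above))}
    if truth is not None:
        true_cis = set(truth.genes.index[truth.genes["var_frac_cis"] > 0])
        out["n_discoveries_bf_true"] = int(
            sum(g in true_cis for g in above.index))
    for name in rep_names:
        sub = above[above[f"tested_{name}"]]
        out[f"replication_rate_{name}"] = (
            float(sub[f"replicated_{name}"].mean()) if len(sub) else None)
        conc = float(sub[f"concordant_{name}"].mean()) if len(sub) else None
        out[f"concordance_rate_{name}"] = conc
        out[f"adjusted_concordance_{name}"] = (
            concordance_adjustment(conc, "single_panel")
            if conc is not None else None)
        try:
            out[f"spearman_{name}"] = effect_correlation(above, name)
        except ValueError:
            out[f"spearman_{name}"] = None
    both = above[above["tested_all"]]
    if len(both):
        out["n_replicated_either"] = int(both["replicated_either"].sum())
        out["n_replicated_both"] = int(both["replicated_both"].sum())
        out["replication_rate_either"] = float(
            both["replicated_either"].mean())
        out["replication_rate_both"] = float(both["replicated_both"].mean())
        conc_e = float(both["concordant_either"].mean())
        out["concordance_rate_either"] = conc_e
        out["adjusted_concordance_either"] = concordance_adjustment(
            conc_e, "either_of_two")
    return out


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full synthetic discovery/replication analysis."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.sim.seed)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.sim.seed,
        "stages": {},
    }

    panels, truth, layout = simulate_multi_study(config.sim)
    genes = layout.genes
    manifest["stages"]["simulate"] = {
        "panels": [p.name for p in panels],
        "panel_sizes": [p.n_samples for p in panels],
        "n_genes": len(genes), "n_snps": len(layout.snps),
    }

    # genotype QC per panel
    qc_counts = {}
    for i, p in enumerate(panels):
        filtered, report = filter_genotypes(
            p.genotypes, maf_min=config.maf_min, miss_max=config.miss_max,
            hwe_alpha=config.hwe_alpha,
        )
        panels[i] = StudyPanel(name=p.name, genotypes=filtered,
                               expression=p.expression,
                               demographics=p.demographics,
                               platform=p.platform)
        qc_counts[p.name] = {
            "n_in": report.n_snps_in, "n_out": report.n_snps_out,
            "removed_callrate": report.n_removed_callrate,
            "removed_hwe": report.n_removed_hwe,
            "removed_maf": report.n_removed_maf,
        }
    manifest["stages"]["qc"] = qc_counts

    variants = [config.use_sva] if not config.compare_sva \
        else [True, False]
    results_by_sva: dict[bool, dict] = {}
    records = curves = None
    scans: dict[str, pd.DataFrame] = {}
    rep_names = [p.name for p in panels if p.name != config.discovery_panel]
    for use_sva in variants:
        adjusted = {
            p.name: adjust_panel(p, config, use_sva=use_sva,
                                 seed=int(rng.integers(2 ** 31)))
            for p in panels
        }
        rec, cur, sc = _scan_and_replicate(panels, adjusted, genes, config)
        head = _headline(rec, config, truth, rep_names)
        results_by_sva[use_sva] = {"headline": head, "records": rec,
                                   "curves": cur, "scans": sc,
                                   "adjusted": adjusted}
        if use_sva == config.use_sva:
            records, curves, scans = rec, cur, sc
    main = results_by_sva[config.use_sva]
    manifest["stages"]["adjust"] = {
        p.name: int(main["adjusted"][p.name].n_svs) for p in panels
    }
    manifest["stages"]["scan"] = {
        name: int(sc.dropna(subset=["snp_id"]).shape[0])
        for name, sc in scans.items()
    }

    report: dict = {"config_hash": config.config_hash(),
                    "seed": config.sim.seed}
    report.update(main["headline"])
    if config.compare_sva:
        report["sva_comparison"] = {
            "sva_on": results_by_sva[True]["headline"],
            "sva_off": results_by_sva[False]["headline"],
        }

    # matched resampling baseline against the smallest replication panel
    if config.run_resampling and rep_names:
        disc_panel = next(p for p in panels
                          if p.name == config.discovery_panel)
        target_panel = min(
            (p for p in panels if p.name != config.discovery_panel),
            key=lambda p: p.n_samples,
        )
        try:
            sets = matched_resample(
                disc_panel.demographics, target_panel.demographics,
                n_sets=config.n_resample_sets, age_tol=config.age_tol,
                seed=int(rng.integers(2 ** 31)),
            )
            best = scans[config.discovery_panel].dropna(subset=["snp_id"])
            baseline = resampling_baseline(
                main["adjusted"][config.discovery_panel],
                disc_panel.genotypes, best, sets,
                p_thresh=config.p_thresh,
            )
            sim_rate = baseline.simulated_rate(
                np.asarray(config.bf_grid))
            at_t = sim_rate[sim_rate["threshold"] == config.bf_threshold]
            report["baseline_rate_at_bf"] = (
                float(at_t["rate"].iloc[0]) if len(at_t) else None)
            report["baseline_n_sets"] = baseline.n_resamples
        except ValueError as exc:
            report["baseline_skipped"] = str(exc)

    # determinants of replication
    try:
        det = replication_determinants(records, bf_min=config.bf_threshold)
        report["determinants"] = {
            "terms": det["terms"], "n": det["n"],
            "lrt_p": {t: v["p"] for t, v in det["lrt"].items()},
        }
    except (ValueError, KeyError) as exc:
        report["determinants_skipped"] = str(exc)
    try:
        attr = probe_artifact_attribution(records)
        report["probe_artifact"] = {
            "interaction_p": attr["interaction_p"],
            "strata": attr["strata"].to_dict(orient="records"),
        }
    except ValueError as exc:
        report["probe_artifact_skipped"] = str(exc)

    if config.run_trans:
        priors = BfPriorSpec(sigma_a=config.prior_sigma_a)
        disc_panel = next(p for p in panels
                          if p.name == config.discovery_panel)
        tr = trans_scan(main["adjusted"][config.discovery_panel],
                        disc_panel.genotypes, genes,
                        maf_min=config.maf_min, priors=priors)
        report["n_trans_bf"] = int(
            (tr.best["log10_bf"] > config.bf_threshold).sum())
        scans["trans"] = tr.best

    if config.outdir:
        _write_outputs(Path(config.outdir), config, report, manifest,
                       records, curves, panels)
    return PipelineResult(
        report=report, manifest=manifest, records=records, curves=curves,
        scans=scans, panels=panels, truth=truth, layout=layout,
    )


def _write_outputs(outdir: Path, config: PipelineConfig, report: dict,
                   manifest: dict, records: pd.DataFrame | None,
                   curves: pd.DataFrame | None,
                   panels: list[StudyPanel]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    for name, df in (("records", records), ("curves", curves)):
        if df is not None:
            with open(outdir / f"{name}.tsv", "w") as fh:
                fh.write(f"# config_hash={h}\n")
                df.to_csv(fh, sep="\t")
    for p in panels:
        eio.write_genotypes_vcf(p.genotypes, outdir / f"{p.name}.vcf")
        eio.write_expression_tsv(p.expression,
                                 outdir / f"{p.name}.expression.tsv")
        eio.write_demographics_tsv(p.demographics,
                                   outdir / f"{p.name}.demographics.tsv")
        eio.write_probes_bed(p.expression.probe_meta,
                             outdir / f"{p.name}.probes.bed")
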