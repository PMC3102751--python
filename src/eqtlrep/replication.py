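"""Cross-panel replication assessment and its diagnostics.

A discovery association replicates in an independent panel when the same SNP
shows a nominally significant coefficient (p < 0.05) with a concordant
direction.  This module builds replication records from per-panel scan
statistics, computes replication-rate curves over Bayes-factor thresholds,
applies the concordance-only false-positive adjustment, constructs
demographically matched resampling baselines and winner's-curse tables,
models the determinants of replication by (stepwise) logistic regression,
and attributes non-replication to in-probe hybridization artifacts.

Null behaviour worth keeping in mind: a true-null discovery replicates with
probability 0.05 * 1/2 = 0.025 per panel under the full criterion and is
direction-concordant with probability 1/2 (single panel) or 3/4 (either of
two panels) — the concordance adjustment inverts exactly these rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .covariates import AdjustedPhenotypes
from .datatypes import Demographics, GenotypeMatrix
from .scan import single_snp_lm

__all__ = [
    "replication_stats",
    "assess_replication",
    "replication_rate_curve",
    "concordance_adjustment",
    "matched_resample",
    "ResamplingBaseline",
    "resampling_baseline",
    "winners_curse_analysis",
    "replication_determinants",
    "enrichment_hypergeometric",
    "effect_correlation",
    "probe_artifact_attribution",
]


def replication_stats(
    discovery_best: pd.DataFrame,
    adjusted: AdjustedPhenotypes,
    genotypes: GenotypeMatrix,
) -> pd.DataFrame:
    """Re-test each discovery best SNP in a replication panel.

    Returns a frame indexed by gene with columns beta, p, tested.  A record
    is tested = False when the SNP is absent from the panel or monomorphic
    there, or the gene is not measured.
    """
    gene_pos = {g: i for i, g in enumerate(adjusted.gene_ids)}
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
    shared = [s for s in adjusted.sample_ids
              if s in set(genotypes.sample_ids)]
    a_idx = [adjusted.sample_ids.index(s) for s in shared]
    g_idx = [genotypes.sample_ids.index(s) for s in shared]
    rows = []
    for gene, row in discovery_best.iterrows():
        snp = row["snp_id"]
        if snp is None or (isinstance(snp, float) and np.isnan(snp)) \
                or gene not in gene_pos or snp not in snp_pos:
            rows.append({"gene_id": gene, "beta": np.nan, "p": np.nan,
                         "tested": False})
            continue
        y = adjusted.residuals[gene_pos[gene]][a_idx]
        g = genotypes.dosages[g_idx, snp_pos[snp]]
        if g.std() == 0:
            rows.append({"gene_id": gene, "beta": np.nan, "p": np.nan,
                         "tested": False})
            continue
        beta, _, _, p = single_snp_lm(y, g)
        rows.append({"gene_id": gene, "beta": beta, "p": p, "tested": True})
    return pd.DataFrame(rows).set_index("gene_id")


def assess_replication(
    discovery: pd.DataFrame,
    panels: dict[str, pd.DataFrame],
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Join discovery statistics with per-panel replication statistics and
    derive replication flags.

    ``discovery`` is indexed by gene with columns snp_id, log10_bf, beta, p;
    each panel frame is indexed by gene with columns beta, p, tested.
    A record replicates in a panel iff p < ``p_thresh`` (strict) and the
    coefficient signs agree.  Concordance-only flags (sign agreement alone)
    are recorded too.  'Either'/'both' flags are computed only over records
    tested in all panels so their denominators match.  Discoveries with an
    exactly zero coefficient are flagged indeterminate and excluded.
    """
    rec = discovery.rename(columns={"beta": "beta_d", "p": "p_d"}).copy()
    rec["indeterminate"] = rec["beta_d"] == 0
    sign_d = np.sign(rec["beta_d"])
    names = list(panels)
    for name in names:
        panel = panels[name].reindex(rec.index)
        tested = panel["tested"].fillna(False).astype(bool) \
            & ~rec["indeterminate"]
        agree = np.sign(panel["beta"]) == sign_d
        rec[f"beta_{name}"] = panel["beta"]
        rec[f"p_{name}"] = panel["p"]
        rec[f"tested_{name}"] = tested
        rec[f"replicated_{name}"] = (
            tested & agree & (panel["p"] < p_thresh)
        ).fillna(False)
        rec[f"concordant_{name}"] = (tested & agree).fillna(False)
    tested_all = np.logical_and.reduce(
        [rec[f"tested_{n}"] for n in names]
    ) if names else np.zeros(len(rec), bool)
    rec["tested_all"] = tested_all
    rep_cols = [rec[f"replicated_{n}"] for n in names]
    con_cols = [rec[f"concordant_{n}"] for n in names]
    rec["replicated_either"] = tested_all & np.logical_or.reduce(rep_cols)
    rec["replicated_both"] = tested_all & np.logical_and.reduce(rep_cols)
    rec["concordant_either"] = tested_all & np.logical_or.reduce(con_cols)
    rec["concordant_both"] = tested_all & np.logical_and.reduce(con_cols)
    return rec


def replication_rate_curve(
    records: pd.DataFrame,
    bf_grid: np.ndarray,
    panel_names: list[str],
) -> pd.DataFrame:
    """Replication rate as a function of discovery log10 BF threshold.

    One row per (threshold, scope) with scope in the panel names plus
    'either' and 'both'.  Rates over empty strata are reported missing.
    """
    scopes = {n: (f"tested_{n}", f"replicated_{n}") for n in panel_names}
    scopes["either"] = ("tested_all", "replicated_either")
    scopes["both"] = ("tested_all", "replicated_both")
    rows = []
    ok = ~records["indeterminate"]
    for t in np.asarray(bf_grid, float):
        above = ok & (records["log10_bf"] >= t)
        for scope, (tcol, rcol) in scopes.items():
            elig = above & records[tcol]
            n_elig = int(elig.sum())
            n_rep = int((elig & records[rcol]).sum())
            rate = n_rep / n_elig if n_elig else np.nan
            se = np.sqrt(rate * (1 - rate) / n_elig) if n_elig else np.nan
            rows.append({"threshold": t, "scope": scope,
                         "n_eligible": n_elig, "n_replicated": n_rep,
                         "rate": rate, "se": se})
    return pd.DataFrame(rows)


def concordance_adjustment(
    concordance: float, scheme: str = "single_panel"
) -> float:
    """Adjust a raw direction-concordance rate for the chance concordance of
    false positives.

    Half of all false positives are direction-concordant in one replication
    panel, and three quarters in at least one of two panels, so

        single_panel : adjusted = 1 - 2 * (1 - c)
        either_of_two: adjusted = 1 - 4 * (1 - c)

    floored at 0.  E.g. c = 0.80 single-panel -> 0.60; c = 0.90 under the
    either-of-two standard -> 0.60.
    """
    if not 0 <= concordance <= 1:
        raise ValueError("concordance must lie in [0, 1]")
    if scheme == "single_panel":
        adj = 1.0 - 2.0 * (1.0 - concordance)
    elif scheme == "either_of_two":
        adj = 1.0 - 4.0 * (1.0 - concordance)
    else:
        raise ValueError("scheme must be 'single_panel' or 'either_of_two'")
    return max(adj, 0.0)


def matched_resample(
    source: Demographics,
    target: Demographics,
    n_sets: int = 100,
    age_tol: float = 3.0,
    seed: int = 0,
    max_restarts: int = 1000,
) -> list[list[str]]:
    """Draw demographically matched subsets of the source panel.

    Each of the ``n_sets`` sets contains one distinct source individual per
    target individual, matched on sex, population and age within
    +/- ``age_tol`` years, sampled without replacement within a set (draws
    are independent across sets).  An infeasible target row raises with the
    row named; partial sets are never returned.
    """
    rng = np.random.default_rng(seed)
    src = source.table
    tgt = target.table
    eligible: dict[str, list[str]] = {}
    for sid, row in tgt.iterrows():
        ok = src[
            (src["sex"] == row["sex"])
            & (src["population"] == row["population"])
            & ((src["age"] - row["age"]).abs() <= age_tol)
        ]
        if ok.empty:
            raise ValueError(
                f"target sample {sid!r} (sex={row['sex']}, "
                f"population={row['population']}, age={row['age']}) has no "
                f"eligible match in the source panel"
            )
        eligible[sid] = list(ok.index)
    sets: list[list[str]] = []
    order = list(tgt.index)
    for _ in range(n_sets):
        for attempt in range(max_restarts):
            used: set[str] = set()
            chosen: list[str] = []
            perm = rng.permutation(len(order))
            failed = False
            for k in perm:
                cands = [c for c in eligible[order[k]] if c not in used]
                if not cands:
                    failed = True
                    break
                pick = cands[rng.integers(len(cands))]
                used.add(pick)
                chosen.append(pick)
            if not failed:
                sets.append(chosen)
                break
        else:
            raise ValueError(
                "could not build a matched set without replacement; "
                "source panel too small for the target demographics"
            )
    return sets


@dataclass
class ResamplingBaseline:
    """Per-gene, per-resample replication outcomes against the full panel.

    ``table`` has one row per (gene, resample) with columns log10_bf,
    beta_full, beta_sub, p_sub, replicated, ratio (beta_full / beta_sub),
    skipped (monomorphic subset).  ``n_resamples`` is the configured count.
    """

    table: pd.DataFrame
    n_resamples: int

    def simulated_rate(self, bf_grid: np.ndarray) -> pd.DataFrame:
        """Simulated replication rate among resamples at each BF threshold."""
        rows = []
        t_ok = self.table[~self.table["skipped"]]
        for t in np.asarray(bf_grid, float):
            sub = t_ok[t_ok["log10_bf"] >= t]
            n = len(sub)
            rate = sub["replicated"].mean() if n else np.nan
            rows.append({"threshold": t, "n": n, "rate": rate})
        return pd.DataFrame(rows)


def resampling_baseline(
    adjusted: AdjustedPhenotypes,
    genotypes: GenotypeMatrix,
    discovery_best: pd.DataFrame,
    sample_sets: list[list[str]],
    p_thresh: float = 0.05,
) -> ResamplingBaseline:
    """Recompute each discovery coefficient on matched subsets and score
    replication against the full-panel effect.

    Covariate residuals are held fixed from the full panel (surrogate
    variables are not re-estimated per subset).  Replication within a
    resample means a concordant sign and p < ``p_thresh``.  Subsets where
    the SNP is monomorphic are skipped and counted.
    """
    gene_pos = {g: i for i, g in enumerate(adjusted.gene_ids)}
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
    col_of = {s: j for j, s in enumerate(adjusted.sample_ids)}
    grow_of = {s: j for j, s in enumerate(genotypes.sample_ids)}
    set_cols = [np.array([col_of[s] for s in ss]) for ss in sample_sets]
    set_rows = [np.array([grow_of[s] for s in ss]) for ss in sample_sets]
    rows = []
    for gene, drow in discovery_best.iterrows():
        snp = drow["snp_id"]
        if snp is None or (isinstance(snp, float) and np.isnan(snp)) \
                or gene not in gene_pos or snp not in snp_pos:
            continue
        y_full = adjusted.residuals[gene_pos[gene]]
        g_full = genotypes.dosages[:, snp_pos[snp]]
        beta_full = drow["beta"]
        for si, (ci, ri) in enumerate(zip(set_cols, set_rows)):
            g = g_full[ri]
            if g.std() == 0:
                rows.append({
                    "gene_id": gene, "resample": si,
                    "log10_bf": drow["log10_bf"], "beta_full": beta_full,
                    "beta_sub": np.nan, "p_sub": np.nan,
                    "replicated": False, "ratio": np.nan, "skipped": True,
                })
                continue
            beta, _, _, p = single_snp_lm(y_full[ci], g)
            rep = (p < p_thresh) and (np.sign(beta) == np.sign(beta_full))
            ratio = beta_full / beta if beta != 0 else np.inf
            rows.append({
                "gene_id": gene, "resample": si,
                "log10_bf": drow["log10_bf"], "beta_full": beta_full,
                "beta_sub": beta, "p_sub": p, "replicated": bool(rep),
                "ratio": ratio, "skipped": False,
            })
    return ResamplingBaseline(
        table=pd.DataFrame(rows), n_resamples=len(sample_sets)
    )


def winners_curse_analysis(
    baseline: ResamplingBaseline,
    ratio_bins: np.ndarray | None = None,
    bf_strata: tuple[float, ...] = (0.0, 5.0, 10.0),
) -> pd.DataFrame:
    """Replication rate per full/resampled coefficient-ratio bin.

    A ratio above 1 means the full-data coefficient exceeds the resampled one
    (the resample simulates effect-size shrinkage).  Sign-flipped resampled
    coefficients (ratio < 0) are binned separately.  Rows per BF-threshold
    stratum; empty bins reported missing.
    """
    if ratio_bins is None:
        ratio_bins = np.array([0.5, 0.8, 1.0, 1.25, 2.0, 4.0])
    tab = baseline.table[~baseline.table["skipped"]].copy()
    rows = []
    for t in bf_strata:
        sub = tab[tab["log10_bf"] >= t]
        flipped = sub[sub["ratio"] < 0]
        if len(flipped):
            rows.append({
                "bf_min": t, "ratio_lo": -np.inf, "ratio_hi": 0.0,
                "n": len(flipped), "rate": flipped["replicated"].mean(),
            })
        pos = sub[sub["ratio"] >= 0]
        edges = np.concatenate([[0.0], ratio_bins, [np.inf]])
        for lo, hi in zip(edges[:-1], edges[1:]):
            binned = pos[(pos["ratio"] >= lo) & (pos["ratio"] < hi)]
            rows.append({
                "bf_min": t, "ratio_lo": lo, "ratio_hi": hi,
                "n": len(binned),
                "rate": binned["replicated"].mean() if len(binned)
                else np.nan,
            })
    return pd.DataFrame(rows)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Logistic fit with separation detection and a small ridge fallback."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=200)
            if np.any(np.abs(fit.params) > 50) or not np.all(
                    np.isfinite(fit.bse)):
                raise np.linalg.LinAlgError("separation")
            return fit, False
        except Exception:
            fit = model.fit_regularized(alpha=1e-3, disp=0, maxiter=500)
            return fit, True


def replication_determinants(
    records: pd.DataFrame,
    terms: list[str] | None = None,
    stepwise: bool = False,
    bf_min: float = 5.0,
    outcome: str = "replicated_either",
) -> dict:
    """Logistic model of replication on candidate determinants.

    Restricted to records with log10 BF > ``bf_min`` that are tested in all
    panels.  Continuous terms are standardized.  Per-term p-values come from
    likelihood-ratio chi-squared tests (drop-one).  With ``stepwise``,
    forward-backward selection by AIC is run first and the report covers the
    selected model.  Complete separation is detected and the model refit
    with a small ridge penalty, flagged in the report.
    """
    if terms is None:
        terms = [t for t in (
            "log10_bf", "abs_tss_distance", "mean_expression",
            "expression_cv", "probe_snps", "probe_snp_x_bf", "maf", "imputed",
        ) if t == "probe_snp_x_bf" or t in records.columns]
    elig = records[
        (records["log10_bf"] > bf_min) & records["tested_all"]
        & ~records["indeterminate"]
    ].copy()
    y = elig[outcome].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both replicated and non-replicated records")
    if "probe_snp_x_bf" in terms:
        if "probe_snps" not in elig.columns:
            terms = [t for t in terms if t != "probe_snp_x_bf"]
        else:
            elig["probe_snp_x_bf"] = (
                (elig["probe_snps"] > 0).astype(float) * elig["log10_bf"]
            )

    def col(term: str) -> np.ndarray:
        v = elig[term].to_numpy(float)
        sd = v.std()
        if term not in ("imputed",) and sd > 0:
            v = (v - v.mean()) / sd
        return v

    terms = [t for t in terms if t in elig.columns and elig[t].std() > 0]

    def design(term_list: list[str]) -> np.ndarray:
        cols = [np.ones(len(y))] + [col(t) for t in term_list]
        return np.column_stack(cols)

    def aic_of(term_list: list[str]) -> float:
        fit, _ = _fit_logit(y, design(term_list))
        k = len(term_list) + 1
        ll = fit.llf if hasattr(fit, "llf") else \
            sm.Logit(y, design(term_list)).loglike(fit.params)
        return 2 * k - 2 * ll

    if stepwise:
        selected: list[str] = []
        best_aic = aic_of(selected)
        improved = True
        while improved:
            improved = False
            for t in terms:  # forward
                if t in selected:
                    continue
                a = aic_of(selected + [t])
                if a < best_aic - 1e-9:
                    best_aic = a
                    selected.append(t)
                    improved = True
            for t in list(selected):  # backward
                rest = [s for s in selected if s != t]
                a = aic_of(rest)
                if a < best_aic - 1e-9:
                    best_aic = a
                    selected = rest
                    improved = True
        model_terms = selected
    else:
        model_terms = list(terms)

    X_full = design(model_terms)
    fit, ridged = _fit_logit(y, X_full)
    ll_full = fit.llf if hasattr(fit, "llf") else \
        sm.Logit(y, X_full).loglike(fit.params)
    lrt = {}
    for j, t in enumerate(model_terms):
        X_red = design([s for s in model_terms if s != t])
        fit_red, _ = _fit_logit(y, X_red)
        ll_red = fit_red.llf if hasattr(fit_red, "llf") else \
            sm.Logit(y, X_red).loglike(fit_red.params)
        chi2 = max(2 * (ll_full - ll_red), 0.0)
        lrt[t] = {"chi2": chi2, "p": float(stats.chi2.sf(chi2, 1))}
    coefs = dict(zip(["intercept"] + model_terms, np.asarray(fit.params)))
    return {
        "n": len(y), "terms": model_terms, "coefficients": coefs,
        "lrt": lrt, "aic": float(getattr(fit, "aic", np.nan)),
        "separation_ridge": ridged, "stepwise": stepwise,
        "outcome": outcome, "bf_min": bf_min,
    }


def enrichment_hypergeometric(
    hit_set: set[str], category: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric probability of >= the observed overlap
    between a hit set and a category within a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    hit_set = set(hit_set) & universe
    category = set(category) & universe
    k = len(hit_set & category)
    return float(stats.hypergeom.sf(
        k - 1, len(universe), len(category), len(hit_set)
    ))


def effect_correlation(
    records: pd.DataFrame, panel: str, method: str = "spearman"
) -> float:
    """Rank correlation between discovery and replication coefficients
    among records tested in the given panel."""
    sub = records[records[f"tested_{panel}"]]
    x = sub["beta_d"].to_numpy(float)
    y = sub[f"beta_{panel}"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need >= 3 paired coefficients")
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError("method must be 'spearman' or 'pearson'")


def probe_artifact_attribution(
    records: pd.DataFrame,
    bf_strata: tuple[float, ...] = (5.0, 10.0),
    outcome: str = "replicated_either",
) -> dict:
    """Fraction of the non-replication rate attributable to in-probe SNPs.

    Per BF stratum, compares replication among discoveries whose probe
    carries a polymorphism against those whose probe does not; the
    attributable fraction is computed on the non-replication scale,
    (nonrep_with - nonrep_without) / nonrep_with.  Also reports the logistic
    probe-SNP x BF interaction test over all eligible records.
    """
    if "probe_snps" not in records.columns:
        raise ValueError("records need a 'probe_snps' column")
    elig = records[records["tested_all"] & ~records["indeterminate"]].copy()
    strata = []
    for t in bf_strata:
        sub = elig[elig["log10_bf"] > t]
        w = sub[sub["probe_snps"] > 0]
        wo = sub[sub["probe_snps"] == 0]
        rate_w = w[outcome].mean() if len(w) else np.nan
        rate_wo = wo[outcome].mean() if len(wo) else np.nan
        nonrep_w, nonrep_wo = 1 - rate_w, 1 - rate_wo
        attr = (nonrep_w - nonrep_wo) / nonrep_w \
            if len(w) and len(wo) and nonrep_w > 0 else np.nan
        strata.append({
            "bf_min": t, "n_with": len(w), "n_without": len(wo),
            "rate_with": rate_w, "rate_without": rate_wo,
            "attributable_fraction": attr,
            "low_confidence": min(len(w), len(wo)) < 10,
        })
    y = elig[outcome].to_numpy(float)
    has_ps = (elig["probe_snps"] > 0).to_numpy(float)
    bf = elig["log10_bf"].to_numpy(float)
    interaction_p = np.nan
    if len(np.unique(y)) == 2 and has_ps.std() > 0:
        X = sm.add_constant(np.column_stack([bf, has_ps, bf * has_ps]))
        fit_full, _ = _fit_logit(y, X)
        ll_full = fit_full.llf if hasattr(fit_full, "llf") else \
            sm.Logit(y, X).loglike(fit_full.params)
        X0 = sm.add_constant(np.column_stack([bf, has_ps]))
        fit0, _ = _fit_logit(y, X0)
        ll0 = fit0.llf if hasattr(fit0, "llf") else \
            sm.Logit(y, X0).loglike(fit0.params)
        chi2 = max(2 * (ll_full - ll0), 0.0)
        interaction_p = float(stats.chi2.sf(chi2, 1))
    return {"strata": pd.DataFrame(strata),
            "interaction_p": interaction_p}
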