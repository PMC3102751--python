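"""Haplotype-specific reporter (luciferase) assay analysis.

Normalized luminescence is modelled per region with a fixed haplotype effect
and a random intercept per plasmid preparation:

    y_ijk = mu_h(i) + b_j + e_ijk,  b_j ~ N(0, sigma_prep^2),
                                    e_ijk ~ N(0, sigma_resid^2)

fit by restricted maximum likelihood, profiled over the variance ratio
lambda = sigma_prep^2 / sigma_resid^2 (a one-dimensional optimization; the
prep blocks make V = I + lambda Z Z' block-diagonal with a closed-form
inverse).  The haplotype term is tested by a Wald F statistic on the REML
fit with Satterthwaite denominator degrees of freedom computed from the
REML information matrix: with as few as three preps per haplotype the
asymptotic chi-squared likelihood-ratio reference is markedly
anticonservative, whereas the Satterthwaite F tracks the exact
balanced-ANOVA F when between-prep variance is present and recovers the
residual degrees of freedom when it vanishes.  Significance is declared at
p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .datatypes import ReporterPlate

__all__ = ["ReporterFit", "fit_reporter_model", "concordance_with_eqtl"]

ALPHA = 0.001


@dataclass
class RegionFit:
    """Mixed-model fit for one region."""

    region_id: str
    haplotype_effects: dict[str, float]  # cell means
    contrasts: dict[str, float]  # vs first haplotype (sorted order)
    sigma2_prep: float
    sigma2_resid: float
    fstat: float
    df1: int
    df2: float
    p: float
    significant: bool
    degenerate_ols: bool = False


@dataclass
class ReporterFit:
    """Per-region fits, keyed by region id."""

    regions: dict[str, RegionFit]

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.regions.values():
            rows.append({
                "region_id": r.region_id, "sigma2_prep": r.sigma2_prep,
                "sigma2_resid": r.sigma2_resid, "fstat": r.fstat,
                "df1": r.df1, "df2": r.df2, "p": r.p,
                "significant": r.significant,
            })
        return pd.DataFrame(rows).set_index("region_id")


def _grouped_solve(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   lam: float):
    """GLS building blocks for V = I + lam * ZZ' with Z the group design.

    Returns (XtViX, XtViy, ytViy, logdetV) using the block closed form
    V_g^{-1} = I - (lam / (1 + lam m_g)) J.
    """
    p = X.shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for g in np.unique(groups):
        idx = groups == g
        m = int(idx.sum())
        Xg, yg = X[idx], y[idx]
        c = lam / (1 + lam * m)
        sX = Xg.sum(axis=0)
        sy = yg.sum()
        XtViX += Xg.T @ Xg - c * np.outer(sX, sX)
        XtViy += Xg.T @ yg - c * sX * sy
        ytViy += yg @ yg - c * sy * sy
        logdet += np.log1p(lam * m)
    return XtViX, XtViy, ytViy, logdet


def _profiled_crit(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   lam: float, reml: bool) -> tuple[float, float, np.ndarray]:
    """Negative profiled (RE)ML criterion, sigma2_resid and beta at lam."""
    n, p = X.shape
    XtViX, XtViy, ytViy, logdetV = _grouped_solve(X, y, groups, lam)
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - beta @ XtViy  # r' V^-1 r
    rss = max(rss, 1e-300)
    if reml:
        dof = n - p
        sigma2 = rss / dof
        crit = 0.5 * (dof * np.log(sigma2) + logdetV
                      + np.linalg.slogdet(XtViX)[1] + dof)
    else:
        sigma2 = rss / n
        crit = 0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
    return crit, sigma2, beta


def _fit_variance_ratio(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                        reml: bool) -> tuple[float, float, np.ndarray, float]:
    """Optimize lambda on the log scale; returns (lam, sigma2, beta, crit)."""

    def obj(log_lam: float) -> float:
        return _profiled_crit(X, y, groups, np.exp(log_lam), reml)[0]

    crit0 = _profiled_crit(X, y, groups, 0.0, reml)[0]
    res = minimize_scalar(obj, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    if res.fun < crit0:
        lam = float(np.exp(res.x))
        crit = float(res.fun)
    else:
        lam, crit = 0.0, float(crit0)  # boundary: no between-prep variance
    _, sigma2, beta = _profiled_crit(X, y, groups, lam, reml)
    return lam, sigma2, beta, crit


def _satterthwaite_df(X: np.ndarray, groups: np.ndarray, C: np.ndarray,
                      sigma2_prep: float, sigma2_resid: float,
                      n_floor: float) -> float:
    """Satterthwaite denominator df for the haplotype contrasts.

    Uses the REML expected-information matrix of (sigma2_prep, sigma2_resid)
    and the gradient of each contrast's variance; multi-row contrasts take
    the mean of per-contrast dfs.  Clipped to [1, residual df].
    """
    n = X.shape[0]
    if sigma2_resid <= 1e-12:  # noiseless limit: V is singular-scaled
        return float(n_floor)
    Z = np.column_stack([
        (groups == g).astype(float) for g in np.unique(groups)
    ])
    ZZt = Z @ Z.T
    V = sigma2_resid * np.eye(n) + sigma2_prep * ZZt
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    B = Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    P = Vi - B
    parts = [ZZt, np.eye(n)]
    info = np.empty((2, 2))
    for j in range(2):
        for k in range(2):
            info[j, k] = 0.5 * np.trace(P @ parts[j] @ P @ parts[k])
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(n_floor)
    Ai = np.linalg.inv(XtViX)
    dfs = []
    for c in np.atleast_2d(C):
        v = float(c @ Ai @ c)
        g = np.empty(2)
        for j in range(2):
            M = X.T @ Vi @ parts[j] @ Vi @ X
            g[j] = float(c @ Ai @ M @ Ai @ c)
        denom = float(g @ info_inv @ g)
        df = 2 * v ** 2 / denom if denom > 0 else n_floor
        dfs.append(min(max(df, 1.0), float(n_floor)))
    return float(np.mean(dfs))


def fit_reporter_model(plate: ReporterPlate) -> ReporterFit:
    """Fit the random-intercept haplotype model to each region of a plate."""
    fits: dict[str, RegionFit] = {}
    for region, sub in plate.table.groupby("region_id"):
        haps = sorted(sub["haplotype_id"].unique())
        if len(haps) < 2:
            raise ValueError(f"region {region!r}: need >= 2 haplotypes")
        preps_per_hap = sub.groupby("haplotype_id")["prep_id"].nunique()
        degenerate = (preps_per_hap <= 1).all()
        y = sub["luminescence"].to_numpy(float)
        groups = sub["prep_id"].to_numpy()
        X = np.column_stack([
            (sub["haplotype_id"] == h).to_numpy(float) for h in haps
        ])
        n = len(y)
        H = len(haps)
        df1 = H - 1
        # contrasts vs the first haplotype
        C = np.hstack([-np.ones((df1, 1)), np.eye(df1)])
        if degenerate:
            warnings.warn(
                f"region {region!r}: a single prep per haplotype; "
                "between-prep variance inestimable, falling back to OLS"
            )
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            rss1 = float(((y - X @ beta) ** 2).sum())
            df2 = float(max(n - H, 1))
            sigma2_prep, sigma2_resid = 0.0, rss1 / df2
            A = X.T @ X
            cov_cb = C @ np.linalg.solve(A, C.T) * sigma2_resid
        else:
            lam_reml, sigma2_resid, beta, _ = _fit_variance_ratio(
                X, y, groups, reml=True)
            sigma2_prep = lam_reml * sigma2_resid
            A = _grouped_solve(X, y, groups, lam_reml)[0] / max(
                sigma2_resid, 1e-300)  # X' V^-1 X in absolute units
            cov_cb = C @ np.linalg.solve(A, C.T)
            df2 = _satterthwaite_df(X, groups, C, sigma2_prep, sigma2_resid,
                                    n_floor=max(n - H, 1))
        cb = C @ beta
        fstat = float(cb @ np.linalg.solve(cov_cb, cb)) / df1 \
            if sigma2_resid > 0 else np.inf
        if not np.isfinite(fstat):
            p = 0.0 if np.any(cb != 0) else 1.0
            fstat = np.inf if np.any(cb != 0) else 0.0
        else:
            p = float(stats.f.sf(fstat, df1, df2))
        effects = dict(zip(haps, beta))
        contrasts = {h: effects[h] - effects[haps[0]] for h in haps[1:]}
        fits[region] = RegionFit(
            region_id=region, haplotype_effects=effects,
            contrasts=contrasts, sigma2_prep=float(sigma2_prep),
            sigma2_resid=float(sigma2_resid), fstat=fstat, df1=df1,
            df2=df2, p=p, significant=p < ALPHA, degenerate_ols=degenerate,
        )
    return ReporterFit(regions=fits)


def concordance_with_eqtl(
    fit: RegionFit,
    eqtl_beta: float,
    haplotype_alleles: dict[str, int],
) -> bool:
    """True iff the reporter's allelic direction matches the eQTL's.

    ``haplotype_alleles`` maps haplotype_id to the alternate-allele count
    (0 or 1) carried at the eQTL SNP.  The haplotype contrast is the mean
    reporter effect of alt-carrying haplotypes minus ref haplotypes; its
    sign is compared with ``eqtl_beta``.  Unmapped haplotypes are excluded
    with a warning.
    """
    mapped = {h: a for h, a in haplotype_alleles.items()
              if h in fit.haplotype_effects}
    unmapped = set(fit.haplotype_effects) - set(mapped)
    if unmapped:
        warnings.warn(f"haplotypes excluded (no allele map): {sorted(unmapped)}")
    alt = [fit.haplotype_effects[h] for h, a in mapped.items() if a == 1]
    ref = [fit.haplotype_effects[h] for h, a in mapped.items() if a == 0]
    if not alt or not ref:
        raise ValueError("need haplotypes on both alleles of the eQTL SNP")
    contrast = float(np.mean(alt) - np.mean(ref))
    return bool(np.sign(contrast) == np.sign(eqtl_beta))
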