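"""Covariate adjustment of expression phenotypes.

Fits per-gene fixed-effect models (age, sex, ancestry, optional batch) with
technical replicates averaged within individual, estimates hidden confounders
by permutation-thresholded singular value decomposition (surrogate variables),
applies the within-population rank-based inverse-normal transform, and
computes Storey q-values for FDR control.  The residual phenotypes produced
here are the traits scanned for eQTLs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Demographics, ExpressionMatrix

__all__ = [
    "CovariateModelSpec",
    "AdjustedPhenotypes",
    "FdrResult",
    "build_design",
    "fit_covariate_model",
    "estimate_surrogate_variables",
    "quantile_normal_transform",
    "storey_qvalues",
    "demographic_association",
]


@dataclass
class CovariateModelSpec:
    """Fixed terms of the per-gene demographic model.

    The full mixed model y ~ m + P + A + C + R + I + W + SV + e (intercept,
    protocol batch, age, sex, ancestry, individual and probe random effects,
    surrogate variables) is approximated here by averaging technical
    replicates within individual (I) and centering probes before averaging
    multi-probe probesets (W), then fitting ordinary least squares on the
    fixed terms per gene.
    """

    use_age: bool = True
    use_sex: bool = True
    ancestry_columns: tuple[str, ...] = ("ancestry1",)
    batch_column: str | None = None
    surrogate_variables: np.ndarray | None = None  # samples x k


@dataclass
class AdjustedPhenotypes:
    """Residual phenotypes plus per-gene fixed-effect statistics."""

    gene_ids: list[str]
    sample_ids: list[str]
    residuals: np.ndarray  # genes x samples
    stats: dict[str, pd.DataFrame]  # term -> (beta, se, t, p) per gene
    n_svs: int = 0
    transformed: bool = False
    gene_meta: pd.DataFrame | None = None


@dataclass
class FdrResult:
    """Storey q-value output."""

    pvalues: np.ndarray
    qvalues: np.ndarray
    pi0: float
    lambda_grid: np.ndarray


def build_design(
    dem: Demographics, sample_ids: list[str], spec: CovariateModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effect design matrix, dropping aliased columns."""
    tab = dem.table.loc[sample_ids]
    cols: list[np.ndarray] = [np.ones(len(sample_ids))]
    names = ["intercept"]
    if spec.batch_column is not None:
        levels = sorted(set(tab[spec.batch_column]))
        for lev in levels[1:]:
            cols.append((tab[spec.batch_column] == lev).to_numpy(float))
            names.append(f"batch[{lev}]")
    if spec.use_age:
        cols.append(tab["age"].to_numpy(float))
        names.append("age")
    if spec.use_sex:
        cols.append((tab["sex"] == "male").to_numpy(float))  # male = 1
        names.append("sex")
    for c in spec.ancestry_columns:
        if c in tab.columns:
            v = tab[c].to_numpy(float)
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
            names.append(c)
    if spec.surrogate_variables is not None \
            and spec.surrogate_variables.size:
        sv = np.asarray(spec.surrogate_variables, float)
        for j in range(sv.shape[1]):
            cols.append(sv[:, j])
            names.append(f"SV{j + 1}")
    X = np.column_stack(cols)
    # drop aliased columns (keep first of each dependent set)
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"design column {names[j]!r} aliased; dropped")
    return X[:, keep], [names[j] for j in keep]


def _probe_centered_gene_matrix(
    expr: ExpressionMatrix,
) -> tuple[list[str], list[str], np.ndarray]:
    """Average replicates within individual and probes within gene, centering
    each probe first so probe-level offsets (the W term) cancel."""
    groups = expr.replicate_map()
    samples = list(groups)
    per_sample = np.column_stack(
        [expr.values[:, groups[s]].mean(axis=1) for s in samples]
    )
    per_sample = per_sample - per_sample.mean(axis=1, keepdims=True)
    gene_of = expr.probe_meta["gene_id"]
    by_gene: dict[str, list[int]] = {}
    for i, p in enumerate(expr.probe_ids):
        by_gene.setdefault(gene_of[p], []).append(i)
    genes = list(by_gene)
    Y = np.vstack([per_sample[by_gene[g]].mean(axis=0) for g in genes])
    return genes, samples, Y


def fit_covariate_model(
    expr: ExpressionMatrix,
    dem: Demographics,
    spec: CovariateModelSpec | None = None,
) -> AdjustedPhenotypes:
    """Per-gene OLS of expression on the fixed demographic terms.

    Technical replicates are averaged within individual and probes centered
    before averaging into gene values.  Returns residuals plus per-term
    estimates, standard errors, t statistics and p-values.
    """
    spec = spec or CovariateModelSpec()
    genes, samples, Y = _probe_centered_gene_matrix(expr)
    X, names = build_design(dem, samples, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} samples <= p = {p} model terms")

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T
    B = Y @ H.T  # genes x p
    fitted = B @ X.T
    resid = Y - fitted
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, B / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    stats_out = {
        name: pd.DataFrame(
            {"beta": B[:, j], "se": se[:, j], "t": tstat[:, j],
             "p": pvals[:, j]},
            index=genes,
        )
        for j, name in enumerate(names)
    }
    n_svs = 0 if spec.surrogate_variables is None \
        else int(np.asarray(spec.surrogate_variables).shape[-1] or 0)
    return AdjustedPhenotypes(
        gene_ids=genes, sample_ids=samples, residuals=resid,
        stats=stats_out, n_svs=n_svs,
    )


def estimate_surrogate_variables(
    residuals: np.ndarray,
    known_covariates: np.ndarray | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Estimate hidden-confounder scores by permutation-thresholded SVD.

    The gene-standardized residual matrix (genes x samples) is decomposed by
    SVD; the number of retained components k is chosen by comparing each
    component's variance-explained fraction with its null distribution under
    independent within-gene permutations (Buja-Eyuboglu style parallel
    analysis), retaining components while the empirical p-value is below
    ``alpha`` and stopping at the first failure.  Returned scores
    (samples x k) are orthogonalized against the known covariates.
    """
    R = np.asarray(residuals, float)
    if not np.all(np.isfinite(R)):
        raise ValueError("residual matrix must be finite")
    rng = np.random.default_rng(seed)
    sd = R.std(axis=1, keepdims=True)
    Z = (R - R.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    n_genes, n_samples = Z.shape
    kmax = min(n_genes, n_samples)

    s_obs = np.linalg.svd(Z, compute_uv=False)
    frac_obs = s_obs ** 2 / (s_obs ** 2).sum()
    null_fracs = np.empty((n_perm, len(s_obs)))
    for b in range(n_perm):
        P = Z.copy()
        # permute each gene independently: destroys cross-gene structure
        for i in range(n_genes):
            P[i] = P[i, rng.permutation(n_samples)]
        s = np.linalg.svd(P, compute_uv=False)
        null_fracs[b] = s ** 2 / (s ** 2).sum()

    k = 0
    for i in range(kmax):
        exceed = (null_fracs[:, i] >= frac_obs[i]).sum()
        p = (1 + exceed) / (1 + n_perm)
        if p < alpha:
            k += 1
        else:
            break
    if k == 0:
        return np.zeros((n_samples, 0))
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = Vt[:k].T  # samples x k
    if known_covariates is not None and np.asarray(known_covariates).size:
        C = np.asarray(known_covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([np.ones(n_samples), C])
        scores = scores - C @ np.linalg.lstsq(C, scores, rcond=None)[0]
        # re-orthonormalize the projected scores
        q, _ = np.linalg.qr(scores)
        scores = q[:, :k]
    return scores


def quantile_normal_transform(
    values: np.ndarray, groups: np.ndarray | list | None = None
) -> np.ndarray:
    """Rank-based inverse-normal (Blom) transform, applied within groups.

    value -> Phi^-1((rank - 3/8) / (n + 1/4)); ties get their mean rank.
    All-constant groups map to zeros with a warning.
    """
    v = np.asarray(values, float)
    if groups is None:
        groups = np.zeros(len(v), dtype=int)
    groups = np.asarray(groups)
    out = np.empty_like(v)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        sub = v[idx]
        if np.all(sub == sub[0]):
            warnings.warn(f"group {g!r} is constant; transformed to zeros")
            out[idx] = 0.0
            continue
        ranks = stats.rankdata(sub, method="average")
        out[idx] = stats.norm.ppf((ranks - 3 / 8) / (len(sub) + 1 / 4))
    return out


def storey_qvalues(
    pvals: np.ndarray, lambda_grid: np.ndarray | None = None
) -> FdrResult:
    """Storey q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fit by a cubic
    polynomial in lambda and evaluated at the largest grid value, clipped to
    (0, 1].  q(p_(i)) = min_{j >= i} pi0 m p_(j) / j.  With fewer than 100
    p-values the smoother is unstable, so pi0 falls back to 1 (the
    Benjamini-Hochberg limit) with a warning.
    """
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lambda_grid = np.asarray(lambda_grid, float)
    m = len(p)
    if m < 100:
        warnings.warn("fewer than 100 p-values; using pi0 = 1")
        pi0 = 1.0
    else:
        pi0_lam = np.array(
            [(p > lam).sum() / (m * (1 - lam)) for lam in lambda_grid]
        )
        coef = np.polynomial.polynomial.polyfit(lambda_grid, pi0_lam, 3)
        pi0 = float(np.polynomial.polynomial.polyval(lambda_grid.max(), coef))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return FdrResult(pvalues=p, qvalues=q, pi0=pi0, lambda_grid=lambda_grid)


def demographic_association(
    expr: ExpressionMatrix,
    dem: Demographics,
    variable: str,
    surrogate_variables: np.ndarray | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene association test of one demographic variable (age or sex)
    on surrogate-adjusted expression.

    Returns a frame indexed by gene with columns beta, se, t, p, q,
    significant.  Sex is coded male = 1, female = 0, so the sign of beta
    equals the sign of (mean male - mean female).
    """
    if variable not in {"age", "sex"}:
        raise ValueError("variable must be 'age' or 'sex'")
    spec = CovariateModelSpec(
        use_age=True, use_sex=True, ancestry_columns=("ancestry1",),
        surrogate_variables=surrogate_variables,
    )
    tab = dem.table
    v = tab["age"].to_numpy(float) if variable == "age" \
        else (tab["sex"] == "male").to_numpy(float)
    if np.std(v) == 0:
        raise ValueError(f"{variable} is constant in this panel")
    adj = fit_covariate_model(expr, dem, spec)
    res = adj.stats[variable].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fdr_res = storey_qvalues(res["p"].to_numpy())
    res["q"] = fdr_res.qvalues
    res["significant"] = res["q"] < fdr
    return res
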