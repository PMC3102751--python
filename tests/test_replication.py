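"""Replication assessment, rate curves, concordance adjustment, matched
resampling, winner's-curse tables, determinant models, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlrep import (
    Demographics,
    assess_replication,
    concordance_adjustment,
    effect_correlation,
    enrichment_hypergeometric,
    matched_resample,
    probe_artifact_attribution,
    replication_determinants,
    replication_rate_curve,
    resampling_baseline,
    winners_curse_analysis,
)
from eqtlrep.covariates import AdjustedPhenotypes
from eqtlrep.datatypes import GenotypeMatrix


def _discovery(n, rng, bf=8.0):
    return pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n)],
        "log10_bf": np.full(n, bf),
        "beta": rng.choice([-1.0, 1.0], n) * rng.uniform(0.2, 1.0, n),
        "p": np.full(n, 1e-8),
    }, index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))


class TestAssessReplication:
    def _records(self, beta_d, beta_r, p_r):
        disc = pd.DataFrame(
            {"snp_id": ["s"], "log10_bf": [8.0], "beta": [beta_d],
             "p": [1e-9]}, index=pd.Index(["g"], name="gene_id"))
        rep = pd.DataFrame(
            {"beta": [beta_r], "p": [p_r], "tested": [True]},
            index=pd.Index(["g"], name="gene_id"))
        return assess_replication(disc, {"rep": rep})

    def test_significant_concordant_replicates(self):
        rec = self._records(0.5, 0.3, 0.04)
        assert rec["replicated_rep"].iloc[0]

    def test_discordant_sign_does_not_replicate(self):
        rec = self._records(0.5, -0.3, 0.04)
        assert not rec["replicated_rep"].iloc[0]
        assert not rec["concordant_rep"].iloc[0]

    def test_boundary_p_is_strict(self):
        rec = self._records(0.5, 0.3, 0.05)
        assert not rec["replicated_rep"].iloc[0]
        assert rec["concordant_rep"].iloc[0]

    def test_zero_discovery_beta_indeterminate(self):
        rec = self._records(0.0, 0.3, 0.01)
        assert rec["indeterminate"].iloc[0]
        assert not rec["replicated_rep"].iloc[0]

    def test_untested_excluded_and_both_implies_either(self):
        rng = np.random.default_rng(0)
        disc = _discovery(50, rng)
        reps = {}
        for name in ("a", "b"):
            reps[name] = pd.DataFrame({
                "beta": disc["beta"] * rng.uniform(0.5, 1.5, 50),
                "p": rng.uniform(0, 0.2, 50),
                "tested": rng.random(50) > 0.2,
            }, index=disc.index)
        rec = assess_replication(disc, reps)
        assert (rec["replicated_both"] <= rec["replicated_either"]).all()
        assert (rec["replicated_a"] <= rec["tested_a"]).all()
        # either/both only over records tested in all panels
        assert not rec.loc[~rec["tested_all"], "replicated_either"].any()


class TestReplicationRateCurve:
    def test_all_replicated_rate_one(self):
        rng = np.random.default_rng(1)
        disc = _discovery(20, rng)
        rep = pd.DataFrame({"beta": disc["beta"], "p": 0.001,
                            "tested": True}, index=disc.index)
        rec = assess_replication(disc, {"r": rep})
        curve = replication_rate_curve(rec, [0, 5], ["r"])
        assert (curve["rate"].dropna() == 1.0).all()

    def test_null_rate_near_theoretical(self):
        """True-null discoveries replicate at 0.05 * 1/2 = 0.025."""
        rng = np.random.default_rng(2)
        n = 10_000
        disc = _discovery(n, rng)
        rep = pd.DataFrame({
            "beta": rng.choice([-1.0, 1.0], n),
            "p": rng.uniform(size=n),
            "tested": True,
        }, index=disc.index)
        rec = assess_replication(disc, {"r": rep})
        rate = rec["replicated_r"].mean()
        se = math.sqrt(0.025 * 0.975 / n)
        assert abs(rate - 0.025) < 3 * se
        # concordance-only null rate is 1/2
        conc = rec["concordant_r"].mean()
        assert abs(conc - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_empty_stratum_missing_not_zero(self):
        rng = np.random.default_rng(3)
        disc = _discovery(5, rng, bf=3.0)
        rep = pd.DataFrame({"beta": disc["beta"], "p": 0.01,
                            "tested": True}, index=disc.index)
        rec = assess_replication(disc, {"r": rep})
        curve = replication_rate_curve(rec, [10.0], ["r"])
        assert curve["rate"].isna().all()

    def test_record_order_invariance(self):
        rng = np.random.default_rng(4)
        disc = _discovery(30, rng)
        rep = pd.DataFrame({"beta": disc["beta"] * rng.choice([-1, 1], 30),
                            "p": rng.uniform(size=30), "tested": True},
                           index=disc.index)
        rec = assess_replication(disc, {"r": rep})
        c1 = replication_rate_curve(rec, [0, 5], ["r"])
        c2 = replication_rate_curve(rec.sample(frac=1, random_state=0),
                                    [0, 5], ["r"])
        pd.testing.assert_frame_equal(c1, c2)


class TestConcordanceAdjustment:
    def test_study_reference_values(self):
        # 80% single-panel concordance -> ~60% adjusted replication;
        # 90% either-of-two -> 60%
        assert concordance_adjustment(0.80, "single_panel") == \
            pytest.approx(0.60)
        assert concordance_adjustment(0.90, "either_of_two") == \
            pytest.approx(0.60)

    def test_perfect_concordance(self):
        assert concordance_adjustment(1.0, "single_panel") == 1.0
        assert concordance_adjustment(1.0, "either_of_two") == 1.0

    def test_inverse_of_null_concordance(self):
        """adjust(0.5 * (1 + r)) = r: the adjustment inverts the 50% null
        concordance of false positives."""
        for r in np.linspace(0, 1, 11):
            c = 0.5 * (1 + r)
            assert concordance_adjustment(c, "single_panel") == \
                pytest.approx(r)
            c2 = 0.75 + 0.25 * r  # null 'either' concordance is 75%
            assert concordance_adjustment(c2, "either_of_two") == \
                pytest.approx(r)

    def test_floored_at_zero(self):
        assert concordance_adjustment(0.1, "either_of_two") == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            concordance_adjustment(1.2, "single_panel")
        with pytest.raises(ValueError):
            concordance_adjustment(0.5, "bogus")


def _dem_table(n, seed, ages=None, pops=None):
    rng = np.random.default_rng(seed)
    return Demographics(pd.DataFrame({
        "age": ages if ages is not None
        else np.clip(rng.normal(50, 12, n), 20, 75).round(1),
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "ancestry1": 0.0,
        "population": pops if pops is not None else "EUR",
    }, index=pd.Index([f"x{seed}_{i}" for i in range(n)],
                      name="sample_id")))


class TestMatchedResample:
    def test_constraints_respected(self):
        src = _dem_table(300, 0)
        tgt = Demographics(pd.DataFrame({
            "age": np.full(10, 40.0), "sex": "male", "ancestry1": 0.0,
            "population": "EUR",
        }, index=pd.Index([f"t{i}" for i in range(10)], name="sample_id")))
        sets = matched_resample(src, tgt, n_sets=5, age_tol=3, seed=1)
        for s in sets:
            sub = src.table.loc[s]
            assert (sub["sex"] == "male").all()
            assert sub["age"].between(37, 43).all()

    def test_hundred_sets_of_sixty_distinct(self):
        src = _dem_table(206, 2)
        rng = np.random.default_rng(3)
        tgt = _dem_table(60, 3, ages=rng.uniform(35, 65, 60).round(1))
        sets = matched_resample(src, tgt, n_sets=100, age_tol=3, seed=4)
        assert len(sets) == 100
        for s in sets:
            assert len(s) == 60 and len(set(s)) == 60

    def test_seed_determinism(self):
        src = _dem_table(206, 2)
        rng = np.random.default_rng(3)
        tgt = _dem_table(60, 3, ages=rng.uniform(35, 65, 60).round(1))
        a = matched_resample(src, tgt, n_sets=10, seed=9)
        b = matched_resample(src, tgt, n_sets=10, seed=9)
        assert a == b

    def test_infeasible_target_named(self):
        src = _dem_table(50, 5)
        tgt = Demographics(pd.DataFrame({
            "age": [200.0], "sex": "male", "ancestry1": 0.0,
            "population": "EUR",
        }, index=pd.Index(["lonely"], name="sample_id")))
        with pytest.raises(ValueError, match="lonely"):
            matched_resample(src, tgt, n_sets=1)


def _panel_for_baseline(n, n_genes, h2, seed):
    """Residual phenotypes + genotypes with planted effects of given h2."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    snp_ids = [f"snp{i}" for i in range(n_genes)]
    dos = rng.binomial(2, 0.3, (n, n_genes)).astype(float)
    meta = pd.DataFrame({"chrom": "chr1",
                         "pos": np.arange(1, n_genes + 1) * 1000,
                         "ref": "A", "alt": "G", "maf": 0.3,
                         "imputed": False}, index=snp_ids)
    geno = GenotypeMatrix(samples, snp_ids, dos, meta)
    Y = np.empty((n_genes, n))
    betas = np.empty(n_genes)
    for i in range(n_genes):
        g = dos[:, i]
        if h2 >= 1:  # noiseless planted effect
            beta = rng.choice([-1.0, 1.0])
            Y[i] = beta * g
        elif h2 > 0:
            beta = np.sqrt(h2 / ((1 - h2) * g.var())) \
                * rng.choice([-1.0, 1.0])
            Y[i] = beta * g + rng.standard_normal(n)
        else:
            beta = 0.0
            Y[i] = rng.standard_normal(n)
        betas[i] = beta
    adjusted = AdjustedPhenotypes(
        gene_ids=[f"g{i}" for i in range(n_genes)], sample_ids=samples,
        residuals=Y, stats={})
    return adjusted, geno, betas


class TestResamplingBaseline:
    @staticmethod
    def _best(adjusted, geno, bf=8.0):
        from eqtlrep import single_snp_lm
        rows = []
        for i, gene in enumerate(adjusted.gene_ids):
            beta, se, t, p = single_snp_lm(adjusted.residuals[i],
                                           geno.dosages[:, i])
            rows.append({"gene_id": gene, "snp_id": geno.snp_ids[i],
                         "log10_bf": bf, "beta": beta, "p": p})
        return pd.DataFrame(rows).set_index("gene_id")

    def test_noiseless_effects_always_replicate(self):
        adjusted, geno, _ = _panel_for_baseline(100, 5, 1.0, 0)
        best = self._best(adjusted, geno)
        sets = [list(np.random.default_rng(s).choice(
            adjusted.sample_ids, 60, replace=False)) for s in range(10)]
        base = resampling_baseline(adjusted, geno, best, sets)
        ok = base.table[~base.table["skipped"]]
        assert ok["replicated"].all()

    def test_strong_effects_high_simulated_rate(self):
        """Planted h2 = 0.3 at n = 206 resampled to 60: simulated
        replication above 0.9 at the discovery threshold."""
        adjusted, geno, _ = _panel_for_baseline(206, 40, 0.3, 1)
        best = self._best(adjusted, geno)
        rng = np.random.default_rng(2)
        sets = [list(rng.choice(adjusted.sample_ids, 60, replace=False))
                for _ in range(50)]
        base = resampling_baseline(adjusted, geno, best, sets)
        rate = base.simulated_rate(np.array([5.0]))["rate"].iloc[0]
        assert rate > 0.9

    def test_null_simulated_rate_matches_overlap_corrected_null(self):
        """Null genes resampled WITHIN the discovery panel: the subset
        coefficient correlates with the full-panel one at rho = sqrt(m/n),
        so the null rate is 2*P(Z_sub > z_crit, Z_full > 0) under that
        correlation — materially above the independent-panel 0.025."""
        adjusted, geno, _ = _panel_for_baseline(206, 80, 0.0, 3)
        best = self._best(adjusted, geno)
        rng = np.random.default_rng(4)
        sets = [list(rng.choice(adjusted.sample_ids, 60, replace=False))
                for _ in range(30)]
        base = resampling_baseline(adjusted, geno, best, sets)
        ok = base.table[~base.table["skipped"]]
        rate = ok["replicated"].mean()
        rho = math.sqrt(60 / 206)
        mvn = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, rho], [rho, 1]])
        z = stats.norm.ppf(0.975)
        # P(Z_sub > z, Z_full > 0) via complement of the lower rectangle
        upper = (1 - stats.norm.cdf(z) - 0.5
                 + mvn.cdf([z, 0.0]))
        want = 2 * upper
        se = math.sqrt(want * (1 - want) / len(ok))
        # resamples share genes, so the effective n is below len(ok)
        assert abs(rate - want) < max(6 * se, 0.02)


class TestWinnersCurse:
    def test_shrunk_coefficients_still_replicate(self):
        """Resamples whose coefficient dropped >= 25% still replicate at
        > 0.9 for strong planted effects."""
        adjusted, geno, _ = _panel_for_baseline(206, 40, 0.3, 5)
        best = TestResamplingBaseline._best(adjusted, geno)
        rng = np.random.default_rng(6)
        sets = [list(rng.choice(adjusted.sample_ids, 60, replace=False))
                for _ in range(50)]
        base = resampling_baseline(adjusted, geno, best, sets)
        table = winners_curse_analysis(
            base, ratio_bins=np.array([1.0, 1.25, 2.0]), bf_strata=(5.0,))
        shrunk = table[(table["ratio_lo"] >= 1.25) & (table["n"] > 10)]
        assert len(shrunk) >= 1
        assert (shrunk["rate"] > 0.9).all()

    def test_null_rates_stay_low_and_reconcile(self):
        """Null genes: no ratio bin shows an inflated replication rate, and
        the bin rates reconcile with the overall overlap-corrected null.
        (Within positive-ratio bins sign agreement is conditioned on, so
        per-bin rates are p-value exceedances, not the joint 2.5% rate.)"""
        adjusted, geno, _ = _panel_for_baseline(206, 80, 0.0, 7)
        best = TestResamplingBaseline._best(adjusted, geno)
        rng = np.random.default_rng(8)
        sets = [list(rng.choice(adjusted.sample_ids, 60, replace=False))
                for _ in range(30)]
        base = resampling_baseline(adjusted, geno, best, sets)
        table = winners_curse_analysis(base, bf_strata=(0.0,))
        big = table[(table["n"] >= 100) & table["rate"].notna()]
        assert len(big) >= 2
        assert (big["rate"] < 0.25).all()
        # weighted mean over all bins equals the overall simulated rate
        ok = base.table[~base.table["skipped"]]
        stratum = table[table["bf_min"] == 0.0].dropna(subset=["rate"])
        weighted = (stratum["rate"] * stratum["n"]).sum() / stratum["n"].sum()
        assert weighted == pytest.approx(ok["replicated"].mean(), abs=1e-9)


def _det_records(n, rng, dependence=None):
    """Synthetic replication records with optional planted dependence."""
    bf = rng.uniform(5.01, 15, n)
    dist = rng.uniform(0, 250_000, n)
    probe = rng.binomial(1, 0.3, n)
    logit = -0.0 + np.zeros(n)
    if dependence == "distance":
        logit = 2.5 - 2e-5 * dist
    prob = 1 / (1 + np.exp(-logit))
    rep = rng.random(n) < prob
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(n)],
        "log10_bf": bf, "beta_d": rng.choice([-1.0, 1.0], n),
        "p_d": 1e-9, "indeterminate": False, "tested_all": True,
        "replicated_either": rep,
        "abs_tss_distance": dist,
        "mean_expression": rng.normal(8, 1, n),
        "expression_cv": rng.uniform(0.05, 0.3, n),
        "probe_snps": probe * rng.integers(1, 3, n),
        "maf": rng.uniform(0.05, 0.5, n),
        "imputed": rng.binomial(1, 0.3, n).astype(float),
    }, index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))


class TestReplicationDeterminants:
    def test_planted_distance_effect_recovered(self):
        """TSS-distance-driven replication: the distance term is detected
        and unrelated terms stay null at alpha = 0.05 in most runs."""
        rng = np.random.default_rng(9)
        dist_hits, false_hits, n_false = 0, 0, 0
        n_runs = 15
        for _ in range(n_runs):
            rec = _det_records(400, rng, dependence="distance")
            rep = replication_determinants(
                rec, terms=["log10_bf", "abs_tss_distance",
                            "mean_expression", "maf"], bf_min=5.0)
            dist_hits += rep["lrt"]["abs_tss_distance"]["p"] < 0.05
            for t in ("mean_expression", "maf"):
                false_hits += rep["lrt"][t]["p"] < 0.05
                n_false += 1
        assert dist_hits / n_runs >= 0.9
        assert false_hits / n_false < 0.2

    def test_null_type_one_error(self):
        rng = np.random.default_rng(10)
        hits, total = 0, 0
        for _ in range(40):
            rec = _det_records(300, rng)
            rec["replicated_either"] = rng.random(300) < 0.5
            rep = replication_determinants(
                rec, terms=["log10_bf", "abs_tss_distance", "maf"],
                bf_min=5.0)
            for t in rep["lrt"]:
                hits += rep["lrt"][t]["p"] < 0.05
                total += 1
        assert abs(hits / total - 0.05) < 0.045

    def test_stepwise_null_selects_intercept_only(self):
        """On a null design, forward-backward AIC keeps the intercept-only
        model in the majority of runs (each extra term needs chi2 > 2,
        p ~ 0.157, so two candidates leave ~71% of runs empty)."""
        rng = np.random.default_rng(99)
        wins = 0
        n_runs = 30
        for _ in range(n_runs):
            rec = _det_records(300, rng)
            rec["replicated_either"] = rng.random(300) < 0.5
            rep = replication_determinants(
                rec, terms=["log10_bf", "maf"], stepwise=True, bf_min=5.0)
            wins += len(rep["terms"]) == 0
        assert wins > n_runs / 2

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(12)
        rec = _det_records(50, rng)
        rec["replicated_either"] = True
        with pytest.raises(ValueError):
            replication_determinants(rec, terms=["log10_bf"])


class TestEnrichmentHypergeometric:
    def test_everything_overlaps(self):
        u = {f"g{i}" for i in range(10)}
        assert enrichment_hypergeometric(u, u, u) == pytest.approx(1.0)

    def test_zero_overlap_with_large_expectation(self):
        u = {f"g{i}" for i in range(100)}
        cat = {f"g{i}" for i in range(50)}
        hits = {f"g{i}" for i in range(50, 100)}
        assert enrichment_hypergeometric(hits, cat, u) > 0.99

    def test_matches_enumeration_oracle(self):
        """Universe 20, category 5, hits 6, overlap 4: exact enumeration."""
        u = {f"g{i}" for i in range(20)}
        cat = {f"g{i}" for i in range(5)}
        hits = {"g0", "g1", "g2", "g3", "g10", "g11"}
        got = enrichment_hypergeometric(hits, cat, u)
        want = sum(
            math.comb(5, k) * math.comb(15, 6 - k) for k in (4, 5)
        ) / math.comb(20, 6)
        assert got == pytest.approx(want, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_hypergeometric(set(), set(), set())


class TestEffectCorrelation:
    @staticmethod
    def _rec(bd, br):
        n = len(bd)
        return pd.DataFrame({
            "beta_d": bd, "beta_r1": br, "tested_r1": True,
        }, index=[f"g{i}" for i in range(n)])

    def test_identical_vectors_rho_one(self):
        b = np.random.default_rng(0).standard_normal(20)
        assert effect_correlation(self._rec(b, b), "r1") == pytest.approx(1.0)

    def test_null_near_zero(self):
        rng = np.random.default_rng(1)
        n = 400
        rho = effect_correlation(
            self._rec(rng.standard_normal(n), rng.standard_normal(n)), "r1")
        assert abs(rho) < 2 / math.sqrt(n)

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        got = effect_correlation(self._rec(x, y), "r1")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert got == pytest.approx(want, rel=1e-12)


class TestProbeArtifactAttribution:
    def test_null_attributable_fraction_near_zero(self):
        rng = np.random.default_rng(13)
        rec = _det_records(4000, rng)
        rec["replicated_either"] = rng.random(4000) < 0.6
        out = probe_artifact_attribution(rec, bf_strata=(5.0,))
        frac = out["strata"]["attributable_fraction"].iloc[0]
        assert abs(frac) < 0.12
        assert out["interaction_p"] > 0.001

    def test_planted_interaction_detected(self):
        """Probe-SNP genes failing preferentially at high BF: the
        interaction term is detected."""
        rng = np.random.default_rng(14)
        rec = _det_records(2000, rng)
        has = rec["probe_snps"] > 0
        logit = 1.5 - 0.4 * (rec["log10_bf"] - 5) * has
        rec["replicated_either"] = rng.random(2000) < 1 / (
            1 + np.exp(-logit))
        out = probe_artifact_attribution(rec, bf_strata=(5.0, 10.0))
        assert out["interaction_p"] < 0.05
        strata = out["strata"].set_index("bf_min")
        assert strata.loc[10.0, "attributable_fraction"] > \
            strata.loc[5.0, "attributable_fraction"] - 0.05
        assert strata.loc[5.0, "rate_without"] > \
            strata.loc[5.0, "rate_with"]


class TestSexChromosomeEnrichment:
    def test_planted_chrx_sex_genes_detected_by_enrichment(self):
        """End to end: sex-affected genes planted on the X chromosome are
        found by the per-gene sex association test, and the hypergeometric
        test detects the chromosomal enrichment."""
        import warnings
        from eqtlrep import (SimulationConfig, demographic_association,
                             simulate_multi_study)
        cfg = SimulationConfig(
            panel_sizes=(206, 60), n_genes=100, n_snps_per_gene=4,
            sex_genes_on_chrx=True, sex_effect_sd=0.5,
            n_confounders_per_panel=0, n_replicates=(1, 1), seed=17)
        panels, truth, layout = simulate_multi_study(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = demographic_association(
                panels[0].expression, panels[0].demographics, "sex")
        hits = set(res.index[res["significant"]])
        chrx = set(layout.genes.index[layout.genes["chrom"] == "chrX"])
        assert len(hits) >= 5
        assert hits <= chrx  # only planted sex genes reach FDR < 5%
        p = enrichment_hypergeometric(hits, chrx,
                                      set(layout.genes.index))
        assert p < 1e-6
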