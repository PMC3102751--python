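"""Matched resampling and the winner's-curse diagnostic.

Draws 100 age (+/- 3 years), sex and population matched sets of 60 samples
from a 206-sample discovery panel, recomputes each discovery coefficient on
every subset, and tabulates the simulated replication rate by the ratio of
full-panel to resampled coefficients.  If winner's curse were deflating
replication, rates would collapse in the bins where the coefficient shrank.
"""

import numpy as np
import warnings

from eqtlrep import (
    PipelineConfig, SimulationConfig, matched_resample, resampling_baseline,
    run_pipeline, winners_curse_analysis,
)

config = PipelineConfig(
    sim=SimulationConfig(panel_sizes=(206, 60), n_genes=80,
                         n_snps_per_gene=8, cis_h2_range=(0.15, 0.4),
                         frac_cis_genes=0.6, n_replicates=(1, 1),
                         frac_non_european=(0.1, 0.0), seed=5),
    run_resampling=False,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(config)
    disc = result.panels[0]
    target = result.panels[1]
    sets = matched_resample(disc.demographics, target.demographics,
                            n_sets=100, age_tol=3, seed=1)
    from eqtlrep.pipeline import adjust_panel
    adjusted = adjust_panel(disc, config, seed=2)
    best = result.scans["panel1"].dropna(subset=["snp_id"])
    baseline = resampling_baseline(adjusted, disc.genotypes, best, sets)

rates = baseline.simulated_rate(np.array([0.0, 5.0, 10.0]))
print("simulated replication rate by discovery BF threshold:")
print(rates.to_string(index=False))
table = winners_curse_analysis(baseline, bf_strata=(5.0,))
strong = table[(table["bf_min"] == 5.0) & (table["n"] > 20)]
print("\nreplication rate by full/resampled coefficient ratio (BF > 5):")
print(strong[["ratio_lo", "ratio_hi", "n", "rate"]].to_string(index=False))
# Ratios > 1 are resamples where the effect estimate shrank; persistent
# high rates there argue against winner's curse as the cause of
# non-replication for strong discoveries.
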