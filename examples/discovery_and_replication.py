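"""Run the full discovery -> replication analysis on synthetic panels.

One panel acts as the discovery cohort; best cis-SNPs per gene are found by
Bayesian single-SNP regression (log10 Bayes factors) on surrogate-adjusted
residuals, then re-tested in the two replication panels.  A discovery
replicates when the same SNP shows p < 0.05 with a concordant direction.
"""

import warnings

from eqtlrep import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    sim=SimulationConfig(panel_sizes=(206, 60, 266), n_genes=120,
                         n_snps_per_gene=8, seed=7),
    run_resampling=True,
    n_resample_sets=50,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(config)

r = result.report
print(f"discoveries at log10 BF > {config.bf_threshold}: "
      f"{r['n_discoveries_bf']} ({r['n_discoveries_bf_true']} with a "
      "planted cis effect)")
for name in ("panel2", "panel3"):
    print(f"  replication in {name}: rate "
          f"{r[f'replication_rate_{name}']:.3f}, concordance "
          f"{r[f'concordance_rate_{name}']:.3f}, Spearman rho "
          f"{r[f'spearman_{name}']:.3f}")
print(f"  either panel: {r['replication_rate_either']:.3f}  "
      f"both: {r['replication_rate_both']:.3f}")
if "baseline_rate_at_bf" in r:
    print(f"matched-resampling baseline at BF>5: "
          f"{r['baseline_rate_at_bf']:.3f} "
          f"({r['baseline_n_sets']} sets of matched samples)")
# A high rate among strong discoveries with a near-1 baseline mirrors the
# expectation that power alone cannot explain non-replication.
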