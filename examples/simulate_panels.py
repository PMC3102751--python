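"""Generate a three-panel synthetic liver eQTL study and write it to disk.

Builds genotype, expression, demographic and probe-annotation files for
three disjoint cohorts that share one table of planted genetic effects,
then prints what was planted.  Output lands in ./panels_out/.
"""

from pathlib import Path

from eqtlrep import SimulationConfig, simulate_multi_study
from eqtlrep import io as eio

config = SimulationConfig(
    panel_sizes=(206, 60, 266),  # the canonical discovery/replication sizes
    n_genes=100,
    n_snps_per_gene=10,
    seed=42,
)
panels, truth, layout = simulate_multi_study(config)

outdir = Path("panels_out")
outdir.mkdir(exist_ok=True)
for panel in panels:
    eio.write_genotypes_vcf(panel.genotypes, outdir / f"{panel.name}.vcf")
    eio.write_expression_tsv(panel.expression,
                             outdir / f"{panel.name}.expression.tsv")
    eio.write_demographics_tsv(panel.demographics,
                               outdir / f"{panel.name}.demographics.tsv")
    eio.write_probes_bed(panel.expression.probe_meta,
                         outdir / f"{panel.name}.probes.bed")
eio.write_genes_bed12(layout.genes, outdir / "genes.bed")

n_cis = int((truth.genes["var_frac_cis"] > 0).sum())
n_conf = int(truth.genes["confounded"].sum())
n_art = int(truth.probes["artifact"].sum())
print(f"panels: {[p.n_samples for p in panels]} samples on platforms "
      f"{[p.platform for p in panels]}")
print(f"planted: {n_cis}/{len(truth.genes)} genes with cis effects, "
      f"{n_conf} confounder-loaded genes, {n_art} artifact probes")
print(f"files written to {outdir}/")
# The truth table is the ground truth downstream stages are scored against:
# cis_beta is in log2 expression units per alternate allele.
print(truth.genes[["cis_snp_id", "cis_beta", "var_frac_cis"]].head())
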