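"""Generate a synthetic paired methylation/expression cohort.

Builds a three-group cohort (normal mucosa, HPV-positive and HPV-negative
tumors) with planted meta-pathway structure: each group drives one pattern,
half of the shared genes are epigenetically silenced (high methylation
exactly where their expression pattern is low), and three gene sets are
enriched in high-amplitude genes.
"""

import numpy as np

from metapathways import SimulationConfig, generate_dataset

config = SimulationConfig(seed=0)  # defaults: 25 normal / 13 HPV+ / 31 HPV-
expression, probes, clinical, gene_sets, truth = generate_dataset(config)

print(f"expression matrix: {expression.shape[0]} genes x {expression.shape[1]} samples")
print(f"probe table: {len(probes)} rows ({probes['probe_id'].nunique()} probes)")
print(f"clinical groups: {clinical['group'].value_counts().to_dict()}")
print(f"gene sets: {len(gene_sets)} ({len(truth.enriched_set_names)} planted enriched)")
print(f"silenced genes: {len(truth.silenced_genes)}")

# anti-correlation between methylation and expression for a silenced gene
gene = truth.silenced_genes[0]
kept = probes[(probes["gene"] == gene) & (probes["n_cpg"] >= 3)]
beta = (kept["M"] / (kept["M"] + kept["U"])).groupby(kept["sample_id"].values).max()
r = np.corrcoef(beta[expression.columns], np.log(expression.loc[gene]))[0, 1]
print(f"silenced gene {gene}: corr(beta, log expression) = {r:.3f}")
print("a strongly negative value means methylation silences this gene's expression")
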