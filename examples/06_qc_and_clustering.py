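"""Replicate-correlation QC and hierarchical clustering of samples."""

from coldatlas import (SimConfig, cluster_samples, generate_dataset,
                       log_expression, replicate_correlation)

cfg = SimConfig(n_genes=1200, seed=3)
counts, design, lengths, *_ = generate_dataset(cfg)

expr = log_expression(counts, lengths)          # log2(RPKM + 1)
report = replicate_correlation(expr, design)
print(f"mean within-replicate Pearson r^2: {report.mean_replicate_r2:.3f}")

Z, newick = cluster_samples(expr)               # average linkage on 1 - r
print(f"dendrogram: {Z.shape[0]} merges over {expr.shape[1]} samples")
print("newick (truncated):", newick[:100], "...")
# Replicates should be near-identical (r^2 close to 1); photosynthetic
# organs (leaf, cotyledons, hypocotyl) cluster apart from flowers/seeds.
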