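"""Classify DE genes across all organs into Down / Up / Mix and count how
many organs share each gene's response."""

from coldatlas import (Contrast, SimConfig, classify, commonality,
                       generate_dataset, test_contrast, unique_genes)

cfg = SimConfig(n_genes=1500, seed=2)
counts, design, *_ = generate_dataset(cfg)

# one scope: all six organs at 3 h
results = {f"{organ}_3h": test_contrast(counts, design, Contrast(organ, 3))
           for organ in design.organs}
cls = classify(results)
by_cat = cls["category"].value_counts().to_dict()
print(f"DE anywhere at 3 h: {len(cls)} genes -> {by_cat}")
# Down = down somewhere and up nowhere; Up symmetric; Mix = both directions
# (opposite responses in different organs).

for direction in ("down", "up"):
    table = commonality(cls, direction)
    print(f"{direction}-regulated genes by number of organs: "
          f"{table.to_dict()}")
uniq = unique_genes(cls, "leaf_3h", "up")
print(f"genes upregulated only in leaf at 3 h: {len(uniq)}")
# Genes shared by all organs form the 'core' cold response; k=1 genes are
# the organ-specific periphery.
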