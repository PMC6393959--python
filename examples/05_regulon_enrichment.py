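"""Fisher-exact enrichment of TF regulons among stress-responsive genes."""

from coldatlas import (Contrast, SimConfig, generate_dataset, test_contrast,
                       tf_enrichment)

cfg = SimConfig(n_genes=1500, n_tf_sets=60, n_active_tfs=8, seed=8)
counts, design, _, annotations, truth = generate_dataset(cfg)

de_union, universe = set(), set()
for organ in design.organs:
    for t in (3, 27):
        res = test_contrast(counts, design, Contrast(organ, t))
        universe |= set(res.index[res["tested"]])
        de_union |= set(res.index[res["status"] != "ns"])

enr = tf_enrichment(de_union, universe, annotations["tf_target"])
sig = enr[enr["significant"]]
print(f"{len(sig)} of {len(enr)} regulons enriched at q <= 0.05")
print(sig[["a", "enrichment", "fold", "qvalue"]].head(8).round(4))
hits = set(sig.index) & set(truth.active_tfs)
print(f"planted active regulons recovered: {len(hits)}/{len(truth.active_tfs)}")
# 'enrichment' is log2 of %target among DE over %target among non-DE genes;
# a value of 2 means targets are 4x overrepresented among responders.
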