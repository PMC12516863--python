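"""Spot-level co-localization of the mCAF-like and endothelial programs.

Generates spatial-transcriptomics samples with correlated mCAF and
endothelial abundance fields, computes bin-matched module scores,
categorizes spots by quantile co-expression, runs rank-sum differential
expression for double-high spots, and annotates the ranking with
pre-ranked gene-set enrichment.
"""

import pandas as pd

from sgctme import (ModuleScoreConfig, SimulationConfig, categorize_spots,
                    module_score, preranked_enrichment, rank_sum_de,
                    score_correlation)
from sgctme.simulate import ENDOTHELIAL_GENES, generate_st

config = SimulationConfig(st_colocalization=0.8)
expr, coords, truth = generate_st(config, n_spots_per_sample=1500,
                                  seed=6, n_samples=3)
print(f"{len(expr)} spots x {expr.shape[1]} genes across 3 samples")

mcaf_genes = [g for g in expr.columns if g.startswith("MCAFG")]
ms_cfg = ModuleScoreConfig(n_bins=24, n_ctrl=100, seed=0)
mcaf = module_score(expr, mcaf_genes, ms_cfg)
endo = module_score(expr, ENDOTHELIAL_GENES, ms_cfg)
r, p = score_correlation(mcaf, endo)
print(f"Pearson r(mCAF score, endothelia score) = {r:.2f} (p = {p:.1e});")
print("the generator planted co-localization 0.8.")

cats = categorize_spots(mcaf, endo, coords["sample_id"], q=0.2)
print("\nspot categories (pooled across samples):")
print(cats.value_counts().to_string())

de = rank_sum_de(expr, cats == "mCAF_high_endothelia_high")
top = de.sort_values("avg_log2FC", ascending=False).head(5)
print("\ntop genes in double-high spots (avg_log2FC / adjusted p):")
print(top[["avg_log2FC", "p_adj"]].round(3).to_string())

sets = {"mcaf_program": mcaf_genes[:50],
        "endothelial_markers": list(ENDOTHELIAL_GENES),
        "random_background": [f"STBG{i:04d}" for i in range(0, 200, 4)]}
enr = preranked_enrichment(de["avg_log2FC"], sets, n_perm=500, seed=1)
print("\npre-ranked enrichment on the DE ranking:")
print(enr.table[["es", "p", "q"]].round(3).to_string())
print("\nPositive enrichment of the mCAF program and endothelial markers")
print("in double-high spots mirrors their planted co-localization.")
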