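"""Cross-tissue DNAm-mRNA coupling stratified by chromatin state.

Simulates the 29-tissue / 2-animal atlas in which promoter methylation in
enhancer states represses expression while methylation in bivalent
promoter / polycomb / TSS states is coupled positively, screens every
promoter CpG against its nearest gene, and summarises the Fisher z per
chromatin state.
"""

from equiclock.atlas import coupling_screen, state_summary
from equiclock.synthetic_data import AtlasSimConfig, simulate_atlas

beta, expression, sheet, annot, truth = simulate_atlas(AtlasSimConfig(seed=1))
print(f"atlas: {beta.shape[0]} samples (29 tissues x 2 animals), "
      f"{beta.shape[1]} CpGs, {expression.shape[0]} genes")

table = coupling_screen(beta, expression, annot.table[["gene", "tss_distance"]])
n_sig = int(table["significant"].sum())
n_pos = int((table.loc[table["significant"], "z"] > 0).sum())
print(f"promoter CpGs screened: {len(table)}; |z| > 2.8: {n_sig} "
      f"({n_pos} positive, {n_sig - n_pos} negative)")

summary = state_summary(table, annot)
print(summary[["n", "median_z", "reported"]].round(2).to_string())
print("\nNegative median z (enhancer states) = methylation represses the "
      "adjacent\ngene; positive median z (bivalent promoter, polycomb, TSS "
      "states) =\nmethylation tracks higher expression, as planted.")
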