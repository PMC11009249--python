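"""Score pathway activity from a differential-expression table.

Builds a small DEG table, filters it at p < 0.05, and averages the log2
fold changes of the genes in each pathway set.
"""

import pandas as pd

from dropflux.pathways import (
    categorize_expressers,
    filter_degs,
    log2fc_to_fold,
    pathway_activity,
)

degs = pd.DataFrame(
    {
        "gene": ["LDHA", "LDHB", "HK2", "PKM", "GLS", "CASP3", "BAX", "SOD2"],
        "cluster": ["plasma"] * 8,
        "log2fc": [1.7, 0.4, 2.4, 2.1, 3.9, 1.2, 0.9, 1.5],
        "p_value": [0.001, 0.03, 0.002, 0.01, 0.0005, 0.04, 0.2, 0.01],
    }
)

significant = filter_degs(degs, alpha=0.05)
print(f"{len(significant)} of {len(degs)} genes significant at p < 0.05")
for act in pathway_activity(significant, category="IgG_high"):
    if act.n_degs_used:
        print(f"  {act.pathway:<18} mean log2FC {act.mean_log2fc:+.2f} "
              f"({act.n_degs_used} DEGs)")

print("\nA mean log2FC of +2 means the pathway's significant genes are on "
      f"average {log2fc_to_fold(2.0):.0f}-fold upregulated.")
print("expresser split at log2FC 1:",
      [str(label) for label in categorize_expressers([0.4, 1.0, 1.7])])
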