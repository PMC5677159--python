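"""miRNA-promoter differential methylation and bisulfite-PCR validation.

Labels miRNA promoters with the two-tier **/* significance rule, checks
promoter->miRNA->target coherence, and validates a region's WGBS
methylation against simulated Sanger clones of a bisulfite amplicon.
"""
import numpy as np
import pandas as pd

from ovulemeth import CloneSet, ContextIndex, analyze_clones, dm_label
from ovulemeth.mirna_bsp import coherence_network

# the two-tier label rule on a few (log2fc, p) pairs
for lfc, p in [(3.0, 0.0167), (1.87, 0.0269), (-3.04, 3.4e-6), (0.5, 0.001)]:
    print(f"log2fc={lfc:+.2f}  p={p:.2g}  ->  {dm_label(lfc, p)!r}")
print("'**' needs |log2fc|>=1 and p<0.01; '*' needs |log2fc|>=1 and "
      "0.01<p<0.05; anything else is 'ns'.\n")

# coherence: hypo-methylated promoter -> miRNA up -> target down
dm = pd.DataFrame([{"mirna": "miR5504", "direction": "hypo-methylation"}])
mirna_expr = pd.DataFrame({"mirna": ["miR5504"], "log2fc": [1.2]})
targets = pd.DataFrame({"mirna": ["miR5504"], "gene_id": ["LOC_g1"]})
gene_expr = pd.DataFrame({"gene_id": ["LOC_g1"], "log2fc": [-0.8]})
triple = coherence_network(dm, mirna_expr, targets, gene_expr)[0]
print(f"promoter {triple.promoter_direction}, miRNA {triple.mirna_log2fc:+.1f}, "
      f"target {triple.target_log2fc:+.1f} -> {triple.verdict}\n")

# BSP clones: 15 clones of a 60-bp amplicon, ~40% methylated CG sites
rng = np.random.default_rng(6)
amplicon = "".join(rng.choice(list("ACGT"), size=60))
clones = []
for _ in range(15):
    clone = [("C" if rng.random() < 0.4 else "T") if b == "C" else b
             for b in amplicon]
    clones.append("".join(clone))
res = analyze_clones(CloneSet(amplicon, clones, sample="fsv1"))
for ctx, pct in res.per_context.items():
    print(f"{ctx}: {pct:.1f}% methylated" if pct == pct
          else f"{ctx}: no sites in amplicon")
print("Percent per context pools C/(C+T) calls over that context's "
      "cytosines across all clones.")
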