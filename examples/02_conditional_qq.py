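"""Conditional Q-Q enrichment: the graphical signature of pleiotropy.

Builds a pleiotropic dataset, then summarizes the conditional Q-Q curves
of trait 1 within strata of increasing trait-2 significance.  Growing
positive enrichment across strata (-log10 p2 >= 1, 2, 3) is the
leftward-deflection pattern that motivates the condFDR analysis; the
all-SNP stratum is the reference and has enrichment 0 by construction.
"""

import pandas as pd

import crosstrait as ct
from crosstrait.condfdr import QQConfig, conditional_qq

s1, s2, ld, _ = ct.simulate_sumstats_pair(n_variants=50_000, seed=7)
paired = pd.DataFrame({"snp": s1["SNP"], "p1": s1["P"], "p2": s2["P"]})
blocks = ct.ld_blocks(ld, s1["SNP"], r2_threshold=0.1)

qq = conditional_qq(paired, blocks, QQConfig(pruning_iterations=50, seed=7))
print("stratum (-log10 p2 >=)   median size   enrichment (mean -log10 p1 gain)")
for t, e in sorted(qq.enrichment.items()):
    print(f"  {t:>4.1f}  {qq.stratum_sizes[t]:>14.0f}  {e:>+10.3f}")
print(
    "\nEnrichment grows with the conditioning threshold: variants associated\n"
    "with trait 2 are enriched for trait-1 signal, i.e. the traits overlap\n"
    "genetically.  The curves themselves are in qq.curves (plot-ready)."
)
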