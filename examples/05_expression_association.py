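"""Associate TSS-proximal hotspots with gene expression.

Compares log2(TPM+1) between genes with and without a hotspot within
+/-200 bp of a TSS, and groups genes by the most TSS-proximal distance
bin of their template-strand hotspots. The generator doubles the TPM of
hotspot-bearing genes, grading the boost by proximity when asked to.
"""

import numpy as np
import pandas as pd

from breakome import SyntheticConfig
from breakome.expression import hierarchical_bins, with_without_comparison
from breakome.synthetic_data import generate_expression
from breakome.tss_enrichment import BIN_LABELS

# balanced cohort: 200 genes with a +/-5 bp template hotspot, 200 without
flags = pd.DataFrame({
    "gene_id": [f"g{i:03d}" for i in range(400)],
    "has_template": [i < 200 for i in range(400)],
    "bin_template": ["5" if i < 200 else "none" for i in range(400)],
    "has_nontemplate": False, "bin_nontemplate": "none"})
expr = generate_expression(SyntheticConfig(expression_effect=2.0),
                           flags, np.random.default_rng(0))
cmp_ = with_without_comparison(flags, expr, "tissue1", "either")
print(f"with hotspot: n={cmp_.n_a}, median log2(TPM+1)={cmp_.median_a:.2f}")
print(f"without:      n={cmp_.n_b}, median log2(TPM+1)={cmp_.median_b:.2f}")
print(f"rank-sum p = {cmp_.p_value:.2e}  (planted 2x expression effect)")

# distance-graded effect: closer hotspots, larger boost
rows = [(f"h{b}_{k:03d}", True, lbl, False, "none")
        for b, lbl in enumerate(BIN_LABELS) for k in range(200)]
graded_flags = pd.DataFrame(rows, columns=["gene_id", "has_template",
                                           "bin_template", "has_nontemplate",
                                           "bin_nontemplate"])
graded = generate_expression(
    SyntheticConfig(expression_effect=2.0, expression_distance_graded=True),
    graded_flags, np.random.default_rng(0))
members, _tests = hierarchical_bins({"tissue1": graded_flags}, graded)
med = members[members.strand == "template"].groupby("bin")["log2_tpm1"].median()
print("\nmedian log2(TPM+1) by template-strand distance bin:")
for lbl in BIN_LABELS:
    print(f"  +/-{lbl:>7s} bp  {med[lbl]:.2f}")
print("The +/-5 bp group sits highest: the planted effect is strongest for "
      "hotspots immediately at the TSS (adjacent bins overlap within noise "
      "at 200 genes per group).")
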