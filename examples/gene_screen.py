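"""Radiogenomic association screen on a synthetic expression matrix.

Generates a genes x cases matrix in which 50 of 1,000 genes carry a known
correlation (r = 0.6) with a per-case phenotype, applies the mean/SD gene
filter, correlates each surviving gene with the phenotype and selects genes
with |r| > 0.1.
"""

import numpy as np

from lesionfm import correlate_predictions, filter_genes, make_expression

rng = np.random.default_rng(0)
phenotype = rng.normal(size=130)
expr, informative = make_expression(phenotype, G=1000, g_informative=50,
                                    r_target=0.6, rng=rng)

kept = filter_genes(expr, top_k=500)
table = correlate_predictions(phenotype, expr.loc[kept])
selected = table.loc[table.selected, "gene_id"]

n_info_kept = len(set(kept) & set(informative))
n_info_selected = len(set(selected) & set(informative))
print(f"genes passing the mean filter + top-500 SD ranking: {len(kept)}")
print(f"informative genes among them:                       {n_info_kept}")
print(f"genes selected at |r| > 0.1:                        {len(selected)}")
print(f"informative genes selected:                         {n_info_selected}")
print("top 5 by |r|:")
print(table.head(5).to_string(index=False))

# Informative genes that survive the variance filter should be recovered
# essentially completely at r = 0.6 and n = 130; the remaining selections
# reflect the null rate of |r| > 0.1 at this sample size (about 26%).
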