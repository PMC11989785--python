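"""Over-representation analysis of a DEG list against gene sets.

Builds a small universe with one gene set holding the DEG list's members
plus random null sets, and shows the hypergeometric tail p-values with BH
correction.  The planted set should come back significant; the null sets
should not.
"""

from lrcrosstalk import generate_gene_sets, ora
from lrcrosstalk.enrichment import enrichment_report

universe = {f"G{i:03d}" for i in range(1, 201)}
degs = {f"G{i:03d}" for i in range(1, 21)}  # 20 DEGs

sets = generate_gene_sets(
    sorted(universe), enriched_members=sorted(degs), n_null_sets=10, set_size=20, seed=3
)
rows = ora(degs, universe, sets)
print(rows[["term_id", "k", "K", "n", "N", "p", "padj", "significant"]].head(5).to_string(index=False))
# k of K set members appear among the n DEGs drawn from an N-gene universe;
# the planted set has k = K = 20, so its tail p is essentially zero.

top, incidence = enrichment_report(rows, top_m=3)
print(f"\nsignificant terms: {int(rows.significant.sum())}; "
      f"gene-term links for the top ones: {len(incidence)}")
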