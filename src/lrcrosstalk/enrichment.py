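"""Hypergeometric over-representation analysis of DEG lists.

Classic ORA: for each gene set, the upper-tail hypergeometric probability of
drawing at least k set members in a DEG list of size n from a universe of N
genes containing K members, with BH correction across all tested sets.  The
universe is the expressed-gene universe (genes surviving the low-count
filter), not the whole annotation.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .io_formats import GeneSetCollection


def ora(
    deg_genes: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One row per term: k, K, n, N, upper-tail p, BH padj, significance.

    Terms are intersected with the universe first; terms with no universe
    member are dropped.  Rows come back sorted by p then term_id.
    """
    outside = deg_genes - universe
    if outside:
        raise ValueError(f"DEG genes outside the universe: {sorted(outside)[:10]}")
    N = len(universe)
    n = len(deg_genes)
    rows = []
    for term_id in sorted(sets.sets):
        name, members = sets.sets[term_id]
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        hits = sorted(in_universe & deg_genes)
        k = len(hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "genes": ",".join(hits),
            }
        )
    table = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p", "genes"])
    if len(table):
        table["padj"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["padj"] < alpha
        table = table.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        table["padj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table[["term_id", "term_name", "k", "K", "n", "N", "p", "padj", "significant", "genes"]]


def enrichment_report(rows: pd.DataFrame, top_m: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top significant terms plus a gene-term incidence table.

    The incidence table (one row per gene-term membership among the reported
    terms) is the tabular equivalent of a Sankey plot linking DEGs to terms.
    """
    sig = rows[rows["significant"]].head(top_m).reset_index(drop=True)
    incidence_rows = []
    for row in sig.itertuples(index=False):
        for gene in (row.genes.split(",") if row.genes else []):
            incidence_rows.append({"gene": gene, "term_id": row.term_id, "term_name": row.term_name})
    incidence = pd.DataFrame(incidence_rows, columns=["gene", "term_id", "term_name"])
    return sig, incidence
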