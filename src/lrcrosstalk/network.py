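"""DEG-induced subnetworks, degree hubs, and k-means module detection.

Hubs are ranked purely by degree (ties broken alphabetically).  Modules come
from spectral k-means: the k smallest eigenvectors of the symmetric
normalized Laplacian, row-normalized, clustered with k-means.  k defaults to
3, the number of subnetworks the co-culture study design expects per DEG
direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def induced_subgraph(network: nx.Graph, genes: set[str]) -> nx.Graph:
    """Subgraph on genes ∩ nodes, keeping edges with both ends retained."""
    return nx.Graph(network.subgraph(genes & set(network.nodes)))


def hub_ranking(network: nx.Graph, top_n: int = 10) -> pd.DataFrame:
    """Nodes sorted by degree descending, name ascending on ties."""
    rows = sorted(network.degree(), key=lambda item: (-item[1], item[0]))
    table = pd.DataFrame(rows[:top_n], columns=["gene", "degree"])
    table["rank"] = range(1, len(table) + 1)
    return table


@dataclass
class ModuleAssignment:
    modules: dict[str, int]  # non-isolated node -> module id in 1..k
    k: int
    isolated: list[str]

    def as_table(self) -> pd.DataFrame:
        rows = [{"gene": g, "module": m} for g, m in sorted(self.modules.items())]
        return pd.DataFrame(rows, columns=["gene", "module"])


def kmeans_modules(network: nx.Graph, k: int = 3, seed: int = 0) -> ModuleAssignment:
    """Spectral embedding + k-means module detection.

    Isolated nodes are excluded (their Laplacian rows carry no information)
    and reported separately.  The embedding takes the k eigenvectors of
    L_sym = I - D^{-1/2} A D^{-1/2} with the smallest eigenvalues; rows are
    normalized to unit length before KMeans(n_init=20, random_state=seed),
    so the result is deterministic for a fixed seed.  Edge 'weight'
    attributes, when present, weight the adjacency.
    """
    nodes = sorted(n for n in network.nodes if network.degree(n) > 0)
    isolated = sorted(n for n in network.nodes if network.degree(n) == 0)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(nodes) < k:
        raise ValueError(
            f"only {len(nodes)} non-isolated nodes for k={k}; reduce k or supply a denser network"
        )
    if k == 1:
        return ModuleAssignment({n: 1 for n in nodes}, 1, isolated)

    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    deg = A.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(len(nodes)) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh(L)
    embed = eigvecs[:, :k]
    norms = np.linalg.norm(embed, axis=1, keepdims=True)
    embed = embed / np.where(norms > 0, norms, 1.0)

    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    labels = km.fit_predict(embed)
    modules = {node: int(lbl) + 1 for node, lbl in zip(nodes, labels)}
    return ModuleAssignment(modules, k, isolated)


def pathway_gene_network(
    enrichment_rows: pd.DataFrame,
    result_table: pd.DataFrame,
    top_pathways: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-pathway incidence and co-membership edges for the top pathways.

    Takes the ``top_pathways`` significant enrichment rows (all of them,
    with a notice, if fewer), links each member gene to its pathway
    (annotated with the gene's log2fc), and connects two genes whenever they
    share at least one selected pathway.
    """
    sig = enrichment_rows[enrichment_rows["significant"]]
    selected = sig.head(top_pathways)
    incidence_rows = []
    members: dict[str, set[str]] = {}
    for row in selected.itertuples(index=False):
        genes = [g for g in (row.genes.split(",") if row.genes else []) if g]
        members[row.term_id] = set(genes)
        for gene in genes:
            lfc = (
                float(result_table.at[gene, "log2fc"]) if gene in result_table.index else float("nan")
            )
            incidence_rows.append({"gene": gene, "term_id": row.term_id, "log2fc": lfc})
    incidence = pd.DataFrame(incidence_rows, columns=["gene", "term_id", "log2fc"])

    edges: dict[tuple[str, str], int] = {}
    for term_genes in members.values():
        for a, b in combinations(sorted(term_genes), 2):
            edges[(a, b)] = edges.get((a, b), 0) + 1
    edge_rows = [
        {"gene_a": a, "gene_b": b, "shared_pathways": n} for (a, b), n in sorted(edges.items())
    ]
    co_membership = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "shared_pathways"])
    return incidence, co_membership
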