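"""Score-weighted gene networks and local over-representation analysis.

Networks are assembled from a user-supplied undirected interaction edge list:
nodes carry the final score, retained edges (both endpoints in the gene list)
carry the mean of the two endpoints' experiment scores multiplied by the
supplied interaction weight. Enrichment is an upper-tail hypergeometric test of
a query gene list against each gene set within a universe, with
Benjamini-Hochberg adjustment across the tested sets.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import EdgeList, GeneSetCollection

__all__ = ["build_network", "ora_enrich"]


def build_network(
    scores: pd.DataFrame,
    gene_list: list[str],
    edges: EdgeList,
    condition: str = "",
) -> nx.Graph:
    """Assemble the score-weighted network over ``gene_list``.

    ``scores`` is a score table with columns ``final_score`` and
    ``experiment_score``. Nodes are exactly ``gene_list`` (isolated nodes
    retained) weighted by final score; an input edge is kept iff both endpoints
    are in the list, with weight
    ``mean(experiment score of endpoints) * interaction weight``.
    """
    gene_list = [g.upper() for g in gene_list]
    missing = set(gene_list) - set(scores.index)
    if missing:
        raise ValueError(f"genes absent from the score table: {sorted(missing)[:5]}")
    g = nx.Graph(condition=condition)
    for gene in gene_list:
        g.add_node(gene, final_score=float(scores.at[gene, "final_score"]))
    members = set(gene_list)
    for a, b, w in edges.pairs():
        if a in members and b in members:
            exp_mean = 0.5 * (
                float(scores.at[a, "experiment_score"])
                + float(scores.at[b, "experiment_score"])
            )
            g.add_edge(a, b, weight=exp_mean * float(w), interaction_weight=float(w))
    return g


def ora_enrich(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
    adjust: str = "BH",
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set, within ``universe``.

    p is the upper-tail hypergeometric probability of observing at least the
    realized overlap; the adjusted column controls the FDR across the tested
    sets (Benjamini-Hochberg). Sets with zero universe overlap are skipped.
    Returns a DataFrame indexed by set name with columns ``overlap``,
    ``set_size``, ``query_size``, ``universe_size``, ``p_value``, ``adjusted``
    and ``genes`` (sorted overlapping symbols).
    """
    if adjust != "BH":
        raise ValueError(f"unknown adjustment {adjust!r}")
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q = {g.upper() for g in query}
    if not q:
        raise ValueError("empty query")
    if not q <= uni:
        raise ValueError(f"query genes outside the universe: {sorted(q - uni)[:5]}")

    rows = []
    for name, members in sorted(sets.items()):
        in_uni = members & uni
        if not in_uni:
            continue
        overlap = q & in_uni
        k, m, n, big_n = len(overlap), len(in_uni), len(q), len(uni)
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n))
        rows.append((name, k, m, n, big_n, min(p, 1.0), sorted(overlap)))
    out = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "query_size", "universe_size",
                 "p_value", "genes"],
    ).set_index("set")
    if len(out):
        out["adjusted"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out["adjusted"] = out[["adjusted", "p_value"]].max(axis=1)
    else:
        out["adjusted"] = pd.Series(dtype=float)
    return out.sort_values("p_value")
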