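"""Compound–target network construction and centrality ranking.

The classified interaction table (typically restricted to probable binders)
is merged with protein–protein interaction (PPI) edges into one undirected,
unweighted graph with typed nodes (compound / protein) and typed edges
(interaction / ppi). Degree, betweenness and closeness centralities are
computed on this merged graph, so a protein with no surviving compound
edges still carries its PPI degree — proteins present in the PPI list are
always retained as nodes. Per-measure dense ranks over the protein nodes
give the prioritization table.

Conventions: shortest-path betweenness with endpoints excluded, normalized
by (n−1)(n−2)/2; closeness computed within each connected component as
(reachable − 1) / Σ distances, 0 for isolated nodes (harmonic closeness is
available as an option).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

NODE_COMPOUND = "compound"
NODE_PROTEIN = "protein"
EDGE_INTERACTION = "interaction"
EDGE_PPI = "ppi"


def build_network(
    classified_interactions: pd.DataFrame,
    ppi_edges: pd.DataFrame,
    compound_attributes: pd.DataFrame | None = None,
    target_attributes: pd.DataFrame | None = None,
    include: frozenset[str] | set[str] = frozenset({"probable_binder"}),
) -> nx.Graph:
    """Merge interaction and PPI edges into one typed graph.

    Only interactions whose ``classification`` is in ``include`` become
    compound–protein edges (with the mean affinity as an edge attribute).
    Every protein named in the PPI edge list or target attribute table is
    kept as a node even if no compound edge survives. Node attributes
    (subcellular location, phytochemical class, ADME flags, ...) are copied
    from the attribute tables; referenced nodes missing from those tables
    warn rather than error.
    """
    g = nx.Graph()

    comp_attrs = _index_attrs(compound_attributes, "compound_id")
    targ_attrs = _index_attrs(target_attributes, "target_id")

    for tid in targ_attrs:
        g.add_node(tid, node_type=NODE_PROTEIN, **targ_attrs[tid])

    for _, row in ppi_edges.iterrows():
        a, b = str(row["target_a"]), str(row["target_b"])
        if a == b:
            raise ValueError(f"self-loop PPI edge on {a}")
        for t in (a, b):
            if t not in g:
                if targ_attrs and t not in targ_attrs:
                    warnings.warn(f"PPI target {t} missing from attribute table", stacklevel=2)
                g.add_node(t, node_type=NODE_PROTEIN)
        g.add_edge(a, b, edge_type=EDGE_PPI)

    kept = classified_interactions[
        classified_interactions["classification"].isin(include)
    ]
    for _, row in kept.iterrows():
        cid, tid = str(row["compound_id"]), str(row["target_id"])
        if cid not in g:
            if comp_attrs and cid not in comp_attrs:
                warnings.warn(f"compound {cid} missing from attribute table", stacklevel=2)
            g.add_node(cid, node_type=NODE_COMPOUND, **comp_attrs.get(cid, {}))
        if tid not in g:
            if targ_attrs and tid not in targ_attrs:
                warnings.warn(f"target {tid} missing from attribute table", stacklevel=2)
            g.add_node(tid, node_type=NODE_PROTEIN)
        if g.nodes[tid]["node_type"] != NODE_PROTEIN or g.nodes[cid]["node_type"] != NODE_COMPOUND:
            raise ValueError(f"malformed interaction edge {cid}–{tid}: node types clash")
        g.add_edge(
            cid,
            tid,
            edge_type=EDGE_INTERACTION,
            mean_affinity=float(row["mean_score"]),
            classification=str(row["classification"]),
        )
    return g


def _index_attrs(table: pd.DataFrame | None, key: str) -> dict[str, dict]:
    if table is None or table.empty:
        return {}
    out = {}
    for _, row in table.iterrows():
        d = {k: v for k, v in row.items() if k != key and pd.notna(v)}
        out[str(row[key])] = d
    return out


def centralities(network: nx.Graph, harmonic_closeness: bool = False) -> pd.DataFrame:
    """Degree, betweenness and closeness per node, with dense ranks over the
    protein nodes for each measure (higher value = better rank)."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = dict(network.degree())
    betweenness = nx.betweenness_centrality(network, normalized=True)
    if harmonic_closeness:
        n = network.number_of_nodes()
        closeness = {
            v: (c / (n - 1) if n > 1 else 0.0)
            for v, c in nx.harmonic_centrality(network).items()
        }
    else:
        # component-local closeness: (reachable - 1) / sum of distances
        closeness = nx.closeness_centrality(network, wf_improved=False)
    table = pd.DataFrame(
        {
            "node": list(network.nodes),
            "node_type": [network.nodes[v].get("node_type", "") for v in network.nodes],
            "degree": [degree[v] for v in network.nodes],
            "betweenness": [betweenness[v] for v in network.nodes],
            "closeness": [closeness[v] for v in network.nodes],
        }
    )
    prot = table["node_type"] == NODE_PROTEIN
    for measure in ("degree", "betweenness", "closeness"):
        ranks = np.full(len(table), np.nan)
        if prot.any():
            ranks[prot.to_numpy()] = dense_rank(
                table.loc[prot, measure].to_numpy(), higher_is_better=True
            )
        table[f"{measure}_rank"] = ranks
    return table


def dense_rank(values, higher_is_better: bool = True) -> np.ndarray:
    """Dense (competition-free) ranks: equal values share a rank and the next
    distinct value gets the previous rank + 1. Rank 1 is best."""
    arr = np.asarray(values, dtype=float)
    distinct = np.unique(arr)
    if higher_is_better:
        distinct = distinct[::-1]
    rank_of = {v: i + 1 for i, v in enumerate(distinct)}
    return np.array([rank_of[v] for v in arr], dtype=int)


def write_sif(network: nx.Graph, path) -> None:
    """Cytoscape SIF export: one line per edge, relation = edge type."""
    with open(path, "w") as fh:
        for a, b, data in network.edges(data=True):
            fh.write(f"{a}\t{data.get('edge_type', 'edge')}\t{b}\n")
        for v in network.nodes:
            if network.degree(v) == 0:
                fh.write(f"{v}\n")


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)
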