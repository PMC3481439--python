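"""Construction of the weighted background network.

The background is a simple undirected :class:`networkx.Graph`: self-pairs
are removed, duplicate pairs (either orientation) collapsed, and each node
carries a finite weight ``z`` taken from the gene score table. By default
nodes without a score are dropped together with their incident edges.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError


def _as_weight_map(scores) -> dict:
    if isinstance(scores, pd.DataFrame):
        return dict(zip(scores["gene_id"], scores["z"].astype(float)))
    return {k: float(v) for k, v in dict(scores).items()}


def build_network(
    pairs: Iterable, scores, drop_unscored: bool = True
) -> tuple[nx.Graph, dict]:
    """Build the weighted simple background network from raw pairs.

    ``scores`` is a gene score DataFrame (``gene_id``/``z`` columns) or a
    mapping gene -> z. Returns ``(graph, report)``; the report counts
    removed self-pairs, collapsed duplicates, and unscored nodes/edges.
    Isolated (but scored) nodes are retained. An empty result raises.
    """
    weights = _as_weight_map(scores)
    for gene, z in weights.items():
        if not np.isfinite(z):
            raise ValidationError(f"non-finite weight for gene {gene!r}")
    report = {
        "n_raw_pairs": 0,
        "n_self_removed": 0,
        "n_duplicates_removed": 0,
        "n_unscored_nodes_removed": 0,
        "n_unscored_edges_removed": 0,
    }
    g = nx.Graph()
    seen = set()
    nodes = set()
    for a, b in pairs:
        report["n_raw_pairs"] += 1
        nodes.update((a, b))
        if a == b:
            report["n_self_removed"] += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key in seen:
            report["n_duplicates_removed"] += 1
            continue
        seen.add(key)
        g.add_edge(a, b)
    g.add_nodes_from(nodes)  # keeps self-loop-only nodes as isolates

    if drop_unscored:
        unscored = [n for n in g.nodes if n not in weights]
        report["n_unscored_nodes_removed"] = len(unscored)
        report["n_unscored_edges_removed"] = sum(
            1 for u, v in g.edges if u in unscored or v in unscored
        )
        g.remove_nodes_from(unscored)
        for n in g.nodes:
            g.nodes[n]["z"] = weights[n]
    else:
        for n in g.nodes:
            g.nodes[n]["z"] = weights.get(n, 0.0)

    if g.number_of_nodes() == 0:
        raise ValidationError("resulting network is empty")
    return g, report


def network_summary(net: nx.Graph) -> dict:
    """Node/edge counts and the degree distribution (degree -> count)."""
    degrees = [d for _, d in net.degree()]
    hist: dict = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "degree_distribution": dict(sorted(hist.items())),
    }
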