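"""Graph statistics for candidate-gene protein–protein interaction networks.

Edges come from a user-supplied interaction list (gene A, gene B, combined
confidence score); only edges scoring strictly above the confidence
threshold (default 0.4) between query genes are kept.  The enrichment
p-value tests whether the query genes are more connected among themselves
than random gene sets of the same size would be, under a density-matched
binomial null: each of the k·(k−1)/2 possible query-internal edges is
present independently with the background network's edge density.  (This
is deliberately simpler than degree-corrected nulls used by interaction
databases, whose exact models are not reproducible; the two are not
numerically comparable.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import pandas as pd
from scipy import stats


@dataclass
class InteractionGraph:
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _read_edge_list(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = ["gene_a", "gene_b", "score"][: len(df.columns)]
    else:
        df = pd.read_csv(
            source, sep="\t", comment="#", header=None,
            names=["gene_a", "gene_b", "score"], dtype={"gene_a": str, "gene_b": str},
        )
    try:
        df["score"] = df["score"].astype(float)
    except (TypeError, ValueError) as exc:
        bad = df[pd.to_numeric(df["score"], errors="coerce").isna()].index
        line = int(bad[0]) + 1 if len(bad) else "?"
        raise ValueError(f"malformed edge-list score at data line {line}") from exc
    if df["gene_a"].isna().any() or df["gene_b"].isna().any():
        bad = df[df["gene_a"].isna() | df["gene_b"].isna()].index
        raise ValueError(f"malformed edge-list row at data line {int(bad[0]) + 1}")
    return df


def build_graph(
    edge_list,
    query_genes: Iterable[str],
    score_min: float = 0.4,
    include_isolated: bool = False,
) -> InteractionGraph:
    """Build the query-gene interaction graph.

    Edges are kept when the score is strictly above ``score_min`` and both
    endpoints are query genes.  Scores on a 0–1000 integer scale (as used
    by common interaction databases) are auto-detected and rescaled to
    [0, 1].  Self-loops and duplicate edges are dropped.
    """
    df = _read_edge_list(edge_list)
    query = {str(g).strip().upper() for g in query_genes}
    if len(df) and df["score"].max() > 1:
        df["score"] = df["score"] / 1000.0
    g = nx.Graph()
    if include_isolated:
        g.add_nodes_from(sorted(query))
    for row in df.itertuples():
        a, b = str(row.gene_a).strip().upper(), str(row.gene_b).strip().upper()
        if a == b:
            continue
        if row.score <= score_min:
            continue
        if a in query and b in query:
            prev = g.edges.get((a, b))
            if prev is None or row.score > prev["score"]:
                g.add_edge(a, b, score=row.score)
    return InteractionGraph(graph=g)


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def average_node_degree(g: InteractionGraph) -> float:
    """2·|E| / |V|, rounded half away from zero to two decimals."""
    if g.n_nodes == 0:
        raise ValueError("average node degree is undefined for an empty graph")
    return _round_half_up(2.0 * g.n_edges / g.n_nodes, 2)


def average_local_clustering(g: InteractionGraph) -> float:
    """Mean local clustering coefficient, counting degree<2 nodes as zero."""
    if g.n_nodes == 0:
        raise ValueError("clustering is undefined for an empty graph")
    return nx.average_clustering(g.graph, count_zeros=True)


def edge_enrichment_p(
    g: InteractionGraph, background_n_nodes: int, background_n_edges: int
) -> float:
    """Density-matched binomial tail probability of >= observed edges.

    X ~ Binomial(k(k-1)/2, q) with q the background edge density; the
    returned value is P(X >= observed).
    """
    if background_n_nodes < g.n_nodes or background_n_edges < g.n_edges:
        raise ValueError("background must be at least as large as the query graph")
    possible_bg = background_n_nodes * (background_n_nodes - 1) / 2
    if possible_bg <= 0:
        raise ValueError("background graph must have >= 2 nodes")
    q = background_n_edges / possible_bg
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"background edge density must lie in [0, 1], got {q}")
    n = g.n_nodes * (g.n_nodes - 1) // 2
    observed = g.n_edges
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n, q))


def graph_stats(
    g: InteractionGraph,
    background_n_nodes: Optional[int] = None,
    background_n_edges: Optional[int] = None,
) -> dict:
    out = {
        "nodes": g.n_nodes,
        "edges": g.n_edges,
        "avg_degree": average_node_degree(g),
        "avg_clustering": average_local_clustering(g),
    }
    if background_n_nodes is not None and background_n_edges is not None:
        out["p_enrichment"] = edge_enrichment_p(g, background_n_nodes, background_n_edges)
    return out


def partition_components(g: InteractionGraph, min_size: int = 2) -> list[set[str]]:
    """Deterministic module partition: connected components, largest first."""
    comps = [set(c) for c in nx.connected_components(g.graph) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), sorted(c)[0] if c else ""))
    return comps
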