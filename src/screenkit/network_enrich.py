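"""PPI-graph summaries, hub genes, and gene-set over-representation.

Graphs are undirected gene networks with per-edge confidence scores in
[0, 1]; summaries are taken after dropping edges below a confidence
threshold (0.9 being the usual "highest confidence" cut). Gene-set
enrichment is the classical hypergeometric upper-tail test against a fixed
background, with BH correction across sets and a STRING-style "strength"
(log10 of observed over expected overlap). The default retention filter is
p < 1e-5, overlap >= 3, strength >= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd
from scipy import stats


@dataclass
class GraphSummary:
    n_nodes: int
    n_edges: int
    avg_degree: float           # 2E/N, half-up to 1 decimal
    avg_local_clustering: float


def build_graph(edges: list[tuple[str, str, float]]) -> nx.Graph:
    """Undirected PPI graph from (gene_a, gene_b, confidence) triples."""
    g = nx.Graph()
    for a, b, conf in edges:
        if a == b:
            raise ValueError(f"self-edge on {a}")
        if not 0 <= conf <= 1:
            raise ValueError(f"confidence {conf} outside [0, 1] for {a}-{b}")
        if g.has_edge(a, b):
            raise ValueError(f"duplicate edge {a}-{b}")
        g.add_edge(a, b, confidence=conf)
    return g


def read_edges_tsv(path) -> nx.Graph:
    """Edge list TSV with columns gene_a, gene_b, confidence."""
    df = pd.read_csv(path, sep="\t")
    return build_graph(
        list(zip(df["gene_a"], df["gene_b"], df["confidence"].astype(float)))
    )


def filter_by_confidence(g: nx.Graph, confidence_min: float) -> nx.Graph:
    """Copy of the graph keeping edges with confidence >= the threshold.

    Nodes are retained even if isolated afterwards.
    """
    kept = nx.Graph()
    kept.add_nodes_from(g.nodes)
    kept.add_edges_from(
        (a, b, d) for a, b, d in g.edges(data=True)
        if d.get("confidence", 1.0) >= confidence_min
    )
    return kept


def graph_summary(g: nx.Graph, confidence_min: float = 0.0) -> GraphSummary:
    """Node/edge counts, average degree (2E/N) and mean local clustering."""
    g = filter_by_confidence(g, confidence_min)
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("graph is empty after confidence filtering")
    avg_degree = float(
        Decimal(str(2 * e / n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
    return GraphSummary(
        n_nodes=n,
        n_edges=e,
        avg_degree=avg_degree,
        avg_local_clustering=round(nx.average_clustering(g), 3),
    )


def hub_nodes(g: nx.Graph, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by degree, ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(g.degree, key=lambda item: (-item[1], item[0]))
    return ranked[:k]


def set_enrichment(
    query: set[str],
    gene_sets: dict[str, set[str]],
    background_size: int,
    p_max: float = 1e-5,
    min_count: int = 3,
    min_strength: float = 2.0,
) -> pd.DataFrame:
    """Hypergeometric over-representation with the three-way retention filter.

    For each named set: overlap with the query, upper-tail hypergeometric p
    (probability of >= the observed overlap), BH q across all tested sets,
    and strength = log10(observed / expected) with expected =
    |set| * |query| / background. Rows failing p < ``p_max``, overlap >=
    ``min_count`` or strength >= ``min_strength`` are dropped.
    """
    if not query:
        raise ValueError("empty query gene set")
    rows = []
    n_query = len(query)
    for name, members in gene_sets.items():
        if len(members) > background_size:
            raise ValueError(
                f"background ({background_size}) smaller than set {name!r} "
                f"({len(members)})"
            )
        overlap = len(query & members)
        p = float(
            stats.hypergeom.sf(overlap - 1, background_size, len(members), n_query)
        )
        expected = len(members) * n_query / background_size
        strength = (
            math.log10(overlap / expected) if overlap > 0 else -math.inf
        )
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "overlap_count": overlap,
                "p": p,
                "strength": strength,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        from .genomics_stats import bh_fdr

        df["q"] = bh_fdr(df["p"].to_numpy())
        keep = (
            (df["p"] < p_max)
            & (df["overlap_count"] >= min_count)
            & (df["strength"] >= min_strength)
        )
        df = df[keep].sort_values("p", kind="stable").reset_index(drop=True)
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
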