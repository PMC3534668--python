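"""Bipartite study–line co-citation network construction and statistics.

Studies and cell lines are the two node classes; an edge joins a study to
every line it used.  A line's degree is its usage frequency; a study's
degree is the number of distinct lines it used.  Edges are stored
undirected — every analysis here uses degree and connectivity only, and
orientation (study → line) is recoverable from the node class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import SimulatedNetwork

__all__ = [
    "build_network",
    "build_network_from_simulation",
    "component_stats",
    "usage_stats",
    "write_graphml",
    "write_edge_list",
    "UsageStats",
]

_STUDY, _LINE = "study", "line"


@dataclass
class UsageStats:
    """Descriptive statistics of a usage network."""

    line_degrees: pd.Series  # usage frequency per line, descending
    max_usage: int
    mean_lines_per_study: float
    n_studies: int
    n_lines: int
    n_edges: int


def build_network(table: pd.DataFrame) -> nx.Graph:
    """Build the bipartite graph from a canonicalized usage table.

    Node names collide only if a study id equals a line id, which the
    generated and curated corpora never produce; a guard raises otherwise.
    """
    g = nx.Graph()
    studies = pd.unique(table["study_id"])
    lines = pd.unique(table["line_id"])
    overlap = set(studies) & set(lines)
    if overlap:
        raise ValueError(f"study and line identifiers overlap: {sorted(overlap)[:5]}")
    g.add_nodes_from(studies, node_type=_STUDY)
    g.add_nodes_from(lines, node_type=_LINE)
    g.add_edges_from(zip(table["study_id"], table["line_id"]))
    return g


def build_network_from_simulation(net: SimulatedNetwork) -> nx.Graph:
    """Bipartite graph of a simulated network (nodes ``s<i>`` and ``l<j>``)."""
    g = nx.Graph()
    g.add_nodes_from((f"s{i}" for i in range(net.n_studies)), node_type=_STUDY)
    g.add_nodes_from((f"l{j}" for j in range(net.n_lines)), node_type=_LINE)
    g.add_edges_from(
        (f"s{s}", f"l{l}") for s, l in zip(net.edge_study, net.edge_line)
    )
    return g


def component_stats(g: nx.Graph) -> pd.DataFrame:
    """Connected components with study/line counts, largest first.

    Small satellite components (typically single derivation reports) are
    retained, not discarded.  Returns one row per component with columns
    ``component``, ``n_studies``, ``n_lines``, ``n_nodes``, ``is_largest``.
    """
    rows = []
    for nodes in nx.connected_components(g):
        n_lines = sum(1 for n in nodes if g.nodes[n]["node_type"] == _LINE)
        rows.append((len(nodes) - n_lines, n_lines, len(nodes)))
    rows.sort(key=lambda r: (-r[2], -r[0]))
    df = pd.DataFrame(rows, columns=["n_studies", "n_lines", "n_nodes"])
    df.insert(0, "component", range(len(df)))
    df["is_largest"] = False
    if len(df):
        df.loc[0, "is_largest"] = True
    return df


def usage_stats(g: nx.Graph) -> UsageStats:
    """Line usage frequencies and per-study line counts."""
    line_deg = {n: d for n, d in g.degree() if g.nodes[n]["node_type"] == _LINE}
    study_deg = [d for n, d in g.degree() if g.nodes[n]["node_type"] == _STUDY]
    degrees = pd.Series(line_deg, dtype=int).sort_values(ascending=False)
    n_edges = int(degrees.sum()) if len(degrees) else 0
    return UsageStats(
        line_degrees=degrees,
        max_usage=int(degrees.max()) if len(degrees) else 0,
        mean_lines_per_study=float(np.mean(study_deg)) if study_deg else float("nan"),
        n_studies=len(study_deg),
        n_lines=len(degrees),
        n_edges=n_edges,
    )


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Two-column TSV, study first on every row."""
    rows = []
    for u, v in g.edges():
        if g.nodes[u]["node_type"] == _LINE:
            u, v = v, u
        rows.append((u, v))
    pd.DataFrame(rows, columns=["study_id", "line_id"]).to_csv(
        path, sep="\t", index=False
    )
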