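"""Residue graphs: nodes at Cβ positions, edges for pairs within 12 Å.

Edges are stored once (i < j) with their Cβ–Cβ distance as the attribute and
expanded to both directions at message-passing time.  The 12 Å boundary is
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .features import FeatureTable

NEIGHBOR_CUTOFF = 12.0  # Å


@dataclass
class ResidueGraph:
    """Undirected residue graph with distance edge attributes."""

    node_features: np.ndarray       # (n, 29)
    node_coords: np.ndarray         # (n, 3) Cβ Å
    edges: np.ndarray               # (m, 2) int, i < j, each pair once
    edge_attr: np.ndarray           # (m,) Cβ-Cβ distance Å
    labels: np.ndarray              # (n,) {0, 1}

    @property
    def n_nodes(self) -> int:
        return len(self.node_features)

    def directed(self) -> tuple[np.ndarray, np.ndarray]:
        """Both-direction edge list and matching attributes (2m, 2)/(2m,)."""
        if len(self.edges) == 0:
            return np.zeros((0, 2), dtype=int), np.zeros(0)
        fwd = self.edges
        rev = self.edges[:, ::-1]
        return np.concatenate([fwd, rev]), np.concatenate([self.edge_attr, self.edge_attr])


def build_graph(table: FeatureTable, cutoff: float = NEIGHBOR_CUTOFF) -> ResidueGraph:
    """Connect every residue pair with 0 < Cβ distance ≤ cutoff (inclusive)."""
    if table.scheme != "graph":
        raise ValueError("build_graph requires a graph-scheme FeatureTable")
    if len(table) == 0:
        raise ValueError("empty feature table")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    coords = table.coords_cb
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(cutoff))  # distance <= cutoff, i < j
    edges = []
    attrs = []
    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d > 0.0:           # coincident anchors carry no direction: no self-like edge
            edges.append((i, j))
            attrs.append(d)
    edges = np.array(edges, dtype=int).reshape(-1, 2)
    attrs = np.array(attrs, dtype=float)
    return ResidueGraph(
        node_features=table.vectors,
        node_coords=coords,
        edges=edges,
        edge_attr=attrs,
        labels=np.asarray(table.labels, int),
    )


# ---------------------------------------------------------------------------
# Serialization


def save_graph(graph: ResidueGraph, node_path, edge_path) -> None:
    """Write the graph as a node-feature TSV and an edge-list TSV."""
    nodes = pd.DataFrame(graph.node_features)
    nodes.columns = [f"f{i}" for i in range(graph.node_features.shape[1])]
    for axis, name in enumerate("xyz"):
        nodes[f"cb_{name}"] = graph.node_coords[:, axis]
    nodes["label"] = graph.labels
    nodes.to_csv(node_path, sep="\t", index=False)

    pd.DataFrame({
        "i": graph.edges[:, 0],
        "j": graph.edges[:, 1],
        "distance": graph.edge_attr,
    }).to_csv(edge_path, sep="\t", index=False)


def load_graph(node_path, edge_path) -> ResidueGraph:
    nodes = pd.read_csv(node_path, sep="\t")
    feat_cols = [c for c in nodes.columns if c.startswith("f")]
    edges_df = pd.read_csv(edge_path, sep="\t")
    return ResidueGraph(
        node_features=nodes[feat_cols].to_numpy(float),
        node_coords=nodes[["cb_x", "cb_y", "cb_z"]].to_numpy(float),
        edges=edges_df[["i", "j"]].to_numpy(int).reshape(-1, 2),
        edge_attr=edges_df["distance"].to_numpy(float),
        labels=nodes["label"].to_numpy(int),
    )
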