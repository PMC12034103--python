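"""Attributed directed graph encoding of RNA loops.

Every loop becomes a strongly connected directed graph: one node per
nucleotide with a 4-way one-hot feature (A, C, G, U; modified/unknown
bases get an all-zero row), and one edge for every ordered node pair.
Each edge carries a 23-element feature vector:

======  ==============================================================
index   meaning
======  ==============================================================
0       inter-nucleotide distance (Angstrom)
1-18    one-hot over the 18 directional Leontis-Westhof pair classes
19-22   one-hot over the 4 stacking orientations
======  ==============================================================

A pair annotation (i, j, cWH) sets the cWH channel on edge i->j and the
edge-swapped class cHW on j->i; a stacking (i, j, upward) sets upward on
i->j and downward on j->i (inward and outward are self-symmetric).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import (
    LW_CLASSES,
    LW_INDEX,
    STACK_CLASSES,
    STACK_INDEX,
    Loop,
)
from .geometry import pairwise_distances

EDGE_FEATURE_DIM = 1 + len(LW_CLASSES) + len(STACK_CLASSES)  # 23
NODE_FEATURE_DIM = 4


@dataclass
class LoopGraph:
    """Dense container for one encoded loop.

    ``edge_features[u, v]`` is the 23-vector of the directed edge u->v;
    the diagonal is unused (zeros).  ``adjacency`` duplicates channel 0 as
    an N x N distance matrix for convenience.
    """

    node_features: np.ndarray          # (N, 4)
    edge_features: np.ndarray          # (N, N, 23)
    label: str | None = None
    loop_id: str | None = None

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edge_features = np.asarray(self.edge_features, dtype=float)
        n = self.node_features.shape[0]
        if self.node_features.shape != (n, NODE_FEATURE_DIM):
            raise ValueError("node_features must be (N, 4)")
        if self.edge_features.shape != (n, n, EDGE_FEATURE_DIM):
            raise ValueError("edge_features must be (N, N, 23)")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1)

    @property
    def adjacency(self) -> np.ndarray:
        return self.edge_features[:, :, 0]

    def edge_list(self) -> list[tuple[int, int, np.ndarray]]:
        """All N(N-1) ordered pairs with their feature vectors."""
        n = self.n_nodes
        return [
            (u, v, self.edge_features[u, v])
            for u in range(n)
            for v in range(n)
            if u != v
        ]

    def incoming_edge_sums(self) -> np.ndarray:
        """(N, 23) matrix: row v is the sum of features of edges u->v.

        This is the sufficient statistic the GIN needs for sum
        aggregation of edge messages on a complete digraph.
        """
        return self.edge_features.sum(axis=0)


def encode_loop(
    loop: Loop,
    distance_mode: str = "center_euclidean",
) -> LoopGraph:
    """Encode a coordinate-bearing, annotated loop as a :class:`LoopGraph`.

    Annotations have set semantics: duplicates are collapsed, but two
    different pair classes (or stacking directions) on the same ordered
    edge are rejected, since an edge carries at most one pair bit and one
    stacking bit.
    """
    n = loop.n_nucleotides
    if n < 2:
        raise ValueError(f"{loop.loop_id}: need at least 2 nucleotides to encode")
    missing = loop.missing_coordinate_indices()
    if missing:
        raise ValueError(
            f"{loop.loop_id}: nucleotides {missing} have no coordinates; "
            "attach coordinates before encoding"
        )

    node_features = np.array([nt.one_hot() for nt in loop.nucleotides])
    edge_features = np.zeros((n, n, EDGE_FEATURE_DIM))
    edge_features[:, :, 0] = pairwise_distances(loop, mode=distance_mode)

    pair_channel: dict[tuple[int, int], str] = {}
    for bp in loop.base_pairs:
        for ann in (bp, bp.reversed()):
            key = (ann.i, ann.j)
            prev = pair_channel.get(key)
            if prev is not None and prev != ann.lw_class:
                raise ValueError(
                    f"{loop.loop_id}: conflicting pair classes {prev} and "
                    f"{ann.lw_class} on edge {key}"
                )
            pair_channel[key] = ann.lw_class
    for (i, j), cls in pair_channel.items():
        edge_features[i, j, 1 + LW_INDEX[cls]] = 1.0

    stack_channel: dict[tuple[int, int], str] = {}
    for st in loop.stackings:
        for ann in (st, st.reversed()):
            key = (ann.i, ann.j)
            prev = stack_channel.get(key)
            if prev is not None and prev != ann.direction:
                raise ValueError(
                    f"{loop.loop_id}: conflicting stacking directions {prev} "
                    f"and {ann.direction} on edge {key}"
                )
            stack_channel[key] = ann.direction
    for (i, j), direction in stack_channel.items():
        edge_features[i, j, 1 + len(LW_CLASSES) + STACK_INDEX[direction]] = 1.0

    return LoopGraph(
        node_features=node_features,
        edge_features=edge_features,
        label=loop.family,
        loop_id=loop.loop_id,
    )


def encode_loops(loops, distance_mode: str = "center_euclidean") -> list[LoopGraph]:
    return [encode_loop(lp, distance_mode) for lp in loops]


# ---------------------------------------------------------------------------
# JSON-lines serialization (one graph per line)

def write_graphs_jsonl(graphs, path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            record = {
                "loop_id": g.loop_id,
                "label": g.label,
                "nodes": g.node_features.tolist(),
                "edges": [
                    [u, v, [round(float(x), 6) for x in feat]]
                    for u, v, feat in g.edge_list()
                ],
            }
            fh.write(json.dumps(record) + "\n")


def read_graphs_jsonl(path) -> list[LoopGraph]:
    graphs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            nodes = np.array(rec["nodes"], dtype=float)
            n = nodes.shape[0]
            edge_features = np.zeros((n, n, EDGE_FEATURE_DIM))
            for u, v, feat in rec["edges"]:
                edge_features[u, v] = feat
            graphs.append(
                LoopGraph(
                    node_features=nodes,
                    edge_features=edge_features,
                    label=rec.get("label"),
                    loop_id=rec.get("loop_id"),
                )
            )
    return graphs
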