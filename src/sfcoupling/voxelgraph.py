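"""Analytic-tractography voxel connectivity via shortest probable paths.

Each in-mask voxel gets directed edges to its up-to-26 lattice neighbours,
weighted by the negative natural logarithm of the fibre transition
probability.  The connectivity (likelihood) of a voxel pair is the
geometric mean of the transition probabilities along the most probable
path, found with Dijkstra's algorithm on the -log weights: minimizing the
summed -log p is the same as maximizing the product of the probabilities.

Path length counts transitions (edges), so a single step returns its own
probability; ``root="voxels"`` switches the geometric-mean root to the node
count.  Ties between equal-probability paths are resolved deterministically
by processing nodes in (distance, node-index) heap order and keeping the
first-found predecessor.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .synthetic import NEIGHBOR_OFFSETS, TransitionField

__all__ = ["VoxelGraph", "build_graph", "pairwise_connectivity", "voxel_connectome"]


@dataclass(frozen=True)
class VoxelGraph:
    """Directed voxel graph with -log-probability edge weights.

    ``voxels`` lists in-mask voxel coordinates in C order; ``index`` maps a
    coordinate tuple to its node id; ``adjacency[u]`` is a list of
    ``(v, weight, prob)`` triples with ``weight = -ln(prob) >= 0``.
    """

    voxels: tuple
    index: dict
    adjacency: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.voxels)


def build_graph(field: TransitionField) -> VoxelGraph:
    """Build the directed graph of an edge for every positive transition."""
    shape = field.shape
    voxels = [tuple(v) for v in np.argwhere(field.mask)]
    index = {v: i for i, v in enumerate(voxels)}
    adjacency: list[list] = [[] for _ in voxels]
    for u, (x, y, z) in enumerate(voxels):
        probs = field.probs[x, y, z]
        for k, (dx, dy, dz) in enumerate(NEIGHBOR_OFFSETS):
            p = probs[k]
            if p <= 0:
                continue
            tgt = (x + dx, y + dy, z + dz)
            v = index.get(tgt)
            if v is None:
                continue
            adjacency[u].append((v, float(-np.log(p)), float(p)))
    return VoxelGraph(
        voxels=tuple(voxels),
        index=index,
        adjacency=tuple(tuple(a) for a in adjacency),
    )


def _dijkstra(graph: VoxelGraph, source: int):
    """Shortest -log-probability distances, predecessors and edge counts."""
    n = graph.n_nodes
    dist = np.full(n, np.inf)
    steps = np.zeros(n, dtype=int)
    dist[source] = 0.0
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v, w, _p in graph.adjacency[u]:
            nd = d + w
            if nd < dist[v]:  # strict: first-found path wins on ties
                dist[v] = nd
                steps[v] = steps[u] + 1
                heapq.heappush(heap, (nd, v))
    return dist, steps


def _to_node(graph: VoxelGraph, voxel) -> int:
    key = tuple(int(c) for c in voxel)
    if key not in graph.index:
        raise ValueError(f"voxel {key} is outside the cortical mask")
    return graph.index[key]


def pairwise_connectivity(
    graph: VoxelGraph, sources, targets, root: str = "edges"
) -> np.ndarray:
    """Likelihood matrix between source and target voxels.

    For each pair the most probable path has transition probabilities
    ``p_1..p_L``; the likelihood is ``(prod p_k)^(1/L)`` with ``L`` the edge
    count (``root="voxels"``: ``L + 1``).  Self-pairs are 1, unreachable
    pairs 0.
    """
    if root not in ("edges", "voxels"):
        raise ValueError("root must be 'edges' or 'voxels'")
    src = [_to_node(graph, v) for v in sources]
    tgt = [_to_node(graph, v) for v in targets]
    out = np.zeros((len(src), len(tgt)))
    for i, s in enumerate(src):
        dist, steps = _dijkstra(graph, s)
        for j, t in enumerate(tgt):
            if t == s:
                out[i, j] = 1.0
            elif np.isfinite(dist[t]):
                length = steps[t] if root == "edges" else steps[t] + 1
                out[i, j] = np.exp(-dist[t] / length)
    return out


def voxel_connectome(
    graph: VoxelGraph, symmetrize: str = "mean", root: str = "edges"
) -> np.ndarray:
    """All-pairs likelihood matrix over the masked voxels.

    The directed likelihoods are symmetrized by averaging the two directions
    (``"mean"``, default), taking their maximum (``"max"``), or left as-is
    (``"none"``).
    """
    if symmetrize not in ("none", "mean", "max"):
        raise ValueError("symmetrize must be 'none', 'mean' or 'max'")
    m = pairwise_connectivity(graph, graph.voxels, graph.voxels, root=root)
    if symmetrize == "mean":
        m = (m + m.T) / 2.0
    elif symmetrize == "max":
        m = np.maximum(m, m.T)
    return m
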