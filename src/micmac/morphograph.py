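"""Skeleton graphs and the 16-feature morphology vector.

Each retained cell mask is thinned to a one-voxel medial skeleton, the
skeleton is converted to a branch graph — endpoints and junctions become
nodes, the voxel chains between them become edges with geodesic lengths in
µm — and sixteen morphological/graph features are computed per cell. High
compactness and low branching metrics correspond to amoeboid (activated)
morphologies; ramified surveillant cells score high on node counts, edge
lengths and tortuosity.

All geometry honours anisotropic voxel sizes: a diagonal skeleton step in
x–y contributes sqrt(dx² + dy²) µm of geodesic length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage import morphology

from .artifact_filter import CellMask

__all__ = [
    "Skeleton",
    "CellGraph",
    "FEATURE_NAMES",
    "skeletonize",
    "build_graph",
    "compute_features",
]

#: Canonical ordering of the morphology feature vector.
FEATURE_NAMES = [
    "volume",
    "mesh_area",
    "compactness",
    "polarity",
    "bound1",
    "bound2",
    "node_density",
    "ending_node_density",
    "avg_node_degree",
    "link_density",
    "s_metric",
    "volume_per_edge",
    "mean_edge_length",
    "max_edge_length",
    "total_skeleton_length",
    "mean_tortuosity",
]

# all 26 neighbour offsets in 3D
_OFFSETS = np.array(
    [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=np.intp
)


@dataclass
class Skeleton:
    """One-voxel-thick medial axis of a cell mask."""

    voxels: np.ndarray  # bool 3D array
    voxel_size: tuple[float, float, float]

    @property
    def coords(self) -> np.ndarray:
        return np.argwhere(self.voxels)


def skeletonize(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> Skeleton:
    """3D thinning to a medial skeleton, preserving 26-connectivity."""
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = morphology.skeletonize(mask)
    if not skel.any():
        # thinning can erase a very small blob; keep its central voxel
        center = np.round(np.argwhere(mask).mean(axis=0)).astype(int)
        skel = np.zeros_like(mask)
        skel[tuple(center)] = True
    return Skeleton(voxels=skel.astype(bool), voxel_size=tuple(float(v) for v in voxel_size))


class CellGraph:
    """Branch graph of one skeleton: junction/endpoint nodes, branch edges.

    ``graph`` is a networkx MultiGraph; node attribute ``coord`` is the µm
    position, edge attributes ``length`` (geodesic µm) and ``path`` (voxel
    coordinates along the branch).
    """

    def __init__(self, graph: nx.MultiGraph, voxel_size):
        self.graph = graph
        self.voxel_size = tuple(float(v) for v in voxel_size)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_endpoints(self) -> int:
        return sum(1 for _, d in self.graph.degree() if d == 1)

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.array([d["length"] for _, _, d in self.graph.edges(data=True)])

    def edge_tortuosities(self) -> np.ndarray:
        """Geodesic/Euclidean ratio per edge; self-loops are skipped."""
        out = []
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                continue
            cu = np.asarray(self.graph.nodes[u]["coord"])
            cv = np.asarray(self.graph.nodes[v]["coord"])
            euclid = float(np.linalg.norm(cu - cv))
            if euclid > 0:
                out.append(max(d["length"] / euclid, 1.0))
        return np.asarray(out)

    def total_length(self) -> float:
        return float(self.edge_lengths.sum()) if self.n_edges else 0.0


def _neighbor_structures(coords: np.ndarray, shape) -> tuple[dict, list[list[int]]]:
    """Index map and 26-adjacency lists over skeleton voxels."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    adjacency: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            nb = tuple(c + off)
            j = index.get(nb)
            if j is not None:
                adjacency[i].append(j)
    return index, adjacency


def build_graph(
    skeleton: Skeleton,
    voxel_size: tuple[float, float, float] | None = None,
    spur_min_length: float = 2.0,
) -> CellGraph:
    """Convert a skeleton into its simplified branch graph.

    Skeleton voxels with a neighbour count other than 2 become node voxels;
    26-adjacent junction voxels (≥3 neighbours) are merged into one node at
    their centroid. Edges follow the degree-2 chains between node voxels,
    with geodesic length the sum of anisotropic µm step lengths. Terminal
    spurs shorter than ``spur_min_length`` (thinning noise at junctions) are
    pruned and degree-2 chains re-simplified. An isolated blob yields the
    degenerate graph N=1, E=0.
    """
    vs = np.asarray(voxel_size if voxel_size is not None else skeleton.voxel_size, dtype=float)
    coords = skeleton.coords
    if coords.shape[0] == 0:
        raise ValueError("empty skeleton")
    index, adjacency = _neighbor_structures(coords, skeleton.voxels.shape)
    n = coords.shape[0]
    ncount = np.array([len(a) for a in adjacency])

    def step_len(i: int, j: int) -> float:
        return float(np.linalg.norm((coords[i] - coords[j]) * vs))

    # --- assign node ids -------------------------------------------------
    node_of_voxel = np.full(n, -1, dtype=np.intp)
    node_coords: list[np.ndarray] = []
    is_junction = ncount >= 3
    # merge adjacent junction voxels into clusters
    visited = np.zeros(n, dtype=bool)
    for i in range(n):
        if is_junction[i] and not visited[i]:
            stack, cluster = [i], []
            visited[i] = True
            while stack:
                cur = stack.pop()
                cluster.append(cur)
                for j in adjacency[cur]:
                    if is_junction[j] and not visited[j]:
                        visited[j] = True
                        stack.append(j)
            nid = len(node_coords)
            node_coords.append((coords[cluster] * vs).mean(axis=0))
            node_of_voxel[cluster] = nid
    for i in range(n):
        if ncount[i] != 2 and not is_junction[i]:  # endpoints and isolated voxels
            node_of_voxel[i] = len(node_coords)
            node_coords.append(coords[i] * vs)

    # pure cycles have no node voxel: anchor one per such component
    comp_seen = np.zeros(n, dtype=bool)
    for i in range(n):
        if comp_seen[i]:
            continue
        stack, comp = [i], []
        comp_seen[i] = True
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for j in adjacency[cur]:
                if not comp_seen[j]:
                    comp_seen[j] = True
                    stack.append(j)
        if all(node_of_voxel[v] < 0 for v in comp):
            anchor = min(comp)
            node_of_voxel[anchor] = len(node_coords)
            node_coords.append(coords[anchor] * vs)

    graph = nx.MultiGraph()
    for nid, c in enumerate(node_coords):
        graph.add_node(nid, coord=tuple(float(x) for x in c))

    # --- trace edges between node voxels ---------------------------------
    traversed: set[tuple[int, int]] = set()
    node_voxels = np.nonzero(node_of_voxel >= 0)[0]
    for start in node_voxels:
        for first in adjacency[start]:
            if node_of_voxel[first] >= 0 and node_of_voxel[first] == node_of_voxel[start]:
                continue  # intra-cluster junction adjacency is not a branch
            if (start, first) in traversed:
                continue
            path = [start, first]
            length = step_len(start, first)
            prev, cur = start, first
            while node_of_voxel[cur] < 0:
                nxt = [j for j in adjacency[cur] if j != prev]
                if not nxt:
                    break  # dangling chain end (should be a node, guard anyway)
                prev, cur = cur, nxt[0]
                path.append(cur)
                length += step_len(prev, cur)
            traversed.add((start, first))
            traversed.add((cur, prev))
            u, v = int(node_of_voxel[start]), int(node_of_voxel[cur])
            if node_of_voxel[cur] < 0:
                continue
            graph.add_edge(u, v, length=length, path=coords[path].copy())

    _prune_spurs(graph, spur_min_length)
    return CellGraph(graph, tuple(float(v) for v in vs))


def _prune_spurs(graph: nx.MultiGraph, spur_min_length: float) -> None:
    """Remove short terminal spurs at junctions, then re-simplify chains."""
    changed = True
    while changed:
        changed = False
        for u, v, key, d in list(graph.edges(keys=True, data=True)):
            if u == v or d["length"] >= spur_min_length:
                continue
            du, dv = graph.degree(u), graph.degree(v)
            tip, hub = (u, v) if du == 1 else (v, u) if dv == 1 else (None, None)
            if tip is None or graph.degree(hub) < 3:
                continue
            graph.remove_edge(u, v, key=key)
            graph.remove_node(tip)
            changed = True
        # merge pass-through nodes left behind by pruning
        for node in [n for n, deg in graph.degree() if deg == 2 and n in graph]:
            edges = list(graph.edges(node, keys=True, data=True))
            if len(edges) != 2:
                continue  # self-loop counts degree 2 via one edge
            (n1, a, k1, d1), (n2, b, k2, d2) = edges
            u = a if n1 == node else n1
            v = b if n2 == node else n2
            if u == node or v == node:
                continue
            graph.remove_node(node)
            graph.add_edge(u, v, length=d1["length"] + d2["length"], path=None)
            changed = True


def _covariance_spectrum(coords_um: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the voxel-coordinate covariance."""
    if coords_um.shape[0] < 2:
        return np.zeros(3)
    cov = np.cov(coords_um.T)
    vals = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(vals, 0.0, None)


def compute_features(cell_mask: CellMask, cell_graph: CellGraph) -> dict[str, float]:
    """The 16-entry morphology feature vector of one cell.

    Shape features come from the mask (volume, smooth surface, sphericity,
    covariance anisotropy, PCA-oriented extents); graph features from the
    branch graph (densities per µm³, degree statistics, s-metric, edge-length
    statistics, tortuosity). Degenerate graphs follow the documented
    conventions: link_density 0 for N<2, mean_tortuosity 1 for E=0,
    volume_per_edge uses max(E, 1).
    """
    V = cell_mask.volume
    area = cell_mask.mesh_area
    coords_um = cell_mask.voxels * np.asarray(cell_mask.voxel_size)

    eig = _covariance_spectrum(coords_um)
    total_eig = eig.sum()
    polarity = float(eig[0] / total_eig) if total_eig > 0 else 1.0 / 3.0

    if coords_um.shape[0] >= 2:
        cov = np.cov(coords_um.T)
        _, vecs = np.linalg.eigh(cov)
        proj = (coords_um - coords_um.mean(axis=0)) @ vecs
        extents = np.sort(proj.max(axis=0) - proj.min(axis=0))[::-1]
    else:
        extents = np.zeros(3)

    g = cell_graph.graph
    N = cell_graph.n_nodes
    E = cell_graph.n_edges
    n_end = cell_graph.n_endpoints
    degrees = dict(g.degree())
    lengths = cell_graph.edge_lengths

    s_metric = float(sum(degrees[u] * degrees[v] for u, v in g.edges()))
    tort = cell_graph.edge_tortuosities()

    return {
        "volume": float(V),
        "mesh_area": float(area),
        "compactness": float((36.0 * np.pi * V**2) ** (1.0 / 3.0) / area) if area > 0 else 0.0,
        "polarity": polarity,
        "bound1": float(extents[0]),
        "bound2": float(extents[1]),
        "node_density": float(N / V) if V > 0 else 0.0,
        "ending_node_density": float(n_end / V) if V > 0 else 0.0,
        "avg_node_degree": float(2.0 * E / N) if N > 0 else 0.0,
        "link_density": float(2.0 * E / (N * (N - 1))) if N >= 2 else 0.0,
        "s_metric": s_metric,
        "volume_per_edge": float(V / max(E, 1)),
        "mean_edge_length": float(lengths.mean()) if E else 0.0,
        "max_edge_length": float(lengths.max()) if E else 0.0,
        "total_skeleton_length": float(lengths.sum()) if E else 0.0,
        "mean_tortuosity": float(tort.mean()) if tort.size else 1.0,
    }
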