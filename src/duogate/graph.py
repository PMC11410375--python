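"""Pruned kNN neighborhood graphs per modality.

For single-cell data, distances come from the expression profiles (RNA after
PCA, protein after CLR); for spatial data, from the tissue coordinates. Each
cell's n nearest neighbors are then pruned to those sharing its Leiden
community in that modality, and the surviving directed edges are weighted by
the Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger("duogate")

N_NEIGHBORS_DEFAULT = 15
PRUNE_RESOLUTION_DEFAULT = 1.0


@dataclass
class NeighborSets:
    """Per-cell ordered neighbor index lists with the neighbor budget ``n``."""

    sets: list  # list of np.ndarray of int
    n: int

    def __post_init__(self) -> None:
        for i, s in enumerate(self.sets):
            if i in s:
                raise ValueError(f"cell {i} lists itself as a neighbor")
            if len(s) > self.n:
                raise ValueError(f"cell {i} exceeds the neighbor budget {self.n}")


@dataclass
class ClusterLabels:
    """Contiguous integer community labels with the modality that produced them."""

    labels: np.ndarray
    modality: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be contiguous integers starting at 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class NeighborhoodGraph:
    """Directed pruned kNN graph: weights W = D * B, binary indicator B."""

    W: sp.csr_matrix  # distance-weighted adjacency
    B: sp.csr_matrix  # binary indicator

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    def edge_list(self) -> pd.DataFrame:
        coo = self.B.tocoo()
        w = np.asarray(self.W[coo.row, coo.col]).ravel()
        return pd.DataFrame({"source": coo.row, "target": coo.col, "distance": w})

    def export(self, mtx_path: str, edges_path: str) -> None:
        from scipy.io import mmwrite

        mmwrite(mtx_path, self.W)
        self.edge_list().to_csv(edges_path, sep="\t", index=False)


def pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    """Full symmetric Euclidean distance matrix with zero diagonal."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("pairwise_euclidean requires finite input")
    return squareform(pdist(X, metric="euclidean"))


def knn_sets(D: np.ndarray, n: int) -> NeighborSets:
    """The n nearest cells per cell; distance ties broken by ascending index."""
    m = D.shape[0]
    if not (0 < n < m):
        raise ValueError(f"n must satisfy 0 < n < m (got n={n}, m={m})")
    sets = []
    idx = np.arange(m)
    for i in range(m):
        others = idx[idx != i]
        d = D[i, others]
        order = np.lexsort((others, d))  # distance first, index breaks ties
        sets.append(others[order[:n]])
    return NeighborSets(sets=sets, n=n)


def _knn_igraph(D: np.ndarray, n: int) -> igraph.Graph:
    sets = knn_sets(D, n)
    edges = {(min(i, j), max(i, j)) for i, s in enumerate(sets.sets) for j in s}
    g = igraph.Graph(n=D.shape[0], edges=sorted(edges), directed=False)
    return g


def leiden_labels(
    X: np.ndarray,
    resolution: float = PRUNE_RESOLUTION_DEFAULT,
    seed: int = 0,
    n_neighbors: int = N_NEIGHBORS_DEFAULT,
    modality: str = "",
) -> ClusterLabels:
    """Leiden communities on a kNN graph of X; deterministic given seed."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("leiden_labels requires finite input")
    m = X.shape[0]
    if m < 2:
        return ClusterLabels(np.zeros(m, dtype=np.int64), modality)
    n_neighbors = min(n_neighbors, m - 1)
    g = _knn_igraph(pairwise_euclidean(X), n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=np.int64)
    # relabel to contiguous 0..k-1 in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterLabels(labels, modality)


def prune_neighbors(sets: NeighborSets, labels: ClusterLabels) -> NeighborSets:
    """Keep only neighbors sharing the cell's community label; order preserved."""
    lab = labels.labels
    if len(lab) < len(sets.sets):
        raise ValueError("labels do not cover all cells")
    pruned = [s[lab[s] == lab[i]] for i, s in enumerate(sets.sets)]
    return NeighborSets(sets=pruned, n=sets.n)


def assemble_graph(D: np.ndarray, pruned: NeighborSets) -> NeighborhoodGraph:
    """B_ij = 1 iff j is a retained neighbor of i; W = D ∘ B (directed)."""
    m = D.shape[0]
    rows, cols = [], []
    for i, s in enumerate(pruned.sets):
        if len(s) and (s.min() < 0 or s.max() >= m):
            raise ValueError("neighbor index out of range")
        rows.extend([i] * len(s))
        cols.extend(s.tolist())
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    data = np.ones(len(rows), dtype=np.float64)
    B = sp.csr_matrix((data, (rows, cols)), shape=(m, m))
    W = sp.csr_matrix((D[rows, cols], (rows, cols)), shape=(m, m))
    return NeighborhoodGraph(W=W, B=B)


def symmetrize(graph: NeighborhoodGraph) -> NeighborhoodGraph:
    """Union-of-edges symmetrization (off by default in the pipeline)."""
    B = ((graph.B + graph.B.T) > 0).astype(np.float64)
    W = graph.W.maximum(graph.W.T)
    return NeighborhoodGraph(W=W.tocsr(), B=B.tocsr())


def build_graphs_single_cell(
    rna_reduced: np.ndarray,
    protein_norm: np.ndarray,
    n: int = N_NEIGHBORS_DEFAULT,
    resolution: float = PRUNE_RESOLUTION_DEFAULT,
    seed: int = 0,
):
    """Expression-derived graphs: kNN + same-community pruning per modality.

    Returns ``(tg, pg, t_labels, p_labels)`` — the transcriptome and proteome
    graphs plus the Leiden labels used for pruning (reused for triplet
    sampling during training).
    """
    if rna_reduced.shape[0] != protein_norm.shape[0]:
        raise ValueError("modalities must cover the same cells")
    graphs, labels = [], []
    for X, tag in ((rna_reduced, "rna"), (protein_norm, "protein")):
        D = pairwise_euclidean(X)
        sets = knn_sets(D, n)
        lab = leiden_labels(X, resolution=resolution, seed=seed, n_neighbors=n, modality=tag)
        graphs.append(assemble_graph(D, prune_neighbors(sets, lab)))
        labels.append(lab)
    return graphs[0], graphs[1], labels[0], labels[1]


def build_graphs_spatial(
    coords: np.ndarray,
    rna_norm: np.ndarray,
    protein_norm: np.ndarray,
    n: int = N_NEIGHBORS_DEFAULT,
    resolution: float = PRUNE_RESOLUTION_DEFAULT,
    seed: int = 0,
    prune: str = "expression",
):
    """Coordinate-derived graphs with modality-specific expression pruning.

    Both modalities share the spatial kNN structure and spatial edge weights;
    pruning labels come from each modality's expression profile
    (``prune="expression"``) or are skipped entirely (``prune="none"``).
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be a cells x 2 matrix")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    if not (coords.shape[0] == rna_norm.shape[0] == protein_norm.shape[0]):
        raise ValueError("coordinates and modalities must cover the same cells")
    if prune not in ("expression", "none"):
        raise ValueError("prune must be 'expression' or 'none'")
    D = pairwise_euclidean(coords)
    sets = knn_sets(D, n)
    graphs, labels = [], []
    for X, tag in ((rna_norm, "rna"), (protein_norm, "protein")):
        if prune == "expression":
            lab = leiden_labels(X, resolution=resolution, seed=seed, n_neighbors=n, modality=tag)
            pruned = prune_neighbors(sets, lab)
        else:
            lab = ClusterLabels(np.zeros(coords.shape[0], dtype=np.int64), tag)
            pruned = sets
        graphs.append(assemble_graph(D, pruned))
        labels.append(lab)
    return graphs[0], graphs[1], labels[0], labels[1]
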