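"""Patient-similarity graphs for the GCN encoders.

For one modality, pairwise cosine distances d_ij = 1 - cos(x_i, x_j) are
computed among samples and a single global threshold is chosen so that each
sample retains about ``edge_per_node`` neighbours on average (the threshold
is the (k*N)-th smallest off-diagonal distance, counting ordered pairs).
Retained edges are weighted by cosine similarity s_ij = 1 - d_ij (clipped at
zero), a self-loop of weight 1 is added to every node, and each row is
L1-normalized so the adjacency is row-stochastic.

For evaluation, a single transductive graph is built over the union of
training and test samples with the same thresholding rule, so test samples
are embedded relative to the training samples without using labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from .preprocess import OmicsView

__all__ = [
    "SampleGraph",
    "cosine_distance_matrix",
    "pick_threshold",
    "build_graph",
    "build_transductive_graph",
    "export_edge_list",
]


@dataclass
class SampleGraph:
    """Row-stochastic weighted adjacency over samples for one modality."""

    adjacency: sp.csr_matrix
    edge_per_node: int
    threshold: float

    def __post_init__(self):
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.nnz and a.data.min() < 0:
            raise ValueError("adjacency weights must be non-negative")
        rows = np.asarray(a.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("adjacency rows must sum to 1")
        if np.any(a.diagonal() <= 0):
            raise ValueError("every node needs a positive self-loop")

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]

    def dense(self) -> np.ndarray:
        return self.adjacency.toarray()


def cosine_distance_matrix(view: OmicsView) -> np.ndarray:
    """Symmetric matrix of d_ij = 1 - cos(x_i, x_j), zero diagonal."""
    x = view.matrix
    norms = np.linalg.norm(x, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"cosine distance undefined for all-zero sample(s) "
            f"{[view.sample_ids[i] for i in bad[:5]]}")
    d = squareform(pdist(x, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return d


def pick_threshold(distances: np.ndarray, edge_per_node: int) -> float:
    """The (k*N)-th smallest off-diagonal distance (ordered pairs), so about
    k directed neighbours per node survive on average."""
    n = distances.shape[0]
    k = int(edge_per_node)
    if k < 1 or k >= n:
        raise ValueError(f"edge_per_node must satisfy 1 <= k < N (k={k}, N={n})")
    off = distances[~np.eye(n, dtype=bool)]
    need = k * n
    if need > off.size:
        raise ValueError(f"k*N = {need} exceeds the {off.size} ordered pairs")
    return float(np.sort(off, kind="stable")[need - 1])


def _adjacency_from_distances(distances: np.ndarray, threshold: float) -> sp.csr_matrix:
    n = distances.shape[0]
    keep = (distances <= threshold) & ~np.eye(n, dtype=bool)
    weights = np.where(keep, np.clip(1.0 - distances, 0.0, None), 0.0)
    weights = weights + np.eye(n)  # self-loop weight 1 before normalization
    weights /= weights.sum(axis=1, keepdims=True)
    return sp.csr_matrix(weights)


def build_graph(view: OmicsView, edge_per_node: int) -> SampleGraph:
    """Threshold + similarity weighting + self-loops + row L1 normalization."""
    d = cosine_distance_matrix(view)
    thr = pick_threshold(d, edge_per_node)
    return SampleGraph(adjacency=_adjacency_from_distances(d, thr),
                       edge_per_node=int(edge_per_node), threshold=thr)


def build_transductive_graph(train_view: OmicsView, test_view: OmicsView,
                             edge_per_node: int) -> tuple[SampleGraph, np.ndarray]:
    """One graph over train+test (test rows appended); returns the graph and
    the boolean test-row mask."""
    if train_view.feature_names != test_view.feature_names:
        raise ValueError("train and test views must share the feature space")
    if test_view.n_samples == 0:
        g = build_graph(train_view, edge_per_node)
        return g, np.zeros(train_view.n_samples, dtype=bool)
    from dataclasses import replace
    union = replace(
        train_view,
        matrix=np.vstack([train_view.matrix, test_view.matrix]),
        sample_ids=list(train_view.sample_ids) + list(test_view.sample_ids),
    )
    g = build_graph(union, edge_per_node)
    is_test = np.zeros(union.n_samples, dtype=bool)
    is_test[train_view.n_samples:] = True
    return g, is_test


def export_edge_list(graph: SampleGraph, path) -> None:
    """Write (i, j, weight) rows as TSV for inspection."""
    coo = graph.adjacency.tocoo()
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{w:.10g}\n")
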