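"""Class graph templates and per-subject functional graphs.

Each diagnostic class gets one template: a KNN graph over the rows of the
class-mean connectivity matrix, weighted by a Gaussian kernel whose width is
the mean retained neighbor distance. A subject is then represented twice —
once per template — sharing its own node features (the rows of its
connectivity matrix) while borrowing each class's edge structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .connectivity import ConnectivityMatrix


@dataclass
class GraphTemplate:
    class_label: str  # "ASD" | "HC"
    weights: np.ndarray  # N x N symmetric, zero diagonal, entries in [0, 1]
    k: int
    theta: float  # Gaussian kernel width
    source_mean: np.ndarray  # the class-mean connectivity the template came from

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class FunctionalGraph:
    """A subject's node features paired with one class template."""

    node_features: np.ndarray  # N x d, rows of the subject's connectivity
    template: GraphTemplate

    def __post_init__(self) -> None:
        f = np.asarray(self.node_features, dtype=float)
        if f.shape[0] != self.template.n_nodes:
            raise ValueError(
                f"feature rows ({f.shape[0]}) do not match template nodes "
                f"({self.template.n_nodes})"
            )
        if not np.isfinite(f).all():
            raise ValueError("non-finite node features")
        self.node_features = f


def class_mean_connectivity(train: list[ConnectivityMatrix], label: str) -> np.ndarray:
    """Element-wise arithmetic mean of the training matrices of one class."""
    mats = [c.values for c in train]
    if not mats:
        raise ValueError(f"no training subjects for class {label!r}")
    return np.mean(np.stack(mats), axis=0)


def build_template(mean_fc: np.ndarray, k: int, label: str) -> GraphTemplate:
    """KNN + Gaussian-kernel template from a class-mean connectivity matrix.

    Nodes are the rows of ``mean_fc``; distances are Euclidean between rows.
    Each node keeps its k nearest other nodes (ties at the k-th distance broken
    by ascending node index); the kernel width theta is the mean of all
    retained directed distances; kept weights are exp(-d^2 / (2 theta^2));
    the directed graph is symmetrized by the element-wise max (union KNN),
    so every node ends with between k and N-1 neighbors.
    """
    mean_fc = np.asarray(mean_fc, dtype=float)
    if mean_fc.ndim != 2 or mean_fc.shape[0] != mean_fc.shape[1]:
        raise ValueError("mean connectivity must be square")
    if not np.isfinite(mean_fc).all():
        raise ValueError("mean connectivity has non-finite entries")
    n = mean_fc.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < N ({n}), got {k}")

    dist = squareform(pdist(mean_fc, metric="euclidean"))

    # Directed KNN: for each node, k nearest others; stable sort keeps
    # ascending-index tie-breaking deterministic.
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        order = order[order != i]
        keep[i, order[:k]] = True

    retained = dist[keep]
    theta = float(retained.mean())

    w_dir = np.zeros((n, n))
    if theta > 0:
        w_dir[keep] = np.exp(-(dist[keep] ** 2) / (2.0 * theta**2))
    else:  # all retained distances zero: kernel value is exactly 1
        w_dir[keep] = 1.0
    weights = np.maximum(w_dir, w_dir.T)
    np.fill_diagonal(weights, 0.0)
    return GraphTemplate(class_label=label, weights=weights, k=k, theta=theta,
                         source_mean=mean_fc.copy())


def assemble_graphs(
    subject_fc: ConnectivityMatrix,
    asd_template: GraphTemplate,
    hc_template: GraphTemplate,
) -> tuple[FunctionalGraph, FunctionalGraph]:
    """Pair a subject's connectivity rows with each class template.

    The two graphs share the identical node-feature matrix (no rescaling);
    only the edge weights differ.
    """
    n = subject_fc.n_rois
    if asd_template.n_nodes != n or hc_template.n_nodes != n:
        raise ValueError(
            f"subject has {n} ROIs but templates have "
            f"{asd_template.n_nodes}/{hc_template.n_nodes} nodes"
        )
    features = subject_fc.values
    return (
        FunctionalGraph(node_features=features, template=asd_template),
        FunctionalGraph(node_features=features, template=hc_template),
    )
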