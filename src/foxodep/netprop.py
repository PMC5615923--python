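"""Network propagation of significance scores with topology-bias correction.

P-values of a protein set are mapped to network nodes as ``Y = -log2(p)``
(proteins outside the set count as p = 1, i.e. score 0) and diffused over the
confidence-filtered interaction network with the update

    F <- alpha * W @ F + (1 - alpha) * Y,      F0 = Y,

where ``W = D^{-1/2} A D^{-1/2}`` is the symmetrically degree-normalized
adjacency and ``alpha`` (default 0.8) is the fraction of score shared with
neighbours per step.  Since the spectral radius of ``alpha * W`` is below 1,
the iteration contracts to the unique solution of
``(I - alpha W) F = (1 - alpha) Y``.

Hubs accumulate score regardless of signal; the *topology bias* is the
smoothed profile of an all-ones input and is subtracted from the smoothed
scores.  Corrected dependent/independent profiles are subtracted from each
other for a combined view and clustered hierarchically (complete linkage,
Euclidean distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy

__all__ = [
    "PropagationConfig",
    "load_network",
    "normalize_adjacency",
    "build_score_vector",
    "propagate",
    "topology_bias",
    "propagate_scores",
    "combined_profile",
    "cluster_scores",
    "linkage_newick",
]


@dataclass
class PropagationConfig:
    alpha: float = 0.8  # share spread to neighbours per iteration
    tol: float = 1e-9  # max-absolute-change convergence threshold
    max_iter: int = 10_000
    min_confidence: float = 0.4
    weighted: bool = False  # confidence-weighted adjacency instead of binary

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def load_network(
    edges: pd.DataFrame,
    min_confidence: float = 0.4,
    nodes: Sequence[str] | None = None,
) -> nx.Graph:
    """Build a simple undirected graph from an edge table.

    Self-loops are dropped, parallel edges collapsed keeping the maximum
    confidence, and edges below ``min_confidence`` removed.  ``nodes``
    optionally fixes the node universe (nodes whose edges were all filtered
    remain as isolated nodes).
    """
    required = {"node_a", "node_b", "confidence"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for a, b, c in edges[["node_a", "node_b", "confidence"]].itertuples(index=False):
        if a == b:
            continue
        c = float(c)
        if c < min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], c)
        else:
            g.add_edge(a, b, confidence=c)
    return g


def normalize_adjacency(
    network: nx.Graph, weighted: bool = False
) -> tuple[sparse.csr_matrix, list[str]]:
    """Symmetric degree normalization W = D^{-1/2} A D^{-1/2}.

    Uses the binary adjacency by default; with ``weighted=True`` the
    confidence scores weight the edges.  Isolated nodes yield zero rows.
    Returns the sparse matrix and the node order it indexes.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodelist = sorted(network.nodes())
    A = nx.to_scipy_sparse_array(
        network, nodelist=nodelist, weight="confidence" if weighted else None
    ).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    D = sparse.diags(inv_sqrt)
    W = (D @ A @ D).tocsr()
    return W, nodelist


def build_score_vector(
    pvalues: pd.Series, node_universe: Sequence[str], subset: Iterable[str]
) -> np.ndarray:
    """Raw node scores Y_i = -log2(p_i) for subset members, 0 elsewhere.

    Excluding a protein amounts to setting its p-value to 1 (score 0).
    Zero p-values are clipped to the smallest positive float with a warning.
    """
    subset = set(subset)
    p = pvalues.reindex(node_universe)
    if ((p > 1) & p.notna()).any():
        raise ValueError("p-values above 1 encountered")
    if ((p == 0) & p.notna()).any():
        warnings.warn("p-values of 0 clipped to the smallest positive float", stacklevel=2)
        p = p.clip(lower=np.finfo(float).tiny)
    y = -np.log2(p.to_numpy(dtype=float))
    in_subset = np.array([n in subset for n in node_universe])
    y = np.where(in_subset & ~np.isnan(y), y, 0.0)
    return y


def propagate(
    Y: np.ndarray,
    W: sparse.spmatrix,
    alpha: float = 0.8,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Iterate F <- alpha W F + (1 - alpha) Y from F0 = Y to convergence."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("scores must be finite")
    F = Y.copy()
    for _ in range(max_iter):
        F_next = alpha * (W @ F) + (1.0 - alpha) * Y
        delta = float(np.max(np.abs(F_next - F))) if F.size else 0.0
        F = F_next
        if delta < tol:
            return F
    raise RuntimeError(
        f"propagation did not converge in {max_iter} iterations (residual {delta:.3e})"
    )


def topology_bias(
    W: sparse.spmatrix,
    alpha: float = 0.8,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Smoothed profile of a uniform unit input; subtracted to de-bias hubs."""
    ones = np.ones(W.shape[0])
    return propagate(ones, W, alpha=alpha, tol=tol, max_iter=max_iter)


def propagate_scores(
    pvalues: pd.Series,
    subset: Iterable[str],
    W: sparse.spmatrix,
    nodes: Sequence[str],
    config: PropagationConfig | None = None,
) -> pd.DataFrame:
    """Raw, smoothed, bias and corrected scores for one protein set."""
    config = config or PropagationConfig()
    y = build_score_vector(pvalues, nodes, subset)
    f = propagate(y, W, config.alpha, config.tol, config.max_iter)
    b = topology_bias(W, config.alpha, config.tol, config.max_iter)
    return pd.DataFrame(
        {"Y": y, "F": f, "bias": b, "corrected": f - b},
        index=pd.Index(nodes, name="node"),
    )


def combined_profile(dep: pd.DataFrame, indep: pd.DataFrame) -> pd.Series:
    """Corrected dependent minus corrected independent score per node."""
    if not dep.index.equals(indep.index):
        raise ValueError("profiles must share the same node universe")
    return dep["corrected"] - indep["corrected"]


def cluster_scores(profiles, n_clusters: int) -> np.ndarray:
    """Agglomerative clustering of node score profiles.

    Complete linkage on Euclidean distances, cut to ``n_clusters``; ties in
    merge height are resolved deterministically by scipy's lowest-index
    ordering, so cluster labels are reproducible for a fixed input order.
    Returns integer labels 1..n_clusters aligned with the input rows.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if n_clusters > X.shape[0]:
        raise ValueError("n_clusters exceeds the number of nodes")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    return hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")


def linkage_newick(profiles, labels: Sequence[str]) -> str:
    """Newick text of the complete-linkage dendrogram, for audit."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    tree = hierarchy.to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = render(node.left), render(node.right)
        return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

    return render(tree) + ";"
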