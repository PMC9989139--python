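"""Topology metrics: flexibility, clustering, global and local efficiency.

Flexibility is the fraction of inter-layer transitions in which a node
changes community label (0 = rigid, 1 = maximally flexible); the other three
metrics are computed on binary graphs obtained by proportional density
thresholding, over the 20-density grid, with graphs whose giant component
covers less than 90% of nodes flagged as fragmented rather than dropped.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix, DensityGrid, proportional_threshold


def node_flexibility(Q: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node flexibility f_i and mean F from an N x T label matrix.

    f_i = (# transitions where the label changes) / (T - 1); equivalently
    one minus the same-label fraction of consecutive layers.  Invariant to
    any global relabelling of communities.
    """
    Q = np.asarray(Q)
    if Q.ndim != 2 or Q.shape[1] < 2:
        raise ValueError("Q must be N x T with T >= 2 layers")
    f = (Q[:, 1:] != Q[:, :-1]).mean(axis=1)
    return f, float(f.mean())


def _binary(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    return (A != 0).astype(float)


def clustering_coefficient(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node C_i = triangles_i / (k_i (k_i - 1) / 2); k_i < 2 gives 0."""
    A = _binary(A)
    np.fill_diagonal(A, 0)
    k = A.sum(axis=1)
    tri = np.diag(A @ A @ A) / 2.0
    denom = k * (k - 1) / 2.0
    C = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return C, float(C.mean())


def global_efficiency(A: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Disconnected pairs contribute 0; normalization is 1/(n(n-1)), so the
    complete graph scores exactly 1.
    """
    A = _binary(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    D = shortest_path(A, method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node efficiency of the subgraph induced on its neighbours.

    The node itself is excluded; nodes with fewer than 2 neighbours get 0.
    """
    A = _binary(A)
    np.fill_diagonal(A, 0)
    n = A.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size < 2:
            continue
        eff[i] = global_efficiency(A[np.ix_(nbrs, nbrs)])
    return eff, float(eff.mean())


def is_fragmented(A: np.ndarray, giant_fraction: float = 0.9) -> bool:
    """True when the largest connected component covers < giant_fraction."""
    A = _binary(A)
    n_comp, labels = connected_components(A, directed=False)
    largest = np.bincount(labels).max()
    return largest < giant_fraction * A.shape[0]


def metrics_over_densities(
    W: np.ndarray | ConnectivityMatrix,
    grid: DensityGrid | None = None,
    Q_supplier: Callable[[float], np.ndarray] | None = None,
    **keys: str,
) -> pd.DataFrame:
    """Tidy metric table over the density grid for one weighted matrix.

    For every density the matrix is proportionally thresholded and
    clustering, global and local efficiency computed on the binary graph;
    when ``Q_supplier`` is given its N x T label matrix for that density
    adds a flexibility row.  Extra keyword arguments (subject, condition,
    band, window, network, ...) are carried into every row.
    """
    if isinstance(W, ConnectivityMatrix):
        keys.setdefault("band", W.band)
        keys.setdefault("window", W.window)
        keys.setdefault("condition", W.condition)
        W = W.W
    grid = grid or DensityGrid()
    rows = []
    for d in grid:
        A = proportional_threshold(W, float(d))
        frag = is_fragmented(A)
        _, C = clustering_coefficient(A)
        ge = global_efficiency(A)
        _, le = local_efficiency(A)
        vals = {"clustering": C, "global_efficiency": ge, "local_efficiency": le}
        if Q_supplier is not None:
            _, F = node_flexibility(Q_supplier(float(d)))
            vals["flexibility"] = F
        for metric, value in vals.items():
            rows.append(
                {**keys, "density": float(d), "metric": metric,
                 "value": value, "fragmented": frag}
            )
    return pd.DataFrame(rows)


def summarize_metrics(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Mean and SD of metric values across densities per grouping key."""
    g = table.groupby(by + ["metric"])["value"]
    out = g.agg(["mean", "std"]).reset_index()
    return out.rename(columns={"mean": "value_mean", "std": "value_sd"})
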