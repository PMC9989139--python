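"""Modularity-based community detection with iterated consensus.

Community structure is found by Louvain modularity maximisation with a
resolution parameter gamma, repeated many times with randomized node
visitation (5000 iterations in the full pipeline), and consolidated by
consensus: every run's labels are aligned to the best-modularity run by
Hungarian matching on the contingency table, the consensus label of a node
is its modal aligned label, and per-node stability is the fraction of runs
agreeing with the consensus.  Dynamic (multi-window) assignments couple
layer copies of each node with an inter-layer weight omega in a
supra-adjacency; omega = 0 reduces to independent per-layer consensus with
labels matched across consecutive layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class CommunityAssignment:
    """Node x layer integer labels with detection metadata."""

    Q: np.ndarray  # N x T int labels
    layer_names: list[str]
    gamma: float
    omega: float
    stability: np.ndarray  # per-node fraction of iterations agreeing


def _check_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    return A


def modularity(A: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Newman-Girvan modularity with resolution gamma.

    Q = (1/2m) sum_ij [a_ij - gamma * k_i k_j / 2m] delta(c_i, c_j), with the
    diagonal included as self-weight; gamma = 1 recovers the standard value.
    """
    A = _check_adjacency(A)
    labels = np.asarray(labels)
    if labels.shape[0] != A.shape[0]:
        raise ValueError("labels must cover all nodes")
    two_m = A.sum()
    if two_m == 0:
        raise ValueError("empty graph: modularity undefined (m = 0)")
    k = A.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((A - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel as contiguous positive integers, by descending community size
    (ties by smallest member index) for reproducibility."""
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    sizes = {u: (labels == u).sum() for u in uniq}
    first = {u: int(np.argmax(labels == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-sizes[u], first[u]))
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in labels], dtype=int)


def louvain_partition(A: np.ndarray, gamma: float = 1.0, seed: int = 0) -> np.ndarray:
    """One Louvain run; labels renumbered by descending community size.

    Isolated nodes come out as singletons.  Node visitation order is
    randomized by ``seed``.
    """
    A = _check_adjacency(A)
    G = nx.from_numpy_array(A)
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=gamma, seed=int(seed)
    )
    labels = np.empty(A.shape[0], dtype=int)
    for c, members in enumerate(comms):
        for i in members:
            labels[i] = c
    return _renumber(labels)


def match_labels(reference: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` to maximally overlap ``reference``.

    Hungarian assignment on the contingency table; labels without a partner
    keep fresh ids above the reference's range.  Matching a partition to
    itself is the identity.
    """
    reference = np.asarray(reference)
    labels = np.asarray(labels)
    ref_ids = np.unique(reference)
    lab_ids = np.unique(labels)
    cont = np.zeros((lab_ids.size, ref_ids.size))
    for a, la in enumerate(lab_ids):
        for b, rb in enumerate(ref_ids):
            cont[a, b] = np.sum((labels == la) & (reference == rb))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {}
    for a, b in zip(rows, cols):
        if cont[a, b] > 0:
            mapping[lab_ids[a]] = ref_ids[b]
    nxt = int(ref_ids.max()) + 1 if ref_ids.size else 1
    for la in lab_ids:
        if la not in mapping:
            mapping[la] = nxt
            nxt += 1
    return np.array([mapping[l] for l in labels], dtype=int)


def consensus_partition(
    A: np.ndarray, gamma: float = 1.0, n_iter: int = 5000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterated-Louvain consensus: (labels, per-node stability, allegiance).

    Runs are aligned to the highest-modularity run; the consensus label is
    the per-node mode of aligned labels, stability the modal fraction, and
    the allegiance matrix P[i, j] the fraction of runs in which i and j
    share a community.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    A = _check_adjacency(A)
    n = A.shape[0]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_iter)]
    G = nx.from_numpy_array(A)  # build once; only the visit order reseeds
    runs = []
    for s in seeds:
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=s
        )
        labels = np.empty(n, dtype=int)
        for c, members in enumerate(comms):
            for i in members:
                labels[i] = c
        runs.append(_renumber(labels))
    qs = [modularity(A, r, gamma) for r in runs]
    ref = runs[int(np.argmax(qs))]
    aligned = np.stack([match_labels(ref, r) for r in runs])  # n_iter x N
    P = np.zeros((n, n))
    for r in runs:
        P += (r[:, None] == r[None, :]).astype(float)
    P /= n_iter
    consensus = np.empty(n, dtype=int)
    stability = np.empty(n)
    for i in range(n):
        vals, counts = np.unique(aligned[:, i], return_counts=True)
        consensus[i] = vals[np.argmax(counts)]
        stability[i] = counts.max() / n_iter
    return _renumber(consensus), stability, P


def sweep_parameters(
    A: np.ndarray,
    gammas: np.ndarray | list[float] | None = None,
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Consensus over a resolution grid: (gamma, n_communities, mean_stability).

    The default grid spans 1 to 2.5 in steps of 0.05 (31 values).
    """
    if gammas is None:
        gammas = default_gamma_grid()
    gammas = np.asarray(gammas, dtype=float)
    if gammas.size == 0:
        raise ValueError("gammas must be non-empty")
    rows = []
    for g in gammas:
        labels, stability, _ = consensus_partition(A, g, n_iter, seed)
        rows.append(
            {
                "gamma": float(g),
                "n_communities": int(np.unique(labels).size),
                "mean_stability": float(stability.mean()),
            }
        )
    return pd.DataFrame(rows)


def default_gamma_grid() -> np.ndarray:
    return np.round(np.arange(1.0, 2.5 + 1e-9, 0.05), 10)


def select_gamma(sweep: pd.DataFrame, target_n: int = 6) -> float:
    """The resolution whose consensus community count is closest to target
    (ties go to the higher stability, then the smaller gamma)."""
    d = sweep.assign(dist=(sweep["n_communities"] - target_n).abs())
    d = d.sort_values(["dist", "mean_stability", "gamma"],
                      ascending=[True, False, True])
    return float(d.iloc[0]["gamma"])


def multilayer_modularity_matrix(
    layers: list[np.ndarray], gamma: float, omega: float
) -> tuple[np.ndarray, float]:
    """Multilayer modularity matrix B and total weight 2*mu.

    Each layer contributes its own null model (A_s - gamma k_s k_s^T / 2m_s)
    on the diagonal block; inter-layer identity coupling omega links every
    pair of layer copies of the same node (categorical coupling) and enters
    B directly, with no null term.  The multilayer quality of a partition is
    (1/2mu) sum_ij B_ij delta(c_i, c_j).
    """
    n = layers[0].shape[0]
    L = len(layers)
    B = np.zeros((n * L, n * L))
    two_mu = 0.0
    for l, A in enumerate(layers):
        A = np.asarray(A, dtype=float)
        two_m = A.sum()
        two_mu += two_m
        k = A.sum(axis=1)
        block = A - (gamma * np.outer(k, k) / two_m if two_m > 0 else 0.0)
        B[l * n : (l + 1) * n, l * n : (l + 1) * n] = block
    if omega > 0:
        idx = np.arange(n)
        for l1 in range(L):
            for l2 in range(l1 + 1, L):
                B[l1 * n + idx, l2 * n + idx] = omega
                B[l2 * n + idx, l1 * n + idx] = omega
        two_mu += omega * n * L * (L - 1)
    return B, two_mu


def multilayer_modularity(
    layers: list[np.ndarray], Q: np.ndarray, gamma: float, omega: float
) -> float:
    """Quality of an N x T assignment under the multilayer matrix above."""
    B, two_mu = multilayer_modularity_matrix(
        [np.asarray(A, dtype=float) for A in layers], gamma, omega
    )
    labels = Q.T.reshape(-1)  # supra order: layer-major, node-minor
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)  # singleton partition scores 0 coupling
    return float((B * same).sum() / two_mu) if two_mu > 0 else 0.0


def _local_move_partition(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy modularity-matrix local moving with randomized node order.

    Starts from singletons and repeatedly moves each node to the community
    with the largest positive gain sum_j-in-c B_ij until no move improves;
    the quality is non-decreasing across passes by construction.
    """
    n = B.shape[0]
    labels = np.arange(n)
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            row = B[i].copy()
            row[i] = 0.0
            gains = np.zeros(n)
            np.add.at(gains, labels, row)
            current = labels[i]
            best = int(np.argmax(gains))
            if gains[best] > gains[current] + 1e-12:
                labels[i] = best
                improved = True
    return labels


def dynamic_assignment(
    layers: list[np.ndarray],
    gamma: float = 1.0,
    omega: float = 1.0,
    n_iter: int = 100,
    seed: int = 0,
    layer_names: list[str] | None = None,
) -> CommunityAssignment:
    """Community labels across time-window layers.

    With omega > 0 a consensus Louvain runs on the supra-adjacency of
    identity-coupled layer copies, so labels are shared across layers by
    construction; with omega = 0 each layer gets its own consensus and
    labels are matched across consecutive layers by maximal overlap.
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    n = layers[0].shape[0]
    for l, A in enumerate(layers):
        if np.asarray(A).shape != (n, n):
            raise ValueError(f"layer {l} node set differs from layer 0")
    layer_names = layer_names or [f"layer{l + 1}" for l in range(len(layers))]
    if omega > 0:
        B, _ = multilayer_modularity_matrix(
            [np.asarray(A, dtype=float) for A in layers], gamma, omega
        )
        ss = np.random.SeedSequence(seed)
        runs, quals = [], []
        for child in ss.spawn(n_iter):
            rng = np.random.default_rng(child)
            lab = _local_move_partition(B, rng)
            runs.append(lab)
            same = lab[:, None] == lab[None, :]
            quals.append(float((B * same).sum()))
        ref = runs[int(np.argmax(quals))]
        aligned = np.stack([match_labels(ref, r) for r in runs])
        nl = B.shape[0]
        consensus = np.empty(nl, dtype=int)
        stability = np.empty(nl)
        for i in range(nl):
            vals, counts = np.unique(aligned[:, i], return_counts=True)
            consensus[i] = vals[np.argmax(counts)]
            stability[i] = counts.max() / n_iter
        consensus = _renumber(consensus)
        Q = consensus.reshape(len(layers), n).T
        node_stab = stability.reshape(len(layers), n).mean(axis=0)
        # weak coupling can leave layer-local community ids; align them
        for l in range(1, Q.shape[1]):
            Q[:, l] = match_labels(Q[:, l - 1], Q[:, l])
    else:
        ss = np.random.SeedSequence(seed)
        cols, stabs = [], []
        for A, child in zip(layers, ss.spawn(len(layers))):
            lab, st, _ = consensus_partition(
                np.asarray(A, dtype=float), gamma, n_iter,
                int(child.generate_state(1)[0] % (2**31)),
            )
            cols.append(lab)
            stabs.append(st)
        for l in range(1, len(cols)):
            cols[l] = match_labels(cols[l - 1], cols[l])
        Q = np.stack(cols, axis=1)
        node_stab = np.stack(stabs, axis=1).mean(axis=1)
    return CommunityAssignment(
        Q=Q, layer_names=layer_names, gamma=gamma, omega=omega, stability=node_stab
    )
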