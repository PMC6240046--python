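"""Connectivity graphs, FDR thresholding, modules, participation coefficients.

Per condition, trial-wise beta series are correlated node-by-node (Pearson),
the matrix is thresholded by keeping only edges significant at FDR q = 0.05
(Benjamini-Hochberg over all unique edges, with negative correlations
removed), the coarse parcel-level graph is partitioned into modules with the
Louvain method, the module labels are propagated to voxels, and each node's
participation coefficient

    PC_i = 1 - sum_s (kappa_is / k_i)^2

is computed from its strength k_i and per-module strengths kappa_is.
Community structure is estimated on the coarse graph only and never
re-estimated at the fine scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .betaseries import BetaSeries

__all__ = [
    "ConnectivityGraph",
    "ModulePartition",
    "correlation_matrix",
    "threshold_fdr",
    "parcel_average",
    "louvain_partition",
    "propagate_modules",
    "participation_coefficient",
    "modularity_q",
]


@dataclass
class ConnectivityGraph:
    """Weighted symmetric connectivity matrix with threshold provenance."""

    weights: np.ndarray  # node x node, zero diagonal
    n_trials: int
    threshold: dict = field(default_factory=dict)  # q, test, n_edges_kept

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class ModulePartition:
    """Node-to-module assignment with its modularity score."""

    labels: np.ndarray  # module id per node, 1..M
    q: float
    resolution: float = 1.0
    rng_seed: int | None = None
    n_restarts: int = 1

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


def correlation_matrix(betas: BetaSeries) -> ConnectivityGraph:
    """Pearson correlation of beta series across trials, diagonal zeroed."""
    data = betas.data
    if betas.n_trials < 3:
        raise ValueError("need at least 3 trials to correlate beta series")
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance nodes: {dead.tolist()}")
    R = np.corrcoef(data)
    np.fill_diagonal(R, 0.0)
    R = (R + R.T) / 2.0
    return ConnectivityGraph(weights=R, n_trials=betas.n_trials)


def _edge_pvalues(r: np.ndarray, n_trials: int) -> np.ndarray:
    """Two-sided p from the t-transform of r with n_trials - 2 df."""
    df = n_trials - 2
    rc = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rc * np.sqrt(df / (1.0 - rc**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    return p


def bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of rejected hypotheses."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        reject[order[: k + 1]] = True
    return reject


def threshold_fdr(graph: ConnectivityGraph, q: float = 0.05) -> ConnectivityGraph:
    """Keep edges significant at FDR q; zero non-survivors and all negatives.

    Per-edge two-sided p-values come from the t-transform of r with
    ``n_trials - 2`` degrees of freedom; Benjamini-Hochberg runs over all
    unique (upper-triangle) edges.
    """
    if graph.n_trials < 4:
        raise ValueError("FDR thresholding needs at least 4 trials")
    W = graph.weights
    iu = np.triu_indices(graph.n_nodes, k=1)
    r = W[iu]
    p = _edge_pvalues(r, graph.n_trials)
    keep = bh_reject(p, q) & (r > 0)
    out = np.zeros_like(W)
    out[iu[0][keep], iu[1][keep]] = r[keep]
    out = out + out.T
    if not keep.any():
        warnings.warn("no edges survive FDR thresholding", stacklevel=2)
    return ConnectivityGraph(
        weights=out,
        n_trials=graph.n_trials,
        threshold=dict(q=q, test="bh_edge_t", n_edges_kept=int(keep.sum())),
    )


def parcel_average(betas: BetaSeries, parcellation: np.ndarray) -> BetaSeries:
    """Average voxel beta series within parcels (unweighted mean).

    ``parcellation`` holds integer labels 1..n_parcels for every voxel, in
    the same flat order as the beta-series nodes.
    """
    labels = np.asarray(parcellation).reshape(-1).astype(int)
    if len(labels) != betas.n_nodes:
        raise ValueError(
            f"parcellation covers {len(labels)} voxels but beta series has "
            f"{betas.n_nodes} nodes"
        )
    n_parcels = int(labels.max())
    counts = np.bincount(labels, minlength=n_parcels + 1)[1:]
    if np.any(counts == 0) or np.any(labels < 1):
        empties = np.flatnonzero(counts == 0) + 1
        raise ValueError(f"empty parcels: {empties.tolist()}")
    sums = np.zeros((n_parcels, betas.n_trials))
    np.add.at(sums, labels - 1, betas.data)
    return BetaSeries(
        data=sums / counts[:, None],
        trial_types=betas.trial_types,
        node_ids=np.arange(1, n_parcels + 1),
    )


def modularity_q(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Direct evaluation of weighted Newman modularity for a partition:
    Q = (1/2m) sum_ij [A_ij - gamma k_i k_j / 2m] delta(c_i, c_j)."""
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    same = np.asarray(labels)[:, None] == np.asarray(labels)[None, :]
    return float(np.sum((W - gamma * np.outer(k, k) / two_m) * same) / two_m)


def _canonical(labels: np.ndarray) -> tuple:
    """Relabel modules by first appearance so partitions compare stably."""
    mapping, out = {}, []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out.append(mapping[lab])
    return tuple(out)


def louvain_partition(
    graph: ConnectivityGraph,
    gamma: float = 1.0,
    n_restarts: int = 100,
    rng_seed: int = 0,
) -> ModulePartition:
    """Weighted Louvain community detection with random restarts.

    Runs ``n_restarts`` Louvain passes with different random node orders and
    keeps the partition with the highest modularity Q (evaluated directly
    from the modularity formula); ties break toward the lexicographically
    lowest canonical labelling.
    """
    W = graph.weights
    if np.any(W < 0):
        raise ValueError("Louvain requires a non-negative graph")
    if not np.any(W > 0):
        raise ValueError("graph has no edges")
    n = graph.n_nodes
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(W, k=1))
    G.add_weighted_edges_from(zip(ii.tolist(), jj.tolist(), W[ii, jj].tolist()))

    best = None
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_restarts)
    for s in seeds:
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=int(s) % (2**32 - 1)
        )
        labels = np.empty(n, dtype=int)
        for m, nodes in enumerate(comms, start=1):
            labels[list(nodes)] = m
        labels = np.array(_canonical(labels))
        q = modularity_q(W, labels, gamma)
        key = (-q, _canonical(labels))
        if best is None or key < best[0]:
            best = (key, labels, q)
    _, labels, q = best
    return ModulePartition(
        labels=labels, q=q, resolution=gamma, rng_seed=rng_seed, n_restarts=n_restarts
    )


def propagate_modules(
    partition: ModulePartition, parcellation: np.ndarray
) -> np.ndarray:
    """Assign each voxel its parcel's module label (flat voxel order)."""
    labels = np.asarray(parcellation).reshape(-1).astype(int)
    n_parcels = int(labels.max())
    if len(partition.labels) < n_parcels:
        missing = np.arange(len(partition.labels) + 1, n_parcels + 1)
        raise ValueError(f"partition does not cover parcels: {missing.tolist()}")
    return np.asarray(partition.labels)[labels - 1]


def participation_coefficient(
    graph: ConnectivityGraph, labels: np.ndarray
) -> np.ndarray:
    """Participation coefficient PC_i = 1 - sum_s (kappa_is / k_i)^2.

    kappa_is is node i's summed edge weight into module s and k_i its total
    strength; zero-strength nodes get 0 by convention. Values lie in
    [0, 1 - 1/M] for M modules: 0 marks a provincial node whose connections
    stay inside its own module.
    """
    W = graph.weights
    labels = np.asarray(labels).reshape(-1)
    if len(labels) != graph.n_nodes:
        raise ValueError("labels must cover all nodes")
    if np.any(W < 0):
        raise ValueError("participation coefficient requires a non-negative graph")
    uniq, inv = np.unique(labels, return_inverse=True)
    onehot = np.zeros((graph.n_nodes, len(uniq)))
    onehot[np.arange(graph.n_nodes), inv] = 1.0
    kappa = W @ onehot  # node x module strengths
    k = kappa.sum(axis=1)
    pc = np.zeros(graph.n_nodes)
    pos = k > 0
    pc[pos] = 1.0 - np.sum((kappa[pos] / k[pos, None]) ** 2, axis=1)
    pc = np.clip(pc, 0.0, None)
    assert np.all(pc <= 1.0 - 1.0 / len(uniq) + 1e-12)
    return pc
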