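"""Resting-state functional-connectivity graph inference and partitioning.

The resting segments (first base block of each run, concatenated) are
confound-regressed and bandpassed, the conditional-independence skeleton
over region series is recovered with the order-independent PC-stable
algorithm using Fisher-z partial-correlation tests, surviving edges are
weighted by the smallest-magnitude partial correlation observed for the
pair (the "net" correlation), and the largest connected component is
partitioned into k functional networks by spectral clustering
(symmetric normalized Laplacian, k-means in the eigenvector embedding).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .cluster import apply_cluster_correction

log = logging.getLogger(__name__)


@dataclass
class RestSeries:
    """Region (or voxel) x time matrix in percent-change units."""

    matrix: np.ndarray
    sampling_interval: float
    node_ids: list = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if np.isnan(self.matrix).any():
            raise ValueError("rest series contains missing values")
        if self.node_ids is None:
            self.node_ids = list(range(self.matrix.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_rest(
    series: np.ndarray,
    confounds: pd.DataFrame | np.ndarray | None,
    band: tuple[float, float],
    sampling_interval: float,
    node_ids: list | None = None,
) -> RestSeries:
    """Confound regression followed by FFT bandpass.

    Fourier bins strictly outside [low, high] Hz (and DC) are zeroed;
    rows are re-centered afterwards.
    """
    X = np.asarray(series, float).copy()
    low, high = band
    nyquist = 0.5 / sampling_interval
    if not 0 <= low < high:
        raise ValueError("band must satisfy 0 <= low < high")
    if high > nyquist:
        raise ValueError(f"band high {high} Hz exceeds Nyquist {nyquist} Hz")

    if confounds is not None:
        C = np.asarray(confounds, float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([np.ones(C.shape[0]), C])
        if C.shape[0] != X.shape[1]:
            raise ValueError("confound length must match the time axis")
        beta, *_ = np.linalg.lstsq(C, X.T, rcond=None)
        X = X - (C @ beta).T

    n = X.shape[1]
    freqs = np.fft.rfftfreq(n, d=sampling_interval)
    F = np.fft.rfft(X, axis=1)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    F[:, ~keep] = 0.0
    X = np.fft.irfft(F, n=n, axis=1)
    X -= X.mean(axis=1, keepdims=True)
    return RestSeries(matrix=X, sampling_interval=sampling_interval, node_ids=node_ids)


def extract_roi_series(
    voxel_series: np.ndarray,
    labels: np.ndarray,
    significance_mask: np.ndarray,
    min_voxels: int = 4,
) -> tuple[np.ndarray, list[int], list[int]]:
    """Mean series per region over label-and-mask voxels.

    ``voxel_series`` is (x, y, z, t); regions whose significant-voxel count
    falls below ``min_voxels`` are dropped (logged). Returns
    (region x time matrix, kept region ids, dropped region ids).
    """
    labels = np.asarray(labels)
    mask = np.asarray(significance_mask, bool)
    if labels.shape != mask.shape or labels.shape != voxel_series.shape[:-1]:
        raise ValueError("labels, mask and voxel grid must share a shape")
    kept, dropped, rows = [], [], []
    for r in sorted(int(v) for v in np.unique(labels) if v != 0):
        vox = (labels == r) & mask
        if vox.sum() < min_voxels:
            dropped.append(r)
            continue
        kept.append(r)
        rows.append(voxel_series[vox].mean(axis=0))
    if not kept:
        raise ValueError("no region has enough significant voxels")
    if dropped:
        log.info("dropped %d regions below %d voxels: %s", len(dropped), min_voxels, dropped)
    return np.vstack(rows), kept, dropped


# ---------------------------------------------------------------------------
# PC-stable skeleton
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityGraph:
    graph: nx.Graph
    ci_alpha: float

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    def weight(self, i, j) -> float:
        return self.graph.edges[i, j]["weight"]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "weight": d["weight"], "min_test_p": d["min_test_p"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "min_test_p"])


def partial_correlation(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation of variables i, j given the set S, from the
    correlation matrix (inversion of the (|S|+2) submatrix)."""
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    K = np.linalg.pinv(sub)
    denom = np.sqrt(K[0, 0] * K[1, 1])
    if denom == 0:
        return 0.0
    return float(np.clip(-K[0, 1] / denom, -1.0, 1.0))


def fisher_z_pvalue(rho: float, n: int, s: int) -> float:
    """Two-sided p of the Fisher-z transformed partial correlation with
    conditioning-set size s."""
    df = n - s - 3
    if df <= 0:
        return 1.0
    rho = min(max(rho, -1 + 1e-12), 1 - 1e-12)
    z = np.sqrt(df) * np.arctanh(rho)
    return float(2.0 * stats.norm.sf(abs(z)))


def pc_stable_skeleton(
    rest: RestSeries,
    ci_alpha: float,
    significant_only: bool = False,
    max_cond_size: int | None = None,
) -> ConnectivityGraph:
    """Order-independent PC-stable skeleton with Fisher-z CI tests.

    An edge is removed as soon as any conditional-independence test given a
    subset of either endpoint's (depth-frozen) neighborhood is
    nonsignificant at ``ci_alpha``. Surviving edges are weighted by the
    smallest-magnitude signed partial correlation seen across the pair's
    tests (restricted to significant tests when ``significant_only``; for
    surviving edges every recorded test is significant, so both readings
    coincide at the default).
    """
    X = rest.matrix
    p, n = X.shape
    sds = X.std(axis=1)
    if np.any(sds == 0):
        bad = [rest.node_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant node series: {bad}")
    corr = np.corrcoef(X)

    adj = {i: set(range(p)) - {i} for i in range(p)}
    # per-pair record of (|rho|, rho, p-value) over all tests performed
    best: dict[tuple[int, int], tuple[float, float, float]] = {}

    def record(i, j, rho, pval):
        key = (min(i, j), max(i, j))
        if significant_only and pval > ci_alpha:
            return
        cur = best.get(key)
        if cur is None or abs(rho) < cur[0]:
            best[key] = (abs(rho), rho, pval)

    depth = 0
    while True:
        frozen = {i: frozenset(adj[i]) for i in range(p)}
        if max_cond_size is not None and depth > max_cond_size:
            break
        any_possible = any(len(frozen[i]) - 1 >= depth for i in range(p))
        if not any_possible:
            break
        for i in range(p):
            for j in sorted(frozen[i]):
                if j <= i or j not in adj[i]:   # unordered pairs, still present
                    continue
                removed = False
                for a, b in ((i, j), (j, i)):
                    neighbors = frozen[a] - {b}
                    if len(neighbors) < depth:
                        continue
                    for S in itertools.combinations(sorted(neighbors), depth):
                        rho = partial_correlation(corr, a, b, S)
                        pval = fisher_z_pvalue(rho, n, depth)
                        record(a, b, rho, pval)
                        if pval > ci_alpha:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            removed = True
                            break
                    if removed:
                        break
        depth += 1

    G = nx.Graph()
    G.add_nodes_from(rest.node_ids)
    for i in range(p):
        for j in adj[i]:
            if i < j:
                _, rho, pval = best[(i, j)]
                G.add_edge(
                    rest.node_ids[i],
                    rest.node_ids[j],
                    weight=rho,
                    min_test_p=pval,
                )
    return ConnectivityGraph(graph=G, ci_alpha=ci_alpha)


def brute_force_skeleton(rest: RestSeries, ci_alpha: float) -> ConnectivityGraph:
    """All-subsets CI-test oracle: an edge survives iff the partial
    correlation is significant given *every* subset of the remaining nodes.
    Exponential in node count; for cross-checks on small graphs only.
    """
    X = rest.matrix
    p, n = X.shape
    corr = np.corrcoef(X)
    G = nx.Graph()
    G.add_nodes_from(rest.node_ids)
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            keep = True
            best = None
            for size in range(len(others) + 1):
                for S in itertools.combinations(others, size):
                    rho = partial_correlation(corr, i, j, S)
                    pval = fisher_z_pvalue(rho, n, size)
                    if best is None or abs(rho) < best[0]:
                        best = (abs(rho), rho, pval)
                    if pval > ci_alpha:
                        keep = False
                        break
                if not keep:
                    break
            if keep:
                G.add_edge(
                    rest.node_ids[i], rest.node_ids[j], weight=best[1], min_test_p=best[2]
                )
    return ConnectivityGraph(graph=G, ci_alpha=ci_alpha)


# ---------------------------------------------------------------------------
# components and spectral partition
# ---------------------------------------------------------------------------

def largest_component(cg: ConnectivityGraph) -> ConnectivityGraph:
    """Induced subgraph on the largest connected component (ties broken
    toward the component containing the smallest node id)."""
    G = cg.graph
    if G.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comps = list(nx.connected_components(G))
    if G.number_of_edges() == 0:
        node = min(G.nodes)
        warnings.warn("edgeless graph: largest component is a single node")
        return ConnectivityGraph(graph=G.subgraph([node]).copy(), ci_alpha=cg.ci_alpha)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ConnectivityGraph(graph=G.subgraph(comps[0]).copy(), ci_alpha=cg.ci_alpha)


@dataclass
class NetworkPartition:
    assignment: dict                # node -> cluster id 1..k
    k: int
    spectral_embedding: np.ndarray = field(repr=False, default=None)
    nodes: list = None

    def labels(self, nodes=None) -> np.ndarray:
        nodes = nodes if nodes is not None else self.nodes
        return np.array([self.assignment[n] for n in nodes])


def spectral_partition(cg: ConnectivityGraph, k: int = 4, seed: int = 0) -> NetworkPartition:
    """Spectral clustering of the weighted graph into k networks.

    Affinity = |edge weight|; symmetric normalized Laplacian; embedding on
    the k eigenvectors of smallest eigenvalue, rows normalized; seeded
    k-means++ with 50 restarts.
    """
    G = cg.graph
    nodes = sorted(G.nodes)
    p = len(nodes)
    if p < k:
        raise ValueError(f"component has {p} nodes, fewer than k={k}")
    W = np.abs(nx.to_numpy_array(G, nodelist=nodes, weight="weight"))
    d = W.sum(axis=1)
    d = np.where(d > 0, d, 1.0)
    Dm12 = 1.0 / np.sqrt(d)
    L = np.eye(p) - (Dm12[:, None] * W) * Dm12[None, :]
    vals, vecs = np.linalg.eigh(L)
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=50, init="k-means++", random_state=seed)
    lab = km.fit_predict(U)
    assignment = {n: int(l) + 1 for n, l in zip(nodes, lab)}
    return NetworkPartition(assignment=assignment, k=k, spectral_embedding=U, nodes=nodes)


# ---------------------------------------------------------------------------
# seed correlation (subcortical analogue)
# ---------------------------------------------------------------------------

def cluster_centroids(
    partition: NetworkPartition, region_series: np.ndarray, region_ids: list[int]
) -> dict[int, np.ndarray]:
    """Representative time series per network: mean over member regions."""
    cents = {}
    for c in sorted(set(partition.assignment.values())):
        members = [i for i, r in enumerate(region_ids) if partition.assignment.get(r) == c]
        if members:
            cents[c] = region_series[members].mean(axis=0)
    return cents


def seed_correlation_map(
    partition: NetworkPartition,
    region_series: np.ndarray,
    region_ids: list[int],
    voxel_series: np.ndarray,
    target_mask: np.ndarray,
    p_voxel: float = 0.001,
    min_voxels: float = 1.0,
    connectivity: int = 1,
) -> dict[int, dict]:
    """Pearson correlation of every target-mask voxel with each network
    centroid, thresholded (two-sided, via the t transform of r) and
    cluster-corrected within the target mask.
    """
    mask = np.asarray(target_mask, bool)
    if not mask.any():
        raise ValueError("target mask is empty")
    n = voxel_series.shape[-1]
    V = voxel_series[mask]
    Vc = V - V.mean(axis=1, keepdims=True)
    Vs = np.linalg.norm(Vc, axis=1)
    out = {}
    for c, cent in cluster_centroids(partition, region_series, region_ids).items():
        cc = cent - cent.mean()
        cn = np.linalg.norm(cc)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where((Vs > 0) & (cn > 0), Vc @ cc / (Vs * cn), 0.0)
        r = np.clip(r, -1.0, 1.0)
        dof = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(dof / np.maximum(1e-300, 1.0 - r**2))
        rmap = np.zeros(mask.shape)
        tmap = np.zeros(mask.shape)
        rmap[mask] = r
        tmap[mask] = t
        surv = apply_cluster_correction(
            tmap, dof, p_voxel, min_voxels, connectivity, mask=mask
        )
        out[c] = {"r": rmap, "t": tmap, "survivors": surv}
    return out
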