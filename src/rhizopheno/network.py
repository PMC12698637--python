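"""SparCC co-abundance networks with hub detection.

SparCC estimates correlations between latent (basis) abundances from
compositional counts via log-ratio variances under a sparsity assumption:
per Dirichlet-resampled fraction draw, the variation matrix
t_ij = Var[ln(f_i/f_j)] is inverted through the linear system
((D-2) I + 1 1^T) w = rowsums(T) for basis variances, strongly correlated
pairs are iteratively excluded from the system, and the final correlation
matrix is the median over draws. Pseudo p-values come from independently
permuting each taxon's counts across samples. Edges with pseudo p below the
threshold form an undirected graph on which Markov clustering, exact
betweenness, degree, and top-decile hub detection operate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AsvTable


# ---------------------------------------------------------------------------
# SparCC core
# ---------------------------------------------------------------------------

def _variation_matrix(frac: np.ndarray) -> np.ndarray:
    """t_ij = Var[ln(f_i/f_j)] across samples, via the log-fraction covariance."""
    logf = np.log(frac)
    V = np.cov(logf.T)
    v = np.diag(V)
    return v[:, None] + v[None, :] - 2.0 * V


def _basis_corr_one(T: np.ndarray, n_exclude_rounds: int,
                    exclude_thresh: float) -> np.ndarray:
    """One SparCC basis-correlation estimate from a variation matrix, with
    iterative exclusion of the strongest pairs."""
    D = T.shape[0]
    M = np.ones((D, D)) + (D - 2) * np.eye(D)
    t_active = T.copy()
    excluded: set[tuple[int, int]] = set()

    def _solve() -> np.ndarray:
        t_vec = t_active.sum(axis=1)
        w2 = np.linalg.solve(M, t_vec)
        if (w2 <= 0).any():
            warnings.warn("negative basis variance clamped")
            w2 = np.maximum(w2, 1e-12)
        w = np.sqrt(w2)
        rho = (w2[:, None] + w2[None, :] - T) / (2.0 * np.outer(w, w))
        return np.clip(rho, -1.0, 1.0)

    rho = _solve()
    for _ in range(n_exclude_rounds):
        a = np.abs(rho)
        np.fill_diagonal(a, 0.0)
        for i, j in excluded:
            a[i, j] = a[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(a), a.shape)
        if a[i, j] <= exclude_thresh:
            break
        excluded.add((min(i, j), max(i, j)))
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        t_active[i, j] = t_active[j, i] = 0.0
        rho = _solve()
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class SparccResult:
    correlation: pd.DataFrame
    pseudo_p: pd.DataFrame | None = None
    n_bootstrap: int = 0

    def __post_init__(self) -> None:
        C = self.correlation.to_numpy()
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


def sparcc_correlations(counts: AsvTable | pd.DataFrame, n_inner: int = 20,
                        n_exclude_rounds: int = 10,
                        exclude_thresh: float = 0.1,
                        seed: int = 0) -> SparccResult:
    """SparCC correlation inference at the algorithm's reference defaults
    (20 inner Dirichlet draws, exclusion threshold 0.1, 10 exclusion
    rounds, median aggregation). Requires more than 3 taxa."""
    if isinstance(counts, AsvTable):
        counts = counts.counts
    X = counts.to_numpy(dtype=float)
    n, D = X.shape
    if D <= 3:
        raise ValueError("SparCC needs more than 3 taxa")
    rng = np.random.default_rng(seed)
    rhos = np.empty((n_inner, D, D))
    for it in range(n_inner):
        g = rng.standard_gamma(X + 1.0)
        frac = np.maximum(g, 1e-300)
        frac = frac / frac.sum(axis=1, keepdims=True)
        T = _variation_matrix(frac)
        rhos[it] = _basis_corr_one(T, n_exclude_rounds, exclude_thresh)
    rho = np.median(rhos, axis=0)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=counts.columns, columns=counts.columns)
    return SparccResult(correlation=corr)


def sparcc_pseudo_p(counts: AsvTable | pd.DataFrame, observed: SparccResult,
                    n_boot: int = 100, seed: int = 0, n_inner: int = 20,
                    n_exclude_rounds: int = 10, exclude_thresh: float = 0.1,
                    ) -> SparccResult:
    """Two-sided pseudo p-values against a permutation null that shuffles
    each taxon's counts across samples independently.

    p = (#{|r_null| >= |r_obs|} + 1) / (n_boot + 1).
    """
    if isinstance(counts, AsvTable):
        counts = counts.counts
    if n_boot < 10:
        warnings.warn("n_boot < 10: p-value resolution is very coarse")
    X = counts.to_numpy(dtype=float)
    n, D = X.shape
    obs = np.abs(observed.correlation.to_numpy())
    rng = np.random.default_rng(seed)
    exceed = np.zeros((D, D))
    for b in range(n_boot):
        Xp = np.empty_like(X)
        for j in range(D):
            Xp[:, j] = X[rng.permutation(n), j]
        null = sparcc_correlations(
            pd.DataFrame(Xp, columns=counts.columns), n_inner=n_inner,
            n_exclude_rounds=n_exclude_rounds, exclude_thresh=exclude_thresh,
            seed=int(rng.integers(2 ** 31 - 1)),
        ).correlation.to_numpy()
        exceed += np.abs(null) >= obs
    p = (exceed + 1.0) / (n_boot + 1.0)
    pseudo = pd.DataFrame(p, index=counts.columns, columns=counts.columns)
    return SparccResult(correlation=observed.correlation, pseudo_p=pseudo,
                        n_bootstrap=n_boot)


# ---------------------------------------------------------------------------
# Network construction and analysis
# ---------------------------------------------------------------------------

def _lowest_rank_label(taxonomy: pd.DataFrame, taxon: str) -> str:
    if taxon not in taxonomy.index:
        return str(taxon)
    row = taxonomy.loc[taxon]
    for rank in reversed(list(taxonomy.columns)):
        v = row[rank]
        if isinstance(v, str) and v.strip():
            return v
    return str(taxon)


def build_network(result: SparccResult, alpha: float = 0.1,
                  taxonomy: pd.DataFrame | None = None) -> nx.Graph:
    """Undirected simple graph with one edge per taxon pair with
    pseudo p < alpha; isolated taxa are omitted. Nodes carry the lowest
    available taxonomic rank label and the phylum."""
    if result.pseudo_p is None:
        raise ValueError("pseudo p-values required; run sparcc_pseudo_p first")
    taxa = list(result.correlation.index)
    R = result.correlation.to_numpy()
    P = result.pseudo_p.to_numpy()
    g = nx.Graph()
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if P[i, j] < alpha:
                g.add_edge(taxa[i], taxa[j], r=float(R[i, j]),
                           pseudo_p=float(P[i, j]),
                           sign=int(np.sign(R[i, j])) or 1)
    if g.number_of_edges() == 0:
        warnings.warn("no significant correlations: empty network")
    for node in g.nodes:
        if taxonomy is not None:
            g.nodes[node]["label"] = _lowest_rank_label(taxonomy, node)
            g.nodes[node]["phylum"] = (
                str(taxonomy.loc[node, "phylum"]) if node in taxonomy.index else ""
            )
        else:
            g.nodes[node]["label"] = str(node)
            g.nodes[node]["phylum"] = ""
    return g


def mcl_clusters(net: nx.Graph, inflation: float = 2.0,
                 prune_eps: float = 1e-5, max_iter: int = 200,
                 tol: float = 1e-8) -> pd.Series:
    """Markov clustering: alternate expansion (matrix square) and inflation
    (elementwise power + column renormalization) with pruning on the
    column-stochastic adjacency matrix (self-loops of weight 1); clusters
    are the connected components of the attractor support."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    np.fill_diagonal(A, 1.0)
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        M2 = M @ M
        M2 = np.power(M2, inflation)
        M2[M2 < prune_eps] = 0.0
        colsum = M2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.abs(M2 - M).max() < tol:
            M = M2
            converged = True
            break
        M = M2
    if not converged:
        warnings.warn("MCL did not converge; using last iterate")
    support = nx.Graph()
    support.add_nodes_from(nodes)
    rows, cols = np.nonzero(M > prune_eps)
    for r, c in zip(rows, cols):
        if r != c:
            support.add_edge(nodes[r], nodes[c])
    labels = {}
    for cid, comp in enumerate(
        sorted(nx.connected_components(support), key=lambda s: (-len(s), min(s)))
    ):
        for nd in comp:
            labels[nd] = cid
    return pd.Series(labels, name="mcl_cluster").loc[nodes]


def node_centralities(net: nx.Graph) -> pd.DataFrame:
    """Normalized betweenness (exact shortest-path counting on the
    unweighted skeleton) and raw degree per node."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    btw = nx.betweenness_centrality(net, normalized=True, weight=None)
    deg = dict(net.degree())
    nodes = sorted(net.nodes)
    return pd.DataFrame(
        {"betweenness": [btw[n] for n in nodes],
         "degree": [deg[n] for n in nodes]},
        index=pd.Index(nodes, name="taxon"),
    )


@dataclass
class HubReport:
    hubs: list[str]
    subnetwork: nx.Graph
    n_nodes: int
    n_edges: int
    betweenness_threshold: float
    degree_threshold: float


def detect_hubs(net: nx.Graph, quantile: float = 0.10,
                centralities: pd.DataFrame | None = None) -> HubReport:
    """Hubs are nodes in the top ``quantile`` of BOTH normalized betweenness
    and degree (thresholds = empirical (1 - q) quantiles, ties inclusive).
    The hub subnetwork contains every edge incident to at least one hub."""
    if centralities is None:
        centralities = node_centralities(net)
    bt = centralities["betweenness"].to_numpy(dtype=float)
    dg = centralities["degree"].to_numpy(dtype=float)
    # quantile over distinct values: nodes tied at a value enter or leave the
    # top decile together, so hub sets cannot depend on tie-breaking order
    bt_thr = float(np.quantile(np.unique(bt), 1.0 - quantile, method="higher"))
    dg_thr = float(np.quantile(np.unique(dg), 1.0 - quantile, method="higher"))
    mask = (bt >= bt_thr) & (dg >= dg_thr)
    if mask.all() or not mask.any():
        warnings.warn("degenerate centrality distribution for hub detection")
    hubs = list(centralities.index[mask])
    edges = [(u, v) for u, v in net.edges if u in set(hubs) or v in set(hubs)]
    sub = nx.Graph()
    sub.add_nodes_from(hubs)
    sub.add_edges_from(
        (u, v, net.edges[u, v]) for u, v in edges
    )
    return HubReport(hubs=hubs, subnetwork=sub, n_nodes=sub.number_of_nodes(),
                     n_edges=sub.number_of_edges(),
                     betweenness_threshold=bt_thr, degree_threshold=dg_thr)
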