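"""Group-wise GLASSO partial-correlation networks with permutation tests.

Edges are the regularised partial correlations implied by the L1-penalised
precision matrix fitted to the Pearson correlation matrix of the node
variables (15 calibrated SIS items plus the raw C-SSRS grade as the
Fatality node).  Edge significance is assessed by refitting on
column-permuted data; topology statistics are per-node degree and the mean
unweighted shortest-path length within each node's connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.covariance import graphical_lasso

from .io_cohort import CohortTable

__all__ = [
    "NODE_LABELS",
    "GlassoConvergenceError",
    "IntentNetwork",
    "TopologyReport",
    "estimate_glasso",
    "ebic_penalty",
    "permutation_significance",
    "topology",
    "build_group_networks",
    "to_graphml",
]

#: figure-style node labels: 15 SIS elements plus the C-SSRS Fatality node
NODE_LABELS = [
    "Iso", "Tinter", "ArecInter", "ActHelp", "FinActD", "ActPrep", "SNote",
    "OvertSI", "APurpo", "ExFatal", "ConMeth", "SeriAtt", "AttiLiv",
    "ConResc", "Dimpuls", "Fatality",
]


class GlassoConvergenceError(RuntimeError):
    """The graphical-lasso optimiser failed to converge."""


@dataclass
class TopologyReport:
    """Per-node topology of the significant-edge graph."""

    degree: np.ndarray  # significant-edge count per node
    avg_shortest_path: np.ndarray  # NaN for isolated nodes
    connected_node_count: int
    edge_count: int


@dataclass
class IntentNetwork:
    """A fitted intent network for one outcome group."""

    group: str
    nodes: list
    edge_weight: np.ndarray
    edge_p: np.ndarray | None = None
    significant: np.ndarray | None = None
    penalty: float | None = None
    topology: TopologyReport | None = field(default=None, repr=False)


def _partial_corr(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return (pc + pc.T) / 2.0


def _fit(corr: np.ndarray, penalty: float) -> np.ndarray:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, precision = graphical_lasso(corr, alpha=penalty, max_iter=500)
    except FloatingPointError as exc:  # pragma: no cover - rare
        raise GlassoConvergenceError(
            f"graphical lasso did not converge at penalty {penalty}"
        ) from exc
    return precision


def ebic_penalty(data: np.ndarray, gamma: float = 0.5,
                 grid: np.ndarray | None = None) -> float:
    """Select the GLASSO penalty by the extended BIC (default gamma 0.5)."""
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    S = np.corrcoef(X, rowvar=False)
    if grid is None:
        grid = np.logspace(-2.5, 0, 20)
    best, best_pen = np.inf, float(grid[0])
    for pen in grid:
        try:
            theta = _fit(S, float(pen))
        except GlassoConvergenceError:
            continue
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            continue
        loglik = (n / 2.0) * (logdet - np.trace(S @ theta))
        n_edges = int(np.count_nonzero(np.triu(theta, 1)))
        ebic = -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)
        if ebic < best:
            best, best_pen = ebic, float(pen)
    return best_pen


def estimate_glasso(data: np.ndarray, penalty: float | None = None) -> np.ndarray:
    """Regularised partial correlations of the columns of ``data``.

    Fits the L1-penalised precision matrix to the Pearson correlation
    matrix and returns -Theta_ij / sqrt(Theta_ii * Theta_jj) with a zero
    diagonal.  When ``penalty`` is None it is chosen by EBIC (gamma 0.5)
    over a log-spaced grid.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 variables")
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    n, p = X.shape
    if n < 3 * p:
        warnings.warn(f"only {n} subjects for {p} variables (< 3x)", stacklevel=2)
    if penalty is None:
        penalty = ebic_penalty(X)
    elif penalty < 0:
        raise ValueError("penalty must be non-negative")
    S = np.corrcoef(X, rowvar=False)
    return _partial_corr(_fit(S, float(penalty)))


def permutation_significance(data: np.ndarray, penalty: float,
                             n_perm: int = 10000, alpha: float = 0.05,
                             seed: int = 0):
    """Two-sided permutation p-values for every GLASSO edge.

    Each permutation independently shuffles every column across subjects
    (breaking all dependence while keeping marginals) and refits GLASSO at
    the same penalty; the empirical p-value for edge (i, j) is
    ``(1 + #{|null| >= |observed|}) / (n_perm + 1)``.  An edge is
    significant when p < alpha and its observed weight is nonzero.

    Returns ``(observed_weights, edge_p, significant)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if 1.0 / (n_perm + 1) >= alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve p-values below alpha={alpha}",
            stacklevel=2,
        )
    X = np.asarray(data, dtype=float)
    observed = estimate_glasso(X, penalty=penalty)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    exceed = np.zeros((p, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # size warning once only
        for _ in range(n_perm):
            Xp = np.empty_like(X)
            for j in range(p):
                Xp[:, j] = X[rng.permutation(X.shape[0]), j]
            null = estimate_glasso(Xp, penalty=penalty)
            exceed += np.abs(null) >= np.abs(observed)
    edge_p = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(edge_p, 1.0)
    significant = (edge_p < alpha) & (observed != 0)
    return observed, edge_p, significant


def topology(significant: np.ndarray) -> TopologyReport:
    """Degree and average shortest path on the significant-edge graph.

    Path lengths are unweighted, averaged over the other nodes of each
    node's connected component; isolated nodes get degree 0 and NaN.
    """
    adj = np.asarray(significant, dtype=bool)
    p = adj.shape[0]
    g = nx.from_numpy_array(adj.astype(int))
    degree = np.array([g.degree[i] for i in range(p)], dtype=float)
    avg_path = np.full(p, np.nan)
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        for i in comp:
            others = [lengths[i][j] for j in comp if j != i]
            avg_path[i] = float(np.mean(others))
    edge_count = int(adj[np.triu_indices(p, 1)].sum())
    connected = int((degree > 0).sum())
    return TopologyReport(degree.astype(int), avg_path, connected, edge_count)


def build_group_networks(cohort: CohortTable, penalty: float | None = None,
                         n_perm: int = 10000, alpha: float = 0.05,
                         seed: int = 0):
    """Fit lethal and nonlethal intent networks from an imputed cohort.

    Node variables are the 15 calibrated SIS items plus the raw C-SSRS
    grade (Fatality).  Returns ``(lethal_network, nonlethal_network)``
    with permutation-tested edges and topology reports.
    """
    sis = cohort.sis_cal
    grade = cohort.cssrs
    labels = cohort.lethal
    if np.isnan(sis).any() or np.isnan(labels).any():
        raise ValueError("cohort must be imputed and labelled")
    data = np.column_stack([sis, grade])
    networks = []
    for group, want in (("lethal", 1), ("nonlethal", 0)):
        X = data[labels == want]
        if X.shape[0] < 30:
            warnings.warn(f"{group} group has only {X.shape[0]} subjects",
                          stacklevel=2)
        pen = ebic_penalty(X) if penalty is None else penalty
        weights, edge_p, signif = permutation_significance(
            X, penalty=pen, n_perm=n_perm, alpha=alpha, seed=seed
        )
        net = IntentNetwork(
            group=group, nodes=list(NODE_LABELS), edge_weight=weights,
            edge_p=edge_p, significant=signif, penalty=pen,
            topology=topology(signif),
        )
        networks.append(net)
    return tuple(networks)


def to_graphml(network: IntentNetwork, path) -> None:
    """Export a network (nodes with topology, significant edges) to GraphML."""
    g = nx.Graph(group=network.group)
    topo = network.topology or topology(network.significant)
    for i, label in enumerate(network.nodes):
        ap = topo.avg_shortest_path[i]
        g.add_node(
            i, label=label, degree=int(topo.degree[i]),
            avg_shortest_path=float(ap) if np.isfinite(ap) else -1.0,
        )
    idx = np.argwhere(np.triu(network.significant, 1))
    for i, j in idx:
        w = float(network.edge_weight[i, j])
        g.add_edge(
            int(i), int(j), weight=w, sign="positive" if w > 0 else "negative",
            p=float(network.edge_p[i, j]),
        )
    nx.write_graphml(g, path)
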