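"""Signed weighted co-expression network: adjacency, topological overlap,
module detection, module eigengenes and hub-gene classification.

The adjacency is the signed soft-thresholded correlation
a_ij = ((1 + cor_ij)/2)^beta, the module structure comes from average-
linkage clustering of 1 - TOM with a static tree cut, and hubs are the top
10% of genes by each of three centralities: Connectivity (sum of adjacency
weights), Degree (number of partners with Spearman rho > 0.90) and
Betweenness (shortest-path centrality on the same thresholded graph).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .experiment import TimecourseExperiment

logger = logging.getLogger(__name__)

# WGCNA's size-ordered module color convention
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
UNASSIGNED = "grey"


def signed_adjacency(expr_matrix: pd.DataFrame, beta: int = 12) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^beta, diagonal 1.

    Pearson correlation across all samples. Genes with zero variance make
    the correlation undefined; they are reported in the raised error so the
    caller can drop them.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = expr_matrix.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = list(expr_matrix.index[sd == 0])
        raise ValueError(
            f"{len(bad)} zero-variance genes must be dropped first: "
            + ", ".join(map(str, bad[:10]))
            + ("..." if len(bad) > 10 else "")
        )
    cor = np.corrcoef(X)
    adj = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr_matrix.index, columns=expr_matrix.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 frequency ~ log10 binned-connectivity fit."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(k[mask].mean())
        ys.append(mask.sum() / len(k))
    if len(xs) < 3:
        return 0.0
    fit = stats.linregress(np.log10(xs), np.log10(ys))
    return float(fit.rvalue**2)


def pick_soft_threshold(
    expr_matrix: pd.DataFrame, beta_grid=(2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    r2_cut: float = 0.8,
) -> tuple[int, dict[int, float]]:
    """Smallest beta whose connectivity distribution fits a scale-free law
    with R^2 >= ``r2_cut``; falls back to the best-fitting grid value."""
    r2_table: dict[int, float] = {}
    for beta in beta_grid:
        adj = signed_adjacency(expr_matrix, beta=beta).to_numpy()
        k = adj.sum(axis=1) - 1.0
        r2_table[beta] = scale_free_fit(k)
        if r2_table[beta] >= r2_cut:
            return beta, r2_table
    best = max(r2_table, key=lambda b: (r2_table[b], -b))
    logger.warning(
        "no beta reached scale-free R^2 >= %.2f; falling back to beta=%d "
        "(R^2=%.3f)", r2_cut, best, r2_table[best],
    )
    return best, r2_table


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with the shared-neighbour sum excluding u in {i, j} and
    k_i = sum_{u != i} a_iu; TOM_ii = 1."""
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A  # zero diagonal already excludes u in {i, j}
    numer = shared + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = numer / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame, min_size: int = 30, cut_height: float = 0.99
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_size`` are left unassigned (grey); surviving
    modules are named by the size-ordered color palette (largest module =
    turquoise, then blue, ...).
    """
    genes = tom.index
    n = len(genes)
    dist = 1.0 - tom.to_numpy()
    iu = np.triu_indices(n, k=1)
    Z = linkage(np.clip(dist[iu], 0.0, None), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes.index[sizes >= min_size]
    ordered = sorted(keep, key=lambda c: (-sizes[c], c))
    name_of = {c: MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
               for i, c in enumerate(ordered)}
    labels = pd.Series(
        [name_of.get(c, UNASSIGNED) for c in raw], index=genes, name="module"
    )
    return labels


def module_eigengene(
    expr: TimecourseExperiment, labels: pd.Series, baseline: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First principal component of each module's standardized submatrix.

    Returns (eigengenes: modules x samples, fc_profiles: modules x time
    points). The eigengene sign is oriented to correlate positively with
    the module's mean expression profile; the fold-change profile is the
    eigengene recomputed on replicate-mean log2 FC vs the baseline.
    """
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    if not modules:
        raise ValueError("no non-grey modules to summarize")
    modules = sorted(modules, key=lambda m: (-(labels == m).sum(), m))
    eig_rows, fc_rows = {}, {}
    traj = expr.log2fc_trajectories(baseline_div=baseline)
    for m in modules:
        genes = labels.index[labels == m]
        eig_rows[m] = _first_pc(expr.signal.loc[genes].to_numpy())
        fc_rows[m] = _first_pc(traj.loc[genes].to_numpy())
    eigengenes = pd.DataFrame(eig_rows, index=expr.signal.columns).T
    fc_profiles = pd.DataFrame(fc_rows, index=traj.columns).T
    return eigengenes, fc_profiles


def _first_pc(X: np.ndarray) -> np.ndarray:
    """Sign-oriented first PC across samples of a genes x samples block."""
    if X.shape[0] == 1:
        row = X[0]
        sd = row.std(ddof=0)
        return (row - row.mean()) / sd if sd > 0 else row - row.mean()
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    pc = vt[0] * s[0] / math.sqrt(max(X.shape[0], 1))
    mean_profile = Xs.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    return pc


@dataclass
class HubTable:
    """Per-gene hub metrics and the top-10% hub sets per metric."""

    metrics: pd.DataFrame  # columns: connectivity, degree, betweenness
    top: dict = field(default_factory=dict)  # metric -> ordered gene list

    def hub_union(self) -> set:
        return set().union(*map(set, self.top.values())) if self.top else set()


def spearman_threshold_graph(
    expr_matrix: pd.DataFrame, spearman_cut: float = 0.90
) -> nx.Graph:
    """Unweighted gene graph: edge iff Spearman rho strictly > the cutoff.

    The strict inequality drops ties at exactly the cutoff.
    """
    genes = list(expr_matrix.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = stats.spearmanr(expr_matrix.to_numpy().T).statistic
    if np.isscalar(rho):
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)  # rank-constant genes correlate with nothing
    edges = np.argwhere(np.triu(rho > spearman_cut, k=1))
    G = nx.Graph()
    G.add_nodes_from(genes)
    G.add_edges_from((genes[i], genes[j]) for i, j in edges)
    return G


def graph_centralities(G: nx.Graph) -> pd.DataFrame:
    """Degree and unnormalized shortest-path betweenness per node.

    Betweenness counts each unordered pair once and splits it fractionally
    across equal-length shortest paths.
    """
    degree = {v: float(d) for v, d in G.degree}
    btw = nx.betweenness_centrality(G, normalized=False)
    return pd.DataFrame({"degree": degree, "betweenness": btw})


def hub_metrics(
    expr_matrix: pd.DataFrame,
    adjacency: pd.DataFrame,
    spearman_cut: float = 0.90,
    hub_quantile: float = 0.10,
) -> HubTable:
    """Connectivity, Degree and Betweenness per gene, with top-10% hub sets.

    Connectivity_i = sum_j a_ij (weighted, from the signed adjacency).
    Degree and Betweenness come from the unweighted Spearman-threshold
    graph. Each top set has ceil(hub_quantile * n) members, ties broken by
    gene ID.
    """
    genes = list(expr_matrix.index)
    n = len(genes)
    if n < 3:
        raise ValueError("hub_metrics requires at least 3 genes")
    A = adjacency.to_numpy(dtype=float)
    connectivity = A.sum(axis=1) - np.diag(A)

    G = spearman_threshold_graph(expr_matrix, spearman_cut)
    cent = graph_centralities(G).loc[genes]

    metrics = pd.DataFrame(
        {
            "connectivity": connectivity,
            "degree": cent["degree"].to_numpy(),
            "betweenness": cent["betweenness"].to_numpy(),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    n_top = math.ceil(hub_quantile * n)
    top = {}
    for col in metrics.columns:
        ranked = metrics.sort_values(
            [col, "gene_id"], ascending=[False, True], kind="stable"
        ).index
        top[col] = list(ranked[:n_top])
    return HubTable(metrics=metrics, top=top)


@dataclass
class ModuleGraph:
    """Bundle of the network stage's outputs."""

    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    labels: pd.Series
    eigengenes: pd.DataFrame | None = None
    fc_profiles: pd.DataFrame | None = None
    hubs: HubTable | None = None
    beta_r2: dict | None = None  # scale-free fit per candidate power
    beta_fallback: bool = False  # no candidate reached the R^2 cutoff


def build_network(
    expr: TimecourseExperiment,
    genes: pd.Index,
    beta: int | None = None,
    beta_grid=(2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    min_module_size: int = 30,
    cut_height: float = 0.99,
    spearman_cut: float = 0.90,
    hub_quantile: float = 0.10,
    baseline: int = 0,
) -> ModuleGraph:
    """Full network stage: soft threshold, adjacency, TOM, modules,
    eigengenes and hub metrics, on the given gene universe.

    Zero-variance genes are dropped with a logged count before the
    correlation step.
    """
    sub = expr.signal.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    # tolerance catches float-residue "constant" rows, not just exact zeros
    low = sd <= 1e-10
    if low.any():
        logger.info("build_network: dropping %d zero-variance genes", int(low.sum()))
        sub = sub.loc[~low]
    beta_r2, fallback = None, False
    if beta is None:
        beta, beta_r2 = pick_soft_threshold(sub, beta_grid=beta_grid)
        fallback = max(beta_r2.values()) < 0.8
    adj = signed_adjacency(sub, beta=beta)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, min_size=min_module_size, cut_height=cut_height)
    sub_expr = expr.subset_features(sub.index)
    try:
        eig, fc = module_eigengene(sub_expr, labels, baseline=baseline)
    except ValueError:
        eig, fc = None, None
    hubs = hub_metrics(sub, adj, spearman_cut=spearman_cut, hub_quantile=hub_quantile)
    return ModuleGraph(
        beta=beta, adjacency=adj, tom=tom, labels=labels,
        eigengenes=eig, fc_profiles=fc, hubs=hubs,
        beta_r2=beta_r2, beta_fallback=fallback,
    )
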