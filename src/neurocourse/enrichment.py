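"""Gene-set over-representation: Fisher grids, rank-rank hypergeometric
overlap maps, and DAG-aware (elim) term enrichment.

The enrichment grid tests every (risk-gene list, gene cluster) pair with
Fisher's exact test against the full platform universe, then applies
Benjamini-Hochberg over exactly lists x clusters tests. RRHO compares two
signed gene rankings by hypergeometric overlap of their top-k prefixes on a
fixed bin grid. The DAG enrichment processes terms leaves-first and removes
the genes of significant descendants from their ancestors before testing
(the elim decorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr


def fisher_enrichment(
    gene_list: set,
    cluster: set,
    universe: set,
    alternative: str = "two-sided",
) -> dict:
    """Fisher's exact test of list membership against cluster membership.

    The 2x2 table is [[a, b], [c, d]] with a = |list & cluster|,
    b = |cluster - list|, c = |list - cluster|, d = the rest of the
    universe. The odds ratio is the sample OR a*d/(b*c), with a Haldane 0.5
    correction applied only when some cell is zero; log OR is natural log.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must not be empty")
    gene_list = set(gene_list) & universe
    cluster = set(cluster) & universe
    a = len(gene_list & cluster)
    b = len(cluster) - a
    c = len(gene_list) - a
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    return {
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "odds_ratio": odds,
        "log_or": float(np.log(odds)),
        "p": float(p),
    }


def enrichment_grid(
    catalog: dict[str, set],
    clusters: dict[str, set],
    universe: set,
    alternative: str = "two-sided",
    fdr_report: float = 0.1,
) -> pd.DataFrame:
    """All (list, cluster) Fisher tests with grid-wide BH correction.

    The BH denominator is exactly len(catalog) * len(clusters). The output
    long-format frame carries the 2x2 counts, OR, log OR, p, FDR, a
    reporting mask (FDR < ``fdr_report``) and significance tiers at
    FDR < 0.05 and FDR < 0.01.
    """
    if not catalog or not clusters:
        raise ValueError("need at least one list and one cluster")
    rows = []
    for list_name, genes in catalog.items():
        for cluster_name, members in clusters.items():
            rec = fisher_enrichment(genes, members, universe, alternative)
            rec["list"] = list_name
            rec["cluster"] = cluster_name
            rows.append(rec)
    grid = pd.DataFrame(rows)
    m = len(catalog) * len(clusters)
    grid["fdr"] = bh_fdr(grid["p"].to_numpy(), m=m)
    grid["reported"] = grid["fdr"] < fdr_report
    grid["sig_05"] = grid["fdr"] < 0.05
    grid["sig_01"] = grid["fdr"] < 0.01
    cols = [
        "list", "cluster", "a", "b", "c", "d",
        "odds_ratio", "log_or", "p", "fdr", "reported", "sig_05", "sig_01",
    ]
    return grid[cols]


def rrho_map(
    scores_a: pd.Series, scores_b: pd.Series, bin_size: int = 200
) -> pd.DataFrame:
    """Rank-rank hypergeometric overlap of two signed gene scores.

    Genes are ranked by descending signed score in each vector; for every
    pair of threshold indices (i*bin, j*bin) the one-sided hypergeometric
    enrichment p of the overlap between the two top prefixes is computed.
    Returns the -log10 p matrix (rows = thresholds in a, cols = in b); its
    maximum is the customary agreement summary.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("score vectors must cover the same gene universe")
    n = len(scores_a)
    if bin_size <= 0 or bin_size > n:
        raise ValueError("bin size must lie in 1..n_genes")
    rank_a = scores_a.sort_values(ascending=False, kind="stable").index
    rank_b = scores_b.sort_values(ascending=False, kind="stable").index
    steps = list(range(bin_size, n + 1, bin_size))
    pos_b = {g: i for i, g in enumerate(rank_b)}
    a_pos_in_b = np.fromiter((pos_b[g] for g in rank_a), dtype=int, count=n)

    mat = np.zeros((len(steps), len(steps)))
    for ii, i_thr in enumerate(steps):
        # genes in a's top prefix, located by their rank in b
        b_ranks = np.sort(a_pos_in_b[:i_thr])
        for jj, j_thr in enumerate(steps):
            k = int(np.searchsorted(b_ranks, j_thr))  # overlap size
            # one-sided enrichment: P(overlap >= k)
            p = stats.hypergeom.sf(k - 1, n, i_thr, j_thr)
            mat[ii, jj] = -np.log10(max(p, 1e-320))
    return pd.DataFrame(mat, index=steps, columns=steps)


@dataclass
class GoTerm:
    term: str
    genes: set
    p: float
    n_study: int
    n_term: int


def go_elim_enrichment(
    annotations: dict[str, set],
    dag_edges: list[tuple[str, str]],
    study: set,
    universe: set,
    p_cut: float = 0.01,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Term enrichment with bottom-up elim decorrelation.

    ``dag_edges`` are (child, parent) pairs; annotations must already be
    propagated to ancestors. Terms are processed leaves-first; when a term
    tests below ``p_cut``, its annotated study genes are removed from all of
    its ancestors before those are tested, so parents are not dragged along
    by a significant child. With ``p_cut=0`` no elimination happens and the
    result equals a per-term Fisher scan.
    """
    dag = nx.DiGraph()
    dag.add_nodes_from(annotations)
    dag.add_edges_from(dag_edges)  # child -> parent
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("term graph contains a cycle")
    study = set(study) & set(universe)
    removed: dict[str, set] = {t: set() for t in dag.nodes}
    rows = []
    for term in nx.topological_sort(dag):  # children before parents
        term_genes = set(annotations.get(term, set())) - removed[term]
        rec = fisher_enrichment(term_genes, study, universe, alternative=alternative)
        rows.append(
            {
                "term": term,
                "p": rec["p"],
                "odds_ratio": rec["odds_ratio"],
                "n_study_in_term": rec["a"],
                "n_term": len(term_genes),
            }
        )
        if rec["p"] < p_cut:
            eliminated = set(annotations.get(term, set())) & study
            for anc in nx.descendants(dag, term):  # ancestors in child->parent
                removed[anc] |= eliminated
    return pd.DataFrame(rows).set_index("term")
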