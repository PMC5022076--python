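"""Normalization, probe collapse, expressed-gene universe, and sample QC.

The pre-processing chain mirrors standard Illumina summary-intensity
practice: log2 transform, quantile normalization across samples, collapse
of multi-probe genes to the highest-variance probe, and definition of the
expressed transcriptome as genes detected above background (detection
p < 0.05) in every sample. Sample-level QC clusters samples on
1 - Pearson correlation over the top-variance genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .experiment import TimecourseExperiment

logger = logging.getLogger(__name__)


def log2_quantile_normalize(raw: TimecourseExperiment) -> TimecourseExperiment:
    """Log2-transform and quantile-normalize so all columns share one
    empirical distribution (the across-column mean of sorted log2 values).

    Within-column ranks are preserved; ties receive the mean of the
    reference values over their rank span. Raises if any signal is <= 0.
    """
    x = raw.signal.to_numpy(dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        bad = np.argwhere(~(x > 0) | ~np.isfinite(x))[0]
        raise ValueError(
            "non-positive signal at feature "
            f"{raw.signal.index[bad[0]]!r}, sample {raw.signal.columns[bad[1]]!r}"
        )
    logx = np.log2(x) if not raw.log2 else x
    n, m = logx.shape
    order = np.argsort(logx, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(logx, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(logx)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        mapped = reference.copy()
        # ties within the column share the mean reference over their span
        start = 0
        while start < n:
            stop = start + 1
            while stop < n and col_sorted[stop] == col_sorted[start]:
                stop += 1
            if stop - start > 1:
                mapped[start:stop] = reference[start:stop].mean()
            start = stop
        out[order[:, j], j] = mapped

    signal = pd.DataFrame(out, index=raw.signal.index, columns=raw.signal.columns)
    return replace(raw, signal=signal, log2=True)


def collapse_probes(
    expr: TimecourseExperiment, probe_map: pd.Series
) -> TimecourseExperiment:
    """Collapse probe-level rows to one row per gene.

    For multi-probe genes the probe with maximal variance across all samples
    is kept (ties broken by lexicographically smallest probe ID); its
    detection-p row is carried along. Probes absent from the mapping are
    dropped with a logged count.
    """
    if len(probe_map) == 0:
        raise ValueError("probe map is empty")
    probes = expr.signal.index
    mapped = probes.intersection(probe_map.index)
    n_dropped = len(probes) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_dropped)
    if len(mapped) == 0:
        raise ValueError("no probe of the experiment is present in the mapping")

    variance = expr.signal.loc[mapped].var(axis=1, ddof=1)
    choice = (
        pd.DataFrame({"gene": probe_map.loc[mapped], "var": variance})
        .rename_axis("probe")
        .reset_index()
        .sort_values(["gene", "var", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    keep = choice.set_index("gene")["probe"].sort_index()

    signal = expr.signal.loc[keep.values]
    signal.index = pd.Index(keep.index, name="gene_id")
    det = None
    if expr.detection_p is not None:
        det = expr.detection_p.loc[keep.values]
        det.index = signal.index
    return replace(expr, signal=signal, detection_p=det, level="gene")


def expressed_set(expr: TimecourseExperiment, alpha: float = 0.05) -> pd.Index:
    """Genes detected above background (p < alpha) in every sample.

    This set is the analysis universe for differential expression, DTW,
    ICA and the co-expression network; enrichment keeps the full platform
    universe separately.
    """
    if expr.detection_p is None:
        raise ValueError("expressed_set requires detection p-values")
    mask = (expr.detection_p < alpha).all(axis=1)
    return expr.signal.index[mask]


@dataclass
class QCResult:
    linkage: np.ndarray  # scipy linkage matrix over samples
    merge_heights: pd.Series  # per sample: height of its first merge
    outliers: pd.Series  # boolean flags per sample
    pc_scores: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray


def qc_samples(expr: TimecourseExperiment, n_top: int = 2000) -> QCResult:
    """Sample-level QC: average-linkage clustering on 1 - Pearson correlation
    over the ``n_top`` highest-variance genes, plus sample PCA scores.

    A sample is flagged as an outlier when the height at which it first joins
    a cluster exceeds median + 3*IQR of all first-merge heights.
    """
    n_samples = expr.signal.shape[1]
    if n_samples < 3:
        raise ValueError("qc_samples requires at least 3 samples")
    n_genes = expr.signal.shape[0]
    if n_top > n_genes:
        logger.warning(
            "qc_samples: n_top=%d exceeds gene count %d; using all genes",
            n_top,
            n_genes,
        )
        n_top = n_genes
    var = expr.signal.var(axis=1, ddof=1)
    top = var.sort_values(ascending=False, kind="stable").index[:n_top]
    sub = expr.signal.loc[top].to_numpy(dtype=float)

    corr = np.corrcoef(sub.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    iu = np.triu_indices(n_samples, k=1)
    Z = linkage(dist[iu], method="average")

    first_merge = np.full(n_samples, np.nan)
    members: dict[int, list[int]] = {i: [i] for i in range(n_samples)}
    for row_idx, (c1, c2, height, _size) in enumerate(Z):
        merged = members.pop(int(c1)) + members.pop(int(c2))
        for leaf in merged:
            if np.isnan(first_merge[leaf]):
                first_merge[leaf] = height
        members[n_samples + row_idx] = merged

    heights = pd.Series(first_merge, index=expr.signal.columns, name="merge_height")
    q1, med, q3 = np.percentile(heights, [25, 50, 75])
    cutoff = med + 3.0 * (q3 - q1)
    outliers = heights > cutoff

    centered = sub - sub.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(5, n_samples)
    scores = pd.DataFrame(
        (vt[:k].T * s[:k]),
        index=expr.signal.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    evr = (s**2) / np.sum(s**2)
    return QCResult(
        linkage=Z,
        merge_heights=heights,
        outliers=outliers,
        pc_scores=scores,
        explained_variance_ratio=evr[:k],
    )
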