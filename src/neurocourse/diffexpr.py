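"""Per-time-point differential expression versus the baseline time point.

Each gene is fitted with a linear model of expression on the dichotomized
time indicator (baseline vs time t) with a random intercept per biological
replicate. For the balanced paired design used here (every replicate
observed at both time points) the restricted-maximum-likelihood variance
components have closed form (the classical ANOVA estimators), so the fit is
vectorized across genes:

- replicate variance estimate > 0: the fixed effect equals the mean of the
  paired replicate differences and its SE is sqrt(var(d)/R) -- the paired
  design; the p-value uses a Student t reference with R-1 residual df.
- replicate variance estimate truncated at 0: the model degenerates to OLS
  and the test coincides with the two-sample pooled-variance t-test with
  2R-2 df.

Multiple testing uses Benjamini-Hochberg with the denominator fixed to the
size of the expressed universe, so skipped genes still count as tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import TimecourseExperiment

logger = logging.getLogger(__name__)


def fit_contrast(
    expr: TimecourseExperiment, t: int, baseline: int = 0
) -> pd.DataFrame:
    """Fit every gene's contrast of time point ``t`` against ``baseline``.

    Returns a DataFrame indexed by gene with columns ``effect`` (log2 mean
    difference), ``se``, ``p``, ``sigma2_rep`` (REML replicate-intercept
    variance) and ``df`` (residual df of the reference distribution).
    """
    if not expr.log2:
        raise ValueError("fit_contrast expects log2-scale expression")
    cols0 = expr.columns_at(baseline)
    cols1 = expr.columns_at(t)
    if len(cols0) < 2 or len(cols1) < 2:
        raise ValueError("both time points need at least 2 replicates")
    if len(cols0) != len(cols1):
        raise ValueError("unbalanced replicate counts are not supported")
    R = len(cols0)

    y0 = expr.signal[cols0].to_numpy(dtype=float)
    y1 = expr.signal[cols1].to_numpy(dtype=float)
    d = y1 - y0  # paired replicate differences
    effect = d.mean(axis=1)

    # ANOVA (= REML, balanced case) mean squares
    ms_err = d.var(axis=1, ddof=1) / 2.0
    rowmean = (y0.mean(axis=1) + y1.mean(axis=1)) / 2.0
    repmean = (y0 + y1) / 2.0
    ms_rep = 2.0 * ((repmean - rowmean[:, None]) ** 2).sum(axis=1) / (R - 1)
    sigma2_rep = np.maximum((ms_rep - ms_err) / 2.0, 0.0)

    mixed = ms_rep > ms_err
    se = np.empty_like(effect)
    df = np.empty_like(effect)
    # paired path: SE from within-replicate differences
    se[mixed] = np.sqrt(ms_err[mixed] * 2.0 / R)
    df[mixed] = R - 1
    # degenerate path: pooled two-sample OLS
    ols = ~mixed
    s2p = (y0.var(axis=1, ddof=1) + y1.var(axis=1, ddof=1)) / 2.0
    se[ols] = np.sqrt(s2p[ols] * 2.0 / R)
    df[ols] = 2 * R - 2

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    zero_se = se == 0
    p[zero_se & (effect == 0)] = 1.0
    p[zero_se & (effect != 0)] = 0.0

    return pd.DataFrame(
        {"effect": effect, "se": se, "p": p, "sigma2_rep": sigma2_rep, "df": df},
        index=expr.signal.index,
    )


def bh_fdr(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with denominator ``m``.

    ``m`` defaults to ``len(p)`` but may be larger to honour a test universe
    in which some genes were skipped. q-values are capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"m={m} is smaller than the number of p-values {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ContrastResultSet:
    """Per-contrast effects/q-values plus up/down call sets and their unions."""

    results: pd.DataFrame  # long: gene, contrast, effect, se, p, q, call
    m: int
    q_cut: float
    up: dict = field(default_factory=dict)  # div -> set of genes
    down: dict = field(default_factory=dict)
    nominal: dict = field(default_factory=dict)  # div -> count with p < 0.05

    @property
    def up_any(self) -> set:
        return set().union(*self.up.values()) if self.up else set()

    @property
    def down_any(self) -> set:
        return set().union(*self.down.values()) if self.down else set()

    @property
    def dex_any(self) -> set:
        return self.up_any | self.down_any

    def counts(self) -> dict:
        up_a, down_a = self.up_any, self.down_any
        return {
            "up_any": len(up_a),
            "down_any": len(down_a),
            "both_directions": len(up_a & down_a),
            "dex_any": len(up_a | down_a),
        }


def union_count(n_a: int, n_b: int, n_overlap: int) -> int:
    """Distinct elements of two sets from their sizes and overlap."""
    return n_a + n_b - n_overlap


def classify_dex(
    fits: dict[int, pd.DataFrame], m: int, q_cut: float = 0.05
) -> ContrastResultSet:
    """Apply BH-FDR per contrast (denominator ``m``) and assemble call sets.

    A gene is called up at time t if q < q_cut and effect > 0, down if
    q < q_cut and effect < 0; a gene may be up at one time point and down
    at another. Nominal (p < 0.05, uncorrected) counts are reported per
    contrast but never enter the call sets.
    """
    rows = []
    res = ContrastResultSet(results=pd.DataFrame(), m=m, q_cut=q_cut)
    for t, fit in sorted(fits.items()):
        q = bh_fdr(fit["p"].to_numpy(), m=m)
        frame = fit.copy()
        frame["q"] = q
        frame["contrast"] = t
        up_mask = (q < q_cut) & (frame["effect"] > 0)
        down_mask = (q < q_cut) & (frame["effect"] < 0)
        frame["call"] = np.where(up_mask, "up", np.where(down_mask, "down", "ns"))
        res.up[t] = set(frame.index[up_mask])
        res.down[t] = set(frame.index[down_mask])
        res.nominal[t] = int((frame["p"] < 0.05).sum())
        rows.append(frame.reset_index(names="gene"))
    res.results = pd.concat(rows, ignore_index=True)[
        ["gene", "contrast", "effect", "se", "p", "q", "call", "sigma2_rep", "df"]
    ]
    return res


def run_diffexpr(
    expr: TimecourseExperiment,
    universe: pd.Index,
    baseline: int = 0,
    q_cut: float = 0.05,
) -> ContrastResultSet:
    """Fit all non-baseline time points vs baseline on the expressed universe."""
    sub = expr.subset_features(universe)
    fits = {
        t: fit_contrast(sub, t, baseline=baseline)
        for t in sub.divs
        if t != baseline
    }
    return classify_dex(fits, m=len(universe), q_cut=q_cut)
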