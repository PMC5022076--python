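"""Dynamic-time-warping detection of dynamically regulated genes.

A gene's replicate-mean log2 fold-change trajectory is compared against the
flat zero trajectory (no regulation) with classic dynamic time warping
(absolute-difference local cost, symmetric match/insert/delete steps, both
endpoints aligned). The dynamic threshold is calibrated from a noise null:
flat trajectories perturbed by Gaussian noise at several SD levels, whose
DTW distance grows linearly with the noise SD; a gene is called dynamic when
its distance exceeds twice the upper 95% confidence boundary of the fitted
intercept. Dynamic genes are then grouped by k-means on their trajectories
with the cluster count picked by an elbow rule on the within-cluster sum of
squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .experiment import TimecourseExperiment


def dtw_distance(a, b) -> float:
    """Unnormalized DTW distance with |a_i - b_j| local cost and the
    symmetric step pattern (match, insert, delete all weighted 1).

    Both endpoints are aligned; the returned value is the accumulated cost
    along the optimal warping path.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise ValueError("dtw_distance requires 1-D series of length >= 2")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("series must not contain missing values")
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        for j in range(1, m):
            acc[i, j] = cost[i, j] + min(
                acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            )
    return float(acc[-1, -1])


def _dtw_to_zero_many(trajectories: np.ndarray) -> np.ndarray:
    """DTW distance of each row to the flat zero reference of equal length.

    Vectorized across rows: the DP recursion is over the (i, j) grid only.
    """
    X = np.abs(np.asarray(trajectories, dtype=float))  # cost to zero reference
    n_rows, T = X.shape
    acc = np.empty((T, T, n_rows))
    acc[0, 0] = X[:, 0]
    for i in range(1, T):
        acc[i, 0] = acc[i - 1, 0] + X[:, i]
        acc[0, i] = acc[0, i - 1] + X[:, 0]
    for i in range(1, T):
        for j in range(1, T):
            step = np.minimum(acc[i - 1, j - 1], np.minimum(acc[i - 1, j], acc[i, j - 1]))
            # aligning trajectory point i against reference point j costs |x_i|
            acc[i, j] = X[:, i] + step
    return acc[-1, -1]


@dataclass
class NoiseModel:
    """Linear null of DTW distance on background-noise SD."""

    slope: float
    intercept: float  # b0
    intercept_se: float
    upper95: float  # u0 = b0 + 1.96 * SE(b0)
    threshold: float  # tau = 2 * u0

    residual_sd: float = 0.0
    n_points: int = 0
    x_mean: float = 0.0
    x_ss: float = 0.0  # sum of squared deviations of the SD regressor

    def predicted_upper95(self, sd: float) -> float:
        """Upper 95% confidence boundary of the mean null distance at ``sd``."""
        if self.n_points < 3 or self.x_ss <= 0:
            return self.upper95 + self.slope * sd
        fitted = self.intercept + self.slope * sd
        se_mean = self.residual_sd * np.sqrt(
            1.0 / self.n_points + (sd - self.x_mean) ** 2 / self.x_ss
        )
        return fitted + 1.96 * se_mean

    def threshold_at(self, sd: float | None) -> float:
        """Dynamic-gene threshold: twice the upper 95% boundary of the
        noise-only distance.

        With ``sd`` given (the experiment's estimated trajectory-noise SD)
        the boundary is the model's prediction at that noise level; without
        it, the boundary of the intercept itself (the zero-noise anchor).
        """
        if sd is None or sd <= 0:
            return self.threshold
        return 2.0 * self.predicted_upper95(sd)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "upper95": self.upper95,
            "threshold": self.threshold,
        }


def calibrate_noise_null(
    n_timepoints: int,
    noise_levels,
    n_noise: int = 100,
    seed: int = 0,
) -> NoiseModel:
    """Fit the noise null: DTW distance of noise-only trajectories vs SD.

    For each SD in ``noise_levels``, ``n_noise`` flat (all-zero) log2-FC
    trajectories are perturbed with Gaussian noise and their DTW distance to
    the zero reference computed; OLS of distance on SD yields slope and
    intercept b0. The dynamic threshold is tau = 2 * u0 with
    u0 = b0 + 1.96*SE(b0), the upper 95% boundary of the intercept.
    """
    levels = np.asarray(noise_levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("noise levels must be non-negative")
    if len(np.unique(levels[levels > 0])) < 3:
        raise ValueError("need at least 3 distinct positive noise levels")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for sd in levels:
        noise = rng.normal(0.0, sd, size=(n_noise, n_timepoints)) if sd > 0 else np.zeros(
            (n_noise, n_timepoints)
        )
        d = _dtw_to_zero_many(noise)
        xs.append(np.full(n_noise, sd))
        ys.append(d)
    return fit_noise_model(np.concatenate(xs), np.concatenate(ys))


def fit_noise_model(sd, distance) -> NoiseModel:
    """OLS of DTW distance on noise SD, packaged as the noise null.

    u0 is the upper 95% confidence boundary of the intercept
    (b0 + 1.96*SE) and the zero-noise-anchored threshold is tau = 2*u0.
    """
    x = np.asarray(sd, dtype=float)
    y = np.asarray(distance, dtype=float)
    fit = stats.linregress(x, y)
    u0 = fit.intercept + 1.96 * fit.intercept_stderr
    resid = y - (fit.intercept + fit.slope * x)
    return NoiseModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        upper95=float(u0),
        threshold=float(2.0 * u0),
        residual_sd=float(np.sqrt(np.sum(resid**2) / max(len(x) - 2, 1))),
        n_points=len(x),
        x_mean=float(x.mean()),
        x_ss=float(np.sum((x - x.mean()) ** 2)),
    )


@dataclass
class DynamicGeneSet:
    """Per-gene DTW distances, dynamic flags, and trajectory clusters."""

    trajectories: pd.DataFrame  # genes x time points, log2 FC vs baseline
    distance: pd.Series  # d_g
    noise_model: NoiseModel
    dynamic: pd.Series  # boolean flags
    threshold_used: float = 0.0
    clusters: pd.Series | None = None  # labels, dynamic genes only
    cluster_means: pd.DataFrame | None = None
    k: int | None = None
    wss: dict | None = None

    @property
    def dynamic_genes(self) -> pd.Index:
        return self.distance.index[self.dynamic]


def estimate_trajectory_noise_sd(
    expr: TimecourseExperiment, baseline: int = 0
) -> float:
    """Estimate the background-noise SD of a replicate-mean log2-FC point.

    Pools the within-time-point replicate variance s^2 across genes and
    times; a fold-change point (mean at t minus mean at baseline) then has
    noise SD sqrt(2 * s^2 / R).
    """
    divs = expr.divs
    r_counts = []
    variances = []
    for d in divs:
        cols = expr.columns_at(d)
        if len(cols) < 2:
            continue
        variances.append(expr.signal[cols].var(axis=1, ddof=1).to_numpy())
        r_counts.append(len(cols))
    if not variances:
        return 0.0
    s2 = float(np.mean(np.concatenate(variances)))
    R = int(np.mean(r_counts))
    return float(np.sqrt(2.0 * s2 / R))


def select_dynamic_genes(
    expr: TimecourseExperiment,
    noise_model: NoiseModel,
    baseline: int = 0,
    noise_sd: float | None = None,
) -> DynamicGeneSet:
    """Flag genes whose trajectory's DTW distance to the zero reference
    exceeds twice the upper 95% boundary of the noise-only distance.

    ``noise_sd`` is the experiment's estimated trajectory-noise SD; when
    given, the boundary is the noise model's prediction at that level
    (see ``NoiseModel.threshold_at``), otherwise the intercept boundary.
    """
    traj = expr.log2fc_trajectories(baseline_div=baseline)
    d = pd.Series(
        _dtw_to_zero_many(traj.to_numpy()), index=traj.index, name="dtw_distance"
    )
    tau = noise_model.threshold_at(noise_sd)
    dynamic = d > tau
    return DynamicGeneSet(
        trajectories=traj,
        distance=d,
        noise_model=noise_model,
        dynamic=dynamic,
        threshold_used=tau,
    )


def pick_elbow(wss: dict[int, float], tol: float = 1e-12) -> int:
    """Elbow rule: the k maximizing the second difference of the scree curve.

    If a single cluster already explains everything (WSS ~ 0 at k=1) the
    elbow is 1; the endpoints of the grid cannot host a second difference
    and are picked only in degenerate cases.
    """
    ks = sorted(wss)
    if wss[ks[0]] <= tol:
        return ks[0]
    if len(ks) < 3:
        return ks[-1]
    best_k, best_curv = ks[1], -np.inf
    for k_prev, k_mid, k_next in zip(ks, ks[1:], ks[2:]):
        curv = wss[k_prev] - 2.0 * wss[k_mid] + wss[k_next]
        if curv > best_curv + tol:
            best_k, best_curv = k_mid, curv
    return best_k


def cluster_trajectories(
    dyn: DynamicGeneSet,
    k_max: int = 12,
    n_init: int = 50,
    seed: int = 0,
) -> DynamicGeneSet:
    """k-means on the dynamic genes' trajectories (Euclidean, unscaled),
    with k picked by the elbow rule and clusters ordered by descending
    mean final log2 FC (cluster 1 = strongest up-responder)."""
    genes = dyn.dynamic_genes
    if len(genes) < k_max + 1:
        raise ValueError(
            f"need more than k_max={k_max} dynamic genes, have {len(genes)}"
        )
    X = dyn.trajectories.loc[genes].to_numpy()
    wss: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        with warnings.catch_warnings():
            # duplicate trajectories can yield fewer distinct centers than k
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = km.fit_predict(X)
        wss[k] = float(km.inertia_)
        labelings[k] = labels
    k_star = pick_elbow(wss)
    labels = labelings[k_star]

    final_fc = pd.Series(X[:, -1], index=genes)
    order = (
        final_fc.groupby(labels).mean().sort_values(ascending=False).index.to_list()
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    clusters = pd.Series([remap[l] for l in labels], index=genes, name="cluster")
    means = (
        dyn.trajectories.loc[genes]
        .groupby(clusters)
        .mean()
        .sort_index()
    )
    dyn.clusters = clusters
    dyn.cluster_means = means
    dyn.k = k_star
    dyn.wss = wss
    return dyn
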