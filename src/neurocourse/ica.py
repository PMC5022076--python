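"""Independent component analysis with cross-run reproducibility selection.

FastICA is iterated many times from independent random initializations for
each candidate component count. Components are matched across runs to a
reference run (optimal one-to-one assignment on absolute load correlation),
sign-aligned, and summarized by a consensus load (first principal component
of the aligned run loads, rescaled to z-scores). The retained component
count is the largest one whose components all reproduce across runs (mean
load correlation with the consensus above the cutoff, 0.999 by default);
genes with |z-scored consensus load| > 3 are called component members.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)


def run_ica_ensemble(
    X: np.ndarray,
    n_components: int,
    n_iter: int = 250,
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-6,
) -> list[np.ndarray]:
    """Run FastICA ``n_iter`` times with independent random starts.

    ``X`` is the genes x samples matrix; each run returns the genes x
    n_components load matrix (the estimated sources, with genes as
    observations). Non-convergent runs are excluded with a logged count.

    The convergence tolerance is deliberately tight: reproducibility across
    restarts is only meaningful between runs that actually reached a fixed
    point, and over-extracted component counts reveal themselves by failing
    to converge rather than by stopping early near an arbitrary point.
    """
    X = np.asarray(X, dtype=float)
    n_genes, n_samples = X.shape
    if not (0 < n_components < min(n_genes, n_samples)):
        raise ValueError(
            f"n_components must lie in 1..{min(n_genes, n_samples) - 1}"
        )
    rng = np.random.default_rng(seed)
    loads, n_failed = [], 0
    for _ in range(n_iter):
        run_seed = int(rng.integers(0, 2**31 - 1))
        ica = FastICA(
            n_components=n_components,
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=run_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                S = ica.fit_transform(X)
            except ConvergenceWarning:
                n_failed += 1
                continue
        loads.append(S)
    if n_failed:
        logger.info(
            "run_ica_ensemble: %d/%d runs did not converge and were excluded",
            n_failed,
            n_iter,
        )
    return loads


def _match_to_reference(ref: np.ndarray, run: np.ndarray) -> np.ndarray:
    """Permute and sign-flip ``run`` columns to best match ``ref`` columns.

    The assignment maximizes total |correlation| (Hungarian algorithm);
    signs are flipped so matched correlations are positive.
    """
    k = ref.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = _safe_corr(ref[:, i], run[:, j])
    rows, cols = linear_sum_assignment(-np.abs(corr))
    aligned = np.empty_like(run)
    for i, j in zip(rows, cols):
        sign = 1.0 if corr[i, j] >= 0 else -1.0
        aligned[:, i] = sign * run[:, j]
    return aligned


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ComponentSet:
    """Consensus ICA loads with per-component reproducibility."""

    loads: pd.DataFrame | np.ndarray  # genes x k, z-scored per component
    reproducibility: np.ndarray  # mean corr of run loads with consensus
    n_runs: int
    activation: np.ndarray | None = None  # k x samples time profiles
    load_z_cut: float = 3.0

    @property
    def n_components(self) -> int:
        arr = self.loads if isinstance(self.loads, np.ndarray) else self.loads.to_numpy()
        return arr.shape[1]

    def significant_genes(self) -> dict[int, pd.Index]:
        return significant_loads(self)


def align_and_consense(run_loads: list[np.ndarray]) -> ComponentSet:
    """Align run loads to the first run and build consensus components.

    The consensus load of a component is the first principal component of
    its aligned gene x run load matrix, rescaled to z-scores and sign-
    oriented toward the mean run load; reproducibility is the mean
    correlation of run loads with the consensus. Degenerate (zero-variance)
    components record reproducibility 0.
    """
    if len(run_loads) < 2:
        raise ValueError("align_and_consense needs at least 2 successful runs")
    ref = run_loads[0]
    k = ref.shape[1]
    aligned = np.stack([ref] + [_match_to_reference(ref, r) for r in run_loads[1:]])
    # aligned: runs x genes x components
    consensus = np.empty((ref.shape[0], k))
    rbar = np.empty(k)
    for c in range(k):
        M = aligned[:, :, c].T  # genes x runs
        Mc = M - M.mean(axis=0, keepdims=True)
        if np.allclose(Mc, 0):
            consensus[:, c] = 0.0
            rbar[c] = 0.0
            continue
        u, s, vt = np.linalg.svd(Mc, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        if _safe_corr(pc1, M.mean(axis=1)) < 0:
            pc1 = -pc1
        sd = pc1.std()
        consensus[:, c] = (pc1 - pc1.mean()) / sd if sd > 0 else 0.0
        rs = [abs(_safe_corr(M[:, r], consensus[:, c])) for r in range(M.shape[1])]
        rbar[c] = float(np.mean(rs))
    return ComponentSet(
        loads=consensus, reproducibility=rbar, n_runs=len(run_loads)
    )


def select_component_count(
    X: np.ndarray,
    component_range=range(2, 9),
    n_iter: int = 250,
    r_cut: float = 0.999,
    seed: int = 0,
    min_converged_frac: float = 0.5,
    max_iter: int = 400,
    tol: float = 1e-6,
) -> tuple[int | None, dict[int, ComponentSet]]:
    """Choose the largest component count whose components all reproduce.

    Runs the ensemble for every count in ``component_range``; a count is
    eligible when at least ``min_converged_frac`` of its runs converged
    (an ensemble that mostly fails to converge carries no reproducibility
    evidence) and passes when its minimum per-component mean correlation
    exceeds ``r_cut``. Returns (n_star or None, table of ComponentSets per
    count) -- absence of a passing count is a valid outcome and the caller
    decides.
    """
    rng = np.random.default_rng(seed)
    table: dict[int, ComponentSet] = {}
    eligible: list[int] = []
    for k in component_range:
        ens_seed = int(rng.integers(0, 2**31 - 1))
        runs = run_ica_ensemble(
            X, k, n_iter=n_iter, seed=ens_seed, max_iter=max_iter, tol=tol
        )
        if len(runs) < 2:
            logger.warning("count %d: fewer than 2 convergent runs; skipped", k)
            continue
        table[k] = align_and_consense(runs)
        if len(runs) >= max(2, int(min_converged_frac * n_iter)):
            eligible.append(k)
    passing = [k for k in eligible if table[k].reproducibility.min() > r_cut]
    n_star = max(passing) if passing else None
    return n_star, table


def significant_loads(consensus: ComponentSet) -> dict[int, pd.Index]:
    """Genes with |z-scored consensus load| > the cutoff, per component."""
    loads = consensus.loads
    if isinstance(loads, pd.DataFrame):
        arr, index = loads.to_numpy(), loads.index
    else:
        arr, index = loads, pd.RangeIndex(loads.shape[0])
    out = {}
    for c in range(arr.shape[1]):
        out[c] = pd.Index(index[np.abs(arr[:, c]) > consensus.load_z_cut])
    return out


def component_activation(X: np.ndarray, consensus: ComponentSet) -> np.ndarray:
    """Per-sample activation profile of each consensus component.

    Least-squares projection of the expression matrix onto the consensus
    loads: solves X ~ loads @ A for the k x samples activation A.
    """
    loads = consensus.loads
    arr = loads.to_numpy() if isinstance(loads, pd.DataFrame) else loads
    A, *_ = np.linalg.lstsq(arr, np.asarray(X, dtype=float), rcond=None)
    consensus.activation = A
    return A
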