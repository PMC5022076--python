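"""DTW distance, noise-null calibration, dynamic-gene selection and
trajectory clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocourse.dtw import (
    NoiseModel,
    calibrate_noise_null,
    cluster_trajectories,
    dtw_distance,
    estimate_trajectory_noise_sd,
    pick_elbow,
    select_dynamic_genes,
    _dtw_to_zero_many,
)
from neurocourse.preprocess import collapse_probes, expressed_set
from neurocourse.simulate import SimulationConfig, generate_timecourse

from conftest import make_experiment


def brute_force_dtw(a, b):
    """Enumerate every warping path (steps: right, down, diagonal) from
    (0,0) to (n-1,m-1); cost = sum of |a_i - b_j| over visited cells."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, acc):
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDtwDistance:
    def test_zero_iff_equal(self):
        a = np.array([0.3, -1.0, 2.0, 0.0])
        assert dtw_distance(a, a) == 0.0
        assert dtw_distance(a, a + 0.5) > 0.0

    def test_flat_versus_unit_series(self):
        assert dtw_distance([0, 0, 0], [1, 1, 1]) == pytest.approx(3.0)

    def test_symmetry(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(32)
        series = [rng.normal(size=rng.integers(2, 5)) for _ in range(50)]
        for a, b in itertools.combinations(series, 2):
            assert dtw_distance(a, b) == pytest.approx(
                brute_force_dtw(a, b), abs=1e-12
            )

    def test_vectorized_zero_reference_agrees(self):
        rng = np.random.default_rng(33)
        X = rng.normal(size=(20, 7))
        fast = _dtw_to_zero_many(X)
        slow = [dtw_distance(row, np.zeros(7)) for row in X]
        assert np.allclose(fast, slow)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([1.0], [1.0, 2.0])


class TestNoiseCalibration:
    def test_intercept_vanishes_at_tiny_noise(self):
        nm = calibrate_noise_null(7, [0.001, 0.002, 0.003], n_noise=200, seed=41)
        assert abs(nm.intercept) < 3 * nm.intercept_se + 1e-6

    def test_ols_recovery_of_planted_linear_relation(self):
        """distance = 0.4 + 1.7*SD + eps: the 95% CI covers the truth in
        most replicates (checked via the OLS machinery used in the fit)."""
        rng = np.random.default_rng(42)
        hits_b0 = hits_b1 = 0
        n_rep = 100
        for _ in range(n_rep):
            sd = np.repeat([0.1, 0.2, 0.3, 0.4], 50)
            y = 0.4 + 1.7 * sd + rng.normal(0, 0.1, sd.size)
            fit = stats.linregress(sd, y)
            if abs(fit.intercept - 0.4) < 1.96 * fit.intercept_stderr:
                hits_b0 += 1
            if abs(fit.slope - 1.7) < 1.96 * fit.stderr:
                hits_b1 += 1
        assert hits_b0 >= 0.90 * n_rep
        assert hits_b1 >= 0.90 * n_rep

    def test_threshold_is_twice_upper_boundary(self):
        nm = NoiseModel(slope=1.0, intercept=1.0, intercept_se=0.0,
                        upper95=1.5, threshold=3.0)
        assert nm.threshold == pytest.approx(2 * nm.upper95)
        nm2 = calibrate_noise_null(7, [0.1, 0.2, 0.3], n_noise=50, seed=43)
        assert nm2.threshold == pytest.approx(2 * nm2.upper95)

    def test_threshold_monotone_in_noise_levels(self):
        lo = calibrate_noise_null(7, [0.1, 0.2, 0.3], n_noise=100, seed=44)
        hi = calibrate_noise_null(7, [0.4, 0.5, 0.6], n_noise=100, seed=44)
        sd = 0.3
        assert hi.threshold_at(sd) >= lo.threshold_at(sd) - 1e-6

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            calibrate_noise_null(7, [-0.1, 0.2, 0.3])


def _gene_level(cfg):
    raw, truth = generate_timecourse(cfg)
    gene = collapse_probes(raw, truth.probe_map)
    gene.signal = np.log2(gene.signal)
    gene.log2 = True
    return gene, truth


class TestSelectDynamic:
    def test_flat_zero_noise_gene_not_dynamic(self):
        expr = make_experiment(np.full((5, 21), 8.0))
        nm = calibrate_noise_null(7, [0.1, 0.2, 0.3], n_noise=50, seed=45)
        dyn = select_dynamic_genes(expr, nm)
        assert dyn.distance.max() == 0.0
        assert not dyn.dynamic.any()

    def test_planted_genes_detected_null_controlled(self):
        """Sensitivity >= 0.95 for planted trajectories at high signal-to-
        noise; false-positive fraction <= 5% on flat genes."""
        cfg = SimulationConfig(
            n_genes=1200, noise_sd=0.25, replicate_sd=0.1, effect_size=2.0,
            n_modules=0, module_size=0, seed=46,
        )
        gene, truth = _gene_level(cfg)
        sub = gene.subset_features(expressed_set(gene))
        nm = calibrate_noise_null(7, [0.1, 0.2, 0.3, 0.4, 0.5],
                                  n_noise=100, seed=47)
        sd = estimate_trajectory_noise_sd(sub)
        dyn = select_dynamic_genes(sub, nm, noise_sd=sd)
        lab = truth.class_label[sub.signal.index]
        planted = lab.isin(["monotone_up", "monotone_down", "transient"])
        sens = (dyn.dynamic & planted).sum() / planted.sum()
        fpr = (dyn.dynamic & ~planted).sum() / (~planted).sum()
        assert sens >= 0.95
        assert fpr <= 0.05

    def test_pure_null_dynamic_fraction_small(self):
        cfg = SimulationConfig(
            n_genes=1500, noise_sd=0.3, replicate_sd=0.1,
            class_fractions={"flat_expressed": 1.0}, n_modules=0,
            module_size=0, seed=48,
        )
        gene, _ = _gene_level(cfg)
        nm = calibrate_noise_null(7, [0.1, 0.2, 0.3, 0.4, 0.5],
                                  n_noise=100, seed=49)
        sd = estimate_trajectory_noise_sd(gene)
        dyn = select_dynamic_genes(gene, nm, noise_sd=sd)
        assert dyn.dynamic.mean() <= 0.05

    def test_dynamic_subset_of_expressed(self, default_run):
        _, _, _, gene = default_run
        ex = expressed_set(gene)
        sub = gene.subset_features(ex)
        nm = calibrate_noise_null(7, [0.1, 0.2, 0.3, 0.4, 0.5],
                                  n_noise=50, seed=50)
        dyn = select_dynamic_genes(sub, nm,
                                   noise_sd=estimate_trajectory_noise_sd(sub))
        assert set(dyn.dynamic_genes) <= set(ex)


def orthogonal_archetypes(n_shapes: int, n_timepoints: int = 7,
                          norm: float = 3.0) -> np.ndarray:
    """Equal-norm, mutually orthogonal trajectory shapes.

    Orthogonality makes the planted clusters a regular simplex (all pairwise
    distances equal), so the within-cluster-sum-of-squares scree curve drops
    linearly until the true k and the second-difference elbow lands there.
    """
    t = np.linspace(0, 1, n_timepoints)
    basis = [t, np.sin(np.pi * t) + 0.3 * t, np.cos(np.pi * t) - 1.0,
             t**3, np.sin(2 * np.pi * t) + 0.4 * t]
    shapes = []
    for f in basis[:n_shapes]:
        v = np.asarray(f, dtype=float)
        for u in shapes:
            v = v - np.dot(v, u) * u
        v = v / np.linalg.norm(v)
        shapes.append(v)
    return np.array(shapes) * norm


class TestClusterTrajectories:
    @staticmethod
    def _dyn_from_matrix(X, genes=None):
        idx = pd.Index(genes or [f"g{i}" for i in range(len(X))])
        traj = pd.DataFrame(X, index=idx)
        d = pd.Series(np.ones(len(X)), index=idx)
        nm = NoiseModel(0, 0, 0, 0.1, 0.2)
        from neurocourse.dtw import DynamicGeneSet

        return DynamicGeneSet(trajectories=traj, distance=d, noise_model=nm,
                              dynamic=pd.Series(True, index=idx))

    def test_identical_trajectories_give_k1(self):
        X = np.tile(np.linspace(0, 2, 7), (30, 1))
        dyn = self._dyn_from_matrix(X)
        dyn = cluster_trajectories(dyn, k_max=6, n_init=5, seed=0)
        assert dyn.k == 1
        assert dyn.wss[1] == pytest.approx(0.0)

    def test_two_archetypes_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        arch = orthogonal_archetypes(2)
        X = np.repeat(arch, 40, axis=0)
        truth = np.repeat([0, 1], 40)
        dyn = self._dyn_from_matrix(X)
        dyn = cluster_trajectories(dyn, k_max=8, n_init=10, seed=1)
        assert dyn.k == 2
        assert adjusted_rand_score(truth, dyn.clusters) == 1.0

    def test_five_archetypes_recovered_with_direction(self):
        """Five shapes (three ending up, two ending down): the elbow picks
        k=5 and cluster-mean final fold changes keep the planted signs."""
        arch = orthogonal_archetypes(5)
        # sign flips keep orthogonality: orient 3 shapes up, 2 down
        signs = np.array([1, 1, 1, -1, -1])
        arch = arch * (signs * np.sign(arch[:, -1]))[:, None]
        rng = np.random.default_rng(52)
        X = np.repeat(arch, 40, axis=0) + rng.normal(0, 0.05, (200, 7))
        dyn = self._dyn_from_matrix(X)
        dyn = cluster_trajectories(dyn, k_max=10, n_init=10, seed=2)
        assert dyn.k == 5
        finals = dyn.cluster_means.iloc[:, -1].to_numpy()
        assert (finals > 0).sum() == 3
        assert (finals < 0).sum() == 2

    def test_too_few_genes_rejected(self):
        X = np.tile(np.linspace(0, 2, 7), (5, 1))
        dyn = self._dyn_from_matrix(X)
        with pytest.raises(ValueError):
            cluster_trajectories(dyn, k_max=12)


def test_pick_elbow_prefers_largest_curvature():
    wss = {1: 100.0, 2: 75.0, 3: 50.0, 4: 25.0, 5: 2.0, 6: 1.5, 7: 1.2}
    assert pick_elbow(wss) == 5
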