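"""Synthetic probe-level time-course data with planted ground truth.

The generator emulates the design of an Illumina-style differentiation
time course: 7 time points (DIV 0..11) x 3 replicates, summary signal
intensities on a raw (linear) scale plus per-probe detection p-values,
multi-probe genes, a background (non-expressed) stratum, planted
monotone/transient trajectory classes, latent-factor co-expression modules,
and risk-gene lists with a requested enrichment odds ratio.

Baseline intensities are drawn in disjoint strata per gene class
(background < flat < dynamic < module). In the noiseless limit this makes
quantile normalization exactly rank-preserving, so the full pipeline admits
an exact-recovery test; at realistic noise levels the strata are immaterial
because trajectories and noise dominate rank order locally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .experiment import DEFAULT_DIVS, TimecourseExperiment, make_sample_table

DYNAMIC_CLASSES = ("monotone_up", "monotone_down", "transient")
ALL_CLASSES = ("flat_expressed", "not_expressed") + DYNAMIC_CLASSES

# baseline log2-intensity strata per class (low, high). Up-regulated and
# transient genes start low and rise through the band where down-regulated
# genes start (down-regulated genes begin highly expressed), so in the
# noiseless limit every dynamic gene crosses other genes' ranks while the
# flat and background strata are never traversed.
BASELINE_BANDS = {
    "not_expressed": (4.0, 6.0),
    "flat_expressed": (7.0, 10.0),
    "monotone_up": (13.0, 15.0),
    "transient": (13.0, 15.0),
    "monotone_down": (15.0, 17.0),
    "module": (19.0, 21.0),
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic time course.

    Defaults mirror the emulated experiment: 7 time points (DIV 0,1,3,5,7,9,11)
    with 3 biological replicates, log2-scale dynamic amplitude 2, residual
    noise SD 0.25 and replicate-offset SD 0.1.
    """

    n_genes: int = 2000
    frac_multi_probe: float = 0.3
    n_timepoints: int = 7
    n_replicates: int = 3
    class_fractions: dict = field(
        default_factory=lambda: {
            "flat_expressed": 0.36,
            "not_expressed": 0.44,
            "monotone_up": 0.08,
            "monotone_down": 0.07,
            "transient": 0.05,
        }
    )
    effect_size: float = 2.0
    noise_sd: float = 0.25
    replicate_sd: float = 0.1
    n_modules: int = 4
    module_size: int = 50
    frac_unannotated: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_timepoints <= 0 or self.n_replicates <= 0:
            raise ConfigurationError("all counts must be positive")
        if not (0.0 <= self.frac_multi_probe <= 1.0):
            raise ConfigurationError("frac_multi_probe must lie in [0, 1]")
        if self.noise_sd < 0 or self.replicate_sd < 0:
            raise ConfigurationError("noise_sd and replicate_sd must be >= 0")
        if set(self.class_fractions) - set(ALL_CLASSES):
            raise ConfigurationError(
                f"unknown classes: {set(self.class_fractions) - set(ALL_CLASSES)}"
            )
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_fractions must sum to 1, got {total}")
        if self.n_modules < 0 or self.module_size < 0:
            raise ConfigurationError("n_modules and module_size must be >= 0")
        if not (0.0 <= self.frac_unannotated <= 1.0):
            raise ConfigurationError("frac_unannotated must lie in [0, 1]")

    @property
    def divs(self) -> tuple:
        if self.n_timepoints == len(DEFAULT_DIVS):
            return DEFAULT_DIVS
        return tuple(range(self.n_timepoints))


@dataclass
class GroundTruth:
    """Planted truth: class labels, module assignment, latent trajectories."""

    class_label: pd.Series  # gene -> class
    module: pd.Series  # gene -> module name or "" (unassigned)
    latent_trajectories: pd.DataFrame  # module x time point (log2 deviation)
    probe_map: pd.Series  # probe -> gene
    gene_log2: pd.DataFrame  # noise-free... see generate_timecourse
    risk_tables: dict = field(default_factory=dict)  # list name -> realized 2x2

    @property
    def dynamic_truth(self) -> pd.Series:
        """Genes that truly change over time: dynamic classes or module members."""
        return self.class_label.isin(DYNAMIC_CLASSES) | (self.module != "")

    @property
    def expressed_truth(self) -> pd.Series:
        return self.class_label != "not_expressed"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.class_label,
                "module": self.module,
                "dynamic": self.dynamic_truth,
                "expressed": self.expressed_truth,
            }
        )

    def write(self, path: str) -> None:
        self.to_frame().rename_axis("gene_id").to_csv(path, sep="\t")


# ----------------------------------------------------------------------------
# trajectory archetypes


def class_trajectory(cls: str, n_timepoints: int) -> np.ndarray:
    """Unit-amplitude log2-FC shape of a trajectory class (starts at 0)."""
    t = np.arange(n_timepoints, dtype=float)
    if cls in ("flat_expressed", "not_expressed"):
        return np.zeros(n_timepoints)
    if cls == "monotone_up":
        return t / (n_timepoints - 1)
    if cls == "monotone_down":
        return -t / (n_timepoints - 1)
    if cls == "transient":
        # discretized Gaussian bump peaking mid-course, anchored to 0 at t=0
        mid = (n_timepoints - 1) / 2.0
        width = (n_timepoints - 1) / 4.0
        bump = np.exp(-0.5 * ((t - mid) / width) ** 2)
        return (bump - bump[0]) / (1.0 - bump[0])
    raise ConfigurationError(f"unknown class {cls!r}")


def latent_module_trajectories(n_modules: int, n_timepoints: int) -> np.ndarray:
    """Distinct smooth latent shapes, one per module, unit peak amplitude.

    Shapes cycle through late ramp-up, early ramp-down, mid bump and dip,
    and phase-shifted half-sines, so module eigengenes are distinguishable.
    """
    t = np.linspace(0.0, 1.0, n_timepoints)
    shapes = [
        t**2,  # accelerating rise
        -t,  # steady decline
        np.sin(np.pi * t),  # mid-course bump
        -np.sin(np.pi * t),  # mid-course dip
        np.sin(0.5 * np.pi * t),  # saturating rise
        t * (t - 1.0) * 4.0 + t,  # dip then rise
    ]
    out = np.empty((n_modules, n_timepoints))
    for m in range(n_modules):
        s = shapes[m % len(shapes)].copy()
        if m >= len(shapes):  # reuse with sign flip to stay distinct
            s = -s
        s = s - s[0]
        peak = np.max(np.abs(s))
        out[m] = s / peak if peak > 0 else s
    return out


def _allocate_counts(n: int, fractions: dict) -> dict:
    """Largest-remainder apportionment of n genes to classes."""
    keys = [k for k in ALL_CLASSES if k in fractions]
    raw = {k: n * fractions[k] for k in keys}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    by_rem = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


# ----------------------------------------------------------------------------
# main generator


def generate_timecourse(config: SimulationConfig):
    """Generate a probe-level raw-scale experiment plus its ground truth.

    The log2 signal of gene g in replicate r at time t is

        baseline_g + offset_{g,r} + shape_class(g)[t] * effect_size
                   + loading_g * latent_{module(g)}[t] + N(0, noise_sd)

    and the written signal is ``2 ** log2``. Multi-probe genes get one extra
    probe whose dynamic part is attenuated by half (so the primary probe wins
    the variance-based collapse). Expressed genes draw detection p-values
    from U(0, 0.04); background genes from U(0.05, 1).

    Returns (TimecourseExperiment at probe level, GroundTruth); deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    T, R = config.n_timepoints, config.n_replicates
    n = config.n_genes
    counts = _allocate_counts(n, config.class_fractions)

    gene_ids = [f"G{i:05d}" for i in range(n)]
    labels = []
    for cls in ALL_CLASSES:
        labels += [cls] * counts.get(cls, 0)
    class_label = pd.Series(labels, index=gene_ids, name="class")

    # modules are carved out of the flat_expressed class
    n_module_genes = config.n_modules * config.module_size
    flat_genes = class_label.index[class_label == "flat_expressed"]
    if n_module_genes > len(flat_genes):
        raise ConfigurationError(
            f"n_modules*module_size={n_module_genes} exceeds the "
            f"{len(flat_genes)} flat_expressed genes available"
        )
    module = pd.Series("", index=gene_ids, name="module")
    for m in range(config.n_modules):
        members = flat_genes[m * config.module_size : (m + 1) * config.module_size]
        module.loc[members] = f"M{m + 1}"

    # baseline strata: all modules share one band, so their genes exchange
    # ranks densely with other modules' genes (different latent shapes) and
    # the normalized trajectories keep order-of-amplitude signal
    baseline = np.empty(n)
    is_module = (module != "").values
    masks = [(is_module, BASELINE_BANDS["module"])]
    for cls in ALL_CLASSES:
        band = BASELINE_BANDS.get(cls, BASELINE_BANDS["flat_expressed"])
        masks.append(((class_label == cls).values & ~is_module, band))
    for mask, band in masks:
        k = int(mask.sum())
        baseline[mask] = rng.uniform(band[0], band[1], size=k)

    # per-gene deterministic trajectory (class shape + module factor)
    latents = latent_module_trajectories(max(config.n_modules, 1), T)
    shape = np.zeros((n, T))
    for cls in ALL_CLASSES:
        mask = (class_label == cls).values
        if mask.any():
            shape[mask] = class_trajectory(cls, T) * config.effect_size
    loading = np.zeros(n)
    for m in range(config.n_modules):
        mask = (module == f"M{m + 1}").values
        loading[mask] = rng.uniform(0.9, 1.1, size=int(mask.sum()))
        shape[mask] += loading[mask, None] * latents[m] * config.effect_size

    gene_log2_mean = baseline[:, None] + shape  # genes x timepoints, noise-free

    # assemble samples: replicate offsets and residual noise
    divs = config.divs
    samples = make_sample_table(divs, R)
    offsets = rng.normal(0.0, config.replicate_sd, size=(n, R))
    log2_mat = np.empty((n, T * R))
    col = 0
    for ti in range(T):
        for r in range(R):
            log2_mat[:, col] = (
                gene_log2_mean[:, ti]
                + offsets[:, r]
                + rng.normal(0.0, config.noise_sd, size=n)
            )
            col += 1
    sample_ids = [f"D{d:02d}_R{r}" for d in divs for r in range(1, R + 1)]

    # probes: every gene has a primary probe; a fraction get an attenuated twin
    n_multi = int(round(config.frac_multi_probe * n))
    multi_mask = np.zeros(n, dtype=bool)
    if n_multi:
        multi_mask[rng.choice(n, size=n_multi, replace=False)] = True

    probe_rows = [log2_mat]
    probe_ids = [f"{g}_P1" for g in gene_ids]
    map_genes = list(gene_ids)
    if n_multi:
        atten = np.empty((n_multi, T * R))
        col = 0
        for ti in range(T):
            for r in range(R):
                atten[:, col] = (
                    baseline[multi_mask]
                    + 0.5 * shape[multi_mask, ti]
                    + offsets[multi_mask, r]
                    + rng.normal(0.0, config.noise_sd, size=n_multi)
                )
                col += 1
        probe_rows.append(atten)
        twin_genes = [g for g, m in zip(gene_ids, multi_mask) if m]
        probe_ids += [f"{g}_P2" for g in twin_genes]
        map_genes += twin_genes

    # unannotated scaffold probes: static intensities spanning the dynamic
    # range, as on real chips where a large probe fraction has no gene
    # annotation; they are dropped at probe collapse but anchor the
    # quantile-normalization reference across the moving strata
    n_scaffold = int(round(config.frac_unannotated * n))
    if n_scaffold:
        lo = BASELINE_BANDS["monotone_up"][0] - config.effect_size * 0.5
        hi = BASELINE_BANDS["module"][1] + config.effect_size * 1.2
        scaffold_base = rng.uniform(lo, hi, size=n_scaffold)
        scaffold = scaffold_base[:, None] + rng.normal(
            0.0, config.noise_sd, size=(n_scaffold, T * R)
        )
        probe_rows.append(scaffold)
        probe_ids += [f"UNANN_{i:05d}" for i in range(n_scaffold)]

    log2_all = np.vstack(probe_rows)
    signal = pd.DataFrame(
        np.exp2(log2_all), index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids
    )

    # detection p-values per probe
    gene_expressed = class_label != "not_expressed"
    probe_expressed = np.array(
        [gene_expressed[g] for g in map_genes] + [True] * n_scaffold
    )
    det = np.empty_like(log2_all)
    det[probe_expressed] = rng.uniform(0.0, 0.04, size=(int(probe_expressed.sum()), T * R))
    det[~probe_expressed] = rng.uniform(
        0.05, 1.0, size=(int((~probe_expressed).sum()), T * R)
    )
    detection_p = pd.DataFrame(det, index=signal.index, columns=sample_ids)

    expr = TimecourseExperiment(
        signal=signal, samples=samples, detection_p=detection_p, level="probe", log2=False
    )
    truth = GroundTruth(
        class_label=class_label,
        module=module,
        latent_trajectories=pd.DataFrame(
            latents[: config.n_modules] * config.effect_size,
            index=[f"M{m + 1}" for m in range(config.n_modules)],
            columns=list(divs),
        ),
        probe_map=pd.Series(
            map_genes, index=probe_ids[: len(map_genes)], name="gene"
        ),
        gene_log2=pd.DataFrame(gene_log2_mean, index=gene_ids, columns=list(divs)),
    )
    return expr, truth


# ----------------------------------------------------------------------------
# risk-gene lists


def _odds_ratio_at(a: int, n: int, K: int, M: int) -> float:
    """Sample OR of the 2x2 (list x class) table with a in-class list genes."""
    b, c, d = n - a, K - a, M - K - n + a
    if b == 0 or c == 0:
        return math.inf
    if a == 0 or d == 0:
        return 0.0
    return (a * d) / (b * c)


def generate_risk_lists(
    truth: GroundTruth,
    target_class: str,
    odds_ratio: float,
    list_size: int,
    seed: int,
    name: str | None = None,
) -> list[str]:
    """Sample a gene list with a planted membership x class odds ratio.

    The in-class count ``a`` is solved from the requested odds ratio (the OR
    is monotone in ``a``; the quadratic root is rounded to the neighbour
    closest in log-OR), then ``a`` class genes and ``list_size - a`` outside
    genes are drawn uniformly. All four table cells are kept positive so the
    realized OR is finite and estimable; a request outside the achievable
    finite range raises with the attainable extreme. The realized 2x2 table
    is recorded in ``truth.risk_tables``. ``target_class`` may be a class
    label, a module name, or ``"dynamic"``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    universe = truth.class_label.index
    M = len(universe)
    if list_size <= 0 or list_size > M:
        raise ValueError(f"list_size must be in 1..{M}")
    if target_class == "dynamic":
        in_class = truth.dynamic_truth
    elif target_class in ALL_CLASSES:
        in_class = truth.class_label == target_class
    else:
        in_class = truth.module == target_class
    class_genes = universe[in_class]
    K = len(class_genes)
    if K == 0:
        raise ValueError(f"target class {target_class!r} is empty")

    n = list_size
    # all cells positive: a>=1, b=n-a>=1, c=K-a>=1, d=M-K-n+a>=1
    a_lo = max(1, n + K - M + 1)
    a_hi = min(n - 1, K - 1)
    if a_lo > a_hi:
        raise ValueError(
            f"no non-degenerate 2x2 table exists for list_size={n} with "
            f"class size {K} in a universe of {M}"
        )

    # solve OR(a) = target: a^2 (1-OR) + a (M-K-n + OR(n+K)) - OR n K = 0
    if abs(odds_ratio - 1.0) < 1e-12:
        a_star = n * K / M
    else:
        A = 1.0 - odds_ratio
        B = (M - K - n) + odds_ratio * (n + K)
        C = -odds_ratio * n * K
        disc = B * B - 4 * A * C
        roots = [(-B + s * math.sqrt(max(disc, 0.0))) / (2 * A) for s in (1.0, -1.0)]
        feas = [r for r in roots if a_lo - 0.5 <= r <= a_hi + 0.5]
        a_star = feas[0] if feas else max(min(roots, key=lambda r: abs(r - a_hi)), a_lo)

    candidates = sorted(
        {max(a_lo, min(a_hi, int(math.floor(a_star)) + d)) for d in (0, 1)}
    )
    target_log = math.log(odds_ratio)

    def log_gap(a: int) -> float:
        orv = _odds_ratio_at(a, n, K, M)
        if orv == 0.0 or math.isinf(orv):
            return abs(target_log) * 1e6 + 1.0 if orv == 0.0 else abs(target_log - 700.0)
        return abs(math.log(orv) - target_log)

    a = min(candidates, key=log_gap)
    or_max = _odds_ratio_at(a_hi, n, K, M)
    or_min = _odds_ratio_at(a_lo, n, K, M)
    if odds_ratio > or_max * 1.0000001:
        raise ValueError(
            f"odds ratio {odds_ratio} unachievable; maximum achievable is {or_max:.4g}"
        )
    if odds_ratio < or_min * 0.9999999:
        raise ValueError(
            f"odds ratio {odds_ratio} unachievable; minimum achievable is {or_min:.4g}"
        )

    rng = np.random.default_rng(seed)
    outside = universe[~in_class]
    chosen = list(rng.choice(class_genes, size=a, replace=False)) + list(
        rng.choice(outside, size=n - a, replace=False)
    )
    chosen = sorted(chosen)
    table = [[a, n - a], [K - a, M - K - n + a]]
    truth.risk_tables[name or f"{target_class}_OR{odds_ratio:g}"] = {
        "table": table,
        "requested_or": odds_ratio,
        "realized_or": _odds_ratio_at(a, n, K, M),
    }
    return chosen
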