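"""End-to-end orchestration: simulate -> preprocess -> DEX -> DTW -> ICA ->
network -> enrichment, with a single config, per-stage seeds derived from
one master seed, and a run report whose overlap counts satisfy
inclusion-exclusion exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dtw as dtw_mod
from . import ica as ica_mod
from .diffexpr import run_diffexpr
from .enrichment import enrichment_grid
from .experiment import TimecourseExperiment
from .io import write_gmt, write_matrix
from .network import UNASSIGNED, build_network
from .preprocess import collapse_probes, expressed_set, log2_quantile_normalize, qc_samples
from .simulate import SimulationConfig, generate_risk_lists, generate_timecourse

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimulationConfig fields; empty = its defaults
    "preprocess": {"alpha_detect": 0.05, "n_top_variance": 2000},
    "diffexpr": {"q_cut": 0.05, "baseline_div": 0},
    "dtw": {
        "n_noise": 100,
        "noise_levels": [0.1, 0.2, 0.3, 0.4, 0.5],
        "k_max": 12,
        "kmeans_n_init": 50,
    },
    "ica": {
        "n_iter": 250,
        "component_range": [2, 8],
        "r_cut": 0.999,
        "load_z_cut": 3.0,
    },
    "network": {
        "beta": None,
        "beta_grid": [2, 4, 6, 8, 10, 12, 14, 16, 18, 20],
        "min_module_size": 30,
        "cut_height": 0.99,
        "spearman_cut": 0.90,
        "hub_quantile": 0.10,
    },
    "enrichment": {
        "fdr_report": 0.1,
        "sidedness": "two-sided",
        "risk_lists": [
            {"name": "planted_up_OR4", "target_class": "monotone_up",
             "odds_ratio": 4.0, "list_size": 300},
            {"name": "planted_dynamic_OR4", "target_class": "dynamic",
             "odds_ratio": 4.0, "list_size": 400},
            {"name": "planted_down_OR2", "target_class": "monotone_down",
             "odds_ratio": 2.0, "list_size": 250},
            {"name": "null_OR1", "target_class": "dynamic",
             "odds_ratio": 1.0, "list_size": 300},
        ],
    },
}


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config (and programmatic overrides) over the defaults."""
    cfg = _deep_merge({}, DEFAULT_CONFIG)
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Expand one master seed into independent per-stage seeds (< 2**31)."""
    rng = np.random.default_rng(master_seed)
    names = ["simulate", "dtw_null", "dtw_kmeans", "ica", "risk_lists"]
    return {n: int(rng.integers(0, 2**31 - 1)) for n in names}


@dataclass
class RunReport:
    config: dict
    seeds: dict
    counts: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    noise_model: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    recovery: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True, default=_json_safe)
        if path:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def three_way_overlap(a: set, b: set, c: set) -> dict:
    """All inclusion-exclusion terms for three gene sets."""
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_c": len(c),
        "ab": len(a & b),
        "ac": len(a & c),
        "bc": len(b & c),
        "abc": len(a & b & c),
        "union": len(a | b | c),
    }


@dataclass
class PipelineResult:
    report: RunReport
    experiment: TimecourseExperiment  # gene level, normalized
    truth: object | None
    expressed: pd.Index
    dex: object
    dyn: object
    components: object | None
    component_table: dict
    network: object
    grids: dict
    catalog: dict


def run_pipeline(
    config: dict | str | None = None,
    out_dir: str | None = None,
    seed: int | None = None,
) -> PipelineResult:
    """Execute the full analysis on a synthetic dataset per the config.

    ``config`` may be a dict or a YAML path; ``seed`` overrides the config
    master seed. When ``out_dir`` is given, stage outputs (TSV), a manifest
    with checksums, and the JSON run report are written there.
    """
    if isinstance(config, str):
        cfg = load_config(config)
    else:
        cfg = _deep_merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    seeds = stage_seeds(cfg["seed"])
    report = RunReport(config=cfg, seeds=seeds)

    # --- simulate -----------------------------------------------------------
    sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": seeds["simulate"]})
    raw, truth = generate_timecourse(sim_cfg)

    # --- preprocess ---------------------------------------------------------
    norm = log2_quantile_normalize(raw)
    gene_expr = collapse_probes(norm, truth.probe_map)
    expressed = expressed_set(gene_expr, alpha=cfg["preprocess"]["alpha_detect"])
    qc = qc_samples(gene_expr, n_top=cfg["preprocess"]["n_top_variance"])
    if qc.outliers.any():
        report.warnings.append(
            f"QC flagged samples: {list(qc.outliers.index[qc.outliers])}"
        )
    report.counts["genes_platform"] = int(gene_expr.signal.shape[0])
    report.counts["expressed"] = int(len(expressed))

    # --- differential expression ---------------------------------------------
    dex = run_diffexpr(
        gene_expr,
        expressed,
        baseline=cfg["diffexpr"]["baseline_div"],
        q_cut=cfg["diffexpr"]["q_cut"],
    )
    report.counts.update({f"dex_{k}": v for k, v in dex.counts().items()})
    report.counts["dex_nominal_first_timepoint"] = dex.nominal[
        min(dex.nominal)
    ]

    # --- DTW dynamics ---------------------------------------------------------
    expr_expressed = gene_expr.subset_features(expressed)
    noise_model = dtw_mod.calibrate_noise_null(
        n_timepoints=len(gene_expr.divs),
        noise_levels=cfg["dtw"]["noise_levels"],
        n_noise=cfg["dtw"]["n_noise"],
        seed=seeds["dtw_null"],
    )
    traj_sd = dtw_mod.estimate_trajectory_noise_sd(
        expr_expressed, baseline=cfg["diffexpr"]["baseline_div"]
    )
    dyn = dtw_mod.select_dynamic_genes(
        expr_expressed,
        noise_model,
        baseline=cfg["diffexpr"]["baseline_div"],
        noise_sd=traj_sd,
    )
    report.noise_model = {**noise_model.to_dict(), "trajectory_noise_sd": traj_sd,
                          "threshold_used": dyn.threshold_used}
    report.counts["dtw_dynamic"] = int(dyn.dynamic.sum())
    if len(dyn.dynamic_genes) > cfg["dtw"]["k_max"]:
        dyn = dtw_mod.cluster_trajectories(
            dyn,
            k_max=cfg["dtw"]["k_max"],
            n_init=cfg["dtw"]["kmeans_n_init"],
            seed=seeds["dtw_kmeans"],
        )
        report.counts["dtw_clusters"] = int(dyn.k)
    else:
        report.warnings.append("too few dynamic genes to cluster")

    # --- reproducible ICA -----------------------------------------------------
    lo, hi = cfg["ica"]["component_range"]
    X = expr_expressed.signal.to_numpy()
    n_star, table = ica_mod.select_component_count(
        X,
        component_range=range(lo, hi + 1),
        n_iter=cfg["ica"]["n_iter"],
        r_cut=cfg["ica"]["r_cut"],
        seed=seeds["ica"],
    )
    ica_genes: set = set()
    components = None
    if n_star is not None:
        components = table[n_star]
        components.load_z_cut = cfg["ica"]["load_z_cut"]
        components.loads = pd.DataFrame(
            components.loads,
            index=expressed,
            columns=[f"C{i + 1}" for i in range(components.n_components)],
        )
        sig = components.significant_genes()
        ica_genes = set().union(*[set(v) for v in sig.values()]) if sig else set()
        report.counts["ica_components"] = int(n_star)
        report.counts["ica_significant"] = len(ica_genes)
        ica_mod.component_activation(X, components)
    else:
        report.warnings.append("no ICA component count passed the r_cut")
        report.counts["ica_components"] = 0
        report.counts["ica_significant"] = 0
    report.counts["ica_r_table"] = {
        int(k): float(cs.reproducibility.min()) for k, cs in table.items()
    }

    # --- co-expression network -------------------------------------------------
    net = build_network(
        gene_expr,
        expressed,
        beta=cfg["network"]["beta"],
        beta_grid=cfg["network"]["beta_grid"],
        min_module_size=cfg["network"]["min_module_size"],
        cut_height=cfg["network"]["cut_height"],
        spearman_cut=cfg["network"]["spearman_cut"],
        hub_quantile=cfg["network"]["hub_quantile"],
        baseline=cfg["diffexpr"]["baseline_div"],
    )
    if net.beta_fallback:
        report.warnings.append(
            f"no soft power reached scale-free R^2 0.8; fell back to beta={net.beta}"
        )
    module_sizes = (
        net.labels[net.labels != UNASSIGNED].value_counts().to_dict()
    )
    report.counts["modules"] = len(module_sizes)
    report.counts["module_sizes"] = {str(k): int(v) for k, v in module_sizes.items()}
    report.counts["network_beta"] = int(net.beta)
    report.counts["hub_set_sizes"] = {
        k: len(v) for k, v in (net.hubs.top if net.hubs else {}).items()
    }

    # --- three-way overlap (DEX / DTW / ICA) -----------------------------------
    dex_set = set(dex.dex_any)
    dtw_set = set(dyn.dynamic_genes)
    report.overlap = three_way_overlap(dex_set, dtw_set, ica_genes)
    report.overlap["labels"] = ["dex_any", "dtw_dynamic", "ica_significant"]

    # --- enrichment --------------------------------------------------------------
    rng = np.random.default_rng(seeds["risk_lists"])
    catalog: dict[str, set] = {}
    for spec_ in cfg["enrichment"]["risk_lists"]:
        lst = generate_risk_lists(
            truth,
            target_class=spec_["target_class"],
            odds_ratio=spec_["odds_ratio"],
            list_size=spec_["list_size"],
            seed=int(rng.integers(0, 2**31 - 1)),
            name=spec_["name"],
        )
        catalog[spec_["name"]] = set(lst)

    universe = set(truth.class_label.index)
    clusters: dict[str, dict[str, set]] = {
        "dex": {"up_any": set(dex.up_any), "down_any": set(dex.down_any)},
        "dtw": {"all_dynamic": dtw_set},
        "modules": {
            f"module_{m}": set(net.labels.index[net.labels == m])
            for m in module_sizes
        },
        "hubs": {k: set(v) for k, v in (net.hubs.top if net.hubs else {}).items()},
    }
    if dyn.clusters is not None:
        for c in sorted(dyn.clusters.unique()):
            clusters["dtw"][f"cluster_{c}"] = set(
                dyn.clusters.index[dyn.clusters == c]
            )
    grids = {}
    for family, cl in clusters.items():
        if not cl:
            continue
        grids[family] = enrichment_grid(
            catalog,
            cl,
            universe,
            alternative=cfg["enrichment"]["sidedness"],
            fdr_report=cfg["enrichment"]["fdr_report"],
        )
    report.counts["enrichment_significant_05"] = {
        fam: int(g["sig_05"].sum()) for fam, g in grids.items()
    }

    result = PipelineResult(
        report=report,
        experiment=gene_expr,
        truth=truth,
        expressed=expressed,
        dex=dex,
        dyn=dyn,
        components=components,
        component_table=table,
        network=net,
        grids=grids,
        catalog=catalog,
    )
    if out_dir:
        _write_outputs(result, out_dir)
    return result


def _write_outputs(res: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def save(name: str, writer) -> None:
        path = os.path.join(out_dir, name)
        writer(path)
        paths[name] = path

    save("expression.gene.tsv", lambda p: write_matrix(res.experiment.signal, p))
    save("dex_results.tsv",
         lambda p: res.dex.results.to_csv(p, sep="\t", index=False))
    dyn_table = pd.DataFrame(
        {
            "dtw_distance": res.dyn.distance,
            "dynamic": res.dyn.dynamic,
        }
    )
    if res.dyn.clusters is not None:
        dyn_table["cluster"] = res.dyn.clusters.reindex(dyn_table.index)
    save("dtw_dynamics.tsv", lambda p: dyn_table.rename_axis("gene_id").to_csv(p, sep="\t"))
    if res.components is not None:
        save("ica_loads.tsv", lambda p: res.components.loads.to_csv(p, sep="\t"))
    save("modules.tsv",
         lambda p: res.network.labels.rename_axis("gene_id").to_csv(p, sep="\t"))
    if res.network.hubs is not None:
        save("hub_metrics.tsv", lambda p: res.network.hubs.metrics.to_csv(p, sep="\t"))
    if res.network.fc_profiles is not None:
        save("module_eigengene_fc.tsv",
             lambda p: res.network.fc_profiles.to_csv(p, sep="\t"))
    for fam, grid in res.grids.items():
        save(f"enrichment_{fam}.tsv", lambda p, g=grid: g.to_csv(p, sep="\t", index=False))
    save("risk_lists.gmt",
         lambda p: write_gmt({k: sorted(v) for k, v in res.catalog.items()}, p))
    if res.truth is not None:
        save("truth.tsv", lambda p: res.truth.write(p))
    save("report.json", lambda p: res.report.to_json(p))

    manifest = {
        name: {
            "sha256": hashlib.sha256(open(path, "rb").read()).hexdigest(),
            "bytes": os.path.getsize(path),
        }
        for name, path in paths.items()
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
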