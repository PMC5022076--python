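import logging

import numpy as np
import pandas as pd
import pytest

from neurocourse.experiment import TimecourseExperiment, make_sample_table
from neurocourse.preprocess import collapse_probes, log2_quantile_normalize
from neurocourse.simulate import SimulationConfig, generate_timecourse

logging.getLogger("neurocourse").setLevel(logging.ERROR)


def make_experiment(log2_matrix: np.ndarray, divs=(0, 1, 3, 5, 7, 9, 11),
                    n_replicates: int = 3, log2: bool = True,
                    detection_p: float | None = None) -> TimecourseExperiment:
    """Wrap a genes x (time*replicate) log2 matrix into an experiment."""
    samples = make_sample_table(divs, n_replicates)
    n = log2_matrix.shape[0]
    index = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    signal = pd.DataFrame(log2_matrix, index=index, columns=samples.index)
    det = None
    if detection_p is not None:
        det = pd.DataFrame(detection_p, index=index, columns=samples.index)
    return TimecourseExperiment(signal=signal, samples=samples,
                                detection_p=det, level="gene", log2=log2)


@pytest.fixture(scope="session")
def default_run():
    """A small default-noise simulated dataset, preprocessed to gene level."""
    cfg = SimulationConfig(n_genes=600, seed=11, n_modules=2, module_size=40)
    raw, truth = generate_timecourse(cfg)
    gene = collapse_probes(log2_quantile_normalize(raw), truth.probe_map)
    return cfg, raw, truth, gene


@pytest.fixture(scope="session")
def zero_noise_run():
    """A noiseless simulated dataset: the exact-recovery limit.

    Gene-level signal is plain log2 (no quantile step): with zero noise the
    columns' distributions differ by construction, and quantile
    normalization would redistribute rank-pinned extremes -- a property of
    the normalization, not of the models under test here.
    """
    cfg = SimulationConfig(
        n_genes=500, seed=7, noise_sd=0.0, replicate_sd=0.0,
        n_modules=0, module_size=0,
    )
    raw, truth = generate_timecourse(cfg)
    gene = collapse_probes(raw, truth.probe_map)
    gene.signal = np.log2(gene.signal)
    gene.log2 = True
    return cfg, raw, truth, gene
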