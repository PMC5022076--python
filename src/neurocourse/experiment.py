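"""Container for probe- or gene-level time-course expression experiments.

The design emulated throughout the package is a neuronal differentiation
course: 7 time points (days in vitro 0, 1, 3, 5, 7, 9, 11) with 3 biological
replicates each, assayed on an Illumina-style expression chip that reports a
summary signal intensity and a detection p-value per probe and sample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_DIVS = (0, 1, 3, 5, 7, 9, 11)


def sample_name(div: int, replicate: int) -> str:
    return f"D{div:02d}_R{replicate}"


def make_sample_table(divs=DEFAULT_DIVS, n_replicates: int = 3) -> pd.DataFrame:
    """Sample metadata table: one row per (time point, replicate)."""
    rows = [
        {"sample_id": sample_name(d, r), "div": int(d), "replicate": int(r)}
        for d in divs
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class TimecourseExperiment:
    """Expression matrix plus sample metadata and optional detection p-values.

    Attributes
    ----------
    signal : DataFrame, features x samples
        Raw (linear) intensities before normalization, log2 intensities after.
    samples : DataFrame indexed by sample_id with columns ``div``, ``replicate``.
    detection_p : DataFrame or None, same shape as ``signal``
        Illumina-convention probability that the signal is background.
    level : ``"probe"`` or ``"gene"``.
    log2 : whether ``signal`` is on the log2 scale.
    """

    signal: pd.DataFrame
    samples: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None
    level: str = "probe"
    log2: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        if list(self.signal.columns) != list(self.samples.index):
            raise ValueError("signal columns must match sample table rows one-to-one")
        if self.detection_p is not None:
            if self.detection_p.shape != self.signal.shape:
                raise ValueError("detection_p must have the same shape as signal")
            if list(self.detection_p.columns) != list(self.signal.columns):
                raise ValueError("detection_p columns must match signal columns")
        pairs = list(zip(self.samples["div"], self.samples["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("every (time point, replicate) pair must be unique")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.signal.index

    @property
    def divs(self) -> list[int]:
        return sorted(self.samples["div"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.samples.groupby("div").size().max())

    def columns_at(self, div: int) -> list[str]:
        """Sample IDs of a time point, ordered by replicate index."""
        sub = self.samples[self.samples["div"] == div].sort_values("replicate")
        return list(sub.index)

    def subset_features(self, ids) -> "TimecourseExperiment":
        det = self.detection_p.loc[ids] if self.detection_p is not None else None
        return replace(self, signal=self.signal.loc[ids], detection_p=det)

    def log2fc_trajectories(self, baseline_div: int = 0) -> pd.DataFrame:
        """Replicate-mean log2 fold change vs the baseline time point.

        Returns a features x time-points frame (baseline column is zero).
        Requires log2-scale signal.
        """
        if not self.log2:
            raise ValueError("log2fc_trajectories requires log2-scale signal")
        means = {}
        for d in self.divs:
            means[d] = self.signal[self.columns_at(d)].mean(axis=1)
        mean_df = pd.DataFrame(means)
        return mean_df.sub(mean_df[baseline_div], axis=0)
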