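"""Readers and writers for the tab-delimited formats used across the pipeline.

Formats:
- signal / detection-p matrices: TSV, feature rows x sample columns, header row;
- sample tables: TSV with sample_id, div, replicate columns;
- probe map: 2-column TSV (probe_id, gene_id);
- gene lists: GMT (name, description, then one gene per column).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .experiment import TimecourseExperiment, make_sample_table


def read_matrix(path: str) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def read_experiment(
    signal_path: str,
    detection_path: Optional[str] = None,
    samples_path: Optional[str] = None,
    level: str = "probe",
    log2: bool = False,
) -> TimecourseExperiment:
    """Load an experiment from TSV matrices.

    If no sample table is given, sample metadata is parsed from column names
    of the form ``D<div>_R<replicate>`` (e.g. ``D03_R1``).
    """
    signal = read_matrix(signal_path)
    detection = read_matrix(detection_path) if detection_path else None
    if samples_path:
        samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        samples = samples.loc[signal.columns]
    else:
        samples = parse_sample_names(signal.columns)
    return TimecourseExperiment(
        signal=signal, samples=samples, detection_p=detection, level=level, log2=log2
    )


def parse_sample_names(columns) -> pd.DataFrame:
    rows = []
    for c in columns:
        try:
            d_part, r_part = c.split("_")
            rows.append(
                {"sample_id": c, "div": int(d_part[1:]), "replicate": int(r_part[1:])}
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"cannot parse sample name {c!r}; expected 'D<div>_R<rep>'"
            ) from exc
    return pd.DataFrame(rows).set_index("sample_id")


def write_experiment(expr: TimecourseExperiment, prefix: str) -> dict:
    """Write signal (+ detection p, sample table) as ``<prefix>.*.tsv`` files."""
    paths = {"signal": f"{prefix}.signal.tsv", "samples": f"{prefix}.samples.tsv"}
    write_matrix(expr.signal, paths["signal"])
    expr.samples.to_csv(paths["samples"], sep="\t")
    if expr.detection_p is not None:
        paths["detection_p"] = f"{prefix}.detection_p.tsv"
        write_matrix(expr.detection_p, paths["detection_p"])
    return paths


def read_probe_map(path: str) -> pd.Series:
    """Probe -> gene mapping from a 2-column TSV (with or without header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.iloc[0, 0].lower() in ("probe", "probe_id"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene")


def write_probe_map(mapping: pd.Series, path: str) -> None:
    mapping.rename("gene_id").rename_axis("probe_id").to_csv(path, sep="\t")


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT gene-list catalog: name <tab> description <tab> gene..."""
    catalog: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            catalog[parts[0]] = [g for g in parts[2:] if g]
    return catalog


def write_gmt(catalog: dict[str, list[str]], path: str, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in catalog.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
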