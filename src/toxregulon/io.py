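"""Tabular I/O: expression matrices with scale tags, metadata, QC and result tables.

All on-disk formats are plain TSV. Expression matrices carry their scale
(``counts``, ``rpm`` or ``log2``) in a one-line sidecar header so a file can
never be fed into the wrong pipeline stage silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCALES = ("counts", "rpm", "log2")

#: canonical sample-metadata columns, in file order
METADATA_COLUMNS = ["sample_id", "chemical", "class", "dose_mg_per_kg", "sex", "replicate"]

#: canonical per-sample QC metric columns
QC_COLUMNS = [
    "sequencing_depth",
    "total_alignment_rate",
    "unique_alignment_rate",
    "aligned_reads",
    "pct_probes_ge5",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix tagged with its scale.

    Parameters
    ----------
    data:
        DataFrame indexed by gene identifier with one column per sample.
    scale:
        One of ``counts`` (non-negative integers), ``rpm`` (reads per
        million) or ``log2`` (log2 of RPM + 1).
    """

    data: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown expression scale {self.scale!r}; expected one of {SCALES}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        values = self.data.to_numpy()
        if self.scale == "counts" and (values < 0).any():
            raise ValueError("count matrix contains negative values")
        if self.scale == "log2" and not np.isfinite(values).all():
            raise ValueError("log2 matrix contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.scale)


def write_expression(em: ExpressionMatrix, path) -> None:
    """Write an expression matrix with its scale tag as a sidecar header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scale={em.scale}\n")
        em.data.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# scale="):
            raise ValueError(f"{path}: missing '# scale=' sidecar header line")
        scale = first.split("=", 1)[1]
        data = pd.read_csv(fh, sep="\t", index_col=0)
    return ExpressionMatrix(data, scale)


def write_table(df: pd.DataFrame, path, float_format: str | None = "%.6f") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    md = read_table(path)
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {missing}")
    return md


def read_qc_metrics(path) -> pd.DataFrame:
    qc = read_table(path)
    if "sample_id" not in qc.columns:
        raise ValueError(f"{path}: QC table must have a sample_id column")
    return qc
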