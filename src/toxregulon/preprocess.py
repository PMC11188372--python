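"""Sample QC, RPM normalization, log2 transform, outlier flagging and
principal-component-regression extrapolation from a measured sentinel gene
panel to the whole transcriptome.

QC follows a strictly-below rule: a sample fails if and only if any metric is
strictly below its threshold, so a metric sitting exactly at a threshold
passes. Outlier flagging uses the median inter-replicate Spearman correlation
within each (chemical, dose, sex) replicate group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, QC_COLUMNS
from .synthdata import Compendium


@dataclass
class QCThresholds:
    """Minimum acceptable per-sample sequencing QC values.

    Defaults: depth and aligned reads 300K, total alignment 40%, unique
    alignment 30%, fraction of probes with >= 5 reads 50%.
    """

    min_depth: float = 300_000
    min_total_align: float = 40.0
    min_unique_align: float = 30.0
    min_aligned_reads: float = 300_000
    min_pct_probes_ge5: float = 50.0

    def __post_init__(self):
        for name, value in self.as_dict().items():
            if value < 0:
                raise ValueError(f"QC threshold {name} must be non-negative")

    def as_dict(self) -> dict:
        return {
            "sequencing_depth": self.min_depth,
            "total_alignment_rate": self.min_total_align,
            "unique_alignment_rate": self.min_unique_align,
            "aligned_reads": self.min_aligned_reads,
            "pct_probes_ge5": self.min_pct_probes_ge5,
        }


def qc_filter(metrics: pd.DataFrame, thresholds: Optional[QCThresholds] = None) -> pd.DataFrame:
    """Flag samples whose QC metrics fall strictly below any threshold.

    Returns a DataFrame with one row per sample: ``sample_id``, ``qc_pass``
    and ``failed_rules`` (semicolon-joined names of every violated metric,
    empty for passing samples).
    """
    thresholds = thresholds or QCThresholds()
    rules = thresholds.as_dict()
    missing_cols = [c for c in QC_COLUMNS if c not in metrics.columns]
    if missing_cols:
        raise ValueError(f"QC table is missing metric columns {missing_cols}")
    rows = []
    for row in metrics.itertuples(index=False):
        failed = []
        for metric, cut in rules.items():
            value = getattr(row, metric)
            if pd.isna(value):
                raise ValueError(f"sample {row.sample_id}: missing QC metric {metric}")
            if value < cut:
                failed.append(metric)
        rows.append((row.sample_id, not failed, ";".join(failed)))
    return pd.DataFrame(rows, columns=["sample_id", "qc_pass", "failed_rules"])


def normalize_rpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample to reads per million (columns sum to 1e6)."""
    if counts.scale != "counts":
        raise ValueError(f"normalize_rpm expects a counts matrix, got scale={counts.scale!r}")
    colsums = counts.data.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(map(str, zero.index))}")
    rpm = counts.data.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(rpm, "rpm")


def log_transform(rpm: ExpressionMatrix) -> ExpressionMatrix:
    """Pseudo-count log transform: value -> log2(value + 1)."""
    if rpm.scale != "rpm":
        raise ValueError(f"log_transform expects an rpm matrix, got scale={rpm.scale!r}")
    if (rpm.data.to_numpy() < 0).any():
        raise ValueError("log_transform requires non-negative values")
    return ExpressionMatrix(np.log2(rpm.data + 1.0), "log2")


def flag_outliers(
    log_matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    min_median_corr: float = 0.8,
) -> pd.Series:
    """Flag replicate outliers by median inter-replicate Spearman correlation.

    Within each (chemical, dose, sex) replicate group of size >= 3, a sample
    is flagged iff the median of its pairwise Spearman correlations with the
    other group members falls below ``min_median_corr``. Groups of size <= 2
    are never flagged.
    """
    if log_matrix.scale != "log2":
        raise ValueError("flag_outliers expects a log2 matrix")
    flags = pd.Series(False, index=log_matrix.samples, name="outlier")
    for _, grp in metadata.groupby(["chemical", "dose_mg_per_kg", "sex"], sort=False):
        ids = [s for s in grp["sample_id"] if s in flags.index]
        if len(ids) < 3:
            continue
        sub = log_matrix.data[ids].to_numpy()
        rho = stats.spearmanr(sub).statistic  # columns are samples
        rho = np.atleast_2d(rho)
        for i, sid in enumerate(ids):
            others = np.delete(rho[i], i)
            others = others[~np.isnan(others)]
            if len(others) and np.median(others) < min_median_corr:
                flags[sid] = True
    return flags


@dataclass
class PCRExtrapolator:
    """Principal-component-regression map from a measured gene panel to all genes.

    Principal components are computed on the sample-centered measured-gene
    submatrix of a reference compendium; every output gene is then regressed
    by ordinary least squares on the component scores.
    """

    measured_genes: list
    output_genes: list
    offsets: np.ndarray        # per measured gene centering offsets
    components: np.ndarray     # measured genes x n_components, orthonormal
    coef: np.ndarray           # n_components x output genes
    intercepts: np.ndarray     # per output gene means
    n_components: int

    def predict(self, measured: pd.DataFrame, passthrough: bool = True) -> pd.DataFrame:
        X = measured.reindex(self.measured_genes).to_numpy().T  # samples x measured
        scores = (X - self.offsets) @ self.components
        pred = self.intercepts + scores @ self.coef
        out = pd.DataFrame(pred.T, index=self.output_genes, columns=measured.columns)
        if passthrough:
            out.loc[self.measured_genes] = measured.reindex(self.measured_genes).to_numpy()
        return out


def fit_pcr_extrapolator(
    compendium: Compendium,
    measured_genes: Optional[Sequence[str]] = None,
    n_components: Optional[int] = None,
    variance_target: float = 0.95,
    max_components: int = 100,
) -> PCRExtrapolator:
    """Fit the PC-regression extrapolator on a reference compendium.

    When ``n_components`` is not given, the smallest number of components
    explaining ``variance_target`` of the measured-panel variance is used,
    capped at ``max_components``.
    """
    expr = compendium.expression
    measured = list(measured_genes) if measured_genes is not None else list(compendium.measured_genes)
    missing = sorted(set(measured) - set(expr.index))
    if missing:
        raise ValueError(f"measured genes absent from compendium: {missing}")
    M = expr.loc[measured].to_numpy().T  # samples x measured
    n_samples, n_measured = M.shape
    offsets = M.mean(axis=0)
    Mc = M - offsets
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    max_rank = min(n_measured, n_samples)
    if n_components is None:
        var = s**2
        ratio = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        n_components = int(np.searchsorted(ratio, variance_target) + 1)
        n_components = min(n_components, max_components, max_rank)
    if not (1 <= n_components <= max_rank):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(measured genes, samples)={max_rank}]"
        )
    components = Vt[:n_components].T                      # measured x k
    scores = Mc @ components                              # samples x k
    Y = expr.to_numpy().T                                 # samples x all genes
    intercepts = Y.mean(axis=0)
    coef, *_ = np.linalg.lstsq(scores, Y - intercepts, rcond=None)
    return PCRExtrapolator(
        measured_genes=measured,
        output_genes=list(expr.index),
        offsets=offsets,
        components=components,
        coef=coef,
        intercepts=intercepts,
        n_components=int(n_components),
    )


def apply_extrapolator(
    model: PCRExtrapolator,
    measured_matrix: ExpressionMatrix,
    passthrough: bool = True,
) -> ExpressionMatrix:
    """Extrapolate a measured-panel log2 matrix to the model's full gene set.

    The input gene set must equal the model's measured panel (order does not
    matter). Measured genes are passed through verbatim by default.
    """
    if measured_matrix.scale != "log2":
        raise ValueError("apply_extrapolator expects a log2 matrix")
    have = set(measured_matrix.genes)
    want = set(model.measured_genes)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        parts = []
        if missing:
            parts.append(f"missing genes: {missing}")
        if extra:
            parts.append(f"unexpected genes: {extra}")
        raise ValueError("measured matrix gene set mismatch — " + "; ".join(parts))
    out = model.predict(measured_matrix.data, passthrough=passthrough)
    return ExpressionMatrix(out, "log2")
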