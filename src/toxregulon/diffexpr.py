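"""Per-condition differential expression: log2 fold changes, per-dose one-way
ANOVA against pooled vehicle controls, and Benjamini-Hochberg FDR adjustment.

A condition is one (chemical, dose, sex) treated group; its controls are the
same chemical's vehicle (dose 0) samples of the same sex, pooled across that
chemical's dose arms. For two groups the one-way ANOVA F statistic equals the
square of the pooled two-sample t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass(frozen=True)
class Condition:
    chemical: str
    chem_class: str
    dose: float
    sex: str

    def label(self) -> str:
        return f"{self.chemical}|{self.sex}|{self.dose:g}"


def conditions_from_metadata(metadata: pd.DataFrame) -> list:
    """All treated (chemical, dose, sex) conditions, ordered by chemical, sex, dose."""
    treated = metadata[metadata["dose_mg_per_kg"] > 0]
    conds = (
        treated[["chemical", "class", "dose_mg_per_kg", "sex"]]
        .drop_duplicates()
        .sort_values(["chemical", "sex", "dose_mg_per_kg"])
    )
    return [
        Condition(chemical, chem_class, dose, sex)
        for chemical, chem_class, dose, sex in conds.itertuples(index=False, name=None)
    ]


def _split_groups(metadata: pd.DataFrame, condition: Condition):
    treated = metadata[
        (metadata["chemical"] == condition.chemical)
        & (metadata["dose_mg_per_kg"] == condition.dose)
        & (metadata["sex"] == condition.sex)
    ]["sample_id"].tolist()
    control = metadata[
        (metadata["chemical"] == condition.chemical)
        & (metadata["dose_mg_per_kg"] == 0)
        & (metadata["sex"] == condition.sex)
    ]["sample_id"].tolist()
    if len(treated) == 0 or len(control) == 0:
        raise ValueError(f"empty treated or control group for condition {condition.label()}")
    return treated, control


def compute_log2fc(
    log_matrix: ExpressionMatrix, metadata: pd.DataFrame, condition: Condition
) -> pd.Series:
    """Per-gene log2FC = mean(log2 treated) - mean(log2 pooled vehicle controls)."""
    if log_matrix.scale != "log2":
        raise ValueError("compute_log2fc expects a log2 matrix")
    treated, control = _split_groups(metadata, condition)
    fc = log_matrix.data[treated].mean(axis=1) - log_matrix.data[control].mean(axis=1)
    fc.name = "log2fc"
    return fc


def anova_per_dose(
    log_matrix: ExpressionMatrix, metadata: pd.DataFrame, condition: Condition
) -> pd.DataFrame:
    """Two-group one-way ANOVA (treated vs pooled vehicle controls), per gene.

    Genes with zero between- and within-group variance get F = 0, p = 1;
    zero within-group variance with a group-mean difference gives p = 0.
    """
    treated, control = _split_groups(metadata, condition)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(f"groups must each have >= 2 samples for condition {condition.label()}")
    t = log_matrix.data[treated].to_numpy()
    c = log_matrix.data[control].to_numpy()
    F, p = two_group_anova(t, c)
    return pd.DataFrame({"F": F, "p": p}, index=log_matrix.genes)


def two_group_anova(t: np.ndarray, c: np.ndarray):
    """Vectorised one-way ANOVA over two groups laid out as (genes, samples)."""
    n1, n2 = t.shape[1], c.shape[1]
    mt, mc = t.mean(axis=1), c.mean(axis=1)
    grand = (n1 * mt + n2 * mc) / (n1 + n2)
    ss_between = n1 * (mt - grand) ** 2 + n2 * (mc - grand) ** 2
    ss_within = ((t - mt[:, None]) ** 2).sum(axis=1) + ((c - mc[:, None]) ** 2).sum(axis=1)
    df2 = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / 1.0) / (ss_within / df2)
    degenerate = ss_within == 0
    F = np.where(degenerate & (ss_between == 0), 0.0, F)
    F = np.where(degenerate & (ss_between > 0), np.inf, F)
    p = stats.f.sf(F, 1, df2)
    p = np.where(degenerate & (ss_between == 0), 1.0, p)
    return F, p


def anova_all_doses(
    log_matrix: ExpressionMatrix, metadata: pd.DataFrame, chemical: str, sex: str
) -> pd.DataFrame:
    """Optional global mode: one-way ANOVA across all dose groups of one (chemical, sex)."""
    sub = metadata[(metadata["chemical"] == chemical) & (metadata["sex"] == sex)]
    groups = [
        log_matrix.data[g["sample_id"].tolist()].to_numpy()
        for _, g in sub.groupby("dose_mg_per_kg", sort=True)
    ]
    if len(groups) < 2:
        raise ValueError(f"need >= 2 dose groups for {chemical} ({sex})")
    F, p = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    F = np.where(np.isnan(F), 0.0, F)
    return pd.DataFrame({"F": F, "p": p}, index=log_matrix.genes)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_adjust requires a non-empty p-value vector")
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_fc_table(log_matrix: ExpressionMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """FoldChangeTable: one record per (gene, chemical, dose, sex) with log2fc, p, q.

    FDR is adjusted across genes within each condition.
    """
    conditions = conditions_from_metadata(metadata)
    if not conditions:
        raise ValueError("metadata contains no treated conditions")
    frames = []
    for cond in conditions:
        fc = compute_log2fc(log_matrix, metadata, cond)
        an = anova_per_dose(log_matrix, metadata, cond)
        q = bh_adjust(an["p"].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "gene": log_matrix.genes,
                    "chemical": cond.chemical,
                    "class": cond.chem_class,
                    "dose_mg_per_kg": cond.dose,
                    "sex": cond.sex,
                    "log2fc": fc.to_numpy(),
                    "p": an["p"].to_numpy(),
                    "q": q,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
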