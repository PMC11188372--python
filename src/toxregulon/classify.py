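"""Per-gene response-pattern classification, dose-trend detection and weighted
gene-signature concordance.

Patterns are called from the top-dose fold change of every (chemical, sex)
cell, in precedence order:

1. ``consistent_up`` / ``consistent_down`` — every cell shares one sign and at
   least ``min_support`` of cells pass the magnitude threshold;
2. ``sex_dependent`` — sign uniform within each sex, opposite between sexes
   (e.g. a gene downregulated in males but upregulated in females);
3. ``class_dependent`` — sign uniform within each chemical class (both sexes),
   opposite between PFAS and PAH;
4. ``none``.

A fold change of exactly 0 counts as neither direction and breaks consistency.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

PATTERNS = ("consistent_up", "consistent_down", "sex_dependent", "class_dependent", "none")


def detect_dose_trend(
    fc_by_dose: Sequence[float],
    doses: Optional[Sequence[float]] = None,
    threshold: float = 0.6,
    window: int = 3,
    monotone: str = "net",
) -> str:
    """Classify a gene's fold-change series over ascending doses as a trend.

    A trend is called when, over the ``window`` highest doses, all fold
    changes share one sign and the top-dose |fc| reaches ``threshold``, and
    the fold change moves in that same direction as dose increases. The
    direction-of-motion clause has two modes:

    ``net`` (default)
        the least-squares slope of fc against log-dose (or dose rank when
        doses are not given) over the whole series must not oppose the sign;
    ``pointwise``
        |fc| must be non-decreasing step by step within the window.

    Fewer than 3 doses (or fewer than ``window``) always yields ``none``.
    """
    if monotone not in ("net", "pointwise"):
        raise ValueError("monotone must be 'net' or 'pointwise'")
    fc = np.asarray(list(fc_by_dose), dtype=float)
    if fc.size < max(3, window):
        return "none"
    w = fc[-window:]
    signs = np.sign(w)
    if signs[0] == 0 or not (signs == signs[0]).all():
        return "none"
    sign = signs[0]
    if abs(w[-1]) < threshold:
        return "none"
    if monotone == "pointwise":
        mag = sign * w
        if (np.diff(mag) < 0).any():
            return "none"
    else:
        if doses is not None:
            x = np.log(np.asarray(list(doses), dtype=float))
        else:
            x = np.arange(fc.size, dtype=float)
        slope = np.polyfit(x, fc, 1)[0]
        if sign * slope < 0:
            return "none"
    return "up" if sign > 0 else "down"


def classify_gene_response(
    cells: Mapping[tuple, float],
    classes: Mapping[str, str],
    threshold: float = 0.6,
    min_support: float = 1.0,
) -> tuple:
    """Classify one gene from its top-dose fold changes per (chemical, sex).

    ``cells`` maps (chemical, sex) to log2fc; ``classes`` maps each chemical
    to its class (PFAS or PAH). Returns ``(pattern, supporting_cells)`` where
    supporting cells are the (chemical, sex) keys whose |fc| passed the
    threshold.
    """
    if not cells:
        raise ValueError("no fold-change cells supplied")
    sexes = sorted({sex for _, sex in cells})
    if len(sexes) < 2:
        raise ValueError(f"both sexes are required; found only {sexes}")
    chem_classes = {classes[chem] for chem, _ in cells}
    if len(chem_classes) < 2:
        raise ValueError(f"both chemical classes are required; found only {sorted(chem_classes)}")

    values = pd.Series(cells)
    signs = np.sign(values)
    support = float((values.abs() >= threshold).mean())
    supporting = sorted(k for k, v in cells.items() if abs(v) >= threshold)
    supported = support >= min_support

    def uniform_sign(keys) -> float:
        s = {signs[k] for k in keys}
        if len(s) == 1 and 0 not in s:
            return s.pop()
        return 0.0

    overall = uniform_sign(list(cells))
    if overall and supported:
        return ("consistent_up" if overall > 0 else "consistent_down", supporting)

    by_sex = {sex: uniform_sign([k for k in cells if k[1] == sex]) for sex in sexes}
    if all(by_sex.values()) and len(set(by_sex.values())) > 1 and supported:
        return ("sex_dependent", supporting)

    by_class = {
        cls: uniform_sign([k for k in cells if classes[k[0]] == cls]) for cls in sorted(chem_classes)
    }
    if all(by_class.values()) and len(set(by_class.values())) > 1 and supported:
        return ("class_dependent", supporting)

    return ("none", supporting)


def dose_trend_table(
    fc_table: pd.DataFrame,
    threshold: float = 0.6,
    window: int = 3,
    monotone: str = "net",
) -> pd.DataFrame:
    """Dose-trend calls for every gene and (chemical, sex) of a fold-change table.

    Returns a gene-indexed frame with one ``trend::<chemical>::<sex>`` column
    per cell, each entry in {up, down, none}.
    """
    columns = {}
    for (chem, sex), grp in fc_table.groupby(["chemical", "sex"], sort=True):
        wide = grp.pivot_table(index="gene", columns="dose_mg_per_kg", values="log2fc").sort_index(axis=1)
        doses = wide.columns.to_numpy(dtype=float)
        columns[f"trend::{chem}::{sex}"] = wide.apply(
            lambda row: detect_dose_trend(
                row.to_numpy(), doses, threshold=threshold, window=window, monotone=monotone
            ),
            axis=1,
        )
    return pd.DataFrame(columns).fillna("none")


def classify_table(
    fc_table: pd.DataFrame,
    threshold: float = 0.6,
    min_support: float = 1.0,
    trend_threshold: float = 0.6,
    trend_window: int = 3,
    trend_monotone: str = "net",
) -> pd.DataFrame:
    """Response calls for every gene of a fold-change table.

    Pattern classification uses the top dose of each (chemical, sex); dose
    trends are detected per (chemical, sex) over the full dose ladder. The
    returned frame has one row per gene: ``gene``, ``pattern``,
    ``supporting_cells`` and one ``trend::<chemical>::<sex>`` column per cell.
    """
    classes = dict(fc_table[["chemical", "class"]].drop_duplicates().itertuples(index=False, name=None))
    top_dose = fc_table.groupby(["chemical", "sex"])["dose_mg_per_kg"].max()

    cell_keys = sorted(top_dose.index)
    top = fc_table.merge(
        top_dose.rename("top_dose"), left_on=["chemical", "sex"], right_index=True
    )
    top = top[top["dose_mg_per_kg"] == top["top_dose"]]
    top_fc = top.pivot_table(index="gene", columns=["chemical", "sex"], values="log2fc")

    trends = dose_trend_table(
        fc_table, threshold=trend_threshold, window=trend_window, monotone=trend_monotone
    )

    rows = []
    for gene in top_fc.index:
        cells = {key: top_fc.loc[gene, key] for key in cell_keys}
        pattern, supporting = classify_gene_response(
            cells, classes, threshold=threshold, min_support=min_support
        )
        row = {
            "gene": gene,
            "pattern": pattern,
            "supporting_cells": ";".join(f"{c}/{s}" for c, s in supporting),
        }
        for col in trends.columns:
            row[col] = trends.at[gene, col] if gene in trends.index else "none"
        rows.append(row)
    return pd.DataFrame(rows)


def read_signature(path) -> pd.DataFrame:
    """Read a weighted gene signature TSV (columns: gene, weight; weights nonzero)."""
    sig = pd.read_csv(path, sep="\t")
    if not {"gene", "weight"} <= set(sig.columns):
        raise ValueError(f"{path}: signature must have gene and weight columns")
    if (sig["weight"] == 0).any():
        raise ValueError(f"{path}: signature weights must be nonzero")
    return sig[["gene", "weight"]]


def signature_concordance(
    fc_table: pd.DataFrame,
    signature: pd.DataFrame,
    condition: tuple,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Compare observed fold-change directions against a weighted signature.

    ``condition`` is a (chemical, dose, sex) tuple. A signature gene is
    ``concordant`` when significant (q < q_threshold, strict) with
    sign(log2fc) matching sign(weight), ``discordant`` when significant with
    opposite sign, ``not_significant`` otherwise, and ``absent`` when missing
    from the table.
    """
    if signature.empty:
        raise ValueError("signature is empty")
    chem, dose, sex = condition
    sub = fc_table[
        (fc_table["chemical"] == chem)
        & (fc_table["dose_mg_per_kg"] == dose)
        & (fc_table["sex"] == sex)
    ].set_index("gene")
    rows = []
    for gene, weight in signature[["gene", "weight"]].itertuples(index=False, name=None):
        if gene not in sub.index:
            rows.append((gene, weight, np.nan, np.nan, "absent"))
            continue
        log2fc, q = sub.at[gene, "log2fc"], sub.at[gene, "q"]
        if q < q_threshold:
            status = "concordant" if np.sign(log2fc) == np.sign(weight) else "discordant"
        else:
            status = "not_significant"
        rows.append((gene, weight, log2fc, q, status))
    return pd.DataFrame(rows, columns=["gene", "weight", "log2fc", "q", "status"])
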