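"""Dysregulation profiling: count each MIE's up/down target genes per
condition at the inclusive +-0.6 log2FC thresholds and assemble the per-MIE x
per-condition profile (with a top-k-doses tabular view mirroring how such
counts are usually reported: MIE rows, chemical x sex x dose columns).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .regulon import MIENetwork


def count_dysregulated(
    fc: Mapping[str, float],
    network: MIENetwork,
    up_thr: float = 0.6,
    down_thr: float = -0.6,
) -> pd.DataFrame:
    """Per-MIE counts of upregulated (fc >= up_thr) and downregulated
    (fc <= down_thr) mapped targets; thresholds are inclusive.

    Targets missing from ``fc`` contribute nothing. Returns a DataFrame
    indexed by MIE with columns n_up, n_down, n_total, up_genes, down_genes
    (gene lists).
    """
    if up_thr <= down_thr:
        raise ValueError(f"up_thr ({up_thr}) must be > down_thr ({down_thr})")
    fc_map = fc if isinstance(fc, pd.Series) else pd.Series(fc)
    rows = []
    for mie in network.counts.index:
        targets = network.targets_of(mie)
        values = fc_map.reindex(targets).dropna()
        up = sorted(values.index[values >= up_thr])
        down = sorted(values.index[values <= down_thr])
        rows.append((mie, len(up), len(down), len(up) + len(down), up, down))
    return pd.DataFrame(
        rows, columns=["mie", "n_up", "n_down", "n_total", "up_genes", "down_genes"]
    ).set_index("mie")


def profile_conditions(
    fc_table: pd.DataFrame,
    network: MIENetwork,
    conditions: Optional[Sequence[tuple]] = None,
    up_thr: float = 0.6,
    down_thr: float = -0.6,
) -> pd.DataFrame:
    """Apply :func:`count_dysregulated` to every condition of a fold-change table.

    ``conditions`` is an optional list of (chemical, dose, sex) tuples; by
    default every condition present in the table is profiled. Returns a long
    DataFrame: mie, chemical, class, sex, dose_mg_per_kg, n_up, n_down,
    n_total, up_genes, down_genes.
    """
    available = {
        (chem, dose, sex): grp
        for (chem, dose, sex), grp in fc_table.groupby(
            ["chemical", "dose_mg_per_kg", "sex"], sort=True
        )
    }
    if conditions is None:
        keys = sorted(available)
    else:
        keys = [tuple(c) for c in conditions]
        missing = [k for k in keys if k not in available]
        if missing:
            raise ValueError(f"conditions absent from fold-change table: {missing}")
    frames = []
    for chem, dose, sex in keys:
        grp = available[(chem, dose, sex)]
        fc = grp.set_index("gene")["log2fc"]
        counts = count_dysregulated(fc, network, up_thr=up_thr, down_thr=down_thr)
        counts = counts.reset_index()
        counts.insert(1, "chemical", chem)
        counts.insert(2, "class", grp["class"].iloc[0])
        counts.insert(3, "sex", sex)
        counts.insert(4, "dose_mg_per_kg", dose)
        frames.append(counts)
    return pd.concat(frames, ignore_index=True)


def top_dose_view(profile: pd.DataFrame, k: int = 3, value: str = "n_total") -> pd.DataFrame:
    """Pivot the profile to MIE rows x (chemical, sex, dose) columns, keeping
    only the k highest doses of each (chemical, sex)."""
    kept = []
    for (chem, sex), grp in profile.groupby(["chemical", "sex"], sort=True):
        doses = sorted(grp["dose_mg_per_kg"].unique())[-k:]
        kept.append(grp[grp["dose_mg_per_kg"].isin(doses)])
    sub = pd.concat(kept, ignore_index=True)
    view = sub.pivot_table(
        index="mie", columns=["chemical", "sex", "dose_mg_per_kg"], values=value, aggfunc="first"
    )
    return view.sort_index(axis=1)


def direction_split(profile: pd.DataFrame) -> pd.DataFrame:
    """Fractions of up vs down dysregulated targets per (MIE, condition).

    Cells with n_total = 0 carry NaN fractions and undefined=True rather than
    a 0/0 artifact.
    """
    if profile.empty:
        raise ValueError("profile is empty")
    out = profile.copy()
    total = out["n_total"].to_numpy().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["frac_up"] = np.where(total > 0, out["n_up"] / total, np.nan)
        out["frac_down"] = np.where(total > 0, out["n_down"] / total, np.nan)
    out["undefined"] = total == 0
    return out


def write_profile(profile: pd.DataFrame, path) -> None:
    """Write the long-format profile TSV (gene lists joined with ';')."""
    flat = profile.copy()
    for col in ("up_genes", "down_genes"):
        flat[col] = flat[col].map(lambda genes: ";".join(genes))
    flat.to_csv(path, sep="\t", index=False, float_format="%.6f")
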