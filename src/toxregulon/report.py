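"""End-to-end pipeline: one structured config drives simulation (or loading) of
a study, QC, normalization, differential expression, MIE network profiling,
response classification, signature concordance, heatmap matrices and network
exports, with a run manifest recording inputs, seeds and per-stage counts.

All floating-point TSV output is rounded to 6 decimals so repeated runs with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy

from . import classify as classify_mod
from . import diffexpr, preprocess, profiling, regulon, synthdata
from .io import read_expression, read_metadata, read_qc_metrics, write_expression

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A pipeline config is missing or has an invalid field."""


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    config["_base_dir"] = str(path.parent)
    return config


def _resolve(config: dict, relpath: str) -> Path:
    base = Path(config.get("_base_dir", "."))
    p = Path(relpath)
    return p if p.is_absolute() else base / p


def _require(config: dict, dotted: str):
    node = config
    for key in dotted.split("."):
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing required config field: {dotted}")
        node = node[key]
    return node


def validate_config(config: dict) -> None:
    _require(config, "inputs.regulons")
    _require(config, "inputs.mie_list")
    if "simulate" not in config:
        for field in ("inputs.expression", "inputs.metadata", "inputs.qc"):
            _require(config, field)
    thresholds = config.get("thresholds", {})
    up = thresholds.get("up", 0.6)
    down = thresholds.get("down", -0.6)
    if up <= down:
        raise ConfigError(f"thresholds.up ({up}) must be > thresholds.down ({down})")
    q = thresholds.get("q", 0.1)
    if not (0 < q < 1):
        raise ConfigError(f"thresholds.q ({q}) must lie in (0, 1)")
    for path_key in ("regulons", "mie_list", "mapping", "signature"):
        rel = config["inputs"].get(path_key)
        if rel is not None and not _resolve(config, rel).exists():
            raise ConfigError(f"inputs.{path_key}: file not found: {rel}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "-", str(text)).strip("-")


def _build_design(sim: dict) -> synthdata.StudyDesign:
    if "chemicals" in sim:
        chemicals = [
            synthdata.Chemical(c["name"], c["class"], tuple(c["doses"])) for c in sim["chemicals"]
        ]
    else:
        chemicals = synthdata.default_design().chemicals
    return synthdata.StudyDesign(
        chemicals=chemicals,
        n_treated=int(sim.get("n_treated", 5)),
        n_control=int(sim.get("n_control", 10)),
        n_genes=int(sim.get("n_genes", 17000)),
    )


def _build_effects(sim: dict) -> list:
    effects = []
    for entry in sim.get("effects", []):
        kwargs = dict(entry)
        if "sexes" in kwargs:
            kwargs["sexes"] = tuple(kwargs["sexes"])
        if "classes" in kwargs:
            kwargs["classes"] = tuple(kwargs["classes"])
        effects.append(synthdata.PlantedEffect(**kwargs))
    return effects


def render_heatmap_matrix(
    fc_table: pd.DataFrame,
    genes: Sequence[str],
    conditions: Sequence[tuple],
    linkage: str = "average",
    metric: str = "euclidean",
):
    """Gene x condition fold-change matrix with rows ordered by hierarchical
    clustering (column order fixed by the supplied condition order: chemicals
    left to right, doses ascending within each chemical).

    ``conditions`` is a list of (chemical, dose, sex) tuples. Genes absent
    from the table are skipped and reported. Returns ``(ordered_df, skipped)``.
    """
    if not len(genes):
        raise ValueError("gene set for the heatmap is empty")
    columns = [f"{chem}|{dose:g}|{sex}" for chem, dose, sex in conditions]
    pieces = {}
    for (chem, dose, sex), col in zip(conditions, columns):
        sub = fc_table[
            (fc_table["chemical"] == chem)
            & (fc_table["dose_mg_per_kg"] == dose)
            & (fc_table["sex"] == sex)
        ]
        pieces[col] = sub.set_index("gene")["log2fc"]
    matrix = pd.DataFrame(pieces, columns=columns)
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in matrix.index and not matrix.loc[g].isna().any()]
    skipped = [g for g in genes if g not in present]
    matrix = matrix.loc[present]
    if len(matrix) > 2:
        link = hierarchy.linkage(matrix.to_numpy(), method=linkage, metric=metric)
        order = hierarchy.leaves_list(link)
        matrix = matrix.iloc[order]
    elif len(matrix) == 2:
        pass  # two rows: clustering cannot reorder anything meaningfully
    return matrix, skipped


def run_pipeline(config, output_dir=None, seed: Optional[int] = None) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    ``config`` is a path to a YAML file or an already-loaded dict. The
    manifest is written to ``<output_dir>/manifest.json`` on success and on
    failure alike.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    validate_config(config)
    out_dir = Path(output_dir or config.get("output_dir", "toxregulon_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))

    echo = {k: v for k, v in config.items() if not k.startswith("_")}
    echo["output_dir"] = "."
    manifest: dict = {
        "config": echo,
        "seed": seed,
        "inputs": {},
        "counts": {},
        "warnings": [],
        "status": "failed",
    }
    warnings_list = manifest["warnings"]

    try:
        _run_stages(config, out_dir, seed, manifest, warnings_list)
        manifest["status"] = "ok"
    finally:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest


def _run_stages(config, out_dir: Path, seed: int, manifest: dict, warnings_list: list) -> None:
    thresholds = config.get("thresholds", {})
    up_thr = float(thresholds.get("up", 0.6))
    down_thr = float(thresholds.get("down", -0.6))
    q_thr = float(thresholds.get("q", 0.1))
    trend_window = int(thresholds.get("trend_window", 3))
    min_support = float(thresholds.get("min_support", 1.0))
    min_median_corr = float(thresholds.get("min_median_corr", 0.8))
    top_k = int(thresholds.get("top_doses", 3))

    # --- stage: regulon ingestion -----------------------------------------
    regulon_path = _resolve(config, config["inputs"]["regulons"])
    edges = regulon.read_regulatory_table(regulon_path)
    manifest["inputs"]["regulons"] = _sha256(regulon_path)
    mapping_rel = config["inputs"].get("mapping")
    if mapping_rel:
        mapping_path = _resolve(config, mapping_rel)
        mapping = regulon.read_symbol_map(mapping_path)
        manifest["inputs"]["mapping"] = _sha256(mapping_path)
    else:
        mapping = {}
    edges, map_report = regulon.map_symbols(edges, mapping)
    if map_report["one_to_many"]:
        warnings_list.append(f"one-to-many symbol mappings: {map_report['one_to_many']}")
    mie_path = _resolve(config, config["inputs"]["mie_list"])
    mies = regulon.read_mie_list(mie_path)
    manifest["inputs"]["mie_list"] = _sha256(mie_path)
    manifest["counts"]["regulon_edges"] = int(len(edges))
    manifest["counts"]["mies"] = int(len(mies))

    # --- stage: study data -------------------------------------------------
    if "simulate" in config:
        sim = config["simulate"]
        design = _build_design(sim)
        bundle = synthdata.simulate_study(
            design,
            edges,
            effects=_build_effects(sim),
            noise_sd=float(sim.get("noise_sd", 0.5)),
            libsize_range=tuple(sim.get("libsize_range", (1_000_000, 3_000_000))),
            mode=sim.get("mode", "lognormal"),
            qc_fail_fraction=float(sim.get("qc_fail_fraction", 0.0)),
            seed=seed,
        )
        expression, metadata, qc = bundle.expression, bundle.metadata, bundle.qc
        synthdata.write_table(bundle.truth, out_dir / "truth.tsv")
    else:
        expr_path = _resolve(config, config["inputs"]["expression"])
        md_path = _resolve(config, config["inputs"]["metadata"])
        qc_path = _resolve(config, config["inputs"]["qc"])
        expression = read_expression(expr_path)
        metadata = read_metadata(md_path)
        qc = read_qc_metrics(qc_path)
        manifest["inputs"]["expression"] = _sha256(expr_path)
        manifest["inputs"]["metadata"] = _sha256(md_path)
        manifest["inputs"]["qc"] = _sha256(qc_path)
    manifest["counts"]["samples"] = int(expression.data.shape[1])
    manifest["counts"]["genes"] = int(expression.data.shape[0])

    # --- stage: QC filtering ----------------------------------------------
    qc_thresholds = preprocess.QCThresholds(**config.get("qc_thresholds", {}))
    qc_result = qc_filter_and_log(qc, qc_thresholds, warnings_list)
    keep = set(qc_result.loc[qc_result["qc_pass"], "sample_id"])
    expression = expression.subset_samples([s for s in expression.samples if s in keep])
    metadata = metadata[metadata["sample_id"].isin(keep)].reset_index(drop=True)
    qc_result.to_csv(out_dir / "qc_filter.tsv", sep="\t", index=False)
    manifest["counts"]["samples_failed_qc"] = int((~qc_result["qc_pass"]).sum())

    # --- stage: normalization ----------------------------------------------
    if expression.scale == "counts":
        expression = preprocess.log_transform(preprocess.normalize_rpm(expression))
    elif expression.scale == "rpm":
        expression = preprocess.log_transform(expression)

    # --- stage: replicate outliers ------------------------------------------
    outliers = preprocess.flag_outliers(expression, metadata, min_median_corr=min_median_corr)
    flagged = sorted(outliers.index[outliers])
    if flagged:
        warnings_list.append(f"replicate outliers removed: {flagged}")
    expression = expression.subset_samples([s for s in expression.samples if s not in set(flagged)])
    metadata = metadata[~metadata["sample_id"].isin(flagged)].reset_index(drop=True)
    manifest["counts"]["samples_flagged_outlier"] = int(len(flagged))
    write_expression(expression, out_dir / "expression_log2.tsv")

    # --- stage: differential expression --------------------------------------
    fc_table = diffexpr.build_fc_table(expression, metadata)
    fc_out = fc_table.copy()
    fc_out.to_csv(out_dir / "fc_table.tsv", sep="\t", index=False, float_format="%.6f")
    manifest["counts"]["fc_records"] = int(len(fc_table))

    # --- stage: MIE network --------------------------------------------------
    network = regulon.build_mie_network(edges, mies, expression.genes)
    network.counts.reset_index().to_csv(out_dir / "mie_counts.tsv", sep="\t", index=False)
    zero = [m for m in network.counts.index if network.counts.at[m, "n_targets"] == 0]
    if zero:
        warnings_list.append(f"MIEs without regulon targets: {zero}")

    # --- stage: dysregulation profile ----------------------------------------
    profile = profiling.profile_conditions(fc_table, network, up_thr=up_thr, down_thr=down_thr)
    profiling.write_profile(profile, out_dir / "profile_long.tsv")
    view = profiling.top_dose_view(profile, k=top_k)
    view.to_csv(out_dir / "profile_table.tsv", sep="\t")
    manifest["counts"]["profile_rows"] = int(len(profile))

    # --- stage: response classification --------------------------------------
    calls = classify_mod.classify_table(
        fc_table,
        threshold=up_thr,
        min_support=min_support,
        trend_threshold=up_thr,
        trend_window=trend_window,
    )
    calls.to_csv(out_dir / "response_calls.tsv", sep="\t", index=False)
    manifest["counts"]["response_calls"] = int(len(calls))

    # --- stage: signature concordance ----------------------------------------
    signature_rel = config["inputs"].get("signature")
    if signature_rel:
        signature_path = _resolve(config, signature_rel)
        signature = classify_mod.read_signature(signature_path)
        manifest["inputs"]["signature"] = _sha256(signature_path)
        frames = []
        for (chem, sex), dose in _top_conditions(fc_table):
            conc = classify_mod.signature_concordance(
                fc_table, signature, (chem, dose, sex), q_threshold=q_thr
            )
            conc.insert(0, "chemical", chem)
            conc.insert(1, "dose_mg_per_kg", dose)
            conc.insert(2, "sex", sex)
            frames.append(conc)
        concordance = pd.concat(frames, ignore_index=True)
        concordance.to_csv(out_dir / "concordance.tsv", sep="\t", index=False, float_format="%.6f")
        manifest["counts"]["concordance_rows"] = int(len(concordance))

    # --- stage: network exports ----------------------------------------------
    for (chem, sex), dose in _top_conditions(fc_table):
        sub = fc_table[
            (fc_table["chemical"] == chem)
            & (fc_table["dose_mg_per_kg"] == dose)
            & (fc_table["sex"] == sex)
        ]
        fc = sub.set_index("gene")["log2fc"]
        regulon.export_network(
            network, fc, out_dir, out_format="sif",
            prefix=f"network_{_slug(chem)}_{sex}", up_thr=up_thr, down_thr=down_thr,
        )

    # --- stage: heatmap matrices ----------------------------------------------
    ladder = {
        chem: sorted(grp["dose_mg_per_kg"].unique())
        for chem, grp in fc_table.groupby("chemical", sort=True)
    }
    heat_genes = [g for g in network.mapped_targets() if g in set(fc_table["gene"])]
    for sex in sorted(fc_table["sex"].unique()):
        conditions = [
            (chem, dose, sex) for chem in sorted(ladder) for dose in ladder[chem]
        ]
        matrix, skipped = render_heatmap_matrix(fc_table, heat_genes, conditions)
        matrix.round(6).to_csv(out_dir / f"heatmap_{sex}.tsv", sep="\t", index_label="gene")
        if skipped:
            warnings_list.append(f"heatmap ({sex}): skipped genes {skipped}")


def _top_conditions(fc_table: pd.DataFrame):
    top = fc_table.groupby(["chemical", "sex"])["dose_mg_per_kg"].max().sort_index()
    return list(top.items())


def qc_filter_and_log(qc, thresholds, warnings_list) -> pd.DataFrame:
    result = preprocess.qc_filter(qc, thresholds)
    for sample_id, rules in result.loc[~result["qc_pass"], ["sample_id", "failed_rules"]].itertuples(
        index=False, name=None
    ):
        warnings_list.append(f"sample {sample_id} failed QC: {rules}")
    return result
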