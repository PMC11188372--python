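"""MIE regulon handling: TRRUST-dialect edge tables, cross-species symbol
mapping, MIE -> target network construction and SIF/GraphML export.

An MIE (molecular initiating event) is named by the gene symbol of the
transcription factor it corresponds to; matching against the edge table is
case-insensitive exact symbol match, so alias reconciliation (e.g. GR vs
NR3C1) is the responsibility of the supplied MIE list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

EDGE_MODES = ("Activation", "Repression", "Unknown")
MIE_SOURCES = ("target_prediction", "aop_database", "literature_review")


@dataclass(frozen=True)
class MIE:
    name: str
    sources: frozenset = frozenset({"literature_review"})

    def __post_init__(self):
        if not self.name:
            raise ValueError("MIE name must be non-empty")
        if not self.sources:
            raise ValueError(f"MIE {self.name}: sources must be non-empty")


@dataclass
class MIENetwork:
    """MIE -> target edges plus per-MIE target and mapped-target counts."""

    mies: list
    edges: pd.DataFrame            # columns: mie, target, mode
    counts: pd.DataFrame           # index: mie; columns: n_targets, n_mapped

    def targets_of(self, mie_name: str) -> list:
        return sorted(set(self.edges.loc[self.edges["mie"] == mie_name, "target"]))

    def mapped_targets(self) -> list:
        return sorted(set(self.edges["target"]))


def read_regulatory_table(path) -> pd.DataFrame:
    """Parse a TRRUST-dialect table: TF <tab> target <tab> mode <tab> references.

    Exact duplicate (tf, target, mode) rows are collapsed; (tf, target) pairs
    carrying conflicting modes are collapsed to a single edge with mode
    ``Unknown`` and a warning is logged.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            tf, target, mode = fields[0].strip(), fields[1].strip(), fields[2].strip()
            references = "\t".join(fields[3:]).strip()
            if not tf or not target:
                raise ValueError(f"{path}: line {lineno}: empty TF or target symbol")
            if mode not in EDGE_MODES:
                raise ValueError(
                    f"{path}: line {lineno}: unknown interaction mode {mode!r} "
                    f"(expected one of {EDGE_MODES})"
                )
            rows.append((tf, target, mode, references))
    edges = pd.DataFrame(rows, columns=["tf", "target", "mode", "references"])
    edges = edges.drop_duplicates(subset=["tf", "target", "mode"], keep="first")
    return _collapse_conflicts(edges)


def _collapse_conflicts(edges: pd.DataFrame) -> pd.DataFrame:
    out = []
    for (tf, target), grp in edges.groupby(["tf", "target"], sort=False):
        modes = set(grp["mode"])
        if len(modes) > 1:
            logger.warning(
                "conflicting regulation modes for (%s, %s): %s -> collapsed to Unknown",
                tf, target, sorted(modes),
            )
            out.append((tf, target, "Unknown", ";".join(grp["references"])))
        else:
            row = grp.iloc[0]
            out.append((tf, target, row["mode"], row["references"]))
    return pd.DataFrame(out, columns=["tf", "target", "mode", "references"])


def read_symbol_map(path) -> dict:
    """Read a symbol mapping TSV (source_symbol, destination_symbol; one row per pair)."""
    df = pd.read_csv(path, sep="\t")
    if not {"source_symbol", "destination_symbol"} <= set(df.columns):
        raise ValueError(f"{path}: mapping must have source_symbol and destination_symbol columns")
    mapping: dict = {}
    for src, dst in df[["source_symbol", "destination_symbol"]].itertuples(index=False, name=None):
        mapping.setdefault(str(src), []).append(str(dst))
    return mapping


def map_symbols(edges: pd.DataFrame, mapping: Optional[Mapping[str, Sequence[str]]] = None):
    """Convert TF and target symbols using a source -> destinations mapping.

    Symbols without a mapping entry fall back to title-case conversion
    (ABCC3 -> Abcc3), emulating human-to-rodent symbol style; they are listed
    in the report as fallback-mapped. One-to-many entries produce one edge
    per destination and are listed as one-to-many.

    Returns ``(mapped_edges, report)`` where report has keys
    ``fallback_mapped`` and ``one_to_many`` (sorted source symbols).
    """
    mapping = dict(mapping or {})
    fallback: set = set()
    one_to_many: set = set()

    def convert(symbol: str) -> list:
        if symbol in mapping:
            dests = [str(d) for d in mapping[symbol]]
            if len(dests) > 1:
                one_to_many.add(symbol)
            return dests
        converted = symbol.capitalize()
        fallback.add(symbol)
        return [converted]

    rows = []
    for tf, target, mode, references in edges[["tf", "target", "mode", "references"]].itertuples(
        index=False, name=None
    ):
        for new_tf in convert(tf):
            for new_target in convert(target):
                rows.append((new_tf, new_target, mode, references))
    mapped = pd.DataFrame(rows, columns=["tf", "target", "mode", "references"])
    mapped = mapped.drop_duplicates(subset=["tf", "target", "mode"], keep="first")
    mapped = _collapse_conflicts(mapped)
    report = {"fallback_mapped": sorted(fallback), "one_to_many": sorted(one_to_many)}
    return mapped, report


def read_mie_list(path) -> list:
    """Read an MIE list TSV with columns ``name`` and ``sources`` (comma-separated)."""
    df = pd.read_csv(path, sep="\t")
    if "name" not in df.columns:
        raise ValueError(f"{path}: MIE list must have a name column")
    mies = []
    for row in df.itertuples(index=False):
        sources = getattr(row, "sources", "literature_review")
        mies.append(MIE(str(row.name), frozenset(str(sources).split(","))))
    return mies


def build_mie_network(
    edges: pd.DataFrame, mies: Sequence[MIE], expression_genes: Sequence[str]
) -> MIENetwork:
    """Restrict the edge table to MIE transcription factors and count targets.

    MIE names match TF symbols case-insensitively. MIEs without any edge are
    retained with zero counts (a warning is logged); ``n_mapped`` counts the
    MIE's distinct targets present in the expression gene set.
    """
    expression_genes = set(expression_genes)
    by_lower = {}
    for mie in mies:
        by_lower[mie.name.lower()] = mie.name
    tf_lower = edges["tf"].str.lower()
    keep = tf_lower.isin(by_lower)
    sub = edges.loc[keep, ["tf", "target", "mode"]].copy()
    sub["mie"] = tf_lower[keep].map(by_lower)
    net_edges = sub[["mie", "target", "mode"]].reset_index(drop=True)

    count_rows = []
    for mie in mies:
        targets = set(net_edges.loc[net_edges["mie"] == mie.name, "target"])
        if not targets:
            logger.warning("MIE %s has no targets in the regulatory table", mie.name)
        count_rows.append((mie.name, len(targets), len(targets & expression_genes)))
    counts = pd.DataFrame(count_rows, columns=["mie", "n_targets", "n_mapped"]).set_index("mie")
    return MIENetwork(list(mies), net_edges, counts)


def node_attributes(
    network: MIENetwork,
    fc: Mapping[str, float],
    up_thr: float = 0.6,
    down_thr: float = -0.6,
) -> pd.DataFrame:
    """Per-node attribute table: log2fc, sign class and dysregulation class.

    Sign class is ``down`` for fc < 0, ``up`` for fc > 0 and ``neutral`` at
    exactly 0 or when the gene is missing from ``fc``; the dysregulation
    class applies the inclusive +-0.6 thresholds.
    """
    rows = []
    for mie in network.counts.index:
        rows.append((mie, "MIE", float("nan"), "neutral", "none"))
    for gene in network.mapped_targets():
        value = fc.get(gene) if hasattr(fc, "get") else None
        if value is None or pd.isna(value):
            rows.append((gene, "target", float("nan"), "neutral", "none"))
            continue
        sign = "up" if value > 0 else ("down" if value < 0 else "neutral")
        dysreg = "up" if value >= up_thr else ("down" if value <= down_thr else "none")
        rows.append((gene, "target", float(value), sign, dysreg))
    return pd.DataFrame(rows, columns=["node", "node_type", "log2fc", "sign_class", "dysregulation_class"])


def export_network(
    network: MIENetwork,
    fc: Mapping[str, float],
    out_dir,
    out_format: str = "sif",
    prefix: str = "network",
    up_thr: float = 0.6,
    down_thr: float = -0.6,
) -> dict:
    """Write the MIE network plus a node attribute table.

    ``sif`` writes one ``MIE<TAB>regulates<TAB>target`` line per edge;
    ``graphml`` writes a directed graph carrying the same node attributes.
    """
    if out_format not in ("sif", "graphml"):
        raise ValueError(f"unknown network export format {out_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    attrs = node_attributes(network, fc, up_thr=up_thr, down_thr=down_thr)
    attr_path = out_dir / f"{prefix}_nodes.tsv"
    attrs.to_csv(attr_path, sep="\t", index=False, float_format="%.6f")
    paths = {"nodes": str(attr_path)}

    if out_format == "sif":
        sif_path = out_dir / f"{prefix}.sif"
        with open(sif_path, "w") as fh:
            for mie, target in network.edges[["mie", "target"]].itertuples(index=False, name=None):
                fh.write(f"{mie}\tregulates\t{target}\n")
        paths["network"] = str(sif_path)
    else:
        g = nx.DiGraph()
        attr_by_node = attrs.set_index("node")
        for node, row in attr_by_node.iterrows():
            g.add_node(
                node,
                node_type=row["node_type"],
                log2fc=0.0 if pd.isna(row["log2fc"]) else float(row["log2fc"]),
                sign_class=row["sign_class"],
                dysregulation_class=row["dysregulation_class"],
            )
        for mie, target, mode in network.edges[["mie", "target", "mode"]].itertuples(index=False, name=None):
            g.add_edge(mie, target, interaction="regulates", mode=mode)
        gml_path = out_dir / f"{prefix}.graphml"
        nx.write_graphml(g, gml_path)
        paths["network"] = str(gml_path)
    return paths
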