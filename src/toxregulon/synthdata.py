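"""Synthetic study generator for dose-response liver toxicogenomics.

Emulates the design of a 5-day acute rat exposure study: four chemicals (three
PFAS, one PAH), nine ascending dose levels plus a shared vehicle control per
chemical, both sexes, n = 5 treated animals per (chemical, dose, sex) group and
n = 10 vehicle controls per (chemical, sex). Effects are planted on explicit
gene sets or on the regulon (TRRUST-style target set) of a transcription
factor, scaled along the dose ladder, and optionally restricted by sex or by
chemical class — so every downstream stage (differential expression, MIE
profiling, response classification, dose-trend detection) has exact ground
truth to recover.

Three generators are exposed:

``simulate_regulons``
    a TF -> target edge table in the TRRUST tab-separated dialect;
``simulate_study``
    an expression study (counts or latent log2 values) with metadata, QC
    metrics and a planted-effect truth table;
``simulate_compendium``
    a low-rank reference expression compendium used to train and test the
    principal-component-regression transcriptome extrapolator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, METADATA_COLUMNS, QC_COLUMNS, write_expression, write_table

EDGE_MODES = ("Activation", "Repression", "Unknown")
CHEMICAL_CLASSES = ("PFAS", "PAH")
SEXES = ("female", "male")
DOSE_SHAPES = ("linear_in_log_dose", "hill")

#: the study's dose ladders in mg/kg
DOSE_LADDER_MAIN = (0.15, 0.50, 1.40, 4.0, 12.0, 37.0, 111.0, 333.0, 1000.0)
DOSE_LADDER_LOW = (0.07, 0.20, 0.70, 2.0, 6.0, 18.0, 55.0, 160.0, 475.0)


@dataclass(frozen=True)
class Chemical:
    name: str
    chem_class: str
    doses: tuple

    def __post_init__(self):
        if self.chem_class not in CHEMICAL_CLASSES:
            raise ValueError(f"chemical class must be one of {CHEMICAL_CLASSES}, got {self.chem_class!r}")
        doses = tuple(float(d) for d in self.doses)
        if len(doses) == 0 or any(d <= 0 for d in doses):
            raise ValueError(f"{self.name}: dose ladder must contain positive doses")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError(f"{self.name}: dose ladder must be strictly increasing")
        object.__setattr__(self, "doses", doses)


@dataclass
class StudyDesign:
    """Experimental layout: chemicals with dose ladders, sexes, group sizes, gene count."""

    chemicals: Sequence[Chemical]
    n_treated: int = 5
    n_control: int = 10
    n_genes: int = 17000
    sexes: tuple = SEXES

    def __post_init__(self):
        names = [c.name for c in self.chemicals]
        if len(set(names)) != len(names):
            raise ValueError("chemical names must be unique")
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("n_treated and n_control must each be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    @property
    def n_samples(self) -> int:
        per_chem = sum(len(c.doses) * self.n_treated * len(self.sexes) for c in self.chemicals)
        return per_chem + len(self.chemicals) * self.n_control * len(self.sexes)


def default_design(n_genes: int = 17000) -> StudyDesign:
    """The full study layout: 3 PFAS + 1 PAH, 9 doses each, n=5 vs n=10 controls."""
    return StudyDesign(
        chemicals=[
            Chemical("2,3-Benzofluorene", "PAH", DOSE_LADDER_MAIN),
            Chemical("6:1 FTOH", "PFAS", DOSE_LADDER_MAIN),
            Chemical("10:2 FTOH", "PFAS", DOSE_LADDER_LOW),
            Chemical("PFHxSAm", "PFAS", DOSE_LADDER_MAIN),
        ],
        n_treated=5,
        n_control=10,
        n_genes=n_genes,
    )


@dataclass
class PlantedEffect:
    """One planted perturbation: a gene set pushed up or down along the dose ladder.

    Targets are either explicit gene symbols or the regulon of a TF
    (``tf=...``, optionally capped at ``n_targets`` genes). The effect at dose
    d is ``max_log2fc`` scaled by the dose shape and applied only to samples
    whose sex is in ``sexes`` and whose chemical class is in ``classes``.
    ``sex_directions`` / ``class_directions`` override the direction per sex or
    per class (e.g. up in females, down in males).
    """

    direction: str = "up"
    max_log2fc: float = 1.0
    targets: Optional[Sequence[str]] = None
    tf: Optional[str] = None
    n_targets: Optional[int] = None
    dose_shape: str = "linear_in_log_dose"
    sexes: tuple = SEXES
    classes: tuple = CHEMICAL_CLASSES
    sex_directions: Optional[dict] = None
    class_directions: Optional[dict] = None

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.max_log2fc <= 0:
            raise ValueError("max_log2fc must be > 0")
        if self.dose_shape not in DOSE_SHAPES:
            raise ValueError(f"dose_shape must be one of {DOSE_SHAPES}")
        if (self.targets is None) == (self.tf is None):
            raise ValueError("exactly one of targets= or tf= must be given")

    def resolve_targets(self, regulons: pd.DataFrame) -> list:
        if self.targets is not None:
            return sorted(set(self.targets))
        tfs = set(regulons["tf"]) if len(regulons) else set()
        if self.tf not in tfs:
            raise ValueError(f"unknown TF in planted effect: {self.tf}")
        targets = sorted(set(regulons.loc[regulons["tf"] == self.tf, "target"]))
        if self.n_targets is not None:
            if self.n_targets > len(targets):
                raise ValueError(
                    f"planted effect requests {self.n_targets} targets of {self.tf}, "
                    f"which has only {len(targets)}"
                )
            targets = targets[: self.n_targets]
        return targets

    def signed_direction(self, sex: str, chem_class: str) -> int:
        direction = self.direction
        if self.sex_directions and sex in self.sex_directions:
            direction = self.sex_directions[sex]
        if self.class_directions and chem_class in self.class_directions:
            direction = self.class_directions[chem_class]
        return 1 if direction == "up" else -1


@dataclass
class StudyBundle:
    """A simulated study: expression + metadata + QC + planted-effect truth."""

    expression: ExpressionMatrix
    metadata: pd.DataFrame
    qc: pd.DataFrame
    truth: pd.DataFrame
    design: StudyDesign


@dataclass
class Compendium:
    """Low-rank reference expression compendium (genes x reference samples, log2).

    ``offsets`` and ``loadings`` are the generative parameters (kept so fresh
    samples can be drawn from the same latent model); they are None for
    compendia loaded from disk.
    """

    expression: pd.DataFrame
    measured_genes: list
    latent_rank: int
    noise_sd: float
    offsets: Optional[np.ndarray] = None
    loadings: Optional[np.ndarray] = None

    def draw_samples(self, n: int, noise_sd: Optional[float] = None, seed: int = 0) -> pd.DataFrame:
        """Fresh samples from the same generative model (requires loadings)."""
        if self.loadings is None or self.offsets is None:
            raise ValueError("compendium carries no generative parameters")
        rng = np.random.default_rng(seed)
        sd = self.noise_sd if noise_sd is None else noise_sd
        scores = rng.normal(0.0, 1.0, size=(self.latent_rank, n))
        expr = self.offsets[:, None] + self.loadings @ scores
        if sd > 0:
            expr = expr + rng.normal(0.0, sd, size=expr.shape)
        return pd.DataFrame(expr, index=self.expression.index, columns=[f"new{j + 1:04d}" for j in range(n)])


def dose_effect_scale(dose: float, ladder: Sequence[float], shape: str) -> float:
    """Fractional effect size in [0, 1] at ``dose`` along a ladder.

    ``linear_in_log_dose`` reaches exactly 1 at the top dose;
    ``hill`` saturates with EC50 at the geometric mid-dose.
    """
    d_min, d_max = ladder[0], ladder[-1]
    if shape == "linear_in_log_dose":
        return math.log(dose / d_min + 1.0) / math.log(d_max / d_min + 1.0)
    if shape == "hill":
        ec50 = math.sqrt(d_min * d_max)
        return dose / (dose + ec50)
    raise ValueError(f"unknown dose shape {shape!r}")


def simulate_regulons(
    n_tfs: int,
    targets_per_tf=(5, 50),
    mode_probs=(0.35, 0.25, 0.40),
    overlap_prob: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a TF -> target edge table in the TRRUST tab-separated dialect.

    Each TF receives a target count drawn uniformly from ``targets_per_tf``
    (inclusive range, or a fixed count if both ends are equal); with
    probability ``overlap_prob`` a target is reused from another TF's regulon.
    Edge modes are drawn i.i.d. from ``mode_probs`` over
    (Activation, Repression, Unknown).
    """
    if n_tfs < 1:
        raise ValueError("n_tfs must be >= 1")
    lo, hi = int(targets_per_tf[0]), int(targets_per_tf[1])
    if lo < 1 or hi < lo:
        raise ValueError("targets_per_tf must be a non-empty positive range (lo, hi)")
    probs = np.asarray(mode_probs, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mode_probs must be a 3-simplex over (Activation, Repression, Unknown)")
    if not (0.0 <= overlap_prob <= 1.0):
        raise ValueError("overlap_prob must be a probability")

    rng = np.random.default_rng(seed)
    pool: list = []  # targets already used by some TF
    fresh = 0
    rows = []
    for i in range(n_tfs):
        tf = f"TF{i + 1:03d}"
        k = int(rng.integers(lo, hi + 1))
        chosen: set = set()
        while len(chosen) < k:
            if pool and rng.random() < overlap_prob:
                target = pool[int(rng.integers(len(pool)))]
                if target in chosen:  # retry as a fresh target to guarantee progress
                    fresh += 1
                    target = f"G{fresh:05d}"
            else:
                fresh += 1
                target = f"G{fresh:05d}"
            chosen.add(target)
            mode = EDGE_MODES[int(rng.choice(3, p=probs))]
            rows.append((tf, target, mode, f"SYN:{len(rows) + 1}"))
        pool.extend(sorted(chosen))
    return pd.DataFrame(rows, columns=["tf", "target", "mode", "references"])


def _gene_universe(design: StudyDesign, regulons: pd.DataFrame, effects: Sequence[PlantedEffect]) -> list:
    core: set = set()
    if len(regulons):
        core |= set(regulons["tf"]) | set(regulons["target"])
    for eff in effects:
        if eff.targets is not None:
            core |= set(eff.targets)
    core_genes = sorted(core)
    if len(core_genes) > design.n_genes:
        raise ValueError(
            f"design.n_genes={design.n_genes} is smaller than the {len(core_genes)} "
            "genes referenced by the regulon table and planted effects"
        )
    background = [f"BG{i + 1:05d}" for i in range(design.n_genes - len(core_genes))]
    return core_genes + background


def _build_metadata(design: StudyDesign) -> pd.DataFrame:
    rows = []
    idx = 0
    for chem in design.chemicals:
        for sex in design.sexes:
            for rep in range(1, design.n_control + 1):
                idx += 1
                rows.append((f"s{idx:04d}", chem.name, chem.chem_class, 0.0, sex, rep))
            for dose in chem.doses:
                for rep in range(1, design.n_treated + 1):
                    idx += 1
                    rows.append((f"s{idx:04d}", chem.name, chem.chem_class, dose, sex, rep))
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def simulate_study(
    design: StudyDesign,
    regulons: pd.DataFrame,
    effects: Sequence[PlantedEffect] = (),
    noise_sd: float = 0.5,
    libsize_range=(1_000_000, 3_000_000),
    mode: str = "lognormal",
    qc_fail_fraction: float = 0.0,
    seed: int = 0,
) -> StudyBundle:
    """Simulate an exposure study with planted regulon-level effects.

    Per-sample latent log2 expression = per-gene baseline + planted effect
    (scaled by the dose shape at that sample's dose, applied only to matching
    sex/class) + Normal(0, noise_sd) noise. In ``counts`` mode the latent
    values are converted to expected per-gene read fractions and Poisson
    counts are drawn at a library size sampled uniformly from
    ``libsize_range``; in ``lognormal`` mode the latent log2 matrix is
    returned directly.

    The returned truth table lists the exact planted mean log2 effect for
    every planted (gene, chemical, dose, sex) combination; all combinations
    absent from the table carry effect 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if mode not in ("counts", "lognormal"):
        raise ValueError("mode must be 'counts' or 'lognormal'")
    if not (0.0 <= qc_fail_fraction <= 1.0):
        raise ValueError("qc_fail_fraction must be a probability")

    rng = np.random.default_rng(seed)
    genes = _gene_universe(design, regulons, effects)
    metadata = _build_metadata(design)
    n_genes, n_samples = len(genes), len(metadata)
    gene_pos = {g: i for i, g in enumerate(genes)}
    class_of = {c.name: c.chem_class for c in design.chemicals}
    ladder_of = {c.name: c.doses for c in design.chemicals}

    # accumulate planted effects per (gene, chemical, dose, sex)
    planted: dict = {}
    for eff in effects:
        targets = eff.resolve_targets(regulons)
        for gene in targets:
            if gene not in gene_pos:
                raise ValueError(f"planted effect target {gene!r} is not in the gene universe")
        for chem in design.chemicals:
            if chem.chem_class not in eff.classes:
                continue
            for sex in design.sexes:
                if sex not in eff.sexes:
                    continue
                sign = eff.signed_direction(sex, chem.chem_class)
                for dose in chem.doses:
                    scale = dose_effect_scale(dose, chem.doses, eff.dose_shape)
                    value = sign * eff.max_log2fc * scale
                    for gene in targets:
                        key = (gene, chem.name, dose, sex)
                        planted[key] = planted.get(key, 0.0) + value

    truth = pd.DataFrame(
        [(g, c, d, s, e) for (g, c, d, s), e in sorted(planted.items())],
        columns=["gene", "chemical", "dose_mg_per_kg", "sex", "effect"],
    )

    baseline = np.clip(rng.normal(6.0, 2.0, size=n_genes), 0.5, 14.0)
    latent = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    if planted:
        effect_cols: dict = {}
        for (gene, chem, dose, sex), value in planted.items():
            effect_cols.setdefault((chem, dose, sex), {})[gene] = value
        for j, row in enumerate(metadata.itertuples(index=False)):
            key = (row.chemical, row.dose_mg_per_kg, row.sex)
            if key in effect_cols:
                for gene, value in effect_cols[key].items():
                    latent[gene_pos[gene], j] += value

    sample_ids = metadata["sample_id"].tolist()
    if mode == "counts":
        lo, hi = int(libsize_range[0]), int(libsize_range[1])
        if lo < 1 or hi < lo:
            raise ValueError("libsize_range must be a positive range (lo, hi)")
        intensity = np.maximum(np.exp2(latent) - 1.0, 0.0)
        libsizes = rng.integers(lo, hi + 1, size=n_samples)
        expected = intensity / intensity.sum(axis=0, keepdims=True) * libsizes[None, :]
        counts = rng.poisson(expected)
        expression = ExpressionMatrix(
            pd.DataFrame(counts, index=genes, columns=sample_ids), "counts"
        )
        depth = counts.sum(axis=0)
    else:
        expression = ExpressionMatrix(
            pd.DataFrame(latent, index=genes, columns=sample_ids), "log2"
        )
        depth = rng.integers(int(libsize_range[0]), int(libsize_range[1]) + 1, size=n_samples)

    qc = _simulate_qc(rng, sample_ids, depth, qc_fail_fraction)
    return StudyBundle(expression, metadata, qc, truth, design)


def _simulate_qc(rng, sample_ids, depth, qc_fail_fraction: float) -> pd.DataFrame:
    n = len(sample_ids)
    total = rng.uniform(75.0, 95.0, size=n)
    unique = rng.uniform(55.0, 85.0, size=n)
    probes = rng.uniform(65.0, 95.0, size=n)
    qc = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sequencing_depth": np.asarray(depth, dtype=int),
            "total_alignment_rate": total,
            "unique_alignment_rate": unique,
            "aligned_reads": (np.asarray(depth, float) * total / 100.0).astype(int),
            "pct_probes_ge5": probes,
        }
    )
    n_fail = int(round(qc_fail_fraction * n))
    if n_fail:
        # push one metric clearly below its default threshold
        failing_values = {
            "sequencing_depth": 150_000,
            "total_alignment_rate": 20.0,
            "unique_alignment_rate": 15.0,
            "aligned_reads": 150_000,
            "pct_probes_ge5": 25.0,
        }
        victims = rng.choice(n, size=n_fail, replace=False)
        for v in victims:
            metric = QC_COLUMNS[int(rng.integers(len(QC_COLUMNS)))]
            qc.loc[v, metric] = failing_values[metric]
    return qc


def simulate_compendium(
    n_reference_samples: int,
    n_genes: int,
    latent_rank: int,
    measured_fraction: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Compendium:
    """Generate a low-rank reference compendium for extrapolator training.

    expression = gene offsets + loadings (genes x rank) @ scores
    (rank x samples) + Normal(0, noise_sd) noise; a ``measured_fraction``
    subset of genes is marked as the measured (sentinel) panel.
    """
    if n_reference_samples < 1 or n_genes < 1:
        raise ValueError("n_reference_samples and n_genes must be positive")
    if latent_rank < 1 or latent_rank > min(n_reference_samples, n_genes):
        raise ValueError(
            f"latent_rank={latent_rank} must be in [1, min(n_genes, n_reference_samples)]"
        )
    if not (0.0 < measured_fraction <= 1.0):
        raise ValueError("measured_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"ref{j + 1:04d}" for j in range(n_reference_samples)]
    offsets = rng.normal(6.0, 1.0, size=n_genes)
    loadings = rng.normal(0.0, 1.0, size=(n_genes, latent_rank))
    scores = rng.normal(0.0, 1.0, size=(latent_rank, n_reference_samples))
    expr = offsets[:, None] + loadings @ scores
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    n_measured = max(1, int(round(measured_fraction * n_genes)))
    if measured_fraction == 1.0:
        measured = list(genes)
    else:
        measured = sorted(rng.choice(genes, size=n_measured, replace=False).tolist())
    return Compendium(
        pd.DataFrame(expr, index=genes, columns=samples),
        measured,
        latent_rank,
        noise_sd,
        offsets=offsets,
        loadings=loadings,
    )


# ---------------------------------------------------------------------------
# writers

def write_regulons(regulons: pd.DataFrame, path) -> None:
    """Write an edge table in the TRRUST dialect (4 tab-separated columns, no header)."""
    regulons[["tf", "target", "mode", "references"]].to_csv(path, sep="\t", index=False, header=False)


def write_study_bundle(bundle: StudyBundle, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "metadata": out_dir / "metadata.tsv",
        "qc": out_dir / "qc.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression(bundle.expression, paths["expression"])
    write_table(bundle.metadata, paths["metadata"])
    write_table(bundle.qc, paths["qc"])
    write_table(bundle.truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
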