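"""Synthetic study-bundle generator.

Emulates the statistical structure the downstream analysis assumes: several
batches of log-scale expression matrices with per-batch location/scale effects,
sample groups drawn from {control, STEMI, NSTEMI, day7, day30, MI}, a small set
of planted high/low-fold genes with known additive effects and i.i.d. Gaussian
noise, plus literature report-count, disease-gene-score, interaction-edge and
gene-set fixtures that are coupled (by construction) to the planted truth.

The generative model for one matrix entry is

    value = scale_b * (baseline_mean + shift_b + effect(gene, group) + noise)

with shift_b ~ Normal(0, batch_shift_sd), scale_b ~ Uniform(batch_scale_range)
per batch, noise ~ Normal(0, noise_sd) i.i.d. Expression is additive
(log2-like), so group effects are additive fold differences.

One global integer seed drives a splittable RNG (numpy SeedSequence); every
sub-generator derives a child seed, so sub-components are reproducible in
isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import (
    EdgeList,
    ExpressionDataset,
    GeneSetCollection,
    write_edge_tsv,
    write_evidence_tsv,
    write_expression_tsv,
    write_gmt,
)

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "StudyBundle",
    "generate_expression_dataset",
    "generate_study_bundle",
    "write_bundle",
    "default_bundle_config",
]


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted effect: gene, group, additive effect."""

    gene: str
    group: str
    effect: float


@dataclass
class SynthConfig:
    """Parameters of one synthetic expression dataset.

    planted entries are (gene index < n_genes, group name, additive effect in
    expression units).
    """

    n_genes: int = 2000
    groups: dict[str, int] = field(default_factory=lambda: {"control": 10, "STEMI": 10, "NSTEMI": 10})
    n_batches: int = 1
    batch_shift_sd: float = 0.0
    batch_scale_range: tuple[float, float] = (1.0, 1.0)
    noise_sd: float = 0.3
    planted: list[tuple[int, str, float]] = field(default_factory=list)
    baseline_mean: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if "control" not in self.groups:
            raise ValueError("groups must include 'control'")
        for g, n in self.groups.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples, got {n}")
        if self.n_batches <= 0:
            raise ValueError("n_batches must be positive")
        lo, hi = self.batch_scale_range
        if not (0 < lo <= hi):
            raise ValueError("batch_scale_range lower bound must be > 0 and <= upper")
        for value, name in [
            (self.batch_shift_sd, "batch_shift_sd"),
            (self.noise_sd, "noise_sd"),
            (self.baseline_mean, "baseline_mean"),
        ]:
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite")
        if self.batch_shift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for idx, group, effect in self.planted:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"planted gene index {idx} out of range")
            if group not in self.groups:
                raise ValueError(f"planted group {group!r} not generated")
            if not math.isfinite(effect):
                raise ValueError("planted effect must be finite")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_expression_dataset(
    config: SynthConfig,
    name: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionDataset, list[TruthRecord]]:
    """Draw one expression dataset from the location-scale Gaussian model.

    Deterministic for a fixed config (including seed). Returns the dataset and
    one TruthRecord per planted (gene, group) effect.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = _gene_names(config.n_genes)

    sample_ids, sample_groups, sample_batches = [], [], []
    counter = 0
    for group in config.groups:  # insertion order
        for j in range(config.groups[group]):
            sample_ids.append(f"{name}_s{counter:03d}")
            sample_groups.append(group)
            sample_batches.append(str(j % config.n_batches))
            counter += 1

    shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches) \
        if config.batch_shift_sd > 0 else np.zeros(config.n_batches)
    lo, hi = config.batch_scale_range
    scales = rng.uniform(lo, hi, size=config.n_batches) if hi > lo else np.full(config.n_batches, lo)

    effect = np.zeros((config.n_genes, len(sample_ids)))
    truth: list[TruthRecord] = []
    seen: set[tuple[int, str]] = set()
    for idx, group, delta in config.planted:
        if (idx, group) in seen:
            raise ValueError(f"duplicate planted effect for gene {idx}, group {group!r}")
        seen.add((idx, group))
        cols = [j for j, g in enumerate(sample_groups) if g == group]
        effect[idx, cols] += delta
        truth.append(TruthRecord(genes[idx], group, float(delta)))

    noise = rng.normal(0.0, config.noise_sd, size=effect.shape) \
        if config.noise_sd > 0 else np.zeros_like(effect)
    batch_idx = np.array([int(b) for b in sample_batches])
    matrix = (config.baseline_mean + shifts[batch_idx][None, :] + effect + noise)
    matrix = matrix * scales[batch_idx][None, :]

    values = pd.DataFrame(matrix, index=pd.Index(genes, name="gene"), columns=sample_ids)
    ds = ExpressionDataset(
        values,
        groups=pd.Series(sample_groups, index=sample_ids),
        batches=pd.Series(sample_batches, index=sample_ids),
        name=name,
    )
    return ds, truth


@dataclass
class StudyBundle:
    """A full synthetic study: acute and follow-up expression datasets, three
    enrichment datasets, evidence tables, interaction edges, gene sets, truth.
    """

    acute: ExpressionDataset
    followup: ExpressionDataset
    enrichment: list[ExpressionDataset]
    report_counts: pd.Series
    disgenet: pd.Series
    edges: EdgeList
    gene_sets: GeneSetCollection
    truth: list[TruthRecord]

    def datasets(self) -> list[ExpressionDataset]:
        return [self.acute, self.followup, *self.enrichment]


def default_bundle_config(seed: int = 0) -> SynthConfig:
    """Study-scale defaults: 2000 genes, 10 samples/group, batch shifts of
    2 expression units between source datasets, noise SD 0.3, and planted
    effects of +/-1.0 (>= 3x noise SD) in STEMI and NSTEMI.
    """
    planted = []
    # 8 high-fold and 4 low-fold genes per acute condition, disjoint blocks
    for i in range(8):
        planted.append((i, "STEMI", 1.0))
        planted.append((20 + i, "NSTEMI", 1.0))
    for i in range(4):
        planted.append((10 + i, "STEMI", -1.0))
        planted.append((30 + i, "NSTEMI", -1.0))
    # persistent (but attenuated) signal at day 7 / day 30 for cut-off work
    for i in range(8):
        planted.append((i, "day7", 0.5))
        planted.append((i, "day30", 0.45))
        planted.append((20 + i, "day7", 0.5))
        planted.append((20 + i, "day30", 0.45))
    for i in range(8):
        planted.append((i, "MI", 1.0))
        planted.append((20 + i, "MI", 1.0))
    return SynthConfig(
        n_genes=2000,
        groups={
            "control": 10, "STEMI": 10, "NSTEMI": 10,
            "day7": 10, "day30": 10, "MI": 10,
        },
        n_batches=1,
        batch_shift_sd=2.0,
        batch_scale_range=(1.0, 1.0),
        noise_sd=0.3,
        planted=planted,
        baseline_mean=8.0,
        seed=seed,
    )


def generate_study_bundle(
    config: SynthConfig | None = None,
    seed: int | None = None,
    evidence_coupling: float = 0.8,
    edge_coupling: float = 0.8,
    evidence_background: float = 0.05,
) -> StudyBundle:
    """Generate the five-dataset study design plus evidence fixtures.

    The acute dataset carries control/STEMI/NSTEMI samples, the follow-up
    dataset control/day7/day30, and the three enrichment datasets control/MI.
    Each dataset is drawn with its own batch location/scale effect so that the
    merge step has genuine batch structure to remove. Report counts and
    DisGeNET scores are positively correlated with planted-effect magnitude for
    ``evidence_coupling`` of the planted genes; the edge list connects
    ``edge_coupling`` of the planted genes.
    """
    if config is None:
        config = default_bundle_config(seed if seed is not None else 0)
    config.validate()
    for grp in ("STEMI", "NSTEMI"):
        if grp not in config.groups:
            raise ValueError(f"study bundle requires acute group {grp!r}")
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(8)

    def sub_config(groups: dict[str, int], planted_groups: set[str]) -> SynthConfig:
        return SynthConfig(
            n_genes=config.n_genes,
            groups=groups,
            n_batches=1,
            batch_shift_sd=config.batch_shift_sd,
            batch_scale_range=config.batch_scale_range,
            noise_sd=config.noise_sd,
            planted=[p for p in config.planted if p[1] in planted_groups],
            baseline_mean=config.baseline_mean,
            seed=config.seed,
        )

    nc = config.groups["control"]
    acute, truth_a = generate_expression_dataset(
        sub_config({"control": nc, "STEMI": config.groups["STEMI"],
                    "NSTEMI": config.groups["NSTEMI"]}, {"STEMI", "NSTEMI"}),
        name="acute", rng=np.random.default_rng(children[0]),
    )
    fu_groups = {"control": nc}
    for g in ("day7", "day30"):
        fu_groups[g] = config.groups.get(g, nc)
    followup, truth_f = generate_expression_dataset(
        sub_config(fu_groups, {"day7", "day30"}),
        name="followup", rng=np.random.default_rng(children[1]),
    )
    n_mi = config.groups.get("MI", nc)
    enrichment = []
    for k in range(3):
        ds, _ = generate_expression_dataset(
            sub_config({"control": nc, "MI": n_mi}, {"MI"}),
            name=f"enrich{k + 1}", rng=np.random.default_rng(children[2 + k]),
        )
        enrichment.append(ds)

    truth = truth_a + truth_f
    genes = list(acute.genes)
    planted_acute = sorted({t.gene for t in truth_a})
    effect_by_gene: dict[str, float] = {}
    for t in truth_a:
        effect_by_gene[t.gene] = max(effect_by_gene.get(t.gene, 0.0), abs(t.effect))

    ev_rng = np.random.default_rng(children[5])
    n_background = max(1, int(evidence_background * len(genes)))
    background = list(ev_rng.choice(
        [g for g in genes if g not in effect_by_gene], size=n_background, replace=False))
    coupled = [g for g in planted_acute if ev_rng.random() < evidence_coupling]
    counts: dict[str, float] = {g: float(ev_rng.poisson(2.0)) for g in background}
    scores: dict[str, float] = {g: float(ev_rng.uniform(0.0, 0.3)) for g in background}
    for g in coupled:
        mag = effect_by_gene[g]
        counts[g] = float(ev_rng.poisson(2.0) + round(10.0 * mag))
        scores[g] = float(min(1.0, 0.3 + 0.15 * mag + ev_rng.uniform(0.0, 0.2)))
    report_counts = pd.Series(counts, name="reports").sort_index()
    disgenet = pd.Series(scores, name="score").sort_index()

    edge_rng = np.random.default_rng(children[6])
    rows = []
    linked = [g for g in planted_acute if edge_rng.random() < edge_coupling]
    for i in range(len(linked) - 1):
        rows.append((linked[i], linked[i + 1], float(edge_rng.uniform(0.4, 1.0))))
    others = [g for g in genes if g not in effect_by_gene]
    for _ in range(5 * len(planted_acute)):
        a, b = edge_rng.choice(len(others), size=2, replace=False)
        rows.append((others[a], others[b], float(edge_rng.uniform(0.1, 1.0))))
    if linked and others:
        for g in linked[: max(1, len(linked) // 2)]:
            partner = others[int(edge_rng.integers(len(others)))]
            rows.append((g, partner, float(edge_rng.uniform(0.2, 0.8))))
    edges = EdgeList(pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]))

    set_rng = np.random.default_rng(children[7])
    sets: dict[str, frozenset[str]] = {}
    if planted_acute:
        sets["PLANTED_RESPONSE"] = frozenset(planted_acute)
    for k in range(4):
        members = set_rng.choice(len(genes), size=25, replace=False)
        sets[f"RANDOM_SET_{k + 1}"] = frozenset(genes[i] for i in members)
    gene_sets = GeneSetCollection(sets, {name: "synthetic gene set" for name in sets})

    return StudyBundle(
        acute=acute, followup=followup, enrichment=enrichment,
        report_counts=report_counts, disgenet=disgenet,
        edges=edges, gene_sets=gene_sets, truth=truth,
    )


def write_bundle(bundle: StudyBundle, outdir) -> dict[str, str]:
    """Write every bundle component as plain text under ``outdir``.

    Returns a manifest of logical name -> file path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for ds in bundle.datasets():
        data = outdir / f"{ds.name}.tsv"
        meta = outdir / f"{ds.name}.meta.tsv"
        write_expression_tsv(ds, data, meta)
        manifest[ds.name] = str(data)
        manifest[f"{ds.name}.meta"] = str(meta)
    write_evidence_tsv(bundle.report_counts, outdir / "report_counts.tsv", "reports")
    write_evidence_tsv(bundle.disgenet, outdir / "disgenet.tsv", "score")
    write_edge_tsv(bundle.edges, outdir / "edges.tsv")
    write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    truth = pd.DataFrame(
        [(t.gene, t.group, t.effect) for t in bundle.truth],
        columns=["gene", "group", "effect"],
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    manifest.update(
        report_counts=str(outdir / "report_counts.tsv"),
        disgenet=str(outdir / "disgenet.tsv"),
        edges=str(outdir / "edges.tsv"),
        gene_sets=str(outdir / "gene_sets.gmt"),
        truth=str(outdir / "truth.tsv"),
    )
    return manifest
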