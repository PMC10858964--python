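"""End-to-end orchestration: merge -> batch correction -> folds -> scores ->
percentile selection -> profiles -> network + enrichment -> time cut-off.

Every stage writes its outputs as TSV/JSON under the configured output
directory, and the run manifest records the seed, thresholds, package versions
and a SHA-256 checksum of every output so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .batch_integrate import correct_batch, merge_datasets
from .expression_io import (
    read_edge_tsv,
    read_evidence_tsv,
    read_expression_tsv,
    read_gmt,
    write_expression_tsv,
)
from .fold_scores import (
    centile_filter,
    expression_score,
    experiment_score,
    final_score,
    gene_fold,
    select_percentile_genes,
)
from .network_enrich import build_network, ora_enrich
from .profiles import heatmap_matrix, select_profile, sub_profile_by_fold
from .time_cutoff import SigmaConfig, find_cutoff, profile_stability_test

logger = logging.getLogger(__name__)

STAGES = [
    "merge", "correct", "folds", "scores",
    "selection", "profiles", "network", "cutoff",
]

ACUTE_GROUPS = ("STEMI", "NSTEMI")
FOLLOWUP_GROUPS = ("day7", "day30")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and provenance."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and QC parameters for one pipeline run."""

    primary: list[dict]            # [{data, meta}, ...] acute + follow-up
    enrichment: list[dict]         # [{data, meta}, ...]
    reports: str
    disgenet: str
    edges: str
    gene_sets: str
    outdir: str
    hi_pct: float = 99.5
    lo_pct: float = 0.25
    centile: float = 25.0
    score_thresholds: dict[str, float] = field(
        default_factory=lambda: {"STEMI": 12.0, "NSTEMI": 8.0}
    )
    fold_subthreshold: float = 0.4
    alpha: float = 0.05
    max_rounds: int = 10
    day_mapping: str = "reported"
    sigma: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if len(self.primary) < 2:
            raise ValueError("need >= 2 primary datasets (acute + follow-up)")
        if not self.enrichment:
            raise ValueError("need >= 1 enrichment dataset")
        if not 0 <= self.lo_pct < self.hi_pct <= 100:
            raise ValueError("percentile thresholds out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: getattr(self, k)
            for k in (
                "primary", "enrichment", "reports", "disgenet", "edges",
                "gene_sets", "outdir", "hi_pct", "lo_pct", "centile",
                "score_thresholds", "fold_subthreshold", "alpha",
                "max_rounds", "day_mapping", "sigma", "seed",
            )
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest.

    Any stage failure raises :class:`PipelineStageError` naming the stage.
    Rerunning with the same config and inputs reproduces byte-identical
    outputs (the manifest checksums match).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "hi_pct": config.hi_pct, "lo_pct": config.lo_pct,
            "centile": config.centile,
            "score_thresholds": dict(config.score_thresholds),
            "fold_subthreshold": config.fold_subthreshold,
            "alpha": config.alpha,
        },
        "stages": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {
            p.name: _sha256(p) for p in paths
        }

    # -- merge ---------------------------------------------------------------
    try:
        sources = [
            read_expression_tsv(entry["data"], entry["meta"])
            for entry in config.primary
        ]
        merged = merge_datasets(sources)
        merged_path = outdir / "merged.tsv"
        write_expression_tsv(merged, merged_path, outdir / "merged.meta.tsv")
        record("merge", merged_path, outdir / "merged.meta.tsv")
    except Exception as exc:
        raise PipelineStageError("merge", str(exc)) from exc

    # -- batch correction ----------------------------------------------------
    try:
        corrected = correct_batch(merged)
        corrected_path = outdir / "corrected.tsv"
        write_expression_tsv(corrected, corrected_path, outdir / "corrected.meta.tsv")
        record("correct", corrected_path, outdir / "corrected.meta.tsv")
    except Exception as exc:
        raise PipelineStageError("correct", str(exc)) from exc

    # -- folds (all contrasts, plus per-dataset enrichment folds) ------------
    try:
        contrasts = [
            g for g in (*ACUTE_GROUPS, *FOLLOWUP_GROUPS)
            if (corrected.groups == g).any()
        ]
        if not contrasts:
            raise ValueError("no case groups present in the merged dataset")
        folds = {g: gene_fold(corrected, g) for g in contrasts}
        fold_table = pd.DataFrame(folds)
        fold_table.index.name = "gene"
        folds_path = outdir / "folds.tsv"
        _write_tsv(fold_table, folds_path)

        enrichment_folds = []
        for entry in config.enrichment:
            ds = read_expression_tsv(entry["data"], entry["meta"])
            case = "MI" if (ds.groups == "MI").any() else \
                next(g for g in ds.groups.unique() if g != "control")
            enrichment_folds.append(gene_fold(ds, case))
        enr_table = pd.concat(enrichment_folds, axis=1, keys=[
            f"enrichment_{i}" for i in range(len(enrichment_folds))
        ])
        enr_table.index.name = "gene"
        enr_path = outdir / "enrichment_folds.tsv"
        _write_tsv(enr_table, enr_path)
        record("folds", folds_path, enr_path)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("folds", str(exc)) from exc

    # -- scores ----------------------------------------------------------------
    try:
        reports = read_evidence_tsv(config.reports)
        disgenet = read_evidence_tsv(config.disgenet)
        exp_scores = experiment_score(reports, disgenet)
        score_tables: dict[str, pd.DataFrame] = {}
        score_paths = []
        for cond in ACUTE_GROUPS:
            if cond not in folds:
                continue
            expr = expression_score(folds[cond], enrichment_folds)
            table = final_score(exp_scores, expr)
            score_tables[cond] = table
            path = outdir / f"scores_{cond}.tsv"
            _write_tsv(table, path)
            score_paths.append(path)
        if not score_tables:
            raise ValueError("no acute contrast available for scoring")
        record("scores", *score_paths)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("scores", str(exc)) from exc

    # -- percentile selection + heatmap matrices -------------------------------
    try:
        selections = {}
        sel_paths = []
        summary = {}
        for cond in score_tables:
            sel = select_percentile_genes(folds[cond], config.hi_pct, config.lo_pct)
            selections[cond] = sel
            others = [folds[g] for g in contrasts if g != cond]
            matrix = heatmap_matrix(sel, [folds[cond], *others])
            path = outdir / f"heatmap_{cond}.tsv"
            _write_tsv(matrix, path)
            sel_paths.append(path)
            summary[cond] = {
                "n_high": len(sel.high), "n_low": len(sel.low),
                "hi_cutoff": sel.hi_cutoff, "lo_cutoff": sel.lo_cutoff,
            }
        sel_json = outdir / "selection.json"
        sel_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
        record("selection", sel_json, *sel_paths)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("selection", str(exc)) from exc

    # -- profiles ---------------------------------------------------------------
    try:
        prof_paths = []
        profiles = {}
        for cond, table in score_tables.items():
            threshold = config.score_thresholds.get(cond, 0.0)
            profile = select_profile(table, threshold, condition=cond)
            profiles[cond] = profile
            out = pd.DataFrame(
                {"final_score": profile.scores,
                 "fold": profile.folds if profile.folds is not None else np.nan}
            )
            out.index.name = "gene"
            path = outdir / f"profile_{cond}.tsv"
            _write_tsv(out, path)
            prof_paths.append(path)
            if cond == "NSTEMI" and len(profile):
                sub = sub_profile_by_fold(profile, config.fold_subthreshold)
                sub_out = pd.DataFrame(
                    {"final_score": sub.scores, "fold": sub.folds}
                )
                sub_out.index.name = "gene"
                sub_path = outdir / f"profile_{cond}_highfold.tsv"
                _write_tsv(sub_out, sub_path)
                prof_paths.append(sub_path)
        record("profiles", *prof_paths)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("profiles", str(exc)) from exc

    # -- network + enrichment ----------------------------------------------------
    try:
        edges = read_edge_tsv(config.edges)
        gene_sets = read_gmt(config.gene_sets)
        universe = list(corrected.genes)
        net_paths = []
        for cond, table in score_tables.items():
            expr_vec = table.loc[table.index.intersection(universe), "expression_score"]
            members = centile_filter(expr_vec, config.centile, side="above")
            net = build_network(table, members, edges, condition=cond)
            nodes = pd.DataFrame(
                {"gene": list(net.nodes),
                 "final_score": [net.nodes[n]["final_score"] for n in net.nodes]}
            ).sort_values("gene")
            net_edges = pd.DataFrame(
                [(a, b, d["weight"]) for a, b, d in net.edges(data=True)],
                columns=["gene_a", "gene_b", "weight"],
            ).sort_values(["gene_a", "gene_b"])
            npath = outdir / f"network_{cond}_nodes.tsv"
            epath = outdir / f"network_{cond}_edges.tsv"
            nodes.to_csv(npath, sep="\t", index=False, float_format="%.10g")
            net_edges.to_csv(epath, sep="\t", index=False, float_format="%.10g")
            enrich = ora_enrich(
                [g for g in members], gene_sets, universe
            ) if members else pd.DataFrame()
            if len(enrich):
                enrich = enrich.copy()
                enrich["genes"] = enrich["genes"].map(",".join)
            apath = outdir / f"enrichment_{cond}.tsv"
            _write_tsv(enrich, apath)
            net_paths.extend([npath, epath, apath])
        record("network", *net_paths)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("network", str(exc)) from exc

    # -- time cut-off -------------------------------------------------------------
    try:
        sigma = SigmaConfig(**config.sigma) if config.sigma else SigmaConfig()
        cut_paths = []
        for cond, profile in profiles.items():
            panel = profile.genes
            if len(panel) < 2 or "day7" not in folds:
                continue
            acute = folds[cond].reindex(panel).to_numpy()
            reference = folds["day7"].reindex(panel).to_numpy()
            case_cols = corrected.samples_in_group(cond)
            sub = corrected.values.loc[panel, case_cols]
            cv = (sub.std(axis=1, ddof=1) / np.sqrt(len(case_cols))).to_numpy()
            result = find_cutoff(
                acute, reference, cv, cfg=sigma, alpha=config.alpha,
                max_rounds=config.max_rounds, day_mapping=config.day_mapping,
            )
            report = {
                "condition": cond,
                "panel": list(panel),
                "k_star": result.k_star,
                "ped_at_cutoff": result.ped_at_cutoff,
                "days": result.days,
                "alpha": result.alpha,
                "direction": result.direction,
                "notes": result.notes,
                "rounds": result.rounds.reset_index().to_dict(orient="records"),
            }
            if "day30" in folds:
                t, p, sig = profile_stability_test(
                    reference, folds["day30"].reindex(panel).to_numpy(),
                    alpha=config.alpha,
                )
                report["followup_stability"] = {"t": t, "p": p, "significant": sig}
            path = outdir / f"cutoff_{cond}.json"
            path.write_text(json.dumps(report, indent=2, sort_keys=True))
            cut_paths.append(path)
        record("cutoff", *cut_paths)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("cutoff", str(exc)) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d stages -> %s", len(manifest["stages"]), outdir)
    return manifest
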