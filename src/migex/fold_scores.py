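"""Per-gene fold statistic, the three-layer evidence-score algebra, and the
percentile/centile selection rules.

The fold for a case group against the control group is

    fold_g = sum(x_case - mean(control)) / n_case
           - sum(x_control - mean(control)) / n_control

evaluated literally; the second term is identically zero when mean(control) is
the mean of the same control samples, so the fold equals mean(case) -
mean(control) on the additive log-like scale.

Score layers (all dimensionless):

* text-mining score   = (report count / max report count) * max DisGeNET score
* experiment score    = DisGeNET score + text-mining score
* expression score    = primary fold + mean of the gene's folds over the
                        enrichment fold tables in which it appears
* final score         = experiment score + expression score

Genes absent from an evidence source contribute 0 from it and are flagged,
never dropped, so the final ranking covers the union universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "gene_fold",
    "experiment_score",
    "expression_score",
    "final_score",
    "select_percentile_genes",
    "centile_filter",
    "HighLowSelection",
]


def gene_fold(
    dataset: ExpressionDataset, case_group: str, control_group: str = "control"
) -> pd.Series:
    """Per-gene fold of ``case_group`` against ``control_group``.

    Returns a Series indexed by gene, named ``"{case}-vs-{control}"``.
    """
    case_cols = dataset.samples_in_group(case_group)
    ctrl_cols = dataset.samples_in_group(control_group)
    if not case_cols:
        raise ValueError(f"group {case_group!r} absent from dataset")
    if not ctrl_cols:
        raise ValueError(f"group {control_group!r} absent from dataset")
    if len(dataset.genes) == 0:
        raise ValueError("empty gene universe")
    for grp, cols in ((case_group, case_cols), (control_group, ctrl_cols)):
        if len(cols) == 1:
            warnings.warn(f"group {grp!r} has a single sample", stacklevel=2)

    case = dataset.values[case_cols].to_numpy(dtype=float)
    ctrl = dataset.values[ctrl_cols].to_numpy(dtype=float)
    mu_ctrl = ctrl.mean(axis=1)
    # literal evaluation of the centred-sum form
    fold = (case - mu_ctrl[:, None]).sum(axis=1) / case.shape[1] \
         - (ctrl - mu_ctrl[:, None]).sum(axis=1) / ctrl.shape[1]
    out = pd.Series(fold, index=dataset.genes, name=f"{case_group}-vs-{control_group}")
    return out


def experiment_score(
    report_counts: pd.Series,
    disgenet: pd.Series,
    normalization: str = "max-count-to-max-score",
) -> pd.DataFrame:
    """Combine literature report counts with DisGeNET scores.

    The text-mining score rescales report frequencies onto the DisGeNET score
    range: count / max(count) * max(DisGeNET score). Returns a DataFrame on the
    union universe with columns ``text_score``, ``disgenet_score``,
    ``experiment_score`` and boolean flags ``missing_reports`` /
    ``missing_disgenet``.
    """
    if normalization != "max-count-to-max-score":
        raise ValueError(f"unknown normalization {normalization!r}")
    if (report_counts < 0).any() or (disgenet < 0).any():
        raise ValueError("evidence values must be non-negative")
    if (disgenet > 1).any():
        raise ValueError("DisGeNET scores must lie in [0, 1]")
    counts = report_counts.copy()
    counts.index = counts.index.astype(str).str.upper()
    dg = disgenet.copy()
    dg.index = dg.index.astype(str).str.upper()

    universe = counts.index.union(dg.index).sort_values()
    counts_u = counts.reindex(universe)
    dg_u = dg.reindex(universe)
    max_count = float(counts.max()) if len(counts) else 0.0
    max_score = float(dg.max()) if len(dg) else 0.0
    if max_count > 0:
        text = counts_u.fillna(0.0) / max_count * max_score
    else:
        text = pd.Series(0.0, index=universe)
    out = pd.DataFrame(
        {
            "text_score": text,
            "disgenet_score": dg_u.fillna(0.0),
            "missing_reports": counts_u.isna(),
            "missing_disgenet": dg_u.isna(),
        }
    )
    out["experiment_score"] = out["text_score"] + out["disgenet_score"]
    return out


def expression_score(
    primary_fold: pd.Series, enrichment_folds: list[pd.Series]
) -> pd.DataFrame:
    """Primary fold plus the mean fold across the enrichment datasets.

    The mean is taken over the enrichment tables in which the gene appears;
    with full coverage over three tables this is the sum-over-three-divided-
    by-three rule. Genes absent from every enrichment table keep the primary
    fold and are flagged ``no_enrichment``; partial coverage is flagged
    ``partial``. Genes absent from the primary fold table are excluded with a
    logged count.
    """
    if not enrichment_folds:
        raise ValueError("need at least one enrichment fold table")
    n_total = len(enrichment_folds)
    enr = pd.concat(enrichment_folds, axis=1, keys=range(n_total))
    universe = primary_fold.index
    missing_primary = enr.index.difference(universe)
    if len(missing_primary):
        logger.info(
            "expression_score: %d gene(s) absent from the primary fold table excluded",
            len(missing_primary),
        )
    enr = enr.reindex(universe)
    n_present = enr.notna().sum(axis=1)
    mean_enr = enr.mean(axis=1).fillna(0.0)
    out = pd.DataFrame(
        {
            "primary_fold": primary_fold,
            "enrichment_mean": mean_enr,
            "n_enrichment": n_present.astype(int),
            "no_enrichment": n_present == 0,
            "partial": (n_present > 0) & (n_present < n_total),
        }
    )
    out["expression_score"] = out["primary_fold"] + out["enrichment_mean"]
    return out


def final_score(
    experiment: pd.DataFrame | pd.Series, expression: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Final score = experiment score + expression score on the union universe.

    A side missing for a gene contributes 0 and is flagged
    (``missing_experiment`` / ``missing_expression``).
    """
    exp_s = experiment["experiment_score"] if isinstance(experiment, pd.DataFrame) else experiment
    expr_s = expression["expression_score"] if isinstance(expression, pd.DataFrame) else expression
    universe = exp_s.index.union(expr_s.index).sort_values()
    exp_u = exp_s.reindex(universe)
    expr_u = expr_s.reindex(universe)
    out = pd.DataFrame(
        {
            "experiment_score": exp_u.fillna(0.0),
            "expression_score": expr_u.fillna(0.0),
            "missing_experiment": exp_u.isna(),
            "missing_expression": expr_u.isna(),
        }
    )
    out["final_score"] = out["experiment_score"] + out["expression_score"]
    if isinstance(experiment, pd.DataFrame):
        for col in ("text_score", "disgenet_score"):
            if col in experiment:
                out[col] = experiment[col].reindex(universe).fillna(0.0)
    if isinstance(expression, pd.DataFrame) and "primary_fold" in expression:
        out["fold"] = expression["primary_fold"].reindex(universe)
    return out


@dataclass
class HighLowSelection:
    """Outcome of a high/low percentile selection on a fold table."""

    high: list[str]
    low: list[str]
    hi_pct: float
    lo_pct: float
    hi_cutoff: float
    lo_cutoff: float

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise ValueError("high and low selections overlap")


def select_percentile_genes(
    folds: pd.Series, hi_pct: float = 99.5, lo_pct: float = 0.25
) -> HighLowSelection:
    """Select high-fold (> hi_pct-th percentile) and low-fold (< lo_pct-th
    percentile) genes; strict inequalities at both cutoffs.

    Percentiles use linear interpolation between closest ranks (numpy's
    default). A constant fold vector yields empty selections with a warning.
    """
    if len(folds) < 10:
        raise ValueError("need at least 10 genes for percentile selection")
    if not hi_pct > lo_pct:
        raise ValueError("hi_pct must exceed lo_pct")
    arr = folds.to_numpy(dtype=float)
    hi_cut = float(np.percentile(arr, hi_pct))
    lo_cut = float(np.percentile(arr, lo_pct))
    high = list(folds.index[arr > hi_cut])
    low = list(folds.index[arr < lo_cut])
    if arr.max() == arr.min():
        warnings.warn("constant fold vector: empty selection", stacklevel=2)
    return HighLowSelection(
        high=high, low=low, hi_pct=hi_pct, lo_pct=lo_pct,
        hi_cutoff=hi_cut, lo_cutoff=lo_cut,
    )


def centile_filter(
    scores: pd.Series, centile: float = 25.0, side: str = "above"
) -> list[str]:
    """Genes whose score rank-percentile is strictly above/below ``centile``.

    The rank percentile of a gene is ``100 * min_rank / n`` where ``min_rank``
    is 1 + the number of scores strictly below it (ties share the lowest rank).
    With all scores tied the above-filter is empty (warning).
    """
    if len(scores) == 0:
        raise ValueError("empty score vector")
    if side not in ("above", "below"):
        raise ValueError(f"side must be 'above' or 'below', got {side!r}")
    arr = scores.to_numpy(dtype=float)
    n = len(arr)
    order = np.sort(arr)
    min_rank = np.searchsorted(order, arr, side="left") + 1
    pct = 100.0 * min_rank / n
    if side == "above":
        mask = pct > centile
        if arr.max() == arr.min() and not mask.any():
            warnings.warn("all scores tied: empty above-filter", stacklevel=2)
    else:
        mask = pct < centile
    return list(scores.index[mask])
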