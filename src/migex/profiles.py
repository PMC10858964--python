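"""High-score gene profiles and heatmap-ready fold matrices.

A profile is the set of genes whose final score strictly exceeds a condition
threshold (the study design uses score > 12 for STEMI and > 8 for NSTEMI),
ordered by descending score. A sub-profile keeps the members whose fold
strictly exceeds a fold threshold (> 0.4 in the reference design); the
inequalities are strict everywhere, so boundary genes are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fold_scores import HighLowSelection

__all__ = ["GeneProfile", "select_profile", "sub_profile_by_fold", "heatmap_matrix"]


@dataclass
class GeneProfile:
    """An ordered, named gene list with scores/folds and selection provenance."""

    condition: str
    genes: list[str]
    scores: pd.Series
    folds: pd.Series | None
    rule: dict = field(default_factory=dict)
    level: str | None = None

    def __post_init__(self) -> None:
        got = self.scores.reindex(self.genes)
        if got.isna().any():
            raise ValueError("every profile gene needs a score")
        if list(got.sort_values(ascending=False, kind="stable").index) != list(self.genes) \
                and not got.is_monotonic_decreasing:
            raise ValueError("profile genes must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.genes)


def select_profile(
    scores: pd.DataFrame | pd.Series,
    threshold: float,
    condition: str = "",
    folds: pd.Series | None = None,
) -> GeneProfile:
    """Genes with final score strictly above ``threshold``, sorted by
    descending score (ties broken by gene symbol).

    ``scores`` may be a full score table (column ``final_score``, optional
    ``fold``) or a bare Series of final scores. An empty result is a warning,
    not an error.
    """
    if isinstance(scores, pd.DataFrame):
        final = scores["final_score"]
        if folds is None and "fold" in scores:
            folds = scores["fold"]
    else:
        final = scores
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    kept = final[final > threshold]
    ordered = kept.sort_values(ascending=False, kind="stable")
    # deterministic tie-break on the symbol
    ordered = ordered.iloc[
        np.lexsort((ordered.index.to_numpy(), -ordered.to_numpy()))
    ]
    if ordered.empty:
        warnings.warn(
            f"no genes with score > {threshold}: empty profile", stacklevel=2
        )
    genes = list(ordered.index)
    return GeneProfile(
        condition=condition,
        genes=genes,
        scores=ordered,
        folds=folds.reindex(genes) if folds is not None else None,
        rule={"score_type": "final_score", "threshold": float(threshold),
              "comparison": ">"},
    )


def sub_profile_by_fold(profile: GeneProfile, fold_threshold: float = 0.4) -> GeneProfile:
    """Members of ``profile`` whose fold is strictly above ``fold_threshold``."""
    if len(profile) == 0:
        raise ValueError("profile is empty")
    if profile.folds is None:
        raise ValueError("profile carries no fold values")
    keep = [g for g in profile.genes if profile.folds[g] > fold_threshold]
    return GeneProfile(
        condition=profile.condition,
        genes=keep,
        scores=profile.scores.reindex(keep),
        folds=profile.folds.reindex(keep),
        rule=dict(profile.rule),
        level=f"fold > {fold_threshold} sub-profile",
    )


def heatmap_matrix(
    selection: HighLowSelection,
    fold_tables: list[pd.Series],
    contrast_names: list[str] | None = None,
) -> pd.DataFrame:
    """Heatmap-ready fold matrix for a high/low selection.

    Rows are the high-fold genes in descending fold order (by the first
    contrast) followed by the low-fold genes in ascending order; ties break
    lexicographically on the symbol. Columns are the contrasts in caller
    order. Genes missing from a fold table get blank (NaN) cells.
    """
    if contrast_names is None:
        contrast_names = [t.name or f"contrast_{i}" for i, t in enumerate(fold_tables)]
    if len(contrast_names) != len(fold_tables):
        raise ValueError("one name per fold table required")
    primary = fold_tables[0]

    def ordered(genes: list[str], ascending: bool) -> list[str]:
        vals = primary.reindex(genes)
        key = vals.to_numpy(dtype=float)
        key = np.where(np.isnan(key), np.inf if ascending else -np.inf, key)
        idx = np.lexsort((np.array(genes), key if ascending else -key))
        return [genes[i] for i in idx]

    rows = ordered(list(selection.high), ascending=False) + \
           ordered(list(selection.low), ascending=True)
    matrix = pd.DataFrame(
        {name: table.reindex(rows) for name, table in zip(contrast_names, fold_tables)}
    )
    matrix.index.name = "gene"
    return matrix
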