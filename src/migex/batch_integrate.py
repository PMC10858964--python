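"""Merging expression datasets and removing batch effects.

Datasets are merged on the intersection of their gene universes; the batch
label of every sample in the merged matrix is the index of its source dataset.
Batch correction is control-anchored location-scale harmonization: per gene,
each batch's values are affinely transformed so that the batch-wise control
mean equals the pooled control mean and the batch-wise control standard
deviation equals the pooled within-batch control standard deviation. Anchoring
on control samples only prevents group-composition differences between source
datasets from being absorbed as batch effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression_io import ExpressionDataset

__all__ = ["merge_datasets", "correct_batch", "batch_sum_of_squares"]

_VAR_TOL = 1e-12


def merge_datasets(
    sources: list[ExpressionDataset],
    allow_duplicate_samples: bool = False,
) -> ExpressionDataset:
    """Merge >= 2 datasets on their common gene universe.

    Rows are the sorted gene intersection; columns are the concatenation of all
    samples; the batch label is the source index. Duplicate sample IDs across
    sources are an error unless ``allow_duplicate_samples`` (which suffixes).
    """
    if len(sources) < 2:
        raise ValueError("merge_datasets needs at least 2 sources")
    common: set[str] = set(sources[0].genes)
    for ds in sources[1:]:
        common &= set(ds.genes)
    if not common:
        raise ValueError("empty gene intersection across sources")
    genes = sorted(common)

    blocks, groups, batches, seen = [], [], [], set()
    for idx, ds in enumerate(sources):
        block = ds.values.loc[genes].copy()
        cols = list(block.columns)
        clash = seen & set(cols)
        if clash:
            if not allow_duplicate_samples:
                raise ValueError(
                    f"duplicate sample IDs across sources: {sorted(clash)[:5]}"
                )
            rename = {c: f"{c}__{idx}" for c in cols}
            block = block.rename(columns=rename)
            cols = list(block.columns)
        seen |= set(cols)
        blocks.append(block)
        groups.append(pd.Series(ds.groups.to_numpy(), index=cols))
        batches.append(pd.Series(str(idx), index=cols))

    merged = ExpressionDataset(
        pd.concat(blocks, axis=1),
        groups=pd.concat(groups),
        batches=pd.concat(batches),
        name="merged",
    )
    merged.attrs["sources"] = [ds.name for ds in sources]
    return merged


def correct_batch(
    merged: ExpressionDataset,
    method: str = "location-scale",
    anchor_group: str = "control",
) -> ExpressionDataset:
    """Remove per-batch location/scale effects, anchored on control samples.

    Per gene g and batch b with control mean m_gb and control SD s_gb, every
    sample x in batch b maps to ``(x - m_gb) / s_gb * S_g + M_g`` where M_g is
    the pooled control mean and S_g the pooled within-batch control SD. Genes
    with (numerically) zero within-batch control variance pass through
    shift-only correction. The transform is exactly idempotent.
    """
    if method != "location-scale":
        raise ValueError(f"unknown batch-correction method {method!r}")
    batches = merged.batches
    values = merged.values
    is_anchor = (merged.groups == anchor_group).to_numpy()
    batch_ids = list(dict.fromkeys(batches))
    for b in batch_ids:
        in_b = (batches == b).to_numpy()
        if in_b.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        if not (in_b & is_anchor).any():
            raise ValueError(
                f"batch {b!r} has no {anchor_group!r} samples; anchored "
                "location-scale correction needs an anchor in every batch "
                "(use a different anchor_group)"
            )

    X = values.to_numpy(dtype=float).copy()
    anchor_cols = {b: ((batches == b).to_numpy() & is_anchor) for b in batch_ids}
    means = {b: X[:, cols].mean(axis=1) for b, cols in anchor_cols.items()}
    sds = {}
    dofs = {}
    for b, cols in anchor_cols.items():
        n_b = int(cols.sum())
        dof = max(n_b - 1, 0)
        sds[b] = X[:, cols].std(axis=1, ddof=1) if n_b > 1 else np.zeros(X.shape[0])
        dofs[b] = dof
    n_anchor = int(is_anchor.sum())
    pooled_mean = sum(means[b] * anchor_cols[b].sum() for b in batch_ids) / n_anchor
    total_dof = sum(dofs.values())
    if total_dof > 0:
        pooled_var = sum(dofs[b] * sds[b] ** 2 for b in batch_ids) / total_dof
        pooled_sd = np.sqrt(pooled_var)
    else:
        pooled_sd = np.zeros(X.shape[0])

    out = X.copy()
    for b in batch_ids:
        cols = (batches == b).to_numpy()
        m, s = means[b], sds[b]
        scalable = (s > _VAR_TOL) & (pooled_sd > _VAR_TOL)
        ratio = np.where(scalable, pooled_sd / np.where(s > _VAR_TOL, s, 1.0), 1.0)
        out[:, cols] = (X[:, cols] - m[:, None]) * ratio[:, None] + pooled_mean[:, None]

    corrected = ExpressionDataset(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        groups=merged.groups.copy(),
        batches=merged.batches.copy(),
        name=merged.name,
        attrs=dict(merged.attrs),
    )
    corrected.attrs["batch_correction"] = {"method": method, "anchor": anchor_group}
    return corrected


def batch_sum_of_squares(dataset: ExpressionDataset, group: str = "control") -> float:
    """Between-batch sum of squares of the given group's samples, summed over
    genes (the 'batch' term of a one-way decomposition); used to quantify how
    much batch structure correction removed.
    """
    mask = (dataset.groups == group).to_numpy()
    if not mask.any():
        raise ValueError(f"no samples in group {group!r}")
    X = dataset.values.to_numpy(dtype=float)[:, mask]
    batches = dataset.batches.to_numpy()[mask]
    grand = X.mean(axis=1)
    ss = 0.0
    for b in dict.fromkeys(batches):
        cols = batches == b
        ss += float((cols.sum() * (X[:, cols].mean(axis=1) - grand) ** 2).sum())
    return ss
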