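"""Reference STEMI/NSTEMI gene panels with a synthetic score fixture.

The gene lists are the published high-score network profiles: 13 genes for
STEMI (final score > 12) and 14 for NSTEMI (final score > 8), of which four
NSTEMI genes (IPO11, CA1, XK, ACOX2) form the high-fold (> 0.4) sub-profile.
The per-gene scores and folds attached by :func:`synthetic_panel_scores` are
SYNTHETIC: the source reports only the thresholds the panels satisfy, not the
individual values, so the fixture assigns deterministic values consistent with
those thresholds. Use it for exercising the selection bookkeeping, not as
measured data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "STEMI_PROFILE_GENES",
    "NSTEMI_PROFILE_GENES",
    "NSTEMI_HIGH_FOLD_GENES",
    "STEMI_SCORE_THRESHOLD",
    "NSTEMI_SCORE_THRESHOLD",
    "HIGH_FOLD_THRESHOLD",
    "synthetic_panel_scores",
]

STEMI_PROFILE_GENES: tuple[str, ...] = (
    "DUSP1", "PADI4", "CDA", "VNN3", "CYP4F3", "MMP9", "NOV",
    "ARG1", "IRS2", "DUSP2", "CRISPLD2", "HMGB2", "TNFRSF12A",
)

NSTEMI_PROFILE_GENES: tuple[str, ...] = (
    "FAM46C", "HBQ1", "CA1", "KRT1", "XK", "BTNL3", "FECH",
    "GLRX5", "ACOX2", "ZBTB32", "IPO11", "LDLR", "NT5DC2", "CD244",
)

NSTEMI_HIGH_FOLD_GENES: tuple[str, ...] = ("IPO11", "CA1", "XK", "ACOX2")

STEMI_SCORE_THRESHOLD = 12.0
NSTEMI_SCORE_THRESHOLD = 8.0
HIGH_FOLD_THRESHOLD = 0.4

_BACKGROUND = (
    "TNNT2", "CRP", "CHI3L1", "MYBPC3", "FKBP5", "CST3", "MPO",
    "LGALS3", "MME", "NPPB", "CXCR4", "PTX3", "AVP", "SFRP5",
)


def synthetic_panel_scores(condition: str) -> pd.DataFrame:
    """Synthetic score table for one condition's panel selection.

    Panel genes receive final scores strictly above the condition threshold
    (spaced by 0.1 in list order) and background genes scores strictly below
    it. NSTEMI folds put exactly the four high-fold genes above 0.4; every
    other fold sits in (0, 0.4). Deterministic.
    """
    if condition == "STEMI":
        panel, threshold = STEMI_PROFILE_GENES, STEMI_SCORE_THRESHOLD
        high_fold: tuple[str, ...] = ()
    elif condition == "NSTEMI":
        panel, threshold = NSTEMI_PROFILE_GENES, NSTEMI_SCORE_THRESHOLD
        high_fold = NSTEMI_HIGH_FOLD_GENES
    else:
        raise ValueError(f"condition must be 'STEMI' or 'NSTEMI', got {condition!r}")

    genes = list(panel) + list(_BACKGROUND)
    final = np.concatenate([
        threshold + 0.1 * (np.arange(len(panel), dtype=float) + 1.0),
        threshold - 0.5 - 0.1 * np.arange(len(_BACKGROUND), dtype=float),
    ])
    folds = np.empty(len(genes))
    for i, g in enumerate(genes):
        if g in high_fold:
            folds[i] = 0.45 + 0.05 * high_fold.index(g)
        elif g in panel:
            folds[i] = 0.10 + 0.02 * (i % 10)
        else:
            folds[i] = 0.05
    out = pd.DataFrame(
        {"final_score": final, "fold": folds},
        index=pd.Index(genes, name="gene"),
    )
    out["experiment_score"] = 0.5 * out["final_score"]
    out["expression_score"] = out["final_score"] - out["experiment_score"]
    return out
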