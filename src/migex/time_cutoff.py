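"""Sigma-metric quality-control arithmetic and the CV-shift round procedure
that yields time cut-off points for measuring a gene profile after MI.

The laboratory-QC budget is the total allowable error

    TEa = Bias + (dSE + Z) * CV           (Z = 1.96 for Pfr = 5%)

and the process capability in SD units is

    Sigma = (TE - Bias) / CV.

The probability of error detection for a systematic shift of dSE CV-units
under a standard normal error model with a detection limit L (default 3 SD) is

    Ped = P(N(dSE, 1) > L) = Phi(dSE - L),

which gives Ped = 16% at dSE = 2, 50% at dSE = 3 and 84% at dSE = 4.

The cut-off procedure shifts an acute fold profile by k * CV per round
(k = 0, 1, 2, ...), compares each shifted profile with the 7-day reference
profile by a two-tailed t test, and declares the first non-significant round
k* the cut-off; k* maps to days after MI through a user-supplied table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SigmaConfig",
    "CutoffResult",
    "REPORTED_DAY_MAPPING",
    "DAY_MAPPINGS",
    "allowable_total_error",
    "sigma_metric",
    "ped",
    "shift_profile",
    "overlap_test",
    "profile_stability_test",
    "find_cutoff",
    "profile_trend",
]

# dSE round -> days after MI, as reported for the reference study design
# (not a monotone function; it is a lookup table, not a formula).
REPORTED_DAY_MAPPING: dict[int, float] = {2: 1.0, 3: 3.0, 4: 2.0}
DAY_MAPPINGS: dict[str, dict[int, float]] = {"reported": REPORTED_DAY_MAPPING}


@dataclass
class SigmaConfig:
    """Sigma-metric parameters.

    tea, bias and cv are in fold units; z is the false-reject quantile
    (1.96 for Pfr = 5%); detection_limit is the Ped quantile in SD units.
    """

    tea: float = 0.0
    bias: float = 0.0
    cv: float = 1.0
    z: float = 1.96
    pfr: float = 0.05
    dre: float = 0.0
    detection_limit: float = 3.0

    def __post_init__(self) -> None:
        if not self.cv > 0:
            raise ValueError("CV must be positive")
        if not 0 < self.pfr < 1:
            raise ValueError("Pfr must lie in (0, 1)")
        if not self.z > 0:
            raise ValueError("Z must be positive")


def allowable_total_error(cfg: SigmaConfig, dse: float) -> float:
    """TEa = Bias + (dSE + Z) * CV."""
    return cfg.bias + (dse + cfg.z) * cfg.cv


def sigma_metric(te: float, bias: float, cv: float) -> float:
    """Sigma = (TE - Bias) / CV."""
    if not cv > 0:
        raise ValueError("CV must be positive")
    return (te - bias) / cv


def ped(dse: float, detection_limit: float = 3.0) -> float:
    """Probability of error detection for a systematic shift of ``dse`` CV
    units: P(N(dse, 1) > detection_limit) = Phi(dse - detection_limit).
    Monotone nondecreasing in dse; equals 0.5 at dse = detection_limit.
    """
    if dse < 0:
        raise ValueError("dse must be non-negative")
    return float(stats.norm.cdf(dse - detection_limit))


def shift_profile(folds, cv, k: int):
    """Shifted fold vector ``fold + k * cv`` (per gene; scalar cv broadcasts)."""
    if k < 0:
        raise ValueError("round index k must be >= 0")
    folds = np.asarray(folds, dtype=float)
    cv_arr = np.asarray(cv, dtype=float)
    if cv_arr.ndim > 0 and cv_arr.shape != folds.shape:
        raise ValueError(f"cv shape {cv_arr.shape} does not match folds {folds.shape}")
    if not np.all(cv_arr > 0):
        raise ValueError("cv must be positive elementwise")
    return folds + k * cv_arr


def overlap_test(
    profile_a, profile_b, alpha: float = 0.05, equal_var: bool = True
) -> tuple[float, float, bool]:
    """Two-sample two-tailed t test between two fold vectors.

    Returns (t, p, significant). Identical vectors (zero pooled variance and
    zero mean difference) return p = 1 by convention.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each profile needs >= 2 values")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(t), float(p)
    if math.isnan(p):  # zero pooled variance, equal means
        t, p = 0.0, 1.0
    return t, p, p < alpha


def profile_stability_test(
    reference_folds, later_folds, alpha: float = 0.05, equal_var: bool = True
) -> tuple[float, float, bool]:
    """Check that a profile is stable between two follow-up times (e.g. 7-day
    vs 30-day); this is the precondition for anchoring the cut-off search on
    the earlier follow-up profile. Alias of :func:`overlap_test`.
    """
    return overlap_test(reference_folds, later_folds, alpha=alpha, equal_var=equal_var)


@dataclass
class CutoffResult:
    """Trajectory of the CV-shift rounds and the selected cut-off.

    rounds holds one record per dSE round k (consecutive from 0) with the
    shifted-profile mean, t statistic and two-tailed p; k_star is the first
    round with p >= alpha (None if never reached); ped_at_cutoff and days are
    evaluated at k_star.
    """

    rounds: pd.DataFrame
    k_star: int | None
    alpha: float
    ped_at_cutoff: float | None = None
    days: float | None = None
    day_mapping_name: str | None = None
    direction: int = 1
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "CV-shift cut-off search",
            f"  alpha = {self.alpha}, shift direction = {self.direction:+d}",
        ]
        for rec in self.rounds.itertuples():
            mark = " <- k*" if rec.Index == self.k_star else ""
            lines.append(
                f"  round {rec.Index}: shifted mean = {rec.shifted_mean:+.4f}, "
                f"t = {rec.t:+.3f}, p = {rec.p:.4g}{mark}"
            )
        if self.k_star is None:
            lines.append("  no non-significant round within the search budget")
        else:
            lines.append(f"  k* = {self.k_star}, Ped(k*) = {self.ped_at_cutoff:.2%}")
            if self.days is not None:
                lines.append(
                    f"  mapped time = {self.days} day(s) "
                    f"[{self.day_mapping_name} mapping]"
                )
        return "\n".join(lines)


def find_cutoff(
    acute_folds,
    reference_folds,
    cv,
    cfg: SigmaConfig | None = None,
    alpha: float = 0.05,
    max_rounds: int = 10,
    day_mapping: str | dict[int, float] | None = None,
    direction: str = "auto",
    equal_var: bool = True,
) -> CutoffResult:
    """Search for the first dSE round at which the shifted acute profile
    overlaps the reference (7-day) profile non-significantly.

    Each round k shifts the acute folds by ``k * cv`` (toward the reference
    when ``direction='auto'``: the sign of the mean reference-minus-acute
    difference; ``'up'``/``'down'`` force the sign) and runs a two-tailed
    t test against the reference. k* is the minimal k with p >= alpha; if no
    round qualifies within ``max_rounds`` the result carries k* = None and a
    warning. Ped at k* uses ``cfg.detection_limit`` (default 3 SD).
    """
    if cfg is None:
        cfg = SigmaConfig()
    acute = np.asarray(acute_folds, dtype=float)
    reference = np.asarray(reference_folds, dtype=float)
    if acute.shape != reference.shape:
        raise ValueError("acute and reference profiles must align gene-by-gene")
    if direction == "auto":
        sign = 1 if reference.mean() >= acute.mean() else -1
    elif direction == "up":
        sign = 1
    elif direction == "down":
        sign = -1
    else:
        raise ValueError(f"direction must be 'auto', 'up' or 'down', got {direction!r}")

    records = []
    k_star: int | None = None
    for k in range(max_rounds + 1):
        shifted = shift_profile(acute, cv, k) if sign > 0 else \
            acute - shift_profile(np.zeros_like(acute), cv, k)
        t, p, significant = overlap_test(shifted, reference, alpha=alpha,
                                         equal_var=equal_var)
        records.append((k, float(np.mean(shifted)), t, p, significant))
        if not significant and k_star is None:
            k_star = k
            break
    rounds = pd.DataFrame(
        records, columns=["k", "shifted_mean", "t", "p", "significant"]
    ).set_index("k")

    notes: list[str] = []
    ped_value = days = mapping_name = None
    if k_star is None:
        warnings.warn(
            f"no non-significant overlap within {max_rounds} rounds", stacklevel=2
        )
        notes.append(f"no cut-off within {max_rounds} rounds")
    else:
        ped_value = ped(k_star, cfg.detection_limit)
        if day_mapping is not None:
            if isinstance(day_mapping, str):
                mapping_name = day_mapping
                table = DAY_MAPPINGS[day_mapping]
            else:
                mapping_name = "custom"
                table = day_mapping
            if k_star in table:
                days = float(table[k_star])
            else:
                notes.append(f"day mapping has no entry for round {k_star}")
    return CutoffResult(
        rounds=rounds, k_star=k_star, alpha=alpha, ped_at_cutoff=ped_value,
        days=days, day_mapping_name=mapping_name, direction=sign, notes=notes,
    )


def profile_trend(fold_series: pd.DataFrame, times=None) -> pd.DataFrame:
    """Ordinary least-squares fold-vs-time slope per gene with a two-tailed
    slope test.

    ``fold_series`` has genes in rows and ordered time points in columns;
    ``times`` gives the numeric times (defaults to the column labels). A
    constant series returns slope 0 and p = 1 by convention.
    """
    if fold_series.shape[1] < 3:
        raise ValueError("trend estimation needs >= 3 time points")
    if times is None:
        times = [float(c) for c in fold_series.columns]
    times = np.asarray(times, dtype=float)
    if len(times) != fold_series.shape[1]:
        raise ValueError("one time per column required")
    rows = []
    for gene, y in fold_series.iterrows():
        yv = y.to_numpy(dtype=float)
        if np.ptp(yv) == 0:
            rows.append((gene, 0.0, 1.0, float(yv[0])))
            continue
        res = stats.linregress(times, yv)
        rows.append((gene, float(res.slope), float(res.pvalue), float(res.intercept)))
    return pd.DataFrame(
        rows, columns=["gene", "slope", "p_value", "intercept"]
    ).set_index("gene")
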