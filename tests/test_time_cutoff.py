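import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from migex.time_cutoff import (
    REPORTED_DAY_MAPPING,
    SigmaConfig,
    allowable_total_error,
    find_cutoff,
    overlap_test,
    ped,
    profile_trend,
    shift_profile,
    sigma_metric,
)


# ------------------------------------------------------------ QC arithmetic

@pytest.mark.parametrize(
    "bias, cv, dse, expected",
    [(0.0, 1.0, 0.0, 1.96), (0.5, 2.0, 2.0, 8.42), (0.0, 1.0, -1.96, 0.0)],
)
def test_allowable_total_error(bias, cv, dse, expected):
    cfg = SigmaConfig(bias=bias, cv=cv)
    assert allowable_total_error(cfg, dse) == pytest.approx(expected)


def test_sigma_metric_values():
    assert sigma_metric(3.0, 0.0, 1.0) == pytest.approx(3.0)
    assert sigma_metric(2.0, 2.0, 0.7) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        sigma_metric(1.0, 0.0, 0.0)


def test_sigma_of_allowable_error_is_dse_plus_z():
    cfg = SigmaConfig(bias=0.3, cv=0.8, z=1.96)
    for dse in np.linspace(0, 6, 13):
        te = allowable_total_error(cfg, dse)
        assert sigma_metric(te, cfg.bias, cfg.cv) == pytest.approx(
            dse + cfg.z, abs=1e-12
        )


def test_ped_matches_reported_percentages():
    """Detection probabilities at shifts of 2, 3 and 4 CV units round to the
    published 16%, 50% and 84% under the 3-SD detection limit."""
    assert round(100 * ped(2.0)) == 16
    assert round(100 * ped(3.0)) == 50
    assert round(100 * ped(4.0)) == 84
    assert ped(3.0) == pytest.approx(0.5, abs=1e-15)


def test_ped_monotone_and_validated():
    grid = [ped(d) for d in np.linspace(0, 6, 25)]
    assert all(b >= a for a, b in zip(grid, grid[1:]))
    with pytest.raises(ValueError):
        ped(-0.1)


def test_sigma_config_validation():
    with pytest.raises(ValueError, match="CV"):
        SigmaConfig(cv=0.0)
    with pytest.raises(ValueError, match="Pfr"):
        SigmaConfig(pfr=1.5)


# ------------------------------------------------------------ shifting / tests

def test_shift_profile_arithmetic():
    np.testing.assert_allclose(shift_profile([0.4, 0.6], 0.1, 0), [0.4, 0.6])
    np.testing.assert_allclose(shift_profile([0.4, 0.6], 0.1, 2), [0.6, 0.8])
    np.testing.assert_allclose(
        shift_profile([0.4, 0.6], 0.1, 3),
        shift_profile([0.4, 0.6], [0.1, 0.1], 3),
    )
    with pytest.raises(ValueError, match="shape"):
        shift_profile([0.4, 0.6], [0.1, 0.1, 0.1], 1)


def test_overlap_test_identical_vectors_p_one():
    t, p, sig = overlap_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert (t, p, sig) == (0.0, 1.0, False)


def test_overlap_test_clear_separation():
    a = [0.0, 0.01, -0.01, 0.02]
    b = [5.0, 5.01, 4.99, 5.02]
    _, p, sig = overlap_test(a, b)
    assert p < 0.05 and sig


def test_overlap_test_matches_textbook_pooled_t(rng):
    a = rng.normal(0.2, 0.1, size=13)
    b = rng.normal(0.3, 0.15, size=13)
    t, p, _ = overlap_test(a, b, equal_var=True)
    # independent textbook computation: pooled variance two-sample t
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_ref = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p_ref = 2 * stats.t.sf(abs(t_ref), na + nb - 2)
    assert t == pytest.approx(t_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)


def test_overlap_test_needs_two_values():
    with pytest.raises(ValueError):
        overlap_test([1.0], [1.0, 2.0])


# ------------------------------------------------------------ cut-off search

def test_find_cutoff_identical_profiles_round_zero():
    folds = np.array([0.4, 0.5, 0.6, 0.7])
    res = find_cutoff(folds, folds.copy(), cv=0.1)
    assert res.k_star == 0
    assert res.ped_at_cutoff == pytest.approx(ped(0))


def test_find_cutoff_recovers_constructed_round(rng):
    """Reference = acute + 3*cv plus tiny noise => first overlap at round 3."""
    acute = np.array([0.40, 0.45, 0.50, 0.55, 0.60, 0.42, 0.48, 0.52,
                      0.58, 0.44, 0.46, 0.54, 0.56])
    cv = 0.1
    reference = acute + 3 * cv + rng.normal(0, 0.005, size=acute.size)
    res = find_cutoff(acute, reference, cv=cv, day_mapping="reported")
    assert res.k_star == 3
    assert res.days == REPORTED_DAY_MAPPING[3] == 3.0
    assert res.ped_at_cutoff == pytest.approx(0.5, abs=1e-12)
    assert list(res.rounds.index) == [0, 1, 2, 3]
    assert (res.rounds.loc[:2, "p"] < 0.05).all()


def test_find_cutoff_vanishing_cv_never_overlaps(rng):
    acute = rng.normal(0.5, 0.01, size=10)
    reference = acute + 1.0
    with pytest.warns(UserWarning, match="no non-significant overlap"):
        res = find_cutoff(acute, reference, cv=1e-9, max_rounds=10)
    assert res.k_star is None
    assert "no cut-off within 10 rounds" in res.notes


def test_find_cutoff_monotone_in_cv(rng):
    acute = np.full(12, 0.5) + rng.normal(0, 0.002, size=12)
    reference = acute + 0.6
    ks = []
    for scale in (1.0, 2.0, 3.0):
        res = find_cutoff(acute, reference, cv=0.1 * scale, max_rounds=20)
        ks.append(res.k_star)
    assert ks[0] >= ks[1] >= ks[2]


def test_find_cutoff_auto_direction_handles_decay(rng):
    # acute folds above the follow-up reference: the shift runs downward
    acute = np.full(10, 1.0) + rng.normal(0, 0.01, size=10)
    reference = acute - 0.4
    res = find_cutoff(acute, reference, cv=0.1)
    assert res.direction == -1
    assert res.k_star is not None


def test_find_cutoff_null_mostly_round_zero(rng):
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        acute = rng.normal(0.5, 0.1, size=10)
        reference = acute + rng.normal(0, 0.1, size=10)
        if find_cutoff(acute, reference, cv=0.05).k_star == 0:
            hits += 1
    mc_se = math.sqrt(0.05 * 0.95 / n_rep)
    assert hits / n_rep >= 1 - 0.05 - 3 * mc_se


def test_cutoff_summary_mentions_selected_round():
    folds = np.array([0.4, 0.5, 0.6])
    res = find_cutoff(folds, folds + 0.001, cv=0.1)
    assert "k* = 0" in res.summary()


# ------------------------------------------------------------ trend

def test_trend_sign_and_flat_convention():
    series = pd.DataFrame(
        {"0": [2.0, 1.0], "7": [1.0, 1.0], "30": [0.0, 1.0]},
        index=["DOWN", "FLAT"],
    )
    out = profile_trend(series, times=[0, 7, 30])
    assert out.loc["DOWN", "slope"] < 0
    assert out.loc["FLAT", "slope"] == 0.0
    assert out.loc["FLAT", "p_value"] == 1.0


def test_trend_matches_closed_form_ols(rng):
    times = np.array([0.0, 1.0, 7.0, 14.0, 30.0])
    y = rng.normal(0.5, 0.2, size=5)
    out = profile_trend(pd.DataFrame([y], index=["G"], columns=times), times)
    sxx = ((times - times.mean()) ** 2).sum()
    slope = ((times - times.mean()) * (y - y.mean())).sum() / sxx
    resid = y - (y.mean() + slope * (times - times.mean()))
    se = math.sqrt((resid ** 2).sum() / (len(y) - 2) / sxx)
    p = 2 * stats.t.sf(abs(slope / se), len(y) - 2)
    assert out.loc["G", "slope"] == pytest.approx(slope, abs=1e-10)
    assert out.loc["G", "p_value"] == pytest.approx(p, abs=1e-10)


def test_trend_needs_three_timepoints():
    with pytest.raises(ValueError, match=">= 3"):
        profile_trend(pd.DataFrame([[1.0, 2.0]], columns=["0", "7"]))
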