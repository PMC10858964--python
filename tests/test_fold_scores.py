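import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migex.fold_scores import (
    centile_filter,
    experiment_score,
    expression_score,
    final_score,
    gene_fold,
    select_percentile_genes,
)
from conftest import make_dataset


# ---------------------------------------------------------------- gene_fold

def mean_difference(ds, case, control="control"):
    """Independent oracle: fold as a plain difference of group means."""
    c = ds.values[ds.samples_in_group(case)].mean(axis=1)
    k = ds.values[ds.samples_in_group(control)].mean(axis=1)
    return c - k


def test_fold_hand_example():
    ds = make_dataset([[1, 3, 3, 5]], ["control", "control", "STEMI", "STEMI"])
    assert gene_fold(ds, "STEMI")["G0"] == pytest.approx(2.0)


def test_fold_zero_when_case_equals_control():
    ds = make_dataset([[1, 3, 1, 3]], ["control", "control", "STEMI", "STEMI"])
    assert gene_fold(ds, "STEMI")["G0"] == pytest.approx(0.0, abs=1e-15)


def test_literal_formula_equals_mean_difference(rng):
    ds = make_dataset(rng.normal(size=(50, 12)),
                      ["control"] * 5 + ["STEMI"] * 7)
    fold = gene_fold(ds, "STEMI")
    oracle = mean_difference(ds, "STEMI")
    np.testing.assert_allclose(fold.to_numpy(), oracle.to_numpy(), atol=1e-12)


def test_fold_translation_invariance(rng):
    ds = make_dataset(rng.normal(size=(20, 8)), ["control"] * 4 + ["STEMI"] * 4)
    base = gene_fold(ds, "STEMI")
    shifted = make_dataset(ds.values.to_numpy() + 7.3, ds.groups)
    np.testing.assert_allclose(gene_fold(shifted, "STEMI").to_numpy(),
                               base.to_numpy(), atol=1e-12)
    case_only = ds.values.to_numpy().copy()
    case_only[:, 4:] += 1.5
    bumped = make_dataset(case_only, ds.groups)
    np.testing.assert_allclose(gene_fold(bumped, "STEMI").to_numpy(),
                               base.to_numpy() + 1.5, atol=1e-12)


def test_fold_missing_group_errors():
    ds = make_dataset([[1, 2]], ["control", "STEMI"])
    with pytest.raises(ValueError, match="absent"):
        gene_fold(ds, "NSTEMI")


def test_fold_single_sample_warns():
    ds = make_dataset([[1, 2, 3]], ["control", "control", "STEMI"])
    with pytest.warns(UserWarning, match="single sample"):
        gene_fold(ds, "STEMI")


# ---------------------------------------------------------------- score algebra

def test_experiment_score_normalization_hand_example():
    counts = pd.Series({"A": 10.0, "B": 5.0})
    dg = pd.Series({"A": 0.4, "B": 0.8})
    out = experiment_score(counts, dg)
    # text score = count / max count * max DisGeNET score
    assert out.loc["A", "text_score"] == pytest.approx(0.8)
    assert out.loc["B", "text_score"] == pytest.approx(0.4)
    assert out.loc["A", "experiment_score"] == pytest.approx(1.2)
    assert out.loc["B", "experiment_score"] == pytest.approx(1.2)


def test_experiment_score_disgenet_only_gene():
    out = experiment_score(pd.Series({"A": 3.0}), pd.Series({"B": 0.3}))
    assert out.loc["B", "experiment_score"] == pytest.approx(0.3)
    assert bool(out.loc["B", "missing_reports"])


def test_experiment_score_equal_counts_degenerate():
    counts = pd.Series({"A": 2.0, "B": 2.0})
    dg = pd.Series({"A": 0.5, "B": 0.9})
    out = experiment_score(counts, dg)
    np.testing.assert_allclose(out["text_score"].to_numpy(), 0.9)


def test_experiment_score_rejects_bad_inputs():
    with pytest.raises(ValueError, match="non-negative"):
        experiment_score(pd.Series({"A": -1.0}), pd.Series({"A": 0.5}))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        experiment_score(pd.Series({"A": 1.0}), pd.Series({"A": 1.5}))


def test_expression_score_full_and_partial_coverage():
    primary = pd.Series({"A": 0.5, "B": 0.5})
    enr = [pd.Series({"A": 0.1, "B": 0.4}), pd.Series({"A": 0.2, "B": 0.8}),
           pd.Series({"A": 0.3})]
    out = expression_score(primary, enr)
    assert out.loc["A", "expression_score"] == pytest.approx(0.5 + 0.2)
    # B present in 2 of 3 tables: mean over the available folds, flagged partial
    assert out.loc["B", "expression_score"] == pytest.approx(0.5 + 0.6)
    assert bool(out.loc["B", "partial"]) and not bool(out.loc["A", "partial"])


def test_expression_score_no_enrichment_flag():
    out = expression_score(pd.Series({"A": 0.7}), [pd.Series({"B": 1.0})])
    assert out.loc["A", "expression_score"] == pytest.approx(0.7)
    assert bool(out.loc["A", "no_enrichment"])


def test_final_score_additivity_random(rng):
    genes = [f"G{i}" for i in range(100)]
    exp = pd.Series(rng.normal(size=100), index=genes)
    expr = pd.Series(rng.normal(size=80), index=genes[:80])
    out = final_score(exp, expr)
    resid = out["final_score"] - out["experiment_score"] - out["expression_score"]
    assert np.abs(resid.to_numpy()).max() < 1e-12
    assert bool(out.loc["G99", "missing_expression"])
    assert out.loc["G99", "final_score"] == pytest.approx(exp["G99"])


# ---------------------------------------------------------------- selection

def percentile_oracle(values, pct):
    """Brute-force linear interpolation between closest ranks on a full sort."""
    s = sorted(values)
    h = (len(s) - 1) * pct / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def selection_oracle(folds: pd.Series, hi_pct=99.5, lo_pct=0.25):
    hi = percentile_oracle(folds.to_numpy(), hi_pct)
    lo = percentile_oracle(folds.to_numpy(), lo_pct)
    return (
        {g for g, v in folds.items() if v > hi},
        {g for g, v in folds.items() if v < lo},
    )


def test_selection_matches_oracle_on_integers():
    folds = pd.Series(np.arange(1.0, 1001.0), index=[f"G{i}" for i in range(1000)])
    sel = select_percentile_genes(folds)
    high, low = selection_oracle(folds)
    assert set(sel.high) == high
    assert set(sel.low) == low
    # 99.5th percentile of 1..1000 is 995.005 -> strictly above: 996..1000
    assert set(sel.high) == {f"G{i}" for i in range(995, 1000)}


def test_selection_matches_oracle_random(rng):
    for _ in range(50):
        n = int(rng.integers(10, 400))
        folds = pd.Series(rng.normal(size=n), index=[f"G{i}" for i in range(n)])
        sel = select_percentile_genes(folds)
        high, low = selection_oracle(folds)
        assert set(sel.high) == high and set(sel.low) == low


def test_selection_median_split_hand_case():
    folds = pd.Series({"A": -2.0, "B": -1.0, "C": 1.0, "D": 2.0})
    with pytest.raises(ValueError, match="at least 10"):
        select_percentile_genes(folds, hi_pct=50)
    padded = pd.Series(
        [-2.0, -1.0, 1.0, 2.0] + [0.0] * 6,
        index=["A", "B", "C", "D"] + [f"Z{i}" for i in range(6)],
    )
    sel = select_percentile_genes(padded, hi_pct=50, lo_pct=0.25)
    # median of the padded vector is 0 -> strictly above: C and D
    assert set(sel.high) == {"C", "D"}


def test_constant_folds_empty_selection_warns():
    folds = pd.Series(np.ones(20), index=[f"G{i}" for i in range(20)])
    with pytest.warns(UserWarning, match="constant"):
        sel = select_percentile_genes(folds)
    assert sel.high == [] and sel.low == []


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=12, max_size=200, unique=True))
def test_selection_size_bounds_property(values):
    folds = pd.Series(values, index=[f"G{i}" for i in range(len(values))])
    sel = select_percentile_genes(folds)
    n = len(values)
    assert len(sel.high) <= int(np.ceil(0.005 * n)) + 1
    assert len(sel.low) <= int(np.ceil(0.0025 * n)) + 1
    assert not set(sel.high) & set(sel.low)
    if sel.high and sel.low:
        assert min(folds[g] for g in sel.high) > max(folds[g] for g in sel.low)


def test_centile_filter_rank_examples():
    scores = pd.Series(np.arange(1.0, 101.0), index=[f"G{i}" for i in range(100)])
    above = centile_filter(scores, 25, "above")
    assert len(above) == 75
    assert set(above) == {f"G{i}" for i in range(25, 100)}
    assert len(centile_filter(scores, 0, "above")) == 100
    below = centile_filter(scores, 25, "below")
    assert set(below) == {f"G{i}" for i in range(24)}


def test_centile_filter_all_tied_warns():
    scores = pd.Series(np.ones(10), index=[f"G{i}" for i in range(10)])
    with pytest.warns(UserWarning, match="tied"):
        assert centile_filter(scores, 25, "above") == []
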