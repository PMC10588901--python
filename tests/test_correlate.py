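"""Spearman screening: coefficients, exact p-values, pruning logic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sevcms.correlate import (
    exact_spearman_pvalue, flag_pairs, prune_parameters, spearman_matrix,
)
from sevcms.datasets import StudyConfig

from conftest import make_table


def test_matches_scipy_spearman(rng):
    x = rng.standard_normal(30)
    y = 0.6 * x + rng.standard_normal(30)
    t = make_table({"x": x, "y": y})
    corr = spearman_matrix(t)
    ref = stats.spearmanr(x, y)
    assert corr.r.loc["x", "y"] == pytest.approx(ref.statistic, abs=1e-12)
    assert corr.p.loc["x", "y"] == pytest.approx(ref.pvalue, abs=1e-12)


def test_symmetry_and_diagonal(rng):
    t = make_table({f"p{i}": rng.standard_normal(25) for i in range(4)})
    corr = spearman_matrix(t)
    np.testing.assert_allclose(corr.r.to_numpy(), corr.r.to_numpy().T)
    np.testing.assert_allclose(corr.p.to_numpy(), corr.p.to_numpy().T)
    np.testing.assert_allclose(np.diag(corr.r), 1.0)
    assert (np.abs(corr.r.to_numpy()) <= 1 + 1e-12).all()


def test_pairwise_complete_n():
    t = make_table({"a": [1, 2, 3, 4, np.nan], "b": [2, 1, 4, np.nan, 5.0]})
    corr = spearman_matrix(t)
    assert corr.n_pairs.loc["a", "b"] == 3


def test_exact_permutation_p_small_n():
    """Perfect concordance of 3 values: one-sided p = 1/6, two-sided 2/6."""
    x = [1.0, 2.0, 3.0]
    y = [10.0, 20.0, 30.0]
    assert exact_spearman_pvalue(x, y, "greater") == pytest.approx(1 / 6)
    assert exact_spearman_pvalue(x, y, "two-sided") == pytest.approx(2 / 6)


def test_exact_p_against_independent_enumeration(rng):
    """Dual route: implementation vs a scipy-statistic permutation count."""
    for _ in range(3):
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        r_obs = stats.spearmanr(x, y).statistic
        count = sum(
            abs(stats.spearmanr(x, np.asarray(perm)).statistic) >= abs(r_obs) - 1e-12
            for perm in itertools.permutations(y)
        )
        oracle = count / math.factorial(5)
        assert exact_spearman_pvalue(x, y) == pytest.approx(oracle, abs=1e-12)


def test_t_approx_close_to_exact_at_n8(rng):
    """At the crossover n the two p-value routes agree within 0.05."""
    for _ in range(5):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        exact = exact_spearman_pvalue(x, y)
        approx = float(stats.spearmanr(x, y).pvalue)
        assert abs(exact - approx) < 0.05


def test_monotone_invariance(rng):
    """r is unchanged by strictly monotone transforms of either column."""
    x = rng.standard_normal(40)
    y = 0.5 * x + rng.standard_normal(40)
    t1 = make_table({"x": x, "y": y})
    t2 = make_table({"x": np.exp(x), "y": y ** 3})
    r1 = spearman_matrix(t1).r.loc["x", "y"]
    r2 = spearman_matrix(t2).r.loc["x", "y"]
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_constant_column_undefined():
    t = make_table({"c": [2.0] * 6, "x": [1, 2, 3, 4, 5, 6.0]})
    corr = spearman_matrix(t)
    assert bool(corr.undefined.loc["c", "x"])
    assert np.isnan(corr.r.loc["c", "x"])


def test_too_few_pairs_undefined():
    t = make_table({"a": [1, 2, np.nan, np.nan], "b": [np.nan, 1.0, 2, 3]})
    corr = spearman_matrix(t)
    assert bool(corr.undefined.loc["a", "b"])


def test_flag_pairs_strict_cutoffs():
    r = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
    p = pd.DataFrame([[0.0, 0.001], [0.001, 0.0]], index=["a", "b"], columns=["a", "b"])
    from sevcms.correlate import CorrelationResult
    corr = CorrelationResult(r=r, p=p, n_pairs=r * 0 + 20, undefined=r.astype(bool) & False)
    report = flag_pairs(corr, StudyConfig())
    assert report.significant_pairs == []  # |r| exactly at the cutoff: not flagged


def test_redundant_subset_of_significant(rng):
    t = make_table({f"p{i}": rng.standard_normal(40) for i in range(3)}
                   | {"p3": rng.standard_normal(40)})
    t.values["p1"] = 0.95 * t.values["p0"] + 0.05 * t.values["p1"]
    report = flag_pairs(spearman_matrix(t), StudyConfig())
    sig = {(d["a"], d["b"]) for d in report.significant_pairs}
    assert report.redundant_set() <= sig


def test_prune_redundant_chain(rng):
    """a ~ b ~ c redundant, a-c not: dropping b resolves both pairs."""
    n = 60
    b = rng.standard_normal(n)
    a = b + 0.45 * rng.standard_normal(n)
    c = b + 0.45 * rng.standard_normal(n)
    t = make_table({"a": a, "b": b, "c": c})
    corr = spearman_matrix(t)
    report = flag_pairs(corr, StudyConfig())
    pairs = report.redundant_set()
    assert ("a", "b") in pairs and ("b", "c") in pairs
    pruned, report = prune_parameters(t, report)
    if ("a", "c") not in pairs:
        assert pruned.parameters == ["a", "c"]
        assert [d["parameter"] for d in report.dropped] == ["b"]


def test_keep_rule_protects_parameter(rng):
    n = 60
    x = rng.standard_normal(n)
    t = make_table({"keepme": x, "dropme": x + 0.2 * rng.standard_normal(n)})
    report = flag_pairs(spearman_matrix(t), StudyConfig())
    pruned, report = prune_parameters(t, report, keep_rules=["keepme"])
    assert pruned.parameters == ["keepme"]
    assert report.dropped[0]["parameter"] == "dropme"
    assert report.dropped[0]["rule"] == "keep_rule"


def test_no_redundant_pairs_after_pruning(rng):
    """Post-condition: survivors contain no redundant pair."""
    n = 50
    base = rng.standard_normal((n, 3))
    vals = {f"b{j}": base[:, j] for j in range(3)}
    for j in range(3):
        vals[f"d{j}"] = base[:, j] + 0.3 * rng.standard_normal(n)
    t = make_table(vals)
    cfg = StudyConfig()
    report = flag_pairs(spearman_matrix(t), cfg)
    pruned, _ = prune_parameters(t, report)
    report2 = flag_pairs(spearman_matrix(pruned), cfg)
    assert report2.redundant_pairs == []


def test_manual_post_correlation_exclusion(rng):
    t = make_table({"a": rng.standard_normal(20), "b": rng.standard_normal(20)})
    report = flag_pairs(spearman_matrix(t), StudyConfig())
    pruned, report = prune_parameters(t, report,
                                      manual_exclusions={"b": "less sensitive assay"})
    assert pruned.parameters == ["a"]
    entry = report.dropped[-1]
    assert entry["reason"] == "manual_post_correlation"
    assert entry["detail"] == "less sensitive assay"


def test_dropped_parameters_each_in_a_redundant_pair_or_manual(rng):
    n = 50
    x = rng.standard_normal(n)
    t = make_table({"a": x, "b": x + 0.2 * rng.standard_normal(n),
                    "c": rng.standard_normal(n)})
    report = flag_pairs(spearman_matrix(t), StudyConfig())
    redundant_members = {m for d in report.redundant_pairs for m in (d["a"], d["b"])}
    _, report = prune_parameters(t, report, manual_exclusions={"c": "reason"})
    for d in report.dropped:
        if d["reason"] == "redundant":
            assert d["parameter"] in redundant_members
        else:
            assert d["reason"] == "manual_post_correlation"
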