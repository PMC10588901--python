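"""Normalization, PCA, resampled ranking and the composite score."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sevcms.datasets import DatasetError, StudyConfig
from sevcms.ranking import (
    BOXCOX_GRID, boxcox_loglik_grid, boxcox_transform, compute_composite_scores,
    fit_normalizer, fit_reference_pca, resampled_parameter_ranking, run_pca,
    select_components, _midrank_ecdf, _stratified_subsample,
)

from conftest import make_table


# -- normalization -----------------------------------------------------------

def test_normalized_output_mean0_sd1(rng):
    t = make_table({"a": rng.standard_normal(50) * 3 + 10,
                    "b": rng.exponential(2.0, 50)})
    norm = fit_normalizer(t)
    out = norm.apply(t.values)
    for col in out:
        assert out[col].mean() == pytest.approx(0.0, abs=1e-10)
        assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_shift_maps_minimum_to_one(rng):
    t = make_table({"a": rng.standard_normal(30) - 5})
    norm = fit_normalizer(t)
    assert float(t.values["a"].min() + norm.shift["a"]) == pytest.approx(1.0)


def test_lambda_near_1_for_normal_data(rng):
    x = rng.standard_normal(500) + 100  # far from 0: already symmetric
    t = make_table({"a": x})
    norm = fit_normalizer(t)
    assert 0.0 <= abs(norm.lam["a"] - 1.0) <= 1.0  # loose sanity
    # the transform must barely change normality
    z = norm.apply(t.values)["a"]
    assert abs(stats.skew(z)) < 0.3


def test_lambda_near_0_recovers_log_for_lognormal(rng):
    x = np.exp(rng.standard_normal(500))
    t = make_table({"a": x})
    norm = fit_normalizer(t)
    # the shift moves support to [1, inf); the optimal lambda is small
    assert norm.lam["a"] < 0.6
    z = norm.apply(t.values)["a"]
    assert abs(stats.skew(z)) < abs(stats.skew(x))


def test_loglik_grid_matches_scipy_oracle(rng):
    x = rng.exponential(1.0, 80) + 0.5
    ours = boxcox_loglik_grid(x)
    theirs = np.array([stats.boxcox_llf(lam, x) for lam in BOXCOX_GRID])
    np.testing.assert_allclose(ours, theirs, rtol=1e-10, atol=1e-8)


def test_boxcox_transform_lambda_zero_is_log():
    x = np.array([1.0, np.e, np.e ** 2])
    np.testing.assert_allclose(boxcox_transform(x, 0.0), [0, 1, 2])


def test_transform_strictly_monotone(rng):
    x = np.sort(rng.exponential(1.0, 50)) + 0.1
    for lam in (-1.5, -0.5, 0.0, 0.5, 2.0):
        y = boxcox_transform(x, lam)
        assert (np.diff(y) > 0).all()


def test_constant_parameter_rejected():
    t = make_table({"a": [3.0] * 10})
    with pytest.raises(DatasetError, match="constant"):
        fit_normalizer(t)


def test_apply_preserves_missing(rng):
    t = make_table({"a": [1.0, np.nan, 3.0, 4.0, 5.0]})
    norm = fit_normalizer(t)
    out = norm.apply(t.values)
    assert np.isnan(out["a"].iloc[1])
    assert out["a"].notna().sum() == 4


# -- PCA ---------------------------------------------------------------------

def test_two_parameter_eigenvalues_closed_form(rng):
    """Eigenvalues of a 2x2 correlation matrix are exactly 1 +/- r."""
    n = 200
    x = rng.standard_normal(n)
    y = 0.7 * x + np.sqrt(1 - 0.49) * rng.standard_normal(n)
    t = make_table({"x": x, "y": y})
    norm = fit_normalizer(t).apply(t.values)
    r = float(np.corrcoef(norm["x"], norm["y"])[0, 1])
    run = run_pca(norm)
    eigvals = run.component_sds ** 2
    np.testing.assert_allclose(sorted(eigvals), sorted([1 - abs(r), 1 + abs(r)]),
                               atol=1e-8)


def test_trace_equals_parameter_count(rng):
    t = make_table({f"p{j}": rng.standard_normal(40) for j in range(6)})
    norm = fit_normalizer(t).apply(t.values)
    run = run_pca(norm)
    assert float((run.component_sds ** 2).sum()) == pytest.approx(6.0, abs=1e-8)
    assert float(run.explained_fraction.sum()) == pytest.approx(1.0, abs=1e-12)


def test_loadings_orthonormal(rng):
    t = make_table({f"p{j}": rng.standard_normal(30) for j in range(5)})
    run = run_pca(fit_normalizer(t).apply(t.values))
    L = run.loadings.to_numpy()
    np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)


def test_scores_match_projection(rng):
    t = make_table({f"p{j}": rng.standard_normal(30) for j in range(4)})
    norm = fit_normalizer(t).apply(t.values)
    run = run_pca(norm)
    X = norm.to_numpy() - run.center.to_numpy()
    np.testing.assert_allclose(run.scores.to_numpy(),
                               X @ run.loadings.to_numpy(), atol=1e-10)


def test_select_components_strict_boundary():
    class Dummy:
        component_sds = np.array([2.0, 1.0, 0.5])
    assert select_components(Dummy(), 1.0) == [0]
    with pytest.raises(DatasetError, match="no component"):
        select_components(Dummy(), 5.0)


def test_reference_pca_imputes_and_transforms(rng):
    vals = {f"p{j}": rng.standard_normal(25) for j in range(4)}
    vals["p0"][3] = np.nan
    t = make_table(vals)
    run = fit_reference_pca(t, StudyConfig())
    out = run.transform(t.values)
    assert out.notna().all().all()
    # training rows reproduce the fitted scores
    np.testing.assert_allclose(out.to_numpy(), run.scores.to_numpy(), atol=1e-10)


def test_incomplete_matrix_rejected():
    df = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]})
    with pytest.raises(DatasetError, match="complete"):
        run_pca(df)


# -- resampled ranking -------------------------------------------------------

def test_ranks_are_permutations(two_group_table, two_group_config):
    cfg = two_group_config
    cfg.n_resamples = 5
    res = resampled_parameter_ranking(two_group_table, cfg)
    p = len(two_group_table.parameters)
    for (_, _), sub in res.records.groupby(["run", "pc"]):
        assert sorted(sub["rank"]) == list(range(1, p + 1))


def test_top_counts_bounded_by_resamples(two_group_table, two_group_config):
    cfg = two_group_config
    cfg.n_resamples = 8
    res = resampled_parameter_ranking(two_group_table, cfg)
    assert (res.top_n_counts(1) <= 8).all()
    assert (res.top_n_counts(5) >= res.top_n_counts(1)).all()


def test_single_full_resample_matches_direct_pca(two_group_table, two_group_config):
    cfg = two_group_config
    cfg.n_resamples = 1
    cfg.train_fraction = 1.0
    res = resampled_parameter_ranking(two_group_table, cfg)
    ref = fit_reference_pca(two_group_table, cfg)
    lead = res.records[(res.records["run"] == 0) & (res.records["pc"] == "PC1")]
    order = lead.sort_values("rank")["parameter"].tolist()
    expected = ref.loadings["PC1"].abs().sort_values(ascending=False).index.tolist()
    assert order == expected


def test_column_permutation_invariance(two_group_table, two_group_config):
    cfg = two_group_config
    cfg.n_resamples = 10
    r1 = resampled_parameter_ranking(two_group_table, cfg, seed=3)
    shuffled = two_group_table.select_parameters(two_group_table.parameters[::-1])
    r2 = resampled_parameter_ranking(shuffled, cfg, seed=3)
    pd.testing.assert_series_equal(r1.mean_rank().sort_index(),
                                   r2.mean_rank().sort_index())


def test_stratified_subsample_respects_groups(rng):
    meta = pd.DataFrame({"animal_id": [str(i) for i in range(20)],
                         "group": ["a"] * 10 + ["b"] * 10})
    rows = _stratified_subsample(meta, 0.8, rng, stratify=True)
    assert len(rows) == 16
    assert (rows < 10).sum() == 8  # exactly 8 from each stratum


def test_stratum_too_small_is_error(rng):
    meta = pd.DataFrame({"animal_id": ["1", "2", "3"],
                         "group": ["a", "a", "b"]})
    with pytest.raises(DatasetError, match="stratum"):
        _stratified_subsample(meta, 0.8, rng, stratify=True)


def test_unknown_scope_rejected(two_group_table, two_group_config):
    cfg = two_group_config
    cfg.n_resamples = 2
    res = resampled_parameter_ranking(two_group_table, cfg)
    with pytest.raises(DatasetError, match="scope"):
        res.mean_rank("bogus")


# -- composite score ---------------------------------------------------------

def test_midrank_ecdf_median_of_nine():
    """The median of 9 training scores maps to (4 + 0.5)/9 = 0.5 per component."""
    train = np.arange(1.0, 10.0)
    assert _midrank_ecdf(train, np.array([5.0]))[0] == pytest.approx(0.5)
    # two such components sum to exactly 1.0
    assert 2 * _midrank_ecdf(train, np.array([5.0]))[0] == pytest.approx(1.0)


def test_midrank_ecdf_range_and_ties():
    train = np.array([1.0, 1.0, 2.0, 3.0])
    out = _midrank_ecdf(train, np.array([0.0, 1.0, 3.0, 99.0]))
    assert out[0] == pytest.approx(0.5 / 4)  # clipped floor, never 0
    assert out[1] == pytest.approx((0 + 0.5 * 2) / 4)
    assert out[2] == pytest.approx((3 + 0.5) / 4)
    assert out[3] == 1.0


def test_composite_in_unit_sum_range(two_group_table, two_group_config):
    ref = fit_reference_pca(two_group_table, two_group_config)
    comp = compute_composite_scores(two_group_table, ref, two_group_config)
    m = len(ref.selected)
    assert comp.n_selected == m
    assert ((comp.scores > 0) & (comp.scores <= m)).all()


def test_composite_orientation_aligns_with_burden(two_group_table, two_group_config):
    ref = fit_reference_pca(two_group_table, two_group_config)
    comp = compute_composite_scores(two_group_table, ref, two_group_config)
    treated = two_group_table.meta["group"] == "treated"
    ids = np.array(two_group_table.animal_ids)
    assert comp.scores[ids[treated]].mean() > comp.scores[ids[~treated]].mean()


def test_composite_invariant_to_loading_sign_flip(two_group_table, two_group_config):
    ref = fit_reference_pca(two_group_table, two_group_config)
    comp1 = compute_composite_scores(two_group_table, ref, two_group_config)
    flipped = fit_reference_pca(two_group_table, two_group_config)
    for pc in flipped.loadings.columns:
        flipped.loadings[pc] *= -1
    flipped.scores *= -1
    comp2 = compute_composite_scores(two_group_table, flipped, two_group_config)
    pd.testing.assert_series_equal(comp1.scores, comp2.scores)


def test_composite_requires_burden_classes(two_group_table):
    cfg = StudyConfig()  # no burden map
    ref = fit_reference_pca(two_group_table, cfg)
    with pytest.raises(DatasetError, match="orient"):
        compute_composite_scores(two_group_table, ref, cfg)


def test_composite_explicit_signs(two_group_table, two_group_config):
    ref = fit_reference_pca(two_group_table, two_group_config)
    signs = {ref.pc_names[j]: 1 for j in ref.selected}
    comp = compute_composite_scores(two_group_table, ref, two_group_config,
                                    pc_signs=signs)
    assert comp.pc_signs == signs
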