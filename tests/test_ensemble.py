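"""The decoding engine: chi-square ranking, wrapper, SVM eval, pools, null."""

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from cfsdecode.ensemble import (
    EnsembleConfig,
    EnsembleDecoder,
    EnsembleResult,
    ModelRun,
    chi_square_rank,
    chi_square_scores,
    fit_eval,
    run_ensemble,
    score_relevance,
    wrapper_select,
)
from cfsdecode.exceptions import (
    ConfigurationError,
    DataError,
    DegenerateModelError,
    StateError,
)
from cfsdecode.spectra import feature_frame, make_trial_rows


# ---------------------------------------------------------------------------
# chi-square filter
# ---------------------------------------------------------------------------

def test_chi_square_matches_hand_computed_contingency():
    """12-row example, 2 quantile bins: oracle is sum (O-E)^2/E by hand.

    Perfect split: bins fall entirely on one class each -> table
    [[6,0],[0,6]], E=3 everywhere, chi2 = 4 * 9/3 = 12.  Partial overlap:
    table [[4,2],[2,4]] -> chi2 = 4 * 1/3 = 4/3.
    """
    y = np.array(["a"] * 6 + ["b"] * 6)
    perfect = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12], dtype=float)
    partial = np.array([1, 2, 3, 4, 9, 10, 5, 6, 7, 8, 11, 12], dtype=float)
    X = np.column_stack([perfect, partial])
    scores = chi_square_scores(X, y, n_bins=2)
    assert scores[0] == pytest.approx(12.0)
    assert scores[1] == pytest.approx(4.0 / 3.0)
    # independent oracle on the same tables
    for table, got in (([[6, 0], [0, 6]], scores[0]),
                       ([[4, 2], [2, 4]], scores[1])):
        chi2 = stats.chi2_contingency(np.array(table), correction=False)[0]
        assert got == pytest.approx(chi2)


def test_label_equal_feature_outranks_independent_feature():
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 30)
    informative = y.astype(float) + 0.0
    noise = rng.permutation(informative)
    X = np.column_stack([noise, informative])
    order = chi_square_rank(X, y, n_bins=4)
    assert order[0] == 1
    scores = chi_square_scores(X, y, n_bins=4)
    assert scores[1] > scores[0]


def test_chi_square_tie_break_is_by_feature_id():
    y = np.array(["a", "b"] * 10)
    X = np.ones((20, 3))  # all constant -> all scores 0
    order = chi_square_rank(X, y)
    assert list(order) == [0, 1, 2]


def test_chi_square_requires_two_classes():
    with pytest.raises(DataError):
        chi_square_scores(np.ones((4, 2)), np.array(["a"] * 4))


# ---------------------------------------------------------------------------
# wrapper selection
# ---------------------------------------------------------------------------

def test_wrapper_selects_perfect_feature_first_and_stops():
    rng = np.random.default_rng(1)
    y = np.repeat([0, 1], 20)
    X = rng.standard_normal((40, 6))
    X[:, 2] = y * 4.0 - 2.0  # perfectly separating
    selected = wrapper_select(X, y, cap=4, inner_folds=2, seed=0)
    assert selected[0] == 2
    assert len(selected) == 1  # accuracy 1.0 cannot improve


def test_wrapper_respects_cap_on_noise():
    rng = np.random.default_rng(2)
    y = np.repeat([0, 1], 15)
    X = rng.standard_normal((30, 12))
    selected = wrapper_select(X, y, cap=5, inner_folds=2, seed=0)
    assert 1 <= len(selected) <= 5


@pytest.mark.parametrize("seed", range(20))
def test_wrapper_accuracy_trace_is_non_decreasing(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=30)
    if len(np.unique(y)) < 2:
        y[0] = 1 - y[0]
    X = rng.standard_normal((30, 8))
    _, trace = wrapper_select(X, y, cap=6, inner_folds=2, seed=seed,
                              return_trace=True)
    assert all(b >= a for a, b in zip(trace, trace[1:]))


# ---------------------------------------------------------------------------
# fit_eval
# ---------------------------------------------------------------------------

def test_separable_training_set_scores_perfectly():
    y = np.repeat(["l", "r"], 10)
    X = np.column_stack([np.repeat([0.0, 1.0], 10), np.zeros(20) + 0.5])
    perf = fit_eval(X, y, X, y, selected=[0])
    assert perf == 1.0


def test_shuffled_labels_score_at_chance():
    """Mean over 100 label-shuffled fits within 3 SE of 1/2."""
    rng = np.random.default_rng(3)
    X = rng.standard_normal((80, 4))
    perfs = []
    for rep in range(100):
        y = rng.permutation(np.repeat(["a", "b"], 40))
        perf = fit_eval(X[:40], y[:40], X[40:], y[40:], selected=[0, 1, 2, 3])
        perfs.append(perf)
    se = 0.5 / np.sqrt(40 * 100)
    assert abs(np.mean(perfs) - 0.5) < 3 * np.sqrt(np.var(perfs) / 100) + 3 * se


def test_constant_feature_dropped_and_all_constant_errors(caplog):
    y = np.repeat(["a", "b"], 10)
    X = np.column_stack([np.repeat([0.0, 1.0], 10), np.full(20, 3.3)])
    perf = fit_eval(X, y, X, y, selected=[0, 1])  # drops the constant
    assert perf == 1.0
    with pytest.raises(DegenerateModelError):
        fit_eval(X, y, X, y, selected=[1])
    with pytest.raises(DataError):
        fit_eval(X, y, X, y, selected=[])


# ---------------------------------------------------------------------------
# run_ensemble + score_relevance
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_decode(small_session, small_features, tiny_ensemble_config):
    rows = make_trial_rows(small_session, small_features,
                           label_mode="response_side", n_ori=4)
    X, y = feature_frame(rows)
    res = run_ensemble(X, y, tiny_ensemble_config, seed=5)
    score_relevance(res)
    return X, y, res


def test_run_and_control_counts_match_config(small_decode, tiny_ensemble_config):
    _, _, res = small_decode
    cfg = tiny_ensemble_config
    assert len(res.runs) == cfg.k_folds * 4 * cfg.n_models_per_method
    assert len(res.controls) == cfg.k_folds * 4 * cfg.n_control_reps


def test_selected_features_stay_in_range(small_decode):
    X, _, res = small_decode
    for run in res.runs + res.controls:
        assert min(run.selected) >= 0 and max(run.selected) < X.shape[1]
        assert len(set(run.selected)) == len(run.selected)


def test_ensemble_is_reproducible(small_decode, tiny_ensemble_config):
    X, y, res = small_decode
    res2 = run_ensemble(X, y, tiny_ensemble_config, seed=5)
    score_relevance(res2)
    assert res.runs == res2.runs
    assert res.controls == res2.controls
    assert res.relevance == res2.relevance


def test_filter_blocks_are_disjoint_per_fold(small_decode):
    _, _, res = small_decode
    by_fold = {}
    for run in res.runs:
        if run.method == "filter":
            by_fold.setdefault(run.fold, []).append(run.selected)
    for sets_ in by_fold.values():
        flat = [f for s in sets_ for f in s]
        assert len(flat) == len(set(flat))


def test_pseudo_random_avoids_filter_and_wrapper_features(small_decode):
    _, _, res = small_decode
    for fold in {r.fold for r in res.runs}:
        fold_runs = [r for r in res.runs if r.fold == fold]
        used = set()
        for r in fold_runs:
            if r.method in ("filter", "wrapper"):
                used |= set(r.selected)
        pseudo = [r for r in fold_runs if r.method == "pseudo_random"]
        # the unused pool here is large, so no fallback top-ups are needed
        for r in pseudo:
            assert not (set(r.selected) & used)


def test_too_few_rows_per_class_rejected(tiny_ensemble_config):
    X = np.random.default_rng(0).standard_normal((6, 5))
    y = np.array(["a", "a", "a", "b", "b", "b"])
    with pytest.raises(ConfigurationError):
        run_ensemble(X, y, tiny_ensemble_config, seed=0)


def test_relevance_weight_is_mean_performance_of_containing_models():
    runs = [
        ModelRun(fold=1, method="random", selected=(0, 1), performance=0.6),
        ModelRun(fold=1, method="random", selected=(1, 2), performance=0.8),
        ModelRun(fold=2, method="random", selected=(2,), performance=0.4),
    ]
    controls = [
        ModelRun(fold=1, method="random", selected=(0,), performance=p,
                 is_control=True)
        for p in np.linspace(0.3, 0.7, 50)
    ]
    res = EnsembleResult(runs=runs, controls=controls, n_classes=2,
                         n_features=4, config=EnsembleConfig(), seed=0)
    rel = score_relevance(res, null_resamples=200, seed=1)
    assert rel[0].weight == pytest.approx(0.6)
    assert rel[1].weight == pytest.approx(0.7)
    assert rel[2].weight == pytest.approx(0.6)
    assert rel[3].weight == 0.0 and rel[3].times_tested == 0
    assert not rel[3].significant


def test_matched_null_threshold_shrinks_with_test_count():
    """null_max(m) is non-increasing in m on average: means of more control
    draws concentrate around the pool mean."""
    rng = np.random.default_rng(7)
    controls = [
        ModelRun(fold=1, method="random", selected=(0,),
                 performance=float(p), is_control=True)
        for p in rng.uniform(0.2, 0.8, size=300)
    ]
    # feature f tested m_f times, with well-separated test counts
    runs = []
    for f, m in enumerate((1, 4, 16, 64)):
        runs.extend(ModelRun(fold=1, method="random", selected=(f,),
                             performance=0.5) for _ in range(m))
    res = EnsembleResult(runs=runs, controls=controls, n_classes=2,
                         n_features=4, config=EnsembleConfig(), seed=0)
    rel = score_relevance(res, null_resamples=500, seed=2)
    thresholds = {r.times_tested: r.null_max for r in rel}
    vals = [thresholds[m] for m in (1, 4, 16, 64)]
    assert all(b < a for a, b in zip(vals, vals[1:]))


def test_empty_pools_raise_state_error():
    res = EnsembleResult(runs=[], controls=[], n_classes=2, n_features=4,
                         config=EnsembleConfig(), seed=0)
    with pytest.raises(StateError):
        score_relevance(res)


def test_null_validity_real_vs_control_indistinguishable_when_shuffled(
        small_features, small_session, tiny_ensemble_config):
    """With shuffled labels, real-model and control performances come from
    the same distribution (rank test on pooled seeds)."""
    rows = make_trial_rows(small_session, small_features,
                           label_mode="response_side", n_ori=4)
    X, y = feature_frame(rows)
    real, ctrl = [], []
    for seed in range(3):
        y_shuf = np.random.default_rng(seed).permutation(y)
        res = run_ensemble(X, y_shuf, tiny_ensemble_config, seed=seed)
        real.extend(r.performance for r in res.runs)
        ctrl.extend(c.performance for c in res.controls)
    p = stats.mannwhitneyu(real, ctrl).pvalue
    assert p > 0.01


def test_decoder_estimator_api(small_session, small_features):
    rows = make_trial_rows(small_session, small_features,
                           label_mode="response_side", n_ori=4)
    X, y = feature_frame(rows)
    dec = EnsembleDecoder(k_folds=4, n_models_per_method=3, n_control_reps=4,
                          wrapper_cap=3, wrapper_pool=6, random_state=3)
    cloned = clone(dec)
    assert cloned.get_params() == dec.get_params()
    dec.fit(X, y)
    assert dec.feature_weights_.shape == (X.shape[1],)
    assert dec.significant_.dtype == bool
    assert len(dec.runs_) == 4 * 4 * 3
    assert len(dec.controls_) == 4 * 4 * 4
    Xt = dec.transform(X)
    assert Xt.shape == (X.shape[0], int(dec.significant_.sum()))
    with pytest.raises(StateError):
        EnsembleDecoder().transform(X)
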