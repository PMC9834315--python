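"""Behavioral statistics: fractions, Friedman, Wilcoxon, bias prediction."""

from dataclasses import replace
from itertools import permutations, product

import numpy as np
import pytest

from cfsdecode.behavior import (
    ExpressionBiasClassifier,
    bias_cv_predict,
    first_percept_fractions,
    fixed_class_predict,
    friedman_test,
    summarize_behavior,
    wilcoxon_signed_rank,
)
from cfsdecode.exceptions import ConfigurationError, DataError, DegenerateTestError
from cfsdecode.synth import make_trial_table


def _forced(trials, rule):
    """Set response sides by a rule(trial) -> 'left' | 'right'."""
    return [replace(t, response_side=rule(t), rt_seconds=1.0) for t in trials]


def _happy_first_rule(t):
    if t.left_class != t.right_class and "happy" in (t.left_class, t.right_class):
        return "left" if t.left_class == "happy" else "right"
    return "left"


@pytest.fixture(scope="module")
def forced_happy_session(small_images):
    trials = make_trial_table(small_images, trials_per_condition=48, seed=1)
    return _forced(trials, _happy_first_rule)


# ---------------------------------------------------------------------------
# fractions
# ---------------------------------------------------------------------------

def test_forced_happy_subject_fractions(forced_happy_session):
    fr = first_percept_fractions(forced_happy_session)
    assert fr.loc["S01", "happy"] == 1.0
    # angry wins only the AN-NE trials where angry is on the left: 24 of 96
    assert fr.loc["S01", "angry"] == pytest.approx(0.25)
    assert fr.loc["S01", "neutral"] == pytest.approx(0.25)


def test_fractions_average_to_half_for_single_subject(small_session):
    fr = first_percept_fractions(small_session)
    # every different-class trial has exactly one winner, equal trial counts
    assert fr.loc["S01"].mean() == pytest.approx(0.5)


def test_fractions_invariant_under_side_swap(small_session):
    swapped = [
        replace(
            t,
            left_image_id=t.right_image_id, right_image_id=t.left_image_id,
            left_class=t.right_class, right_class=t.left_class,
            response_side="right" if t.response_side == "left" else "left",
        )
        for t in small_session
    ]
    a = first_percept_fractions(small_session)
    b = first_percept_fractions(swapped)
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_random_responses_give_balanced_fractions(small_images):
    rng = np.random.default_rng(2)
    counts = {c: [0, 0] for c in ("happy", "angry", "neutral")}
    for rep in range(40):
        trials = make_trial_table(small_images, trials_per_condition=8,
                                  seed=rep)
        forced = _forced(trials,
                         lambda t: "left" if rng.random() < 0.5 else "right")
        fr = first_percept_fractions(forced)
        for c in counts:
            counts[c][0] += fr.loc["S01", c]
            counts[c][1] += 1
    for c, (tot, n) in counts.items():
        se = 0.5 / np.sqrt(n * 32)  # 32 eligible trials per class per rep
        assert abs(tot / n - 0.5) < 3 * se


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

def test_friedman_on_identical_rows_is_zero():
    m = np.tile([0.4, 0.4, 0.4], (6, 1))
    chi2, df, p = friedman_test(m)
    assert chi2 == 0.0 and df == 2 and p == 1.0


def test_friedman_perfect_concordance_closed_form():
    """Every subject ranks the classes in the same strict order:
    chi2 = n (k - 1) = 20 for n = 10, k = 3."""
    m = np.array([[0.2 + 0.01 * i, 0.5 + 0.01 * i, 0.8 + 0.01 * i]
                  for i in range(10)])
    chi2, df, p = friedman_test(m)
    assert chi2 == pytest.approx(20.0)
    assert df == 2


def test_friedman_matches_exhaustive_permutation_oracle():
    """p within 0.02 of the exact within-row permutation distribution on a
    4-subject toy."""
    m = np.array([
        [0.30, 0.55, 0.50],
        [0.40, 0.60, 0.45],
        [0.35, 0.70, 0.40],
        [0.50, 0.65, 0.60],
    ])
    chi2_obs, _, p_obs = friedman_test(m)

    perms = list(permutations(range(3)))
    stats_all = []
    for combo in product(perms, repeat=4):
        mm = np.array([m[i, list(combo[i])] for i in range(4)])
        stats_all.append(friedman_test(mm)[0])
    stats_all = np.array(stats_all)
    p_exact = np.mean(stats_all >= chi2_obs - 1e-12)
    assert abs(p_obs - p_exact) < 0.02


def test_friedman_input_validation():
    with pytest.raises(DataError):
        friedman_test(np.array([[1.0, 2.0, 3.0]]))  # one subject
    bad = np.array([[1.0, np.nan, 2.0], [1.0, 2.0, 3.0]])
    with pytest.raises(DataError):
        friedman_test(bad)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_identical_vectors_degenerate():
    x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    with pytest.raises(DegenerateTestError):
        wilcoxon_signed_rank(x, x)


def test_wilcoxon_all_positive_differences_maximal_rank_sum():
    x = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    z, w, p = wilcoxon_signed_rank(x, y)
    assert w == 15.0
    assert z > 0


def test_wilcoxon_matches_exhaustive_sign_flip_oracle():
    """p within 0.01 of the exact 2^8 sign-flip distribution (8 subjects)."""
    rng = np.random.default_rng(4)
    d = np.round(rng.normal(0.08, 0.1, size=8), 3)
    d[d == 0] = 0.01
    x = 0.5 + d
    y = np.full(8, 0.5)
    z_obs, w_obs, p_obs = wilcoxon_signed_rank(x, y)

    from scipy import stats

    ranks = stats.rankdata(np.abs(d))
    ws = []
    for signs in product([1, -1], repeat=8):
        ws.append(ranks[np.array(signs) > 0].sum())
    ws = np.array(ws)
    mean_w = d.size * (d.size + 1) / 4
    p_exact = np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    assert abs(p_obs - p_exact) < 0.01


def test_wilcoxon_discards_zero_differences():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    y = np.array([1.0, 2.5, 2.0, 5.0, 4.0, 5.0, 6.5])  # one zero difference
    z, w, p = wilcoxon_signed_rank(x, y)
    # non-zero differences: -0.5, +1, -1, +1, +1, +0.5; midranks give the
    # 0.5s (1+2)/2 = 1.5 and the 1s (3+4+5+6)/4 = 4.5
    # -> W+ = 3 * 4.5 + 1.5 = 15
    assert w == pytest.approx(15.0)


# ---------------------------------------------------------------------------
# bias prediction
# ---------------------------------------------------------------------------

def test_bias_classifier_majority_and_tie_behavior():
    clf = ExpressionBiasClassifier(random_state=0)
    pairs = np.array(["HA-AN"] * 10 + ["AN-NE"] * 10)
    outcomes = np.array([1] * 8 + [0] * 2 + [1] * 5 + [0] * 5)
    clf.fit(pairs, outcomes)
    assert clf.bias_["HA-AN"] == (8, 10)
    pred = clf.predict(np.array(["HA-AN"] * 4))
    assert np.all(pred == 1)
    tied = clf.predict(np.array(["AN-NE"] * 200))
    assert 0.3 < tied.mean() < 0.7  # seeded coin flips


def test_forced_happy_bias_prediction_is_significant(forced_happy_session):
    res = bias_cv_predict(forced_happy_session, k_folds=10, seed=0,
                          n_permutations=2000)
    # happy-containing pairs predicted perfectly (96 of 144 trials)
    assert res.overall_accuracy > 0.75
    assert res.perm_p <= 0.001
    assert res.n_trials == 144
    assert len(res.fold_accuracies) == 10


def test_bias_prediction_type_one_error_rate(small_images, small_features):
    """Class-blind responses: permutation p uniform; <= 10% of 50 seeds
    below 0.05."""
    from cfsdecode.synth import ResponseModel, simulate_responses

    model = ResponseModel(driver_wedges=(0,), beta=0.0, lapse=0.0)
    below = 0
    for seed in range(50):
        trials = make_trial_table(small_images, trials_per_condition=16,
                                  seed=seed)
        responded = simulate_responses(trials, small_features, model,
                                       seed=seed)
        res = bias_cv_predict(responded, k_folds=10, seed=seed,
                              n_permutations=500)
        below += res.perm_p < 0.05
    assert below / 50 <= 0.10


def test_bias_uses_only_different_class_trials(forced_happy_session):
    # 6 x 48 design -> 144 different-class trials over 10 folds
    res = bias_cv_predict(forced_happy_session, k_folds=10, seed=3,
                          n_permutations=100)
    assert res.n_trials == 144
    assert len(res.fold_accuracies) == 10
    assert min(res.fold_accuracies) >= 0 and max(res.fold_accuracies) <= 1


def test_bias_cv_requires_two_folds(forced_happy_session):
    with pytest.raises(ConfigurationError):
        bias_cv_predict(forced_happy_session, k_folds=1)


def test_fixed_class_prediction_extremes(forced_happy_session):
    acc, p = fixed_class_predict(forced_happy_session, "happy",
                                 pair_filter=("happy", "angry"), seed=0,
                                 n_permutations=2000)
    assert acc == 1.0 and p <= 0.001
    acc2, p2 = fixed_class_predict(forced_happy_session, "angry",
                                   pair_filter=("happy", "angry"), seed=0,
                                   n_permutations=200)
    assert acc2 == 0.0 and p2 > 0.5
    with pytest.raises(DataError):
        fixed_class_predict(forced_happy_session, "happy",
                            pair_filter=("happy", "happy"))


def test_fixed_class_unbiased_accuracy_near_half(small_images, small_features):
    from cfsdecode.synth import ResponseModel, simulate_responses

    model = ResponseModel(driver_wedges=(0,), beta=0.0, lapse=0.0)
    accs = []
    for seed in range(30):
        trials = make_trial_table(small_images, trials_per_condition=16,
                                  seed=seed)
        responded = simulate_responses(trials, small_features, model,
                                       seed=seed)
        acc, _ = fixed_class_predict(responded, "happy", seed=seed,
                                     n_permutations=50)
        accs.append(acc)
    se = 0.5 / np.sqrt(30 * 64)
    assert abs(np.mean(accs) - 0.5) < 3 * se


def test_group_summary_on_multi_subject_data(small_session, small_features,
                                             small_grid):
    from cfsdecode.synth import ResponseModel, simulate_multi_subject

    driver = tuple(int(i) for i in small_grid.axis_wedges("horizontal"))
    model = ResponseModel(driver_wedges=driver, beta=0.05, lapse=0.05)
    trials = simulate_multi_subject(small_session, small_features, model,
                                    n_subjects=8, beta_sd=0.4, seed=9)
    summary = summarize_behavior(trials)
    assert summary.fractions.shape == (8, 3)
    assert summary.friedman_df == 2
    assert 0 <= summary.friedman_p <= 1
    assert set(summary.pairwise) == {("happy", "angry"), ("happy", "neutral"),
                                     ("angry", "neutral")}
    d = summary.to_dict()
    assert "friedman" in d and "pairwise" in d
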