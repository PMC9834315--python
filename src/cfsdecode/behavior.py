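"""Behavioral statistics on first-percept outcomes.

Covers the non-decoding half of the analysis: per-class fractions of
being reported first (over different-class trials only), a Friedman
ANOVA across the three expression classes with pairwise Wilcoxon
signed-rank follow-ups, and the bias-based prediction test — can which
image class is seen first be predicted purely from each class pair's
majority outcome in held-out data?  Significance of the bias predictor
comes from a within-condition permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from ._rng import subseed, substream
from .exceptions import ConfigurationError, DataError, DegenerateTestError
from .spectra import CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "BehavioralSummary",
    "BiasPredictionResult",
    "first_percept_fractions",
    "friedman_test",
    "wilcoxon_signed_rank",
    "summarize_behavior",
    "ExpressionBiasClassifier",
    "bias_cv_predict",
    "fixed_class_predict",
]


@dataclass(frozen=True)
class BehavioralSummary:
    """Group-level behavioral statistics."""

    fractions: pd.DataFrame  # subjects x classes
    friedman_chi2: float
    friedman_df: int
    friedman_p: float
    pairwise: dict = field(default_factory=dict)  # (c1, c2) -> {z, W, p}

    def to_dict(self) -> dict:
        return {
            "fractions": {
                str(s): {c: float(v) for c, v in row.items()}
                for s, row in self.fractions.iterrows()
            },
            "friedman": {"chi2": self.friedman_chi2, "df": self.friedman_df,
                         "p": self.friedman_p},
            "pairwise": {f"{a}-{b}": stats_ for (a, b), stats_ in self.pairwise.items()},
        }


@dataclass(frozen=True)
class BiasPredictionResult:
    """Cross-validated accuracy of bias-only prediction and its permutation p."""

    fold_accuracies: tuple[float, ...]
    overall_accuracy: float
    perm_p: float
    n_permutations: int
    seed: int
    n_trials: int


def _different_class(trials) -> list:
    return [t for t in trials if t.left_class != t.right_class]


def first_percept_fractions(trials) -> pd.DataFrame:
    """Per subject x class: fraction of different-class trials containing the
    class in which it was reported first.  Same-class pairings are excluded;
    a class with no eligible trial gets NaN (flagged in the log)."""
    eligible = _different_class(trials)
    if not eligible:
        raise DataError("no different-class trials with responses")
    rows = {}
    for t in eligible:
        if t.response_side is None:
            raise DataError(f"trial {t.trial_id} has no response")
        rec = rows.setdefault(t.subject, {c: [0, 0] for c in CLASSES})
        for cls in (t.left_class, t.right_class):
            rec[cls][1] += 1
            if t.response_class == cls:
                rec[cls][0] += 1
    out = {}
    for subject, rec in sorted(rows.items()):
        vals = {}
        for cls in CLASSES:
            wins, n = rec[cls]
            if n == 0:
                logger.warning("subject %s: class %r never presented against a "
                               "different class; fraction undefined", subject, cls)
                vals[cls] = np.nan
            else:
                vals[cls] = wins / n
        out[subject] = vals
    return pd.DataFrame.from_dict(out, orient="index", columns=list(CLASSES))


def friedman_test(matrix: np.ndarray) -> tuple[float, int, float]:
    """Friedman ANOVA over k=3 within-subject conditions.

    Within-subject midranks with tie correction; df = k - 1; p from the
    chi-square upper tail.  Fully tied data (every subject identical
    across conditions) carry no information: chi2 = 0, p = 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 3:
        raise DataError("need >= 2 subjects and >= 3 conditions")
    if np.isnan(matrix).any():
        raise DataError("missing cells are not allowed")
    k = matrix.shape[1]
    if np.all(matrix == matrix[:, [0]]):
        return 0.0, k - 1, 1.0
    chi2, p = stats.friedmanchisquare(*matrix.T)
    return float(chi2), k - 1, float(p)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank test: returns (z, W, p).

    Zero differences are discarded; tied absolute differences get
    midranks; W is the sum of the ranks of the positive differences; z
    uses the normal approximation with tie-corrected variance and no
    continuity correction.  The two-tailed p comes from the exact
    sign-flip distribution for small panels (n <= 14, where the normal
    approximation is off by several hundredths) and from z above that.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n < 5:
        raise DataError(f"need >= 5 non-zero differences; got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var_w <= 0:
        raise DegenerateTestError("zero variance in signed ranks")
    z = (w_pos - mean_w) / np.sqrt(var_w)
    if n <= 14:
        # enumerate all 2^n sign assignments of the midranks
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ ranks
        p = float(np.mean(np.abs(w_all - mean_w) >= abs(w_pos - mean_w) - 1e-12))
    else:
        p = min(float(2.0 * stats.norm.sf(abs(z))), 1.0)
    return float(z), w_pos, p


def summarize_behavior(trials) -> BehavioralSummary:
    """Fractions plus Friedman ANOVA and all pairwise Wilcoxon tests.

    Requires multiple subjects (the group-level tests are within-subject
    across the three classes).
    """
    fractions = first_percept_fractions(trials)
    if fractions.shape[0] < 2:
        raise DataError("group statistics need >= 2 subjects")
    chi2, df, p = friedman_test(fractions.to_numpy())
    pairwise = {}
    for i, a in enumerate(CLASSES):
        for b in CLASSES[i + 1:]:
            try:
                z, w, pw = wilcoxon_signed_rank(fractions[a], fractions[b])
                pairwise[(a, b)] = {"z": z, "W": w, "p": pw}
            except DegenerateTestError:
                pairwise[(a, b)] = {"z": np.nan, "W": np.nan, "p": np.nan}
    return BehavioralSummary(fractions=fractions, friedman_chi2=chi2,
                             friedman_df=df, friedman_p=p, pairwise=pairwise)


# ---------------------------------------------------------------------------
# bias-based prediction
# ---------------------------------------------------------------------------

class ExpressionBiasClassifier(ClassifierMixin, BaseEstimator):
    """Predicts, per class pair, the class most often reported first in training.

    ``fit`` takes the pair (condition) label per trial and a binary
    outcome (whether the alphabetically-first class of the pair was
    reported first); ``predict`` returns the training majority outcome
    for each test trial's pair, falling back to the global training
    majority for unseen pairs and to a seeded coin flip for exact ties.
    """

    def __init__(self, random_state: int = 0):
        self.random_state = random_state

    def fit(self, pairs, outcomes):
        pairs = np.asarray(pairs)
        outcomes = np.asarray(outcomes, dtype=int)
        if pairs.size == 0:
            raise DataError("empty training data")
        self.bias_: dict = {}
        for pair in np.unique(pairs):
            sel = outcomes[pairs == pair]
            self.bias_[pair] = (int(sel.sum()), int(sel.size))
        self.global_bias_ = (int(outcomes.sum()), int(outcomes.size))
        self._rng = substream(self.random_state, "bias-ties")
        return self

    def predict(self, pairs):
        pairs = np.asarray(pairs)
        out = np.empty(pairs.size, dtype=int)
        for i, pair in enumerate(pairs):
            wins, n = self.bias_.get(pair, (None, None))
            if n is None:
                logger.info("pair %r absent from training split; using global bias",
                            pair)
                wins, n = self.global_bias_
            if 2 * wins > n:
                out[i] = 1
            elif 2 * wins < n:
                out[i] = 0
            else:
                out[i] = int(self._rng.random() < 0.5)
        return out


def _pair_outcomes(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per different-class trial: condition, binary outcome, and layout.

    The outcome is 1 when the pair's alphabetically-first class was
    reported first; the layout flag is 1 when that class sat on the left.
    ``outcome = (response_side == left) == layout`` — which is what makes
    response-side shuffles within condition a meaningful null (the
    layout varies across trials, so shuffled sides decouple class from
    outcome while preserving the response-side marginals).
    """
    diff = _different_class(trials)
    if not diff:
        raise DataError("no different-class trials")
    pairs, outcomes, layouts = [], [], []
    for t in diff:
        if t.response_side is None:
            raise DataError(f"trial {t.trial_id} has no response")
        first_cls = min(t.left_class, t.right_class)
        pairs.append(t.condition)
        outcomes.append(int(t.response_class == first_cls))
        layouts.append(int(t.left_class == first_cls))
    return (np.asarray(pairs), np.asarray(outcomes, dtype=int),
            np.asarray(layouts, dtype=int))


def bias_cv_predict(
    trials,
    k_folds: int = 10,
    seed: int = 0,
    n_permutations: int = 10_000,
) -> BiasPredictionResult:
    """Ten-fold cross-validated bias-only prediction with a permutation test.

    Folds are stratified by condition.  In each fold the majority-first
    class of every pair in the 90% training split is predicted for all
    test trials of that pair (exact 50/50 training bias -> seeded coin
    flip).  The permutation null shuffles the response *sides* within
    each condition ``n_permutations`` times (sides are exchangeable
    within a condition when behavior is class-blind; the counterbalanced
    layout then decouples outcome from class) and re-runs the same
    cross-validation; p = (1 + #{perm >= observed}) / (n_permutations + 1).
    """
    if k_folds < 2:
        raise ConfigurationError("k_folds must be >= 2")
    pairs, outcomes, layouts = _pair_outcomes(trials)
    n = outcomes.size
    rng = substream(seed, "bias-perm")

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                          random_state=subseed(seed, "bias-folds"))
    folds = [te for _, te in skf.split(np.zeros(n), pairs)]
    conditions = np.unique(pairs)

    # observed accuracy via the classifier, fold by fold
    fold_accs, correct_total = [], 0
    for f, te in enumerate(folds):
        tr = np.setdiff1d(np.arange(n), te)
        clf = ExpressionBiasClassifier(random_state=subseed(seed, f"bias-tie-{f}"))
        clf.fit(pairs[tr], outcomes[tr])
        pred = clf.predict(pairs[te])
        correct = int((pred == outcomes[te]).sum())
        correct_total += correct
        fold_accs.append(correct / te.size)
    observed = correct_total / n

    # permutation null, vectorized over permutations: shuffle sides within
    # condition, then outcome = (side == layout)
    sides = (outcomes == layouts).astype(np.int8)  # 1 = responded left
    perm_sides = np.tile(sides, (n_permutations, 1))
    for c in conditions:
        cols = np.flatnonzero(pairs == c)
        perm_sides[:, cols] = rng.permuted(perm_sides[:, cols], axis=1)
    perm_outcomes = (perm_sides == layouts[None, :]).astype(np.int8)

    perm_correct = np.zeros(n_permutations)
    for te in folds:
        te_mask = np.zeros(n, dtype=bool)
        te_mask[te] = True
        for c in conditions:
            cmask = pairs == c
            csel = cmask & te_mask
            n_test = int(csel.sum())
            if n_test == 0:
                continue
            n_cond = int(cmask.sum())
            n_train = n_cond - n_test
            cond_wins = perm_outcomes[:, cmask].sum(axis=1)
            test_wins = perm_outcomes[:, csel].sum(axis=1)
            train_wins = cond_wins - test_wins
            if n_train == 0:
                # degenerate split; global-bias fallback is per-permutation
                train_wins = perm_outcomes.sum(axis=1) - test_wins
                n_train = n - n_test
            pred_one = 2 * train_wins > n_train
            pred_zero = 2 * train_wins < n_train
            tie = ~(pred_one | pred_zero)
            add = np.where(pred_one, test_wins, n_test - test_wins).astype(float)
            if tie.any():  # per-trial coin flips for tied training biases
                add[tie] = rng.binomial(n_test, 0.5, size=int(tie.sum()))
            perm_correct += add
    perm_acc = perm_correct / n
    perm_p = float((1 + (perm_acc >= observed - 1e-12).sum()) / (n_permutations + 1))

    return BiasPredictionResult(
        fold_accuracies=tuple(fold_accs),
        overall_accuracy=observed,
        perm_p=perm_p,
        n_permutations=n_permutations,
        seed=seed,
        n_trials=n,
    )


def fixed_class_predict(
    trials,
    predicted_class: str,
    pair_filter: Optional[tuple[str, str]] = None,
    seed: int = 0,
    n_permutations: int = 10_000,
) -> tuple[float, float]:
    """Accuracy of always predicting one class to be perceived first.

    Eligible trials are different-class trials containing
    ``predicted_class`` (optionally restricted to one pairing).  The
    permutation null shuffles response sides within condition, exactly
    as in :func:`bias_cv_predict`.
    """
    eligible = [
        t for t in _different_class(trials)
        if predicted_class in (t.left_class, t.right_class)
    ]
    if pair_filter is not None:
        want = frozenset(pair_filter)
        eligible = [
            t for t in eligible
            if frozenset((t.left_class, t.right_class)) == want
        ]
    if not eligible:
        raise DataError("no eligible trials for fixed-class prediction")
    for t in eligible:
        if t.response_side is None:
            raise DataError(f"trial {t.trial_id} has no response")
    pairs = np.array([t.condition for t in eligible])
    layouts = np.array([int(t.left_class == predicted_class) for t in eligible])
    sides = np.array([int(t.response_side == "left") for t in eligible],
                     dtype=np.int8)
    hits = (sides == layouts)
    n = hits.size
    accuracy = float(hits.mean())

    rng = substream(seed, "fixed-perm")
    perm_sides = np.tile(sides, (n_permutations, 1))
    for c in np.unique(pairs):
        cols = np.flatnonzero(pairs == c)
        perm_sides[:, cols] = rng.permuted(perm_sides[:, cols], axis=1)
    perm_acc = (perm_sides == layouts[None, :]).mean(axis=1)
    perm_p = float((1 + (perm_acc >= accuracy - 1e-12).sum()) / (n_permutations + 1))
    return accuracy, perm_p
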