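"""Ensemble feature-selection decoding with a shuffled-label null.

The engine asks which wedge features carry information about a trial
label (which side was reported first, or which expression an image
shows) by pooling many small SVM models, each allowed to pick its own
feature subset, and scoring every feature by the mean test performance
of the models that used it.

Per stratified fold (default 10) four selection methods each contribute
``n_models_per_method`` (default 10) linear-SVM models:

* ``filter`` — disjoint rank blocks from a chi-square ranking of the
  training split (ranks 1-3, 4-6, ..., 28-30 at defaults);
* ``wrapper`` — forward stepwise inclusion judged by inner
  cross-validated SVM accuracy, diversified over seeded bootstrap
  resamples of the training split (candidates pre-screened by
  chi-square for tractability);
* ``random`` — uniformly drawn sets, sizes matched to the filter sets;
* ``pseudo_random`` — sets drawn from features *unused* by the fold's
  filter and wrapper selections, probing unselected feature space.

For every fold x method, 25 control models repeat the method's
selection and fit under a shuffled labeling of the whole dataset —
10 x 4 x 25 = 1000 chance performances at defaults.  The 25 labelings
are shared across folds and methods (each spans a parallel pipeline),
and controls are tested under their own labeling: a finite dataset
carries chance feature-label associations that transfer from training
to test splits, and the null must include that transfer, not just
pure guessing.  A feature's weight is the mean performance of the real
models containing it; it is significant when that weight exceeds the
maximum of a null distribution of means *matched to how often the
feature was tested* (means of m control draws concentrate as m grows —
the regression-to-the-mean correction).  With the default 10,000 null
resamples the per-feature level is 1e-4 — comfortably below the 0.001
the max-based rule is meant to guarantee — which keeps the whole
384-768-feature family essentially free of false flags under a global
null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._rng import subseed, substream
from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateModelError,
    StateError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "ModelRun",
    "FeatureRelevance",
    "EnsembleResult",
    "chi_square_scores",
    "chi_square_rank",
    "wrapper_select",
    "fit_eval",
    "run_ensemble",
    "score_relevance",
    "EnsembleDecoder",
]

METHODS = ("filter", "wrapper", "random", "pseudo_random")


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunables of the decoding engine (defaults give 400 runs + 1000 controls)."""

    k_folds: int = 10
    n_models_per_method: int = 10
    n_control_reps: int = 25
    filter_block: int = 3
    n_bins: int = 10
    wrapper_cap: int = 8
    wrapper_pool: int = 20
    wrapper_inner_folds: int = 2
    svm_c: float = 1.0
    null_resamples: int = 10_000

    def filter_blocks(self, n_features: int) -> list[tuple[int, int]]:
        """(start, stop) rank ranges of the disjoint filter models.

        Model r takes ranks [r*block, (r+1)*block) of the chi-square
        ordering; disjoint blocks keep each model's performance
        attributable to its own features (a top-ranked feature never
        rides along in the lower models), which is what makes the
        mean-performance weight selective.
        """
        blocks = []
        for r in range(self.n_models_per_method):
            start = r * self.filter_block
            stop = min((r + 1) * self.filter_block, n_features)
            if stop <= start:
                break
            blocks.append((start, stop))
        if not blocks:
            raise ConfigurationError("filter_block too large for feature count")
        return blocks

    def sizes(self, n_features: int) -> tuple[int, ...]:
        """Filter model sizes (random/pseudo-random sets are size-matched)."""
        return tuple(stop - start
                     for start, stop in self.filter_blocks(n_features))


@dataclass(frozen=True)
class ModelRun:
    """One fitted model: its fold, selection method, features, and test accuracy.

    ``stratum`` labels the model's provenance: the method name for real
    models, ``L{j}:{method}`` for controls (j = the shared shuffled
    labeling the control was trained and tested under).
    """

    fold: int
    method: str
    selected: tuple[int, ...]
    performance: float
    is_control: bool = False
    replicate: int = 0
    stratum: str = ""

    def __post_init__(self):
        if not self.selected:
            raise DataError("a model run must select at least one feature")
        if not (0.0 <= self.performance <= 1.0):
            raise DataError("performance must lie in [0, 1]")
        if not self.stratum:
            object.__setattr__(self, "stratum", self.method)


@dataclass(frozen=True)
class FeatureRelevance:
    """Per-feature evidence: how often tested, mean performance, significance."""

    feature_id: int
    times_tested: int
    weight: float
    null_max: float
    significant: bool


@dataclass
class EnsembleResult:
    """All real and control model runs plus (after scoring) per-feature relevance."""

    runs: list[ModelRun]
    controls: list[ModelRun]
    n_classes: int
    n_features: int
    config: EnsembleConfig
    seed: int
    relevance: list[FeatureRelevance] = field(default_factory=list)

    @property
    def control_performances(self) -> np.ndarray:
        return np.array([c.performance for c in self.controls])

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.relevance])

    @property
    def significant_features(self) -> np.ndarray:
        return np.array([r.feature_id for r in self.relevance if r.significant],
                        dtype=int)

    def runs_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": r.fold,
                "method": r.method,
                "replicate": r.replicate,
                "is_control": r.is_control,
                "performance": r.performance,
                "selected": ";".join(map(str, r.selected)),
            }
            for r in self.runs + self.controls
        ]
        return pd.DataFrame(rows)

    def relevance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": r.feature_id,
                    "times_tested": r.times_tested,
                    "weight": r.weight,
                    "null_max": r.null_max,
                    "significant": r.significant,
                }
                for r in self.relevance
            ]
        )


# ---------------------------------------------------------------------------
# chi-square filter ranking
# ---------------------------------------------------------------------------

def chi_square_scores(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Chi-square statistic of (quantile-binned feature) x class, per feature.

    Each feature is discretized into up to ``n_bins`` quantile bins on the
    supplied data (duplicate quantiles collapse); the score is
    sum((O - E)^2 / E) over the bin x class contingency table with
    expected counts from the margins.  Empty bins contribute nothing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    classes, y_idx = np.unique(y, return_inverse=True)
    n_classes = classes.size
    if n_classes < 2:
        raise DataError("need at least 2 classes for chi-square ranking")
    n, p = X.shape

    quantiles = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    edges = np.quantile(X, quantiles, axis=0)  # (n_bins-1, p)
    # bin code per observation per feature: number of edges strictly below
    bins = (X[None, :, :] > edges[:, None, :]).sum(axis=0)  # (n, p)

    n_cells = n_bins * n_classes
    flat = (np.arange(p)[None, :] * n_cells + bins * n_classes + y_idx[:, None])
    table = np.bincount(flat.ravel(), minlength=p * n_cells).reshape(
        p, n_bins, n_classes
    ).astype(float)

    row_sums = table.sum(axis=2, keepdims=True)  # (p, n_bins, 1)
    class_counts = np.bincount(y_idx, minlength=n_classes).astype(float)
    expected = row_sums * class_counts[None, None, :] / n
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return cells.sum(axis=(1, 2))


def chi_square_rank(X: np.ndarray, y: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Feature ids ordered by descending chi-square score, ties by id."""
    scores = chi_square_scores(X, y, n_bins)
    # stable sort on -score keeps ascending feature id within ties
    return np.argsort(-scores, kind="stable")


# ---------------------------------------------------------------------------
# SVM fit/eval and wrapper selection
# ---------------------------------------------------------------------------

def _standardize(train: np.ndarray, *others: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    # tolerance: a constant column's std is rounding noise, not variance
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    sd_safe = np.where(keep, sd, 1.0)
    out = [(train - mean) / sd_safe]
    out.extend((o - mean) / sd_safe for o in others)
    return keep, out


def fit_eval(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    selected: Sequence[int],
    c: float = 1.0,
) -> float:
    """Accuracy of a linear SVM (cost ``c``, one-vs-one for 3 classes) on
    the selected features, standardized by training mean/SD.

    Zero-variance selected features are dropped with a warning; if none
    survive a :class:`DegenerateModelError` is raised.
    """
    selected = np.asarray(list(selected), dtype=int)
    if selected.size == 0:
        raise DataError("selected feature set must be non-empty")
    keep, (tr, te) = _standardize(X_train[:, selected], X_test[:, selected])
    if not keep.all():
        dropped = selected[~keep]
        logger.warning("dropping %d zero-variance feature(s): %s",
                       dropped.size, dropped.tolist())
    if not keep.any():
        raise DegenerateModelError("all selected features have zero training variance")
    clf = SVC(kernel="linear", C=c)
    clf.fit(tr[:, keep], y_train)
    return float(np.mean(clf.predict(te[:, keep]) == y_test))


def wrapper_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    cap: int = 8,
    inner_folds: int = 2,
    seed: int = 0,
    candidates: Optional[Sequence[int]] = None,
    c: float = 1.0,
    return_trace: bool = False,
):
    """Forward stepwise feature inclusion judged by inner-CV SVM accuracy.

    At each step the candidate whose addition maximizes the inner
    cross-validated accuracy is included (ties broken by lowest feature
    id); selection stops when no candidate improves the accuracy or when
    ``cap`` features are selected.  The recorded accuracy trace is
    non-decreasing by construction.
    """
    if cap < 1:
        raise ConfigurationError("cap must be >= 1")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if X_train.shape[0] == 0:
        raise DataError("empty training split")
    pool = (np.arange(X_train.shape[1]) if candidates is None
            else np.asarray(list(candidates), dtype=int))

    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = []
    for tr_idx, te_idx in skf.split(X_train, y_train):
        keep, (tr, te) = _standardize(X_train[tr_idx][:, pool],
                                      X_train[te_idx][:, pool])
        tr[:, ~keep] = 0.0
        te[:, ~keep] = 0.0
        folds.append((tr, te, y_train[tr_idx], y_train[te_idx]))

    def cv_accuracy(col_idx: list[int]) -> float:
        accs = []
        for tr, te, ytr, yte in folds:
            clf = SVC(kernel="linear", C=c)
            clf.fit(tr[:, col_idx], ytr)
            accs.append(np.mean(clf.predict(te[:, col_idx]) == yte))
        return float(np.mean(accs))

    selected_cols: list[int] = []
    best = -np.inf
    trace: list[float] = []
    remaining = list(range(pool.size))
    while len(selected_cols) < cap and remaining:
        step_best, step_col = -np.inf, None
        for col in remaining:
            acc = cv_accuracy(selected_cols + [col])
            if acc > step_best:
                step_best, step_col = acc, col
        if step_col is None or (selected_cols and step_best <= best):
            break
        selected_cols.append(step_col)
        remaining.remove(step_col)
        best = step_best
        trace.append(best)

    selected = tuple(int(pool[c_]) for c_ in selected_cols)
    return (selected, trace) if return_trace else selected


# ---------------------------------------------------------------------------
# the ensemble
# ---------------------------------------------------------------------------

def _bootstrap_rows(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    """Bootstrap row indices guaranteed to contain >= 2 classes."""
    n = y.size
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if np.unique(y[idx]).size >= 2:
            return idx
    raise DataError("could not draw a bootstrap resample with >= 2 classes")


def _draw_unused(
    rng: np.random.Generator,
    size: int,
    unused_all: np.ndarray,
    unused_wrapper: np.ndarray,
    n_features: int,
) -> tuple[int, ...]:
    """Pseudo-random draw from the fold's unused features, with fallback.

    If fewer features than ``size`` escaped both the filter and wrapper
    selections, the remainder is filled from features unused by the
    wrapper only, then (small feature spaces only) from any remaining
    features; both top-ups are logged.
    """
    if unused_all.size >= size:
        return tuple(int(i) for i in rng.choice(unused_all, size=size, replace=False))
    logger.info("pseudo-random pool short (%d < %d); topping up from "
                "wrapper-unused features", unused_all.size, size)
    chosen = unused_all
    for extra_pool in (np.setdiff1d(unused_wrapper, chosen),
                       np.setdiff1d(np.arange(n_features), chosen)):
        need = size - chosen.size
        if need <= 0:
            break
        take = min(need, extra_pool.size)
        if take:
            chosen = np.concatenate(
                [chosen, rng.choice(extra_pool, size=take, replace=False)])
    if chosen.size < size:
        raise ConfigurationError("not enough features for pseudo-random draw")
    return tuple(int(i) for i in chosen)


def run_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    config: EnsembleConfig = EnsembleConfig(),
    seed: int = 0,
) -> EnsembleResult:
    """Run the full pool of selection models and shuffled-label controls.

    Returns an :class:`EnsembleResult` holding ``k_folds x 4 x
    n_models_per_method`` real runs and ``k_folds x 4 x n_control_reps``
    controls (400 and 1000 at defaults).  Relevance is not yet scored;
    see :func:`score_relevance`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DataError("need at least 2 classes")
    if counts.min() < config.k_folds:
        raise ConfigurationError(
            f"every class needs >= k_folds rows; smallest has {counts.min()}"
        )
    n_features = X.shape[1]
    sizes = config.sizes(n_features)
    rng = substream(seed, "ensemble")

    skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                          random_state=subseed(seed, "folds"))
    fold_splits = list(skf.split(X, y))
    fold_blocks = [te for _, te in fold_splits]  # partition of the rows
    runs: list[ModelRun] = []
    controls: list[ModelRun] = []

    def shuffled_labeling() -> np.ndarray:
        # a global random labeling that stays class-balanced within every
        # fold (permuting within the stratified test blocks): controls
        # trained AND tested under it carry the same cross-fold transfer
        # of chance feature-label associations as a real shuffled dataset
        y_c = y.copy()
        for block in fold_blocks:
            y_c[block] = rng.permutation(y_c[block])
        return y_c

    # the n_control_reps labelings are SHARED across folds and methods, so
    # each labeling spans a full parallel pipeline; the matched null can
    # then be sampled labeling-clustered (see score_relevance)
    control_labelings = [shuffled_labeling()
                         for _ in range(config.n_control_reps)]

    for fold, (tr_idx, te_idx) in enumerate(fold_splits, start=1):
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        X_te, y_te = X[te_idx], y[te_idx]
        has_var = X_tr.std(axis=0) > 0  # structurally empty wedges are constant

        def draw_viable(draw_fn, tries: int = 50) -> tuple[int, ...]:
            # random/pseudo-random sets must keep >= 1 non-constant feature
            for _ in range(tries):
                sel = draw_fn()
                if has_var[np.asarray(sel, dtype=int)].any():
                    return sel
            raise ConfigurationError(
                "could not draw a feature set with any training variance"
            )

        def eval_run(selected, method, replicate, is_control=False,
                     y_train=None, y_test=None, stratum="") -> ModelRun:
            perf = fit_eval(X_tr, y_train if y_train is not None else y_tr,
                            X_te, y_test if y_test is not None else y_te,
                            selected, c=config.svm_c)
            return ModelRun(fold=fold, method=method, selected=tuple(selected),
                            performance=perf, is_control=is_control,
                            replicate=replicate, stratum=stratum)

        # --- filter: disjoint rank blocks from one training ranking
        ranking = chi_square_rank(X_tr, y_tr, config.n_bins)
        filter_sets = [tuple(int(i) for i in ranking[start:stop])
                       for start, stop in config.filter_blocks(n_features)]
        for rep, sel in enumerate(filter_sets):
            runs.append(eval_run(sel, "filter", rep, stratum=f"filter{rep}"))

        # --- wrapper: stepwise on bootstrap resamples, chi2-screened pool
        wrapper_sets = []
        for rep in range(config.n_models_per_method):
            boot = _bootstrap_rows(rng, y_tr)
            Xb, yb = X_tr[boot], y_tr[boot]
            pool = chi_square_rank(Xb, yb, config.n_bins)[: config.wrapper_pool]
            sel = wrapper_select(
                Xb, yb, cap=config.wrapper_cap,
                inner_folds=config.wrapper_inner_folds,
                seed=int(rng.integers(0, 2**31 - 1)),
                candidates=pool, c=config.svm_c,
            )
            wrapper_sets.append(sel)
            runs.append(eval_run(sel, "wrapper", rep))

        # --- random: sizes matched to the filter sets
        for rep, k in enumerate(sizes):
            sel = draw_viable(lambda k=k: tuple(
                int(i) for i in rng.choice(n_features, size=k, replace=False)))
            runs.append(eval_run(sel, "random", rep))

        # --- pseudo-random: from features unused by this fold's filter+wrapper
        used_fw = set().union(*filter_sets, *wrapper_sets)
        used_w = set().union(*wrapper_sets)
        unused_all = np.setdiff1d(np.arange(n_features), sorted(used_fw))
        unused_w = np.setdiff1d(np.arange(n_features), sorted(used_w))
        for rep, k in enumerate(sizes):
            sel = draw_viable(lambda k=k: _draw_unused(rng, k, unused_all, unused_w, n_features))
            runs.append(eval_run(sel, "pseudo_random", rep))

        # --- shuffled-label controls: selection re-run per replicate under
        # the replicate's shared shuffled labeling, applied to the fold's
        # training and test rows alike — the null then includes chance
        # feature-label associations that transfer across the folds of a
        # finite dataset, not just pure guessing.
        for method in METHODS:
            for rep in range(config.n_control_reps):
                y_perm = control_labelings[rep]
                y_shuf, y_te_shuf = y_perm[tr_idx], y_perm[te_idx]
                stratum = method
                if method == "filter":
                    block = (rep + fold) % len(sizes)  # spread blocks around
                    start, stop = config.filter_blocks(n_features)[block]
                    sel = tuple(int(i) for i in chi_square_rank(
                        X_tr, y_shuf, config.n_bins)[start:stop])
                    stratum = f"filter{block}"
                elif method == "wrapper":
                    boot = _bootstrap_rows(rng, y_shuf)
                    Xb, yb = X_tr[boot], y_shuf[boot]
                    pool = chi_square_rank(Xb, yb, config.n_bins)[: config.wrapper_pool]
                    sel = wrapper_select(
                        Xb, yb, cap=config.wrapper_cap,
                        inner_folds=config.wrapper_inner_folds,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        candidates=pool, c=config.svm_c,
                    )
                elif method == "random":
                    k = int(rng.choice(sizes))
                    sel = draw_viable(lambda k=k: tuple(
                        int(i) for i in rng.choice(n_features, size=k,
                                                   replace=False)))
                else:  # pseudo_random: label-independent, fold's real unused pool
                    k = int(rng.choice(sizes))
                    sel = draw_viable(
                        lambda k=k: _draw_unused(rng, k, unused_all, unused_w, n_features))
                controls.append(
                    eval_run(sel, method, rep, is_control=True,
                             y_train=y_shuf, y_test=y_te_shuf,
                             stratum=stratum)
                )

    return EnsembleResult(
        runs=runs, controls=controls, n_classes=int(classes.size),
        n_features=n_features, config=config, seed=seed,
    )


def score_relevance(
    result: EnsembleResult,
    null_resamples: Optional[int] = None,
    seed: Optional[int] = None,
) -> list[FeatureRelevance]:
    """Per-feature weight and matched-null significance.

    A feature's weight is the mean performance of the real models that
    contained it.  The matched null respects three properties of how
    the feature was tested:

    * its *test count* m — means of more draws concentrate (the
      regression-to-the-mean correction);
    * the *provenance* of those tests — selection-favored models
      (top filter blocks, wrapper) run above the pool average under the
      null, because selection chases whatever chance associations a
      finite dataset offers; filter models are matched at the rank-block
      level, the other methods at the method level;
    * the *sharing of one labeling* across a feature's models — a
      chance feature-label association transfers to every fold's test
      split at once, so the m null draws for one resample all come from
      a single shuffled labeling's parallel control pipeline rather
      than being independent across the pool.

    Each of ``null_resamples`` (default 10,000) null means therefore
    picks one control labeling and draws, per real model of the
    feature, a performance from that labeling's controls of the same
    stratum.  The feature is significant iff its weight exceeds the
    maximum of its matched null (empirical p below 1/null_resamples).
    Features never tested get weight 0 and are never significant.
    """
    if not result.runs or not result.controls:
        raise StateError("ensemble result must hold non-empty runs and controls")
    if null_resamples is None:
        null_resamples = result.config.null_resamples
    rng = substream(result.seed if seed is None else seed, "null")

    n_features = result.n_features
    perf_sum = np.zeros(n_features)
    tested = np.zeros(n_features, dtype=int)
    strata_count: list[dict[str, int]] = [dict() for _ in range(n_features)]
    for run in result.runs:
        sel = np.asarray(run.selected, dtype=int)
        perf_sum[sel] += run.performance
        tested[sel] += 1
        for f in sel:
            counts = strata_count[f]
            counts[run.stratum] = counts.get(run.stratum, 0) + 1

    weights = np.where(tested > 0, perf_sum / np.maximum(tested, 1), 0.0)

    pool_all = result.control_performances
    grouped: dict[tuple[int, str], list[float]] = {}
    method_pool: dict[tuple[int, str], list[float]] = {}
    labeling_all: dict[int, list[float]] = {}
    for c in result.controls:
        grouped.setdefault((c.replicate, c.stratum), []).append(c.performance)
        method_pool.setdefault((c.replicate, c.method), []).append(c.performance)
        labeling_all.setdefault(c.replicate, []).append(c.performance)
    pools = {k: np.asarray(v) for k, v in grouped.items()}
    by_method = {k: np.asarray(v) for k, v in method_pool.items()}
    labelings = sorted(labeling_all)
    per_labeling = max(null_resamples // len(labelings), 1)

    # cache sums of `count` draws per (labeling, stratum, count)
    sum_cache: dict[tuple[int, str, int], np.ndarray] = {}

    def clustered_sums(j: int, stratum: str, count: int) -> np.ndarray:
        key = (j, stratum, count)
        if key not in sum_cache:
            pool = pools.get((j, stratum))
            if pool is None or pool.size == 0:
                # e.g. a filter block this labeling never visited: fall
                # back to the labeling's method-level, then full, pool
                method = stratum.rstrip("0123456789")
                pool = by_method.get((j, method))
                if pool is None or pool.size == 0:  # pragma: no cover
                    pool = np.asarray(labeling_all.get(j, pool_all))
            draws = rng.choice(pool, size=(per_labeling, count), replace=True)
            sum_cache[key] = draws.sum(axis=1)
        return sum_cache[key]

    null_max = np.zeros(n_features)
    for f in range(n_features):
        m = int(tested[f])
        if m == 0:
            continue
        best = -np.inf
        for j in labelings:
            total = np.zeros(per_labeling)
            for stratum, count in strata_count[f].items():
                total += clustered_sums(j, stratum, count)
            best = max(best, float(total.max()))
        null_max[f] = best / m

    relevance = [
        FeatureRelevance(
            feature_id=int(f),
            times_tested=int(tested[f]),
            weight=float(weights[f]),
            null_max=float(null_max[f]) if tested[f] else 0.0,
            significant=bool(tested[f] and weights[f] > null_max[f]),
        )
        for f in range(n_features)
    ]
    result.relevance = relevance
    return relevance


class EnsembleDecoder(BaseEstimator):
    """Scikit-learn-style front end to the ensemble engine.

    ``fit(X, y)`` runs the full pool of selection models plus controls
    and scores per-feature relevance; fitted attributes expose the
    feature weights, test counts, matched-null thresholds and the
    significance mask.  ``transform`` restricts a matrix to the
    significant features.
    """

    def __init__(self, k_folds: int = 10, n_models_per_method: int = 10,
                 n_control_reps: int = 25, filter_block: int = 3, n_bins: int = 10,
                 wrapper_cap: int = 8, wrapper_pool: int = 20,
                 wrapper_inner_folds: int = 2, svm_c: float = 1.0,
                 null_resamples: int = 10_000, random_state: int = 0):
        self.k_folds = k_folds
        self.n_models_per_method = n_models_per_method
        self.n_control_reps = n_control_reps
        self.filter_block = filter_block
        self.n_bins = n_bins
        self.wrapper_cap = wrapper_cap
        self.wrapper_pool = wrapper_pool
        self.wrapper_inner_folds = wrapper_inner_folds
        self.svm_c = svm_c
        self.null_resamples = null_resamples
        self.random_state = random_state

    def _config(self) -> EnsembleConfig:
        return EnsembleConfig(
            k_folds=self.k_folds,
            n_models_per_method=self.n_models_per_method,
            n_control_reps=self.n_control_reps,
            filter_block=self.filter_block,
            n_bins=self.n_bins,
            wrapper_cap=self.wrapper_cap,
            wrapper_pool=self.wrapper_pool,
            wrapper_inner_folds=self.wrapper_inner_folds,
            svm_c=self.svm_c,
            null_resamples=self.null_resamples,
        )

    def fit(self, X, y):
        self.result_ = run_ensemble(X, y, self._config(), seed=self.random_state)
        self.relevance_ = score_relevance(self.result_)
        self.runs_ = self.result_.runs
        self.controls_ = self.result_.controls
        self.n_features_in_ = self.result_.n_features
        self.feature_weights_ = self.result_.weights
        self.times_tested_ = np.array([r.times_tested for r in self.relevance_])
        self.null_max_ = np.array([r.null_max for r in self.relevance_])
        self.significant_ = np.array([r.significant for r in self.relevance_])
        return self

    def transform(self, X):
        if not hasattr(self, "significant_"):
            raise StateError("EnsembleDecoder is not fitted")
        return np.asarray(X)[:, self.significant_]
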