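"""End-to-end orchestration of the six analyses.

``run_all`` executes, from one seeded config: stimulus synthesis (or
loading of user-supplied PNGs + trial CSV), wedge-feature extraction,
the three ensemble decodes (first-percept side on different-expression
trials, expression class per image, first-percept side on
same-expression trials), the weight-correlation comparisons, the
behavioral statistics, and the bias-based prediction test.  Every stage
writes CSV/JSON under the output directory and the whole run is
bit-reproducible from the config file and master seed.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import __version__
from ._rng import subseed
from .behavior import (
    bias_cv_predict,
    first_percept_fractions,
    fixed_class_predict,
    summarize_behavior,
)
from .ensemble import EnsembleConfig, run_ensemble, score_relevance
from .exceptions import CfsDecodeError, ConfigurationError, DataError
from .grid import FeatureGrid, build_grid
from .io import read_images, read_trials, write_images, write_trials
from .spectra import CLASSES, extract_features, feature_frame, make_trial_rows
from .synth import (
    ResponseModel,
    WedgeEnergySpec,
    calibrate_beta,
    make_stimulus_set,
    make_trial_table,
    simulate_multi_subject,
    simulate_responses,
)
from .weights import average_sides, correlate_weights, split_sides

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RESULT_FILES", "run_all", "subset_trials",
           "default_class_deltas", "resolve_driver_wedges"]

#: The declared result manifest written under <out>/results/.
RESULT_FILES = (
    "trials.csv",
    "image_features.csv",
    "awareness_relevance.csv",
    "expression_relevance.csv",
    "same_expression_relevance.csv",
    "weight_correlations.json",
    "behavior.json",
)


@dataclass
class RunConfig:
    """Flat, YAML-round-trippable configuration of a full run.

    All sub-seeds are derived deterministically from ``master_seed``.
    When ``images_dir``/``trials_csv`` are set, real data replace the
    synthetic stimuli/responses and the synthesis fields are ignored.
    """

    # paths
    out_dir: str = "cfsdecode_out"
    images_dir: Optional[str] = None
    trials_csv: Optional[str] = None
    # feature grid
    n_sf: int = 24
    n_ori: int = 16
    image_side: int = 128
    sf_spacing: str = "log"
    # synthesis
    n_per_class: int = 39
    base_energy: float = 1.0
    identity_sd: float = 0.2
    target_michelson: float = 0.176
    # broad per-class signatures of moderate strength: expressions are
    # widely but modestly decodable, as real face classes are
    class_delta_amount: float = 0.25
    trials_per_condition: int = 48
    # response model (the generative stand-in; drives vertical image
    # contours by default, mirroring the direction of the reported effect)
    driver: Union[str, Sequence[int]] = "horizontal"
    # logistic slope of the response rule; None -> calibrated to the
    # stimulus set so typical driver-energy differences map to ~+-2
    # logits (P(first) ~ 0.1-0.9, predictable but stochastic)
    beta: Optional[float] = None
    beta_logit_sd: float = 2.0
    lapse: float = 0.05
    n_subjects: int = 1
    beta_sd: float = 0.5
    # ensemble
    k_folds: int = 10
    n_models_per_method: int = 10
    n_control_reps: int = 25
    n_bins: int = 10
    wrapper_cap: int = 8
    wrapper_pool: int = 20
    wrapper_inner_folds: int = 2
    svm_c: float = 1.0
    null_resamples: int = 1000
    # behavior
    behavior_k_folds: int = 10
    n_permutations: int = 10_000
    # seeding
    master_seed: int = 0

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            k_folds=self.k_folds,
            n_models_per_method=self.n_models_per_method,
            n_control_reps=self.n_control_reps,
            n_bins=self.n_bins,
            wrapper_cap=self.wrapper_cap,
            wrapper_pool=self.wrapper_pool,
            wrapper_inner_folds=self.wrapper_inner_folds,
            svm_c=self.svm_c,
            null_resamples=self.null_resamples,
        )

    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = asdict(self)
        if not isinstance(data["driver"], str):
            data["driver"] = [int(i) for i in data["driver"]]
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def default_class_deltas(grid: FeatureGrid, amount: float) -> dict[str, np.ndarray]:
    """Planted expression signatures in class-specific orientation sectors.

    Each class gets the same added energy (``amount`` per wedge over one
    full spatial-frequency column) but in its own sector: happy on the
    vertical Fourier axis (90 deg propagation, horizontal image
    contours), angry on the 45 deg diagonal, neutral on the 135 deg
    diagonal.  All are disjoint from the horizontal-axis wedges that
    drive first-percept behavior, so expression content and awareness
    drivers are orthogonal by construction.  Energy-balancing the three
    signatures matters: the final Michelson rescale divides every wedge
    by the image's peak-to-peak range, so a class that added *more total*
    energy would shrink all its other wedges and leak class information
    into every feature.
    """
    if grid.n_ori >= 4 and grid.n_ori % 4 == 0:
        sectors = {
            "happy": grid.n_ori // 2,        # 90 deg
            "angry": grid.n_ori // 4,        # 45 deg
            "neutral": 3 * grid.n_ori // 4,  # 135 deg
        }
    else:  # too coarse for the canonical sectors: any three distinct non-zero
        if grid.n_ori < 4:
            raise ConfigurationError(
                "default class signatures need n_ori >= 4 (sector 0 is "
                "reserved for the response driver)"
            )
        sectors = {"happy": 1, "angry": 2, "neutral": 3}
    deltas = {}
    for cls, sec in sectors.items():
        d = np.zeros((grid.n_sf, grid.n_ori))
        d[:, sec] = amount
        deltas[cls] = d
    return deltas


def resolve_driver_wedges(grid: FeatureGrid, driver) -> tuple[int, ...]:
    """Map a config driver spec to concrete wedge ids.

    ``"horizontal"``/``"vertical"`` name a Fourier axis (sector across
    all SF bands); an explicit sequence of wedge ids passes through.
    """
    if isinstance(driver, str):
        return tuple(int(i) for i in grid.axis_wedges(driver))
    return tuple(int(i) for i in driver)


def subset_trials(trials, mode: str):
    """Filter a trial collection by condition labels, order preserved.

    Modes: ``different_expression``, ``same_expression``,
    ``pair:happy-angry`` (one unordered pairing), ``contains:happy``
    (different-class trials containing a class).  An empty result is
    flagged in the log so the caller can skip the downstream stage.
    """
    if mode == "different_expression":
        out = [t for t in trials if t.left_class != t.right_class]
    elif mode == "same_expression":
        out = [t for t in trials if t.left_class == t.right_class]
    elif mode.startswith("pair:"):
        a, _, b = mode[5:].partition("-")
        for cls in (a, b):
            if cls not in CLASSES:
                raise ConfigurationError(f"unknown class {cls!r} in {mode!r}")
        want = frozenset((a, b))
        out = [t for t in trials
               if frozenset((t.left_class, t.right_class)) == want]
    elif mode.startswith("contains:"):
        cls = mode[9:]
        if cls not in CLASSES:
            raise ConfigurationError(f"unknown class {cls!r} in {mode!r}")
        out = [t for t in trials
               if t.left_class != t.right_class
               and cls in (t.left_class, t.right_class)]
    else:
        raise ConfigurationError(f"unknown subset mode {mode!r}")
    if not out:
        logger.warning("subset %r selected no trials; downstream stage will be "
                       "skipped", mode)
    return out


def _decode(rows, config: RunConfig, seed_name: str):
    X, y = feature_frame(rows)
    result = run_ensemble(X, y, config.ensemble_config(),
                          seed=subseed(config.master_seed, seed_name))
    score_relevance(result)
    return result


def _json_dump(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict (also on disk).

    Output layout: ``<out>/results/`` holds the seven declared result
    files, ``<out>/intermediate/`` the model-run pools, and ``<out>/``
    the echoed config plus ``run_log.json``.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    results_dir = out / "results"
    inter_dir = out / "intermediate"
    results_dir.mkdir(parents=True, exist_ok=True)
    inter_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: dict = {"version": __version__, "python": platform.python_version(),
                 "master_seed": config.master_seed, "stages": {}}

    grid = build_grid(config.n_sf, config.n_ori, config.image_side,
                      config.sf_spacing)

    # --- stimuli ---------------------------------------------------------
    if config.images_dir is not None:
        images = read_images(Path(config.images_dir))
    else:
        spec = WedgeEnergySpec(
            base_energy=config.base_energy,
            class_deltas=default_class_deltas(grid, config.class_delta_amount
                                              * config.base_energy),
            identity_sd=config.identity_sd,
            target_michelson=config.target_michelson,
        )
        images = make_stimulus_set(spec, config.n_per_class, config.image_side,
                                   seed=subseed(config.master_seed, "stimuli"),
                                   grid=grid)
        write_images(images, out / "images")
    log["stages"]["stimuli"] = {"n_images": len(images)}

    # --- features --------------------------------------------------------
    features = {img.image_id: extract_features(img, grid) for img in images}
    log["stages"]["features"] = {
        "n_images": len(features),
        "features_per_image": grid.n_features,
        "features_per_trial": 2 * grid.n_features,
    }

    # --- trials + responses ---------------------------------------------
    if config.trials_csv is not None:
        trials = read_trials(Path(config.trials_csv))
    else:
        table = make_trial_table(images, config.trials_per_condition,
                                 seed=subseed(config.master_seed, "design"))
        driver = resolve_driver_wedges(grid, config.driver)
        beta = (config.beta if config.beta is not None
                else calibrate_beta(features, driver, config.beta_logit_sd))
        model = ResponseModel(driver_wedges=driver, beta=beta,
                              lapse=config.lapse)
        if config.n_subjects == 1:
            trials = simulate_responses(
                table, features, model,
                seed=subseed(config.master_seed, "responses"))
        else:
            trials = simulate_multi_subject(
                table, features, model, config.n_subjects,
                beta_sd=config.beta_sd,
                seed=subseed(config.master_seed, "responses"))
    write_trials(trials, results_dir / "trials.csv")
    subjects = sorted({t.subject for t in trials})
    decode_trials = [t for t in trials if t.subject == subjects[0]]
    log["stages"]["trials"] = {"n_trials": len(trials),
                               "n_subjects": len(subjects),
                               "n_decode_trials": len(decode_trials)}

    # image feature matrix (one row per image, expression label)
    image_rows = make_trial_rows(decode_trials, features,
                                 label_mode="expression", n_ori=config.n_ori)
    image_rows.to_csv(results_dir / "image_features.csv")

    # --- three decodes ---------------------------------------------------
    analyses = {}
    diff_trials = subset_trials(decode_trials, "different_expression")
    same_trials = subset_trials(decode_trials, "same_expression")

    aware_rows = make_trial_rows(diff_trials, features,
                                 label_mode="response_side", n_ori=config.n_ori)
    analyses["awareness"] = _decode(aware_rows, config, "decode-awareness")
    analyses["awareness"].relevance_frame().to_csv(
        results_dir / "awareness_relevance.csv", index=False)

    analyses["expression"] = _decode(image_rows, config, "decode-expression")
    analyses["expression"].relevance_frame().to_csv(
        results_dir / "expression_relevance.csv", index=False)

    if same_trials:
        same_rows = make_trial_rows(same_trials, features,
                                    label_mode="response_side",
                                    n_ori=config.n_ori)
        analyses["same_expression"] = _decode(same_rows, config,
                                              "decode-same-expression")
        analyses["same_expression"].relevance_frame().to_csv(
            results_dir / "same_expression_relevance.csv", index=False)
    else:  # pragma: no cover - only with degenerate user-supplied designs
        (results_dir / "same_expression_relevance.csv").write_text("")

    for name, res in analyses.items():
        res.runs_frame().to_csv(inter_dir / f"{name}_runs.csv", index=False)
        _json_dump({"seed": res.seed, "n_classes": res.n_classes,
                    "n_features": res.n_features,
                    "config": asdict(res.config)},
                   inter_dir / f"{name}_config.json")
        log["stages"][f"decode_{name}"] = {
            "n_runs": len(res.runs),
            "n_controls": len(res.controls),
            "n_significant": int(res.significant_features.size),
        }

    # --- weight correlations --------------------------------------------
    aware_left, aware_right = split_sides(analyses["awareness"].relevance_frame())
    corr: dict = {}
    try:
        lr = correlate_weights(aware_left, aware_right, "untested_either")
        corr["left_vs_right"] = {"r": lr.r, "p": lr.p, "n": lr.n,
                                 "exclusion": "untested_either"}
    except CfsDecodeError as exc:  # pragma: no cover - degenerate weights
        corr["left_vs_right"] = {"error": str(exc)}
    aware_avg = average_sides(aware_left, aware_right)
    expr_weights = analyses["expression"].weights
    try:
        ae = correlate_weights(aware_avg, expr_weights, "untested_either")
        corr["awareness_vs_expression"] = {"r": ae.r, "p": ae.p, "n": ae.n,
                                           "exclusion": "untested_either"}
    except CfsDecodeError as exc:
        corr["awareness_vs_expression"] = {"error": str(exc)}
    sig_expr = set(int(i) for i in analyses["expression"].significant_features)
    if len(sig_expr) >= 3:
        try:
            sub = correlate_weights(aware_avg, expr_weights, sig_expr)
            corr["awareness_vs_expression_significant_subset"] = {
                "r": sub.r, "p": sub.p, "n": sub.n, "exclusion": "subset"}
        except CfsDecodeError as exc:
            corr["awareness_vs_expression_significant_subset"] = {
                "error": str(exc)}
    else:
        corr["awareness_vs_expression_significant_subset"] = {
            "error": f"only {len(sig_expr)} significant expression features"}
    _json_dump(corr, results_dir / "weight_correlations.json")
    log["stages"]["weights"] = {k: v.get("r") for k, v in corr.items()}

    # --- behavioral statistics ------------------------------------------
    behavior: dict = {}
    fractions = first_percept_fractions(trials)
    behavior["fractions"] = {
        str(s): {c: (None if np.isnan(v) else float(v)) for c, v in row.items()}
        for s, row in fractions.iterrows()
    }
    if len(subjects) >= 2:
        summary = summarize_behavior(trials)
        behavior["friedman"] = {"chi2": summary.friedman_chi2,
                                "df": summary.friedman_df,
                                "p": summary.friedman_p}
        behavior["pairwise"] = {
            f"{a}-{b}": stats_ for (a, b), stats_ in summary.pairwise.items()}
    else:
        behavior["friedman"] = None
        behavior["pairwise"] = None
        logger.info("single subject: group-level Friedman/Wilcoxon skipped")

    bias = bias_cv_predict(decode_trials, k_folds=config.behavior_k_folds,
                           seed=subseed(config.master_seed, "bias"),
                           n_permutations=config.n_permutations)
    behavior["bias_prediction"] = {
        "fold_accuracies": list(bias.fold_accuracies),
        "overall_accuracy": bias.overall_accuracy,
        "perm_p": bias.perm_p,
        "n_permutations": bias.n_permutations,
        "n_trials": bias.n_trials,
    }
    for label, kwargs in (
        ("always_happy_vs_angry", {"pair_filter": ("happy", "angry")}),
        ("always_happy_all_pairs", {}),
    ):
        try:
            acc, p = fixed_class_predict(
                decode_trials, "happy", seed=subseed(config.master_seed, label),
                n_permutations=config.n_permutations, **kwargs)
            behavior[label] = {"accuracy": acc, "perm_p": p}
        except DataError as exc:  # pragma: no cover
            behavior[label] = {"error": str(exc)}
    _json_dump(behavior, results_dir / "behavior.json")
    log["stages"]["behavior"] = {
        "n_trials": len(trials),
        "bias_accuracy": bias.overall_accuracy,
        "bias_perm_p": bias.perm_p,
    }

    log["wall_clock_seconds"] = round(time.time() - t0, 3)
    _json_dump(log, out / "run_log.json")
    return {"log": log, "corr": corr, "behavior": behavior,
            "analyses": analyses, "out_dir": str(out)}
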