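"""Synthetic stimuli, trial design and simulated first-percept responses.

Real face photographs are not redistributable, so every downstream stage
is exercised with phase-randomized noise images whose Fourier wedge
energies are controlled exactly: a :class:`WedgeEnergySpec` fixes a base
energy per spatial-frequency x orientation wedge, optional per-class
("expression") additive signatures, and per-image multiplicative
lognormal jitter standing in for identity-level variability (how a given
actor's photographs differ from each other).

Synthesis inverts an FFT whose magnitudes are constant within each wedge
(set so the wedge's summed magnitude hits its target) and whose phases
come from a seeded white-noise field — hence Hermitian-symmetric by
construction.  The final image is linearly rescaled to a target Michelson
contrast (default 0.176, the scale of contrast-ramped suppression
stimuli), which preserves the *relative* wedge-energy pattern while
fixing the presentation contrast.

The trial design emulates a six-condition breaking-continuous-flash-
suppression (bCFS) session: each condition pairs two expression classes
(HA-HA, HA-NE, HA-AN, AN-NE, AN-AN, NE-NE), left/right placement is
counterbalanced within condition, and 48 trials per condition give 288
trials.  Responses (which side was reported first) are drawn from a
lapse-logistic model on the energy difference between the two images over
a chosen set of driver wedges; reaction times are lognormal (median ~3 s)
and carry no signal — they are stored but never analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from ._rng import substream
from .exceptions import ConfigurationError, DataError, DomainError
from .grid import FeatureGrid, build_grid
from .spectra import CLASSES, SpectralFeatureVector

__all__ = [
    "WedgeEnergySpec",
    "GrayImage",
    "TrialRecord",
    "ResponseModel",
    "CONDITIONS",
    "condition_name",
    "make_wedge_noise_image",
    "make_stimulus_set",
    "make_trial_table",
    "simulate_responses",
    "simulate_multi_subject",
    "calibrate_beta",
]

#: The six pairings of expression classes, in the session's canonical order.
CONDITIONS: tuple[tuple[str, str], ...] = (
    ("happy", "happy"),
    ("happy", "neutral"),
    ("happy", "angry"),
    ("angry", "neutral"),
    ("angry", "angry"),
    ("neutral", "neutral"),
)

_ABBREV = {"happy": "HA", "angry": "AN", "neutral": "NE"}


def condition_name(pair: tuple[str, str]) -> str:
    return f"{_ABBREV[pair[0]]}-{_ABBREV[pair[1]]}"


@dataclass(frozen=True)
class WedgeEnergySpec:
    """Target wedge energies for synthetic stimuli.

    ``base_energy`` is an (n_sf, n_ori) array (or scalar, broadcast) of
    non-negative per-wedge energies in arbitrary units; ``class_deltas``
    adds a per-class offset (the planted "expression" signature);
    ``identity_sd`` is the SD of a per-wedge multiplicative lognormal
    jitter applied independently per image; ``target_michelson`` in
    (0, 1] fixes the final image's Michelson contrast.
    """

    base_energy: np.ndarray = 1.0
    class_deltas: Mapping[str, np.ndarray] = field(default_factory=dict)
    identity_sd: float = 0.2
    target_michelson: float = 0.176

    def __post_init__(self):
        if not (0.0 < self.target_michelson <= 1.0):
            raise DomainError("target_michelson must be in (0, 1]")
        if self.identity_sd < 0:
            raise DomainError("identity_sd must be >= 0")

    def wedge_targets(self, grid: FeatureGrid, class_label: Optional[str]) -> np.ndarray:
        """Base + class-delta energies on ``grid``, validated non-negative."""
        base = np.broadcast_to(
            np.asarray(self.base_energy, dtype=float), (grid.n_sf, grid.n_ori)
        ).reshape(-1)
        targets = base.copy()
        if class_label is not None:
            if class_label not in CLASSES:
                raise DomainError(f"unknown class label {class_label!r}")
            delta = self.class_deltas.get(class_label)
            if delta is not None:
                delta = np.broadcast_to(
                    np.asarray(delta, dtype=float), (grid.n_sf, grid.n_ori)
                ).reshape(-1)
                if delta.size != targets.size:
                    raise ConfigurationError(
                        "class_delta shape does not match the feature grid"
                    )
                targets = targets + delta
        if np.any(targets < 0):
            raise DomainError("base_energy + class_delta must be >= 0 in every wedge")
        return targets


@dataclass(frozen=True)
class GrayImage:
    """A square grayscale stimulus with pixels in [0, 1]."""

    pixels: np.ndarray
    image_id: str
    class_label: Optional[str] = None

    def __post_init__(self):
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
            raise DataError("pixels must form a square 2-D array")
        if pixels.shape[0] < 32 or pixels.shape[0] % 2:
            raise DataError("image side must be even and >= 32")
        if not np.all(np.isfinite(pixels)) or pixels.min() < -1e-12 or pixels.max() > 1 + 1e-12:
            raise DataError("pixel values must be finite and within [0, 1]")
        object.__setattr__(self, "pixels", np.clip(pixels, 0.0, 1.0))

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    def michelson_contrast(self) -> float:
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        return 0.0 if hi + lo == 0 else (hi - lo) / (hi + lo)


@dataclass
class TrialRecord:
    """One bCFS trial: the pairing, the two stimuli, and the response."""

    trial_id: int
    condition: str
    left_image_id: str
    right_image_id: str
    left_class: str
    right_class: str
    response_side: Optional[str] = None
    rt_seconds: Optional[float] = None
    subject: str = "S01"

    def __post_init__(self):
        if self.left_image_id == self.right_image_id:
            raise DataError("a trial needs two distinct images")
        if self.response_side not in (None, "left", "right"):
            raise DataError(f"bad response_side {self.response_side!r}")

    @property
    def response_class(self) -> Optional[str]:
        if self.response_side is None:
            return None
        return self.left_class if self.response_side == "left" else self.right_class


@dataclass(frozen=True)
class ResponseModel:
    """Lapse-logistic first-percept model on driver-wedge energy.

    P(left) = (1 - lapse) * sigmoid(beta * (E_left - E_right)) + lapse/2,
    where E is the summed feature energy over ``driver_wedges``.  With
    beta = 0 or lapse = 1 responses are unbiased coin flips; as beta grows
    the side with more driver energy is reported almost surely.
    """

    driver_wedges: tuple[int, ...]
    beta: float = 1.0
    lapse: float = 0.05
    rt_log_median: float = np.log(3.0)
    rt_log_sd: float = 0.35

    def __post_init__(self):
        if self.beta < 0:
            raise DomainError("beta must be >= 0")
        if not (0.0 <= self.lapse <= 1.0):
            raise DomainError("lapse must be in [0, 1]")

    def p_left(self, e_left: float, e_right: float) -> float:
        z = np.clip(self.beta * (e_left - e_right), -700, 700)
        return float((1.0 - self.lapse) / (1.0 + np.exp(-z)) + self.lapse / 2.0)


def make_wedge_noise_image(
    spec: WedgeEnergySpec,
    grid: FeatureGrid,
    side: int,
    class_label: Optional[str] = None,
    seed: int = 0,
    image_id: Optional[str] = None,
) -> GrayImage:
    """Phase-randomized noise image with prescribed wedge energies.

    The target summed magnitude of each wedge is the spec's base energy
    plus the class delta, times a per-wedge lognormal jitter; each
    coefficient in a wedge gets magnitude target/count, and phases are
    taken from a seeded Gaussian white-noise field (so the spectrum is
    Hermitian and the inverse transform real).  Pixels are then linearly
    mapped onto [(1-M)/2, (1+M)/2] so the Michelson contrast is exactly
    ``target_michelson`` (wedge energies all scale by one common factor).
    """
    if side != grid.image_side:
        raise ConfigurationError(
            f"requested side {side} does not match grid side {grid.image_side}"
        )
    rng = np.random.default_rng(seed)
    targets = spec.wedge_targets(grid, class_label)
    if spec.identity_sd > 0:
        jitter = rng.lognormal(
            mean=-0.5 * spec.identity_sd**2, sigma=spec.identity_sd, size=targets.size
        )
        targets = targets * jitter

    counts = grid.wedge_counts()
    per_coeff = np.zeros_like(targets)
    populated = counts > 0
    per_coeff[populated] = targets[populated] / counts[populated]

    magnitude = np.zeros((side, side))
    mask = grid.assignment >= 0
    magnitude[mask] = per_coeff[grid.assignment[mask]]

    # Hermitian phases from a real white-noise field
    noise_fft = np.fft.fftshift(np.fft.fft2(rng.standard_normal((side, side))))
    with np.errstate(invalid="ignore", divide="ignore"):
        phase = np.where(np.abs(noise_fft) > 0, noise_fft / np.abs(noise_fft), 1.0)
    spectrum = np.fft.ifftshift(magnitude * phase)
    raw = np.fft.ifft2(spectrum).real

    lo, hi = raw.min(), raw.max()
    m = spec.target_michelson
    if hi - lo <= 0:
        pixels = np.full_like(raw, 0.5)  # all-zero spectrum -> flat mid-gray
    else:
        pixels = (1 - m) / 2 + m * (raw - lo) / (hi - lo)
    return GrayImage(
        pixels=pixels,
        image_id=image_id or f"synth_{class_label or 'none'}_{seed}",
        class_label=class_label,
    )


def make_stimulus_set(
    spec: WedgeEnergySpec,
    n_per_class: int,
    side: int = 128,
    seed: int = 0,
    grid: Optional[FeatureGrid] = None,
) -> list[GrayImage]:
    """``n_per_class`` images per expression class (3 * n_per_class total).

    Image ids are ``{class}_{index:03d}``; each image gets its class delta
    and its own identity jitter via a per-image sub-seed.
    """
    if n_per_class < 1:
        raise DomainError("n_per_class must be >= 1")
    if grid is None:
        grid = build_grid(image_side=side)
    rng = substream(seed, "stimuli")
    images = []
    for cls in CLASSES:
        for i in range(n_per_class):
            img_seed = int(rng.integers(0, 2**31 - 1))
            images.append(
                make_wedge_noise_image(
                    spec, grid, side, class_label=cls, seed=img_seed,
                    image_id=f"{cls}_{i:03d}",
                )
            )
    return images


def make_trial_table(
    images: Sequence[GrayImage],
    trials_per_condition: int = 48,
    seed: int = 0,
) -> list[TrialRecord]:
    """Six-condition counterbalanced trial table (responses unset).

    Within every condition, each class of the pair appears on the left in
    half the trials (+-1 when the count is odd); image identities are
    sampled uniformly (two distinct identities for same-class pairings).
    """
    if trials_per_condition < 1:
        raise DomainError("trials_per_condition must be >= 1")
    by_class: dict[str, list[str]] = {c: [] for c in CLASSES}
    for img in images:
        if img.class_label in by_class:
            by_class[img.class_label].append(img.image_id)
    for cls, ids in by_class.items():
        if len(ids) < 2:
            raise ConfigurationError(
                f"need >= 2 images of class {cls!r} for same-class conditions"
            )
    rng = substream(seed, "trials")
    trials: list[TrialRecord] = []
    trial_id = 0
    for pair in CONDITIONS:
        name = condition_name(pair)
        n_first_left = (trials_per_condition + 1) // 2
        for i in range(trials_per_condition):
            a, b = pair
            left_cls, right_cls = (a, b) if i < n_first_left else (b, a)
            if left_cls == right_cls:
                left_id, right_id = rng.choice(
                    by_class[left_cls], size=2, replace=False
                )
            else:
                left_id = rng.choice(by_class[left_cls])
                right_id = rng.choice(by_class[right_cls])
            trials.append(
                TrialRecord(
                    trial_id=trial_id,
                    condition=name,
                    left_image_id=str(left_id),
                    right_image_id=str(right_id),
                    left_class=left_cls,
                    right_class=right_cls,
                )
            )
            trial_id += 1
    return trials


def simulate_responses(
    trials: Sequence[TrialRecord],
    features: Mapping[str, SpectralFeatureVector] | Mapping[str, np.ndarray],
    model: ResponseModel,
    seed: int = 0,
) -> list[TrialRecord]:
    """Draw a first-percept side and an RT for every trial (new records)."""
    lookup = {
        k: np.asarray(getattr(v, "values", v), dtype=float)
        for k, v in features.items()
    }
    rng = substream(seed, "responses")
    driver = np.asarray(model.driver_wedges, dtype=int)
    out = []
    for t in trials:
        for image_id in (t.left_image_id, t.right_image_id):
            if image_id not in lookup:
                raise DataError(f"no feature vector for image {image_id!r}")
        e_left = float(lookup[t.left_image_id][driver].sum()) if driver.size else 0.0
        e_right = float(lookup[t.right_image_id][driver].sum()) if driver.size else 0.0
        p_left = model.p_left(e_left, e_right)
        side = "left" if rng.random() < p_left else "right"
        rt = float(rng.lognormal(mean=model.rt_log_median, sigma=model.rt_log_sd))
        out.append(replace(t, response_side=side, rt_seconds=rt))
    return out


def calibrate_beta(
    features: Mapping[str, SpectralFeatureVector] | Mapping[str, np.ndarray],
    driver_wedges: Sequence[int],
    target_logit_sd: float = 2.0,
) -> float:
    """Logistic slope matched to the stimulus ensemble's energy scale.

    Sets beta so that the standard deviation of beta * (E_left - E_right)
    over random image pairs equals ``target_logit_sd`` (default 2: typical
    trials land at P(first) ~ 0.1-0.9, i.e. predictable but stochastic).
    Keeps the response model's operating point invariant to image size or
    contrast units.
    """
    if target_logit_sd <= 0:
        raise DomainError("target_logit_sd must be > 0")
    driver = np.asarray(list(driver_wedges), dtype=int)
    if driver.size == 0:
        raise DomainError("driver_wedges must be non-empty")
    energies = np.array([
        float(np.asarray(getattr(v, "values", v), dtype=float)[driver].sum())
        for v in features.values()
    ])
    sd_diff = float(energies.std() * np.sqrt(2.0))  # sd of E_i - E_j, i != j
    if sd_diff == 0:
        raise DomainError("driver energies are constant; beta is undefined")
    return target_logit_sd / sd_diff


def simulate_multi_subject(
    trials: Sequence[TrialRecord],
    features: Mapping[str, SpectralFeatureVector] | Mapping[str, np.ndarray],
    model: ResponseModel,
    n_subjects: int,
    beta_sd: float = 0.5,
    seed: int = 0,
) -> list[TrialRecord]:
    """Independent response sets for several simulated observers.

    Every subject sees the same trial table; each gets their own
    sensitivity ``beta_s = beta * lognormal(0, beta_sd)`` (multiplicative
    between-subject variability, keeping beta >= 0) and an independent
    response stream.  Returns the flat concatenation of all subjects'
    trials with ``subject`` set to S01..Snn.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    if beta_sd < 0:
        raise DomainError("beta_sd must be >= 0")
    rng = substream(seed, "subjects")
    out: list[TrialRecord] = []
    for s in range(n_subjects):
        beta_s = float(model.beta * rng.lognormal(mean=0.0, sigma=beta_sd))
        subject_model = replace_model(model, beta=beta_s)
        responded = simulate_responses(
            trials, features, subject_model, seed=int(rng.integers(0, 2**31 - 1))
        )
        sid = f"S{s + 1:02d}"
        out.extend(replace(t, subject=sid) for t in responded)
    return out


def replace_model(model: ResponseModel, **changes) -> ResponseModel:
    """dataclasses.replace for :class:`ResponseModel` (re-validates fields)."""
    return replace(model, **changes)
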