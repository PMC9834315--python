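"""Spectral wedge features: image -> 384-vector, trial -> 768-row.

An image's features are the sums of its centered Fourier *magnitude*
spectrum (mean-subtracted image, absolute value, not power) over the
wedges of a :class:`~cfsdecode.grid.FeatureGrid`.  At the default 24 x 16
grid this gives 384 features per image; a two-image trial row concatenates
the left image's 384 features then the right image's 384, for 768 total.

No windowing is applied before the transform and no per-image energy
normalization afterwards: the raw contrast energy is the quantity of
interest, and stimuli are assumed contrast-controlled at presentation.
Scaling an image's pixel contrast by c therefore scales every feature by c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigurationError, DataError
from .grid import FeatureGrid, build_grid

__all__ = [
    "SpectralFeatureVector",
    "magnitude_spectrum",
    "extract_features",
    "make_trial_rows",
    "WedgeFeatureExtractor",
    "feature_frame",
]

CLASSES = ("happy", "angry", "neutral")


@dataclass(frozen=True)
class SpectralFeatureVector:
    """Wedge energies of one image (arbitrary units, all >= 0)."""

    values: np.ndarray
    image_id: str
    grid_id: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise DataError("feature values must be a 1-D vector")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise DataError("feature values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def _as_pixels(image) -> np.ndarray:
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise DataError(f"image must be square 2-D; got shape {pixels.shape}")
    return pixels


def magnitude_spectrum(image) -> np.ndarray:
    """Centered Fourier magnitude spectrum of a (mean-subtracted) image.

    The per-image mean is removed first, so a constant image maps to an
    all-zero spectrum; the returned array is fftshift-centered and
    conjugate-symmetric up to numerical tolerance.
    """
    pixels = _as_pixels(image)
    return np.abs(np.fft.fftshift(np.fft.fft2(pixels - pixels.mean())))


def extract_features(image, grid: FeatureGrid) -> SpectralFeatureVector:
    """Sum the magnitude spectrum over each wedge of ``grid``.

    The total over all wedges equals the sum of the included coefficients'
    magnitudes (the binning is a partition).
    """
    pixels = _as_pixels(image)
    if pixels.shape[0] != grid.image_side:
        raise ConfigurationError(
            f"image side {pixels.shape[0]} does not match grid side {grid.image_side}"
        )
    mag = magnitude_spectrum(pixels)
    mask = grid.assignment >= 0
    values = np.bincount(
        grid.assignment[mask], weights=mag[mask], minlength=grid.n_features
    )
    return SpectralFeatureVector(
        values=values,
        image_id=str(getattr(image, "image_id", "")),
        grid_id=grid.grid_id,
    )


class WedgeFeatureExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: grayscale images -> wedge-energy features.

    Parameters
    ----------
    n_sf, n_ori : int
        Grid resolution (default 24 x 16 -> 384 features).
    image_side : int
        Expected side length of the square input images.
    sf_spacing : {"log", "linear"}
        Spatial-frequency band spacing.

    Attributes
    ----------
    grid_ : FeatureGrid
        The wedge partition built during :meth:`fit`.
    n_features_out_ : int
        ``n_sf * n_ori``.
    """

    def __init__(self, n_sf: int = 24, n_ori: int = 16, image_side: int = 128,
                 sf_spacing: str = "log"):
        self.n_sf = n_sf
        self.n_ori = n_ori
        self.image_side = image_side
        self.sf_spacing = sf_spacing

    def fit(self, X=None, y=None):
        self.grid_ = build_grid(self.n_sf, self.n_ori, self.image_side,
                                self.sf_spacing)
        self.n_features_out_ = self.grid_.n_features
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        """Extract one feature row per image (GrayImage or 2-D array)."""
        if not hasattr(self, "grid_"):
            self.fit()
        return np.vstack([extract_features(img, self.grid_).values for img in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        if not hasattr(self, "grid_"):
            self.fit()
        return np.array(
            [f"f{sf + 1}_{ori + 1}" for sf in range(self.n_sf)
             for ori in range(self.n_ori)]
        )


def _feature_lookup(features) -> Mapping[str, np.ndarray]:
    out = {}
    for key, vec in (features.items() if isinstance(features, Mapping) else
                     ((f.image_id, f) for f in features)):
        out[key] = np.asarray(getattr(vec, "values", vec), dtype=float)
    return out


def make_trial_rows(
    trials: Sequence,
    features,
    label_mode: str = "response_side",
    n_ori: int = 16,
) -> pd.DataFrame:
    """Assemble labeled feature rows for decoding.

    ``response_side`` mode: one row per trial — left-image features in the
    first block, right-image features in the second, labeled by the
    reported side.  ``expression`` mode: one row per *image* (features
    only from that image), labeled by its expression class; the label is
    independent of behavior.

    Returns a DataFrame with feature columns ``f{sf}_{ori}_{L|R}`` (or
    ``f{sf}_{ori}`` in expression mode), a ``label`` column last, and the
    trial or image id as index.
    """
    lookup = _feature_lookup(features)
    n_feat = next(iter(lookup.values())).size
    if n_feat % n_ori != 0:
        n_ori = 1
    base_names = [f"f{i // n_ori + 1}_{i % n_ori + 1}" for i in range(n_feat)]

    if label_mode == "expression":
        seen, rows, labels, ids = set(), [], [], []
        for t in trials:
            for image_id, cls in ((t.left_image_id, t.left_class),
                                  (t.right_image_id, t.right_class)):
                if image_id in seen:
                    continue
                seen.add(image_id)
                if image_id not in lookup:
                    raise DataError(f"no features for image {image_id!r}")
                rows.append(lookup[image_id])
                labels.append(cls)
                ids.append(image_id)
        df = pd.DataFrame(np.vstack(rows), columns=base_names, index=ids)
        df["label"] = labels
        return df

    if label_mode != "response_side":
        raise ConfigurationError(f"unknown label_mode {label_mode!r}")

    rows, labels, ids = [], [], []
    for t in trials:
        if t.response_side is None:
            raise DataError(f"trial {t.trial_id} has no response")
        for image_id in (t.left_image_id, t.right_image_id):
            if image_id not in lookup:
                raise DataError(f"no features for image {image_id!r}")
        rows.append(np.concatenate([lookup[t.left_image_id],
                                    lookup[t.right_image_id]]))
        labels.append(t.response_side)
        ids.append(t.trial_id)
    columns = [f"{n}_L" for n in base_names] + [f"{n}_R" for n in base_names]
    df = pd.DataFrame(np.vstack(rows), columns=columns, index=ids)
    df["label"] = labels
    return df


def feature_frame(rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a trial-row DataFrame into (X, y)."""
    if "label" not in rows.columns:
        raise DataError("feature rows need a 'label' column")
    X = rows.drop(columns="label").to_numpy(dtype=float)
    y = rows["label"].to_numpy()
    return X, y
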