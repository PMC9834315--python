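"""Partition of 2-D Fourier space into spatial-frequency x orientation wedges.

The centered magnitude spectrum of an N x N image is divided into ``n_sf``
annular spatial-frequency bands (log-spaced radii, in cycles/image, from 1
to Nyquist = N/2) crossed with ``n_ori`` orientation sectors of width
180/n_ori degrees, the first sector centered on the horizontal Fourier
axis.  Orientation refers to the *propagation direction* of the waveform:
a coefficient on the horizontal axis describes luminance change from left
to right, i.e. vertical contours in the image.

The DC coefficient and coefficients with radius outside [1, Nyquist] are
excluded; every other coefficient belongs to exactly one wedge, and
conjugate-symmetric coefficient pairs always share a wedge (angles are
taken modulo 180 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["FeatureGrid", "build_grid"]

EXCLUDED = -1


@dataclass(frozen=True)
class FeatureGrid:
    """Wedge assignment of every Fourier coefficient of an N x N image.

    Attributes
    ----------
    n_sf, n_ori : int
        Number of spatial-frequency bands and orientation sectors.
    image_side : int
        Side length N of the (square) images this grid applies to.
    sf_edges : ndarray, shape (n_sf + 1,)
        Band edges in cycles/image, strictly increasing, from 1 to N/2.
    ori_edges : ndarray, shape (n_ori + 1,)
        Sector edges in degrees; the first sector is centered on 0.
    assignment : ndarray of int, shape (N, N)
        Wedge id per fftshift-centered coefficient, ``EXCLUDED`` (-1) for
        the DC term and out-of-range radii.  Wedge id = sf_band * n_ori +
        ori_sector.
    """

    n_sf: int
    n_ori: int
    image_side: int
    sf_edges: np.ndarray
    ori_edges: np.ndarray
    assignment: np.ndarray = field(repr=False)

    @property
    def n_features(self) -> int:
        return self.n_sf * self.n_ori

    @property
    def grid_id(self) -> str:
        return f"grid{self.n_sf}x{self.n_ori}@{self.image_side}"

    def wedge_counts(self) -> np.ndarray:
        """Number of Fourier coefficients assigned to each wedge."""
        inside = self.assignment[self.assignment >= 0]
        return np.bincount(inside, minlength=self.n_features)

    def wedge_id(self, sf_band: int, ori_sector: int) -> int:
        if not (0 <= sf_band < self.n_sf and 0 <= ori_sector < self.n_ori):
            raise ConfigurationError(
                f"wedge ({sf_band}, {ori_sector}) outside {self.n_sf}x{self.n_ori} grid"
            )
        return sf_band * self.n_ori + ori_sector

    def axis_wedges(self, axis: str = "horizontal") -> np.ndarray:
        """Wedge ids on one Fourier axis, across all spatial-frequency bands.

        ``horizontal`` — propagation angle 0 deg (sector 0): light-dark
        change left to right, i.e. *vertical* contours in the image.
        ``vertical`` — propagation angle 90 deg: horizontal image contours.
        Angles are modulo 180 deg, so each axis is a single sector.
        """
        if axis == "horizontal":
            sector = 0
        elif axis == "vertical":
            if self.n_ori % 2:
                raise ConfigurationError("vertical axis needs an even n_ori")
            sector = self.n_ori // 2
        else:
            raise ConfigurationError(f"unknown axis {axis!r}")
        return sector + self.n_ori * np.arange(self.n_sf)


def _frequency_coords(side: int) -> tuple[np.ndarray, np.ndarray]:
    # fftshift-centered integer frequencies: -N/2 .. N/2-1
    f = np.fft.fftshift(np.fft.fftfreq(side, d=1.0 / side))
    fx, fy = np.meshgrid(f, f)  # fx varies along columns, fy along rows
    return fx, fy


def _sf_edges(n_sf: int, nyquist: float, spacing: str) -> np.ndarray:
    """Band edges in cycles/image from 1 to Nyquist.

    ``log`` spacing is log-spaced but with a minimum band width of one
    cycle/image: attainable radii on the integer frequency lattice are
    sparse below ~2 cycles/image (1, sqrt(2), 2, ...), so bands narrower
    than one cycle there would be structurally empty.  The result is
    linear (one cycle per band) at low frequencies and log-spaced above
    the crossover.  ``linear`` is uniformly spaced.
    """
    if spacing == "linear":
        return np.linspace(1.0, nyquist, n_sf + 1)
    if spacing != "log":
        raise ConfigurationError(f"unknown sf spacing {spacing!r}")
    if nyquist < n_sf + 1:
        raise ConfigurationError(
            f"{n_sf} log bands with one-cycle minimum width need Nyquist >= "
            f"{n_sf + 1}; got {nyquist}"
        )
    log_part = np.logspace(0.0, np.log10(nyquist), n_sf + 1)
    lin_part = 1.0 + np.arange(n_sf + 1)
    edges = np.maximum(log_part, lin_part)
    edges[0], edges[-1] = 1.0, nyquist  # exact endpoints
    return edges


def build_grid(
    n_sf: int = 24,
    n_ori: int = 16,
    image_side: int = 128,
    sf_spacing: str = "log",
) -> FeatureGrid:
    """Construct the wedge partition for ``image_side`` x ``image_side`` images.

    Spatial-frequency edges run from 1 cycle/image to Nyquist (log-spaced
    with a one-cycle minimum width by default); orientation sectors have
    uniform width 180/n_ori with the first sector centered on 0 degrees
    (the horizontal Fourier axis).

    Raises
    ------
    ConfigurationError
        If parameters are non-positive, the side is odd or too small, or
        any spatial-frequency band would contain no Fourier coefficient.
    """
    if n_sf < 1 or n_ori < 1:
        raise ConfigurationError("n_sf and n_ori must be >= 1")
    if image_side % 2 != 0 or image_side < 2 * n_sf or image_side < 4:
        raise ConfigurationError(
            f"image_side must be even and >= max(4, 2*n_sf); got {image_side}"
        )

    nyquist = image_side / 2.0
    sf_edges = _sf_edges(n_sf, nyquist, sf_spacing)

    ori_width = 180.0 / n_ori
    ori_edges = -ori_width / 2.0 + ori_width * np.arange(n_ori + 1)

    fx, fy = _frequency_coords(image_side)
    radius = np.hypot(fx, fy)
    # propagation angle modulo 180, then offset so the first sector is
    # centered on 0 degrees
    theta = np.degrees(np.arctan2(fy, fx)) % 180.0

    included = (radius >= sf_edges[0] - 1e-9) & (radius <= sf_edges[-1] + 1e-9)
    included &= radius > 0  # DC excluded

    sf_band = np.clip(np.searchsorted(sf_edges, radius, side="right") - 1, 0, n_sf - 1)
    ori_sector = np.floor((theta + ori_width / 2.0) / ori_width).astype(int) % n_ori

    assignment = np.where(included, sf_band * n_ori + ori_sector, EXCLUDED)

    counts = np.bincount(assignment[assignment >= 0].ravel(), minlength=n_sf * n_ori)
    band_counts = counts.reshape(n_sf, n_ori).sum(axis=1)
    if np.any(band_counts == 0):
        empty = int(np.flatnonzero(band_counts == 0)[0])
        raise ConfigurationError(
            f"spatial-frequency band {empty} contains no Fourier coefficient; "
            f"increase image_side or decrease n_sf"
        )

    return FeatureGrid(
        n_sf=n_sf,
        n_ori=n_ori,
        image_side=image_side,
        sf_edges=sf_edges,
        ori_edges=ori_edges,
        assignment=assignment,
    )
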