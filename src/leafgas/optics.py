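"""Relative chlorophyll-fluorescence profiles from leaf cross-section images.

Absolute fluorescence from epi-illuminated cross sections is not
comparable across samples (exposure differences, Kautsky decay), so all
outputs are relative: depth profiles are normalized per column to the
mesophyll extent and scaled so the maximum bin reads 100%, and lateral
profiles around bundle sheath extensions are normalized per BSE before
averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FluorImage", "NormalizedProfile", "depth_profile", "bse_proximity_profile"]


@dataclass
class FluorImage:
    """Grayscale cross-section image with a mesophyll mask.

    ``intensity`` is ``(rows, cols)`` with rows running through the leaf
    depth; ``mask`` selects mesophyll pixels (epidermis, veins and other
    non-photosynthetic structures excluded).  ``adaxial_top`` records the
    orientation (row 0 at the adaxial edge).
    """

    intensity: np.ndarray
    pixel_size_um: float
    mask: np.ndarray
    adaxial_top: bool = True

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.shape != self.mask.shape:
            raise ValueError("intensity and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mesophyll mask is empty")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    def oriented(self) -> "FluorImage":
        """Return a copy with the adaxial edge at row 0."""
        if self.adaxial_top:
            return self
        return FluorImage(
            self.intensity[::-1].copy(), self.pixel_size_um, self.mask[::-1].copy(), True
        )


@dataclass
class NormalizedProfile:
    """Positions (depth % or signed lateral um) and values (% of maximum)."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def _normalize(values: np.ndarray) -> np.ndarray:
    """Scale so the maximum equals 100; idempotent."""
    m = np.nanmax(values)
    if m <= 0:
        raise ValueError("profile has no positive signal to normalize")
    return values * (100.0 / m)


def _fill_empty_bins(values: np.ndarray, counts: np.ndarray) -> np.ndarray:
    empty = counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} empty depth bin(s) interpolated from neighbours",
            stacklevel=3,
        )
        idx = np.arange(values.size)
        values = values.copy()
        values[empty] = np.interp(idx[empty], idx[~empty], values[~empty])
    return values


def depth_profile(
    image: FluorImage, strip_width_px: int = 75, n_bins: int = 20
) -> NormalizedProfile:
    """Mean relative fluorescence per relative-depth bin along a strip.

    The strip of ``strip_width_px`` columns is centered laterally (the
    whole image is used if narrower).  Each column's mesophyll extent is
    normalized to 0-100% depth independently, so leaves of varying local
    thickness bin consistently; the binned means are then scaled to a
    maximum of 100%.
    """
    img = image.oriented()
    nrow, ncol = img.intensity.shape
    if strip_width_px <= 0:
        raise ValueError("strip width must be positive")
    c0 = max(0, ncol // 2 - strip_width_px // 2)
    c1 = min(ncol, c0 + strip_width_px)

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    rows = np.arange(nrow)
    for c in range(c0, c1):
        m = img.mask[:, c]
        if not m.any():
            continue
        top, bottom = rows[m][0], rows[m][-1]
        extent = bottom - top + 1
        rel = (rows[m] - top + 0.5) / extent  # (0, 1)
        bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        np.add.at(sums, bins, img.intensity[m, c])
        np.add.at(counts, bins, 1)
    if counts.sum() == 0:
        raise ValueError("strip contains no mesophyll pixels")
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means = _fill_empty_bins(means, counts)
    centers = (np.arange(n_bins) + 0.5) / n_bins * 100.0
    return NormalizedProfile(centers, _normalize(means))


def bse_proximity_profile(
    image: FluorImage,
    bse_centers_px,
    half_window_um: float,
    n_bins: int = 20,
) -> NormalizedProfile:
    """Fluorescence vs signed lateral distance from BSE centers.

    Intensity is averaged over masked pixels binned by signed distance
    (negative to the left of a BSE, positive to the right), normalized to
    a maximum of 100% per BSE before averaging across BSEs, then
    renormalized.  Windows extending beyond the image are truncated with
    a warning.
    """
    img = image.oriented()
    centers_px = np.atleast_1d(np.asarray(bse_centers_px, dtype=float))
    if centers_px.size == 0:
        raise ValueError("need at least one BSE center")
    ncol = img.intensity.shape[1]
    half_px = half_window_um / img.pixel_size_um
    edges = np.linspace(-half_window_um, half_window_um, n_bins + 1)

    per_bse = []
    for xc in centers_px:
        if xc - half_px < 0 or xc + half_px > ncol - 1:
            warnings.warn("BSE window exceeds image; truncated", stacklevel=2)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        lo = max(0, int(np.floor(xc - half_px)))
        hi = min(ncol, int(np.ceil(xc + half_px)) + 1)
        for c in range(lo, hi):
            d = (c - xc) * img.pixel_size_um
            b = np.searchsorted(edges, d, side="right") - 1
            if b < 0 or b >= n_bins:
                continue
            m = img.mask[:, c]
            if not m.any():
                continue
            sums[b] += img.intensity[m, c].sum()
            counts[b] += int(m.sum())
        if counts.sum() == 0:
            continue
        with np.errstate(invalid="ignore"):
            vals = sums / counts
        vals = _fill_empty_bins(vals, counts)
        per_bse.append(_normalize(vals))
    if not per_bse:
        raise ValueError("no BSE window contained mesophyll pixels")
    mean_profile = np.mean(per_bse, axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return NormalizedProfile(centers, _normalize(mean_profile))
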