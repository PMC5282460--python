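"""Noise filtering and gray-level quantization ahead of co-occurrence analysis.

The texture operators work on a small number of gray levels (default 32): the
segmented cell is histogram-equalized so that its within-mask intensity
distribution is spread as evenly as possible over those levels. Equalization
pools all spectral bands of one cell by default, which keeps level meanings
comparable along the spectral axis for volumetric pixel pairs; a per-band
mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError
from .imgio import CellMask, MultispectralVolume, check_mask_matches

__all__ = ["QuantizedVolume", "average_filter", "equalize_to_levels", "DEFAULT_LEVELS"]

DEFAULT_LEVELS = 32


@dataclass
class QuantizedVolume:
    """Gray levels in [0, n_levels) for every voxel of a volume.

    Levels outside the cell mask are set to 0 but carry no meaning; the
    co-occurrence stage never pairs out-of-mask pixels.
    """

    levels: np.ndarray  # (n_bands, height, width) integer array
    n_levels: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.levels)
        if arr.ndim != 3 or not np.issubdtype(arr.dtype, np.integer):
            raise ParameterError("levels: expected 3-D integer array")
        if self.n_levels < 2:
            raise ParameterError(f"n_levels: must be >= 2, got {self.n_levels}")
        if arr.size and (arr.min() < 0 or arr.max() >= self.n_levels):
            raise ParameterError(
                f"levels: values must lie in [0, {self.n_levels}), "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        self.levels = arr

    @property
    def n_bands(self) -> int:
        return self.levels.shape[0]

    @property
    def band_shape(self) -> tuple[int, int]:
        return self.levels.shape[1:]


def average_filter(volume: MultispectralVolume, kernel: int = 3) -> MultispectralVolume:
    """Per-band 2-D mean filter with edge replication at the borders.

    Each pixel is replaced by the mean of its ``kernel x kernel``
    neighbourhood, rounded half-up to the nearest integer. ``kernel`` must be
    odd; ``kernel=1`` is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel: must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return MultispectralVolume(volume.intensities.copy(), volume.wavelengths_nm)
    k2 = kernel * kernel
    out = np.empty_like(volume.intensities)
    footprint = np.ones((kernel, kernel), dtype=np.int64)
    for b in range(volume.n_bands):
        # integer neighbourhood sums are exact; round half-up, then clip
        sums = ndimage.correlate(
            volume.intensities[b].astype(np.int64), footprint, mode="nearest"
        )
        out[b] = np.clip((2 * sums + k2) // (2 * k2), 0, 255).astype(np.uint8)
    return MultispectralVolume(out, volume.wavelengths_nm)


def average_filter_image(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Mean-filter a single 2-D float image (same border handling, no rounding)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError(f"kernel: must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return np.asarray(image, dtype=float).copy()
    return ndimage.uniform_filter(np.asarray(image, dtype=float), size=kernel, mode="nearest")


def equalize_to_levels(
    volume: MultispectralVolume,
    mask: CellMask,
    n_levels: int = DEFAULT_LEVELS,
    per_band: bool = False,
) -> QuantizedVolume:
    """Histogram-equalize the within-mask intensities to ``n_levels`` gray levels.

    The mapping is ``level(v) = min(floor(n_levels * CDF(v)), n_levels - 1)``
    where ``CDF`` is the empirical (inclusive) cumulative distribution of the
    masked intensities, pooled over all bands by default or computed per band
    with ``per_band=True``. The mapping is monotone and invariant to strictly
    monotone intensity transforms. Out-of-mask pixels get level 0.
    """
    if n_levels < 2:
        raise ParameterError(f"n_levels: must be >= 2, got {n_levels}")
    m = check_mask_matches(volume, mask)
    if not m.any():
        raise DegenerateInputError("mask is empty: cannot equalize zero pixels")

    out = np.zeros(volume.intensities.shape, dtype=np.int16)
    if per_band:
        for b in range(volume.n_bands):
            out[b][m] = _equalize_values(volume.intensities[b][m], n_levels)
    else:
        pooled = volume.intensities[:, m]  # (n_bands, n_masked)
        out[:, m] = _equalize_values(pooled.ravel(), n_levels).reshape(pooled.shape)
    return QuantizedVolume(out, n_levels)


def _equalize_values(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Map 8-bit intensities to levels via the inclusive empirical CDF."""
    hist = np.bincount(values.ravel(), minlength=256)
    cdf = np.cumsum(hist) / values.size
    lut = np.minimum(np.floor(n_levels * cdf).astype(np.int16), n_levels - 1)
    return lut[values]
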