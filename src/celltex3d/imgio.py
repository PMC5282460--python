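"""I/O and in-memory containers for multispectral volumes, cell masks and manifests.

Coordinate convention (used everywhere in the package): arrays are indexed
``[z, y, x]`` = (band, row, column), 0-based, origin at the top-left pixel.
``x`` grows rightwards (columns), ``y`` grows downwards (rows), ``z`` runs
along the spectral axis in increasing-wavelength order (TIFF page order).
Displacement signs in :mod:`celltex3d.glcm` follow this convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError

__all__ = [
    "MultispectralVolume",
    "CellMask",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_manifest",
    "save_manifest",
]

#: A cell mask is a plain 2-D boolean array (height x width); True = inside cell.
CellMask = np.ndarray

MASK_THRESHOLD = 127  # grayscale values > 127 load as True


@dataclass
class MultispectralVolume:
    """A stack of co-registered 8-bit grayscale bands of one microscopic scene.

    The spectral axis is treated as the third spatial axis of a 3-D image so
    that volumetric texture operators can pair pixels across wavelengths.

    Parameters
    ----------
    intensities : ndarray, shape (n_bands, height, width), uint8
        Band-major pixel data; band order is increasing wavelength.
    wavelengths_nm : ndarray, optional
        Center wavelength of each band in nanometres.
    """

    intensities: np.ndarray
    wavelengths_nm: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ParameterError(
                f"intensities: expected 3-D (band, row, col) array, got {arr.ndim}-D"
            )
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise ParameterError(
                    f"intensities: values must be 8-bit integers in [0, 255], got dtype {arr.dtype}"
                )
        self.intensities = arr
        if self.wavelengths_nm is not None:
            wl = np.asarray(self.wavelengths_nm, dtype=float)
            if wl.shape != (arr.shape[0],):
                raise ParameterError(
                    f"wavelengths_nm: expected {arr.shape[0]} entries, got {wl.shape}"
                )
            self.wavelengths_nm = wl

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[0]

    @property
    def height(self) -> int:
        return self.intensities.shape[1]

    @property
    def width(self) -> int:
        return self.intensities.shape[2]

    @property
    def band_shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def band_mean(self) -> np.ndarray:
        """Mean image across bands, as float64 (height x width)."""
        return self.intensities.mean(axis=0)


def check_mask_matches(volume: MultispectralVolume, mask: CellMask) -> np.ndarray:
    """Validate a mask against a volume and return it as a bool array."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ParameterError(f"mask: expected 2-D array, got {m.ndim}-D")
    if m.shape != volume.band_shape:
        raise ParameterError(
            f"mask: shape {m.shape} does not match volume bands {volume.band_shape}"
        )
    return m.astype(bool)


def load_volume(path: str | os.PathLike) -> MultispectralVolume:
    """Read a multi-page 8-bit grayscale TIFF as a multispectral volume.

    Page order maps to band order (increasing wavelength).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise FormatError(f"{path}: TIFF contains no pages")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"{path}: ragged page sizes {sorted(shapes)}")
    arr = np.stack(pages, axis=0)
    if arr.ndim != 3:
        raise FormatError(f"{path}: pages are not single-channel grayscale")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit pages, got dtype {arr.dtype}")
    return MultispectralVolume(arr)


def save_volume(volume: MultispectralVolume, path: str | os.PathLike) -> None:
    """Write a volume as a multi-page grayscale TIFF, one page per band."""
    tifffile.imwrite(path, volume.intensities, photometric="minisblack")


def load_mask(path: str | os.PathLike) -> CellMask:
    """Read a mask image; grayscale values > 127 become True."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse an RGB(A) encoding of a binary mask
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2-D mask image")
    return arr > MASK_THRESHOLD


def save_mask(mask: CellMask, path: str | os.PathLike) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    m = np.asarray(mask).astype(bool)
    iio.imwrite(path, (m.astype(np.uint8) * 255))


MANIFEST_COLUMNS = ["sample_id", "path_volume", "path_mask", "label"]


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV (sample_id, path_volume, path_mask, label)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    return df[MANIFEST_COLUMNS]


def save_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)
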