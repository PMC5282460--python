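"""Synthetic multispectral cell phantoms with class-dependent texture.

The generator emulates the study conditions the pipeline was designed for:
27 labeled volumes (9 per class) of 16 co-registered 8-bit bands at
512 x 512 pixels, each containing one roughly elliptical abnormal cell on a
smooth, brighter background. The three lesion classes differ only in the
statistics of the intracellular texture, ordered along the benign-to-
malignant continuum:

* benign hyperplasia (BH) — the most homogeneous texture: long correlation
  length, low contrast;
* intraepithelial neoplasia (IN) — intermediate;
* carcinoma (Ca) — the most heterogeneous: short correlation length, high
  contrast.

The texture is a band-correlated Gaussian random field (Gaussian-smoothed
white noise with a shared low-frequency component across bands, emulating
spectral redundancy). The cell boundary is a smooth random-star polygon
(radial harmonic perturbation of a circle) so the active-contour stage is
non-trivially exercised. Everything is driven by one integer seed and is
bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .imgio import (
    MultispectralVolume,
    save_manifest,
    save_mask,
    save_volume,
)

__all__ = [
    "CLASS_PARAMS",
    "PhantomSpec",
    "LabeledSample",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
]

#: Per-class (correlation_length px, contrast_amplitude gray levels) defaults.
#: Ordering encodes the continuum: BH most homogeneous, Ca most heterogeneous.
CLASS_PARAMS: dict[str, tuple[float, float]] = {
    "BH": (8.0, 20.0),
    "IN": (4.0, 35.0),
    "Ca": (2.0, 50.0),
}

#: Mean gray level of the background and of the cell interior (pre-texture).
BACKGROUND_LEVEL = 190.0
CELL_LEVEL = 120.0

#: Fraction of band-to-band shared variance in the texture field.
BAND_CORRELATION = 0.5


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic labeled cell volume.

    ``correlation_length`` (pixels) controls texture smoothness (larger →
    more homogeneous); ``contrast_amplitude`` (gray levels) is the texture
    SD inside the cell. Both default to the class-typical values in
    ``CLASS_PARAMS``. ``jitter`` is the relative (log-normal) intra-class
    spread applied to the two texture parameters, emulating patient-to-
    patient variability. The same spec (including ``seed``) always produces
    bit-identical output.
    """

    class_label: str
    image_size: int = 512
    n_bands: int = 16
    correlation_length: float | None = None
    contrast_amplitude: float | None = None
    cell_radius_fraction: float = 0.3
    jitter: float = 0.15
    background_level: float = BACKGROUND_LEVEL
    cell_level: float = CELL_LEVEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_PARAMS:
            raise ParameterError(
                f"class_label: expected one of {sorted(CLASS_PARAMS)}, got {self.class_label!r}"
            )
        if self.n_bands < 1:
            raise ParameterError(f"n_bands: must be >= 1, got {self.n_bands}")
        if self.image_size < 16:
            raise ParameterError(f"image_size: must be >= 16, got {self.image_size}")
        if not 0.0 < self.cell_radius_fraction < 0.5:
            raise ParameterError(
                f"cell_radius_fraction: must be in (0, 0.5), got {self.cell_radius_fraction}"
            )
        if self.jitter < 0:
            raise ParameterError(f"jitter: must be >= 0, got {self.jitter}")
        cl, ca = self.base_params
        if cl <= 0:
            raise ParameterError(f"correlation_length: must be > 0, got {cl}")
        if ca < 0:
            raise ParameterError(f"contrast_amplitude: must be >= 0, got {ca}")

    @property
    def base_params(self) -> tuple[float, float]:
        cl_default, ca_default = CLASS_PARAMS[self.class_label]
        cl = self.correlation_length if self.correlation_length is not None else cl_default
        ca = self.contrast_amplitude if self.contrast_amplitude is not None else ca_default
        return float(cl), float(ca)


@dataclass
class LabeledSample:
    """One generated volume with its ground-truth mask and class label."""

    volume: MultispectralVolume
    truth_mask: np.ndarray
    label: str
    sample_id: str = ""
    spec: PhantomSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.truth_mask.shape != self.volume.band_shape:
            raise ParameterError(
                f"truth_mask: shape {self.truth_mask.shape} does not match "
                f"volume bands {self.volume.band_shape}"
            )


def _star_mask(rng: np.random.Generator, size: int, radius_fraction: float) -> np.ndarray:
    """A smooth random-star region: a circle with radial harmonic ripple."""
    r0 = radius_fraction * size
    center = size / 2.0 + rng.uniform(-0.04 * size, 0.04 * size, size=2)
    harmonics = np.arange(2, 6)
    amps = rng.uniform(0.0, 0.25, size=harmonics.size) / harmonics
    phases = rng.uniform(0.0, 2.0 * np.pi, size=harmonics.size)
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    phi = np.arctan2(dy, dx)
    radius = r0 * (
        1.0 + sum(a * np.cos(k * phi + ph) for a, k, ph in zip(amps, harmonics, phases))
    )
    return np.hypot(dy, dx) < radius


def _unit_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to zero mean, unit SD."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def generate_phantom(spec: PhantomSpec) -> LabeledSample:
    """Generate one labeled multispectral cell phantom.

    The cell interior carries a band-correlated Gaussian random field with
    the spec's correlation length and contrast; the background is a smooth
    shaded plane with faint large-scale structure. Output is 8-bit with the
    mask marking the cell interior.
    """
    rng = np.random.default_rng(spec.seed)
    n, nb = spec.image_size, spec.n_bands
    cl, ca = spec.base_params
    if spec.jitter > 0:
        cl *= float(np.exp(spec.jitter * rng.standard_normal()))
        ca *= float(np.exp(spec.jitter * rng.standard_normal()))

    mask = _star_mask(rng, n, spec.cell_radius_fraction)

    # smooth background: tilted plane + faint low-frequency structure
    yy, xx = np.mgrid[0:n, 0:n].astype(float) / max(n - 1, 1)
    slope = rng.uniform(-8.0, 8.0, size=2)
    background = spec.background_level + slope[0] * (yy - 0.5) + slope[1] * (xx - 0.5)
    background = background + 4.0 * _unit_field(rng, n, n / 6.0)

    # spectral profile: smooth gentle modulation along the band axis
    t = np.linspace(0.0, 1.0, nb) if nb > 1 else np.zeros(1)
    profile = 1.0 + 0.08 * np.sin(np.pi * t + rng.uniform(0, 2 * np.pi))

    shared = _unit_field(rng, n, cl)
    rho = BAND_CORRELATION if nb > 1 else 0.0
    bands = np.empty((nb, n, n), dtype=np.uint8)
    for b in range(nb):
        indep = _unit_field(rng, n, cl) if nb > 1 else np.zeros((n, n))
        texture = ca * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep)
        img = background * profile[b]
        img = np.where(mask, spec.cell_level * profile[b] + texture, img)
        img = img + rng.normal(0.0, 1.5, size=(n, n))  # sensor noise floor
        bands[b] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return LabeledSample(
        volume=MultispectralVolume(bands),
        truth_mask=mask,
        label=spec.class_label,
        spec=spec,
    )


def generate_cohort(
    n_per_class: int,
    base_seed: int = 0,
    template: PhantomSpec | None = None,
    **overrides,
) -> list[LabeledSample]:
    """Generate a balanced labeled cohort (3 x ``n_per_class`` samples).

    Samples are ordered class-major (all BH, then IN, then Ca) and the
    per-sample seed is ``base_seed + sample_index``, so the whole cohort is
    reproducible from one integer. Keyword overrides (``image_size``,
    ``n_bands``, ...) apply to every sample.
    """
    if n_per_class < 1:
        raise ParameterError(f"n_per_class: must be >= 1, got {n_per_class}")
    samples = []
    idx = 0
    for label in CLASS_PARAMS:
        base = template if template is not None else PhantomSpec(class_label=label)
        for k in range(n_per_class):
            spec = replace(base, class_label=label, seed=base_seed + idx, **overrides)
            sample = generate_phantom(spec)
            sample.sample_id = f"{label}{k:02d}"
            samples.append(sample)
            idx += 1
    return samples


def write_cohort(samples: list[LabeledSample], outdir: str | os.PathLike) -> str:
    """Write volumes (multi-page TIFF), masks (PNG) and the manifest CSV.

    Returns the manifest path.
    """
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for s in samples:
        vol_path = os.path.join(outdir, f"{s.sample_id}_volume.tif")
        mask_path = os.path.join(outdir, f"{s.sample_id}_mask.png")
        save_volume(s.volume, vol_path)
        save_mask(s.truth_mask, mask_path)
        rows.append(
            {
                "sample_id": s.sample_id,
                "path_volume": vol_path,
                "path_mask": mask_path,
                "label": s.label,
            }
        )
    manifest_path = os.path.join(outdir, "manifest.csv")
    save_manifest(pd.DataFrame(rows), manifest_path)
    return manifest_path
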