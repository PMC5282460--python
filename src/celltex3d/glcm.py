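"""Masked gray-level co-occurrence matrices in 2-D and 3-D.

A GLCM ``P_{d,θ}(i, j)`` counts ordered voxel pairs ``(p, p + t)`` whose gray
levels are ``i`` and ``j``, for a fixed translation vector
``t = d * (ux, uy, uz)`` built from a unit direction and an integer offset
``d``. Both endpoints must fall inside the image and inside the cell mask
(the mask applies at every band), so the statistics describe the cell alone.

Directions follow the package coordinate convention (x = column, y = row,
z = band; see :mod:`celltex3d.imgio`). In 2-D there are 4 unit directions; in
3-D the 26-neighborhood of a voxel splits into 13 ± pairs and one direction
per pair suffices, because the matrix for ``-t`` is the transpose of the
matrix for ``t``. Each direction keeps its own matrix (no symmetrization);
features are computed on the normalized (probability) form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyGLCMError, ParameterError
from .imgio import CellMask
from .preprocess import QuantizedVolume

__all__ = [
    "Displacement",
    "GLCM",
    "directions_2d",
    "directions_3d",
    "compute_glcm",
    "glcm_count",
    "DEFAULT_OFFSETS",
]

DEFAULT_OFFSETS = (1, 2, 4, 8)


@dataclass(frozen=True)
class Displacement:
    """A translation vector: unit direction scaled by an integer offset.

    ``dx``, ``dy``, ``dz`` are the already-scaled components;
    ``direction_id`` indexes the direction within its geometry's canonical
    ordering (see :func:`directions_2d` / :func:`directions_3d`).
    """

    dx: int
    dy: int
    dz: int
    offset: int = 1
    direction_id: int = 0

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise ParameterError(f"offset: must be >= 1, got {self.offset}")
        unit = (self.dx // self.offset, self.dy // self.offset, self.dz // self.offset)
        if any(u * self.offset != c for u, c in zip(unit, (self.dx, self.dy, self.dz))):
            raise ParameterError(
                f"displacement ({self.dx},{self.dy},{self.dz}) is not a multiple "
                f"of offset {self.offset}"
            )
        if any(u not in (-1, 0, 1) for u in unit) or unit == (0, 0, 0):
            raise ParameterError(
                f"unit direction {unit}: components must be in {{-1,0,1}}, not all zero"
            )

    @property
    def unit(self) -> tuple[int, int, int]:
        return (self.dx // self.offset, self.dy // self.offset, self.dz // self.offset)

    def scaled(self, offset: int) -> "Displacement":
        """The same unit direction at a different offset."""
        ux, uy, uz = self.unit
        return Displacement(ux * offset, uy * offset, uz * offset, offset, self.direction_id)

    def negated(self) -> "Displacement":
        return Displacement(-self.dx, -self.dy, -self.dz, self.offset, self.direction_id)

    @property
    def name(self) -> str:
        return f"d{self.offset}_dir{self.direction_id:02d}"


# Canonical unit directions. 2-D: the four standard co-occurrence angles.
_UNITS_2D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),  # 0 deg
    (1, 1, 0),  # 45 deg
    (0, 1, 0),  # 90 deg
    (-1, 1, 0),  # 135 deg
)

# 3-D: the 13 half-space representatives of the 26-neighborhood — the four
# in-plane directions above, then the nine directions that step one band up.
_UNITS_3D: tuple[tuple[int, int, int], ...] = _UNITS_2D + (
    (0, 0, 1),
    (1, 0, 1),
    (-1, 0, 1),
    (0, 1, 1),
    (0, -1, 1),
    (1, 1, 1),
    (-1, 1, 1),
    (1, -1, 1),
    (-1, -1, 1),
)


def directions_2d(offset: int = 1) -> list[Displacement]:
    """The 4 in-plane unit directions, scaled by ``offset``."""
    return [
        Displacement(ux * offset, uy * offset, uz * offset, offset, i)
        for i, (ux, uy, uz) in enumerate(_UNITS_2D)
    ]


def directions_3d(offset: int = 1) -> list[Displacement]:
    """The 13 volumetric unit directions (one per ± pair of the
    26-neighborhood), scaled by ``offset``."""
    return [
        Displacement(ux * offset, uy * offset, uz * offset, offset, i)
        for i, (ux, uy, uz) in enumerate(_UNITS_3D)
    ]


@dataclass
class GLCM:
    """One co-occurrence table in count form, with its provenance.

    ``counts[i, j]`` is the number of ordered in-mask pairs whose gray levels
    are ``(i, j)`` (0-based levels). The probability form divides by the
    total count; an empty matrix (zero valid pairs) is flagged and refused by
    the feature stage.
    """

    counts: np.ndarray
    displacement: Displacement
    n_levels: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.n_levels, self.n_levels):
            raise ParameterError(
                f"counts: expected ({self.n_levels}, {self.n_levels}), got {c.shape}"
            )
        if not np.issubdtype(c.dtype, np.integer) or (c < 0).any():
            raise ParameterError("counts: must be non-negative integers")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def probabilities(self) -> np.ndarray:
        """Normalized table summing to 1; raises on an empty matrix."""
        t = self.total
        if t == 0:
            raise EmptyGLCMError(
                f"GLCM for {self.displacement.name} holds zero valid pairs"
            )
        return self.counts / t


def compute_glcm(q: QuantizedVolume, mask: CellMask, disp: Displacement) -> GLCM:
    """Count in-mask ordered level pairs at a fixed displacement.

    A pair ``(p, p + disp)`` is counted when both voxels lie inside the
    volume and both in-plane positions lie inside ``mask``. The mask is 2-D
    and applies identically at every band.
    """
    levels = q.levels
    nb, h, w = levels.shape
    m = np.asarray(mask).astype(bool)
    if m.shape != (h, w):
        raise ParameterError(f"mask: shape {m.shape} does not match bands ({h}, {w})")
    dx, dy, dz = disp.dx, disp.dy, disp.dz
    if abs(dx) >= w or abs(dy) >= h or abs(dz) >= nb:
        raise ParameterError(
            f"displacement ({dx},{dy},{dz}) exceeds volume extent ({w},{h},{nb})"
        )

    z0, z1 = max(0, -dz), nb - max(0, dz)
    y0, y1 = max(0, -dy), h - max(0, dy)
    x0, x1 = max(0, -dx), w - max(0, dx)
    src = levels[z0:z1, y0:y1, x0:x1]
    dst = levels[z0 + dz : z1 + dz, y0 + dy : y1 + dy, x0 + dx : x1 + dx]
    pair_ok = m[y0:y1, x0:x1] & m[y0 + dy : y1 + dy, x0 + dx : x1 + dx]

    ng = q.n_levels
    i = src[:, pair_ok].ravel().astype(np.int64)
    j = dst[:, pair_ok].ravel().astype(np.int64)
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
    return GLCM(counts, disp, ng)


def glcm_count(n_slices: int, n_offsets: int, mode: str) -> int:
    """Number of co-occurrence matrices a configuration produces.

    In 2-D, each slice contributes 4 directions per offset; in 3-D the whole
    volume contributes 13 directions per offset, independent of slice count.
    """
    if n_slices < 1 or n_offsets < 1:
        raise ParameterError("n_slices and n_offsets must be >= 1")
    key = mode.lower()
    if key == "2d":
        return n_slices * 4 * n_offsets
    if key == "3d":
        return 13 * n_offsets
    raise ParameterError(f"mode: expected '2d' or '3d', got {mode!r}")
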