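"""Texture statistics of a co-occurrence matrix and grouped feature vectors.

Twelve scalar functions summarize one normalized GLCM ``p(i, j)`` (gray
levels indexed 1..Ng, with marginals ``px``, ``py`` and their means/SDs
``μx, μy, σx, σy``):

==== ========================= =========================================
f1   energy                    ``Σ p(i,j)²``
f2   entropy                   ``-Σ p log p`` (0·log 0 := 0, natural log)
f3   correlation               ``(Σ i·j·p - μxμy) / (σxσy)``
f4   contrast                  ``Σ_n n² Σ_{|i-j|=n} p``
f5   homogeneity               ``Σ p / (1 + (i-j)²)``
f6   variance                  ``Σ (i-μx)² p + (j-μy)² p``
f7   sum-mean                  ``Σ_n n Σ_{i+j=n} p``
f8   inertia                   ``Σ (i-j)² p``
f9   cluster shade             ``Σ (i+j-μx-μy)³ p``
f10  cluster tendency          ``Σ (i+j-μx-μy)² p``
f11  maximum probability       ``max p``
f12  inverse difference moment ``Σ p / (1 + (i-j)²)``
==== ========================= =========================================

Contrast and inertia (f4, f8) are the same quantity written two ways, as are
homogeneity and the inverse difference moment (f5, f12); both aliases are
kept so grouped feature vectors have the full 12-function layout.

Feature vectors are grouped by offset: G1–G4 use a single offset (1, 2, 4, 8
pixels respectively) over the 13 volumetric directions, giving
12 x 13 = 156 features each; G5 concatenates all four offsets (624 features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyGLCMError, ParameterError
from .glcm import GLCM, compute_glcm, directions_3d
from .imgio import CellMask
from .preprocess import QuantizedVolume

__all__ = [
    "HaralickVector",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "GROUP_OFFSETS",
    "features_from_glcm",
    "assemble_group",
    "mean_feature_table",
]

FEATURE_NAMES = (
    "energy",
    "entropy",
    "correlation",
    "contrast",
    "homogeneity",
    "variance",
    "sum_mean",
    "inertia",
    "cluster_shade",
    "cluster_tendency",
    "max_probability",
    "inverse_difference_moment",
)

#: Offset sets defining the feature groups (13 directions each).
GROUP_OFFSETS: dict[str, tuple[int, ...]] = {
    "G1": (1,),
    "G2": (2,),
    "G3": (4,),
    "G4": (8,),
    "G5": (1, 2, 4, 8),
}

_NORMALIZATION_TOL = 1e-9


@dataclass(frozen=True)
class HaralickVector:
    """The 12 texture function values for one (direction, offset) GLCM."""

    values: np.ndarray  # length 12, ordered as FEATURE_NAMES
    degenerate_correlation: bool = False  # σx or σy was 0; f3 reported as 0

    def __getattr__(self, name: str):
        if name in FEATURE_NAMES:
            return float(self.values[FEATURE_NAMES.index(name)])
        if name.startswith("f") and name[1:].isdigit() and 1 <= int(name[1:]) <= 12:
            return float(self.values[int(name[1:]) - 1])
        raise AttributeError(name)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, map(float, self.values)))


def features_from_glcm(glcm: GLCM, log_base: float | None = None) -> HaralickVector:
    """Evaluate the 12 texture functions on a GLCM's probability form.

    ``log_base`` sets the entropy logarithm (default: natural log). Gray
    levels are indexed 1..Ng in every moment formula. When a marginal is
    degenerate (σx or σy = 0) the correlation is reported as 0 and flagged.
    """
    if glcm.is_empty:
        raise EmptyGLCMError(f"GLCM {glcm.displacement.name} is empty; features undefined")
    p = glcm.probabilities
    s = p.sum()
    if not np.isfinite(s) or abs(s - 1.0) > _NORMALIZATION_TOL or (p < 0).any():
        raise ContractError("GLCM probabilities must be non-negative and sum to 1")

    ng = glcm.n_levels
    idx = np.arange(1, ng + 1, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ py))

    diff2 = (i - j) ** 2
    dev = i + j - mu_x - mu_y

    f1 = float((p**2).sum())
    nz = p[p > 0]
    f2 = float(-(nz * np.log(nz)).sum())
    if log_base is not None:
        f2 /= np.log(log_base)
    degenerate = sigma_x == 0.0 or sigma_y == 0.0
    if degenerate:
        f3 = 0.0
    else:
        f3 = float(((i * j * p).sum() - mu_x * mu_y) / (sigma_x * sigma_y))
    f4 = float((diff2 * p).sum())
    f5 = float((p / (1.0 + diff2)).sum())
    f6 = float((((i - mu_x) ** 2) * p + ((j - mu_y) ** 2) * p).sum())
    f7 = float(((i + j) * p).sum())
    f8 = f4
    f9 = float((dev**3 * p).sum())
    f10 = float((dev**2 * p).sum())
    f11 = float(p.max())
    f12 = f5
    vals = np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12])
    return HaralickVector(vals, degenerate_correlation=degenerate)


@dataclass
class FeatureMatrix:
    """Samples x named texture features, with optional class labels.

    Column names encode (offset, direction, function) as
    ``d{offset}_dir{NN}_f{K}_{name}`` and follow a fixed, versioned order:
    offset-major, then direction id, then f1..f12.
    """

    data: pd.DataFrame
    labels: np.ndarray | None = None
    group: str | None = None
    schema_version: str = field(default="1", repr=False)

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.data):
                raise ContractError(
                    f"labels: {len(self.labels)} entries for {len(self.data)} rows"
                )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def group_columns(group: str) -> list[str]:
    """The versioned column layout for a feature group."""
    if group not in GROUP_OFFSETS:
        raise ParameterError(f"group: expected one of {sorted(GROUP_OFFSETS)}, got {group!r}")
    cols = []
    for offset in GROUP_OFFSETS[group]:
        for did in range(13):
            for k, name in enumerate(FEATURE_NAMES, start=1):
                cols.append(f"d{offset}_dir{did:02d}_f{k}_{name}")
    return cols


def sample_feature_row(q: QuantizedVolume, mask: CellMask, group: str) -> np.ndarray:
    """All (offset, direction, function) features of one quantized cell."""
    row = []
    for offset in GROUP_OFFSETS[group]:
        for disp in directions_3d(offset):
            g = compute_glcm(q, mask, disp)
            if g.is_empty:
                raise EmptyGLCMError(
                    f"zero valid pairs for direction {disp.direction_id} offset {offset}"
                )
            row.append(features_from_glcm(g).values)
    return np.concatenate(row)


def assemble_group(
    samples: list[tuple[QuantizedVolume, CellMask]],
    group: str = "G5",
    labels=None,
    sample_ids=None,
) -> FeatureMatrix:
    """Build the grouped feature matrix for a list of quantized cells.

    Raises a per-sample error identifying (sample, direction, offset) if any
    displacement yields an empty GLCM.
    """
    cols = group_columns(group)
    ids = list(sample_ids) if sample_ids is not None else list(range(len(samples)))
    rows = []
    for sid, (q, mask) in zip(ids, samples):
        try:
            rows.append(sample_feature_row(q, mask, group))
        except EmptyGLCMError as exc:
            raise EmptyGLCMError(f"sample {sid}: {exc}") from exc
    data = pd.DataFrame(np.asarray(rows).reshape(len(rows), len(cols)), columns=cols, index=ids)
    return FeatureMatrix(data, labels=None if labels is None else np.asarray(labels), group=group)


def mean_feature_table(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-class mean ± SD of each texture function, averaged over all
    directions and offsets in the matrix.

    Returns a 12-row table indexed by function name with ``(class, mean)``
    and ``(class, sd)`` columns (population SD, so a one-sample class has
    SD 0).
    """
    if matrix.labels is None:
        raise ContractError("mean_feature_table requires a labeled FeatureMatrix")
    per_sample = pd.DataFrame(index=matrix.data.index)
    for k, name in enumerate(FEATURE_NAMES, start=1):
        cols = [c for c in matrix.data.columns if c.split("_", 3)[2] == f"f{k}"]
        per_sample[name] = matrix.data[cols].mean(axis=1)
    per_sample["label"] = matrix.labels
    grouped = per_sample.groupby("label", sort=False)
    out = {}
    for cls, block in grouped:
        out[(cls, "mean")] = block[list(FEATURE_NAMES)].mean()
        out[(cls, "sd")] = block[list(FEATURE_NAMES)].std(ddof=0)
    return pd.DataFrame(out)
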