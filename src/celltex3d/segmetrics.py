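"""Overlap metrics between a ground-truth mask A and a segmented mask B.

With ``A`` the truth region and ``B`` the prediction, all four metrics are
normalized so that the identity ``JSC = 1 - FPR - FNR`` holds exactly:

* ``jsc = |A ∩ B| / |A ∪ B|`` (Jaccard similarity coefficient)
* ``dsc = 2|A ∩ B| / (|A| + |B|)`` (Dice similarity coefficient)
* ``fpr = |B \\ A| / |A ∪ B|`` (over-segmentation fraction)
* ``fnr = |A \\ B| / |A ∪ B|`` (under-segmentation fraction)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedMetricError

__all__ = ["SegScore", "score_masks"]


@dataclass(frozen=True)
class SegScore:
    """The four overlap fractions for one (truth, prediction) mask pair."""

    jsc: float
    dsc: float
    fpr: float
    fnr: float

    def as_dict(self) -> dict[str, float]:
        return {"jsc": self.jsc, "dsc": self.dsc, "fpr": self.fpr, "fnr": self.fnr}


def score_masks(truth: np.ndarray, pred: np.ndarray) -> SegScore:
    """Score a predicted mask against ground truth.

    Raises
    ------
    ParameterError
        If the masks have different shapes.
    UndefinedMetricError
        If both masks are empty (the union is empty).
    """
    a = np.asarray(truth).astype(bool)
    b = np.asarray(pred).astype(bool)
    if a.shape != b.shape:
        raise ParameterError(f"mask shapes differ: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise UndefinedMetricError("both masks are empty: overlap metrics undefined")
    n_a = int(np.count_nonzero(a))
    n_b = int(np.count_nonzero(b))
    return SegScore(
        jsc=inter / union,
        dsc=2.0 * inter / (n_a + n_b),
        fpr=(n_b - inter) / union,
        fnr=(n_a - inter) / union,
    )
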