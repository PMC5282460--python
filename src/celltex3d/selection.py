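"""Feature standardization, ANOVA significance filtering, and PCA reduction.

The selection chain mirrors the narrative order of the analysis: every
feature column is z-scored (sample SD, ``ddof=1``), a one-way fixed-effects
ANOVA F-test across the three cell classes keeps features with ``p < alpha``
(default 0.01, no multiple-testing correction by default), and PCA on the
significant set retains the smallest number of components whose cumulative
explained variance reaches the target (default 97%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ContractError, ParameterError
from .haralick import FeatureMatrix

__all__ = [
    "ZScoreParams",
    "SelectionResult",
    "zscore",
    "anova_select",
    "pca_reduce",
    "select_features",
    "feature_correlation",
]


@dataclass
class ZScoreParams:
    """Per-feature standardization parameters (fit on training data)."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray  # sample SD, ddof=1

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[self.feature_names].to_numpy(dtype=float)
        return pd.DataFrame(
            (x - self.mean) / self.sd, columns=self.feature_names, index=df.index
        )


@dataclass
class SelectionResult:
    """Everything the selection chain fits, reusable on held-out samples."""

    zscore_params: ZScoreParams
    p_values: pd.Series  # per z-scored feature
    selected_features: list[str]
    alpha: float
    pca: PCA | None = None
    loading_signs: np.ndarray | None = None
    scores: pd.DataFrame | None = None  # PC scores of the training samples
    explained_variance_ratio: np.ndarray | None = None
    n_components: int = 0
    fallback_used: bool = field(default=False)

    @property
    def cumulative_variance(self) -> np.ndarray:
        if self.explained_variance_ratio is None:
            raise ContractError("PCA has not been fit")
        return np.cumsum(self.explained_variance_ratio)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        """Project new samples onto the retained components."""
        if self.pca is None:
            raise ContractError("PCA has not been fit")
        z = self.zscore_params.transform(df)[self.selected_features].to_numpy()
        return self.pca.transform(z)[:, : self.n_components] * self.loading_signs


def zscore(matrix: FeatureMatrix) -> tuple[FeatureMatrix, ZScoreParams]:
    """Standardize every feature column to zero mean and unit sample SD.

    Zero-variance columns carry no class information and would divide by
    zero; they are dropped with a warning before scaling.
    """
    if matrix.n_samples < 2:
        raise ContractError(f"zscore needs >= 2 samples, got {matrix.n_samples}")
    x = matrix.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k in zip(matrix.feature_names, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}...",
            stacklevel=2,
        )
    names = [n for n, k in zip(matrix.feature_names, keep) if k]
    params = ZScoreParams(names, mean[keep], sd[keep])
    z = pd.DataFrame(
        (x[:, keep] - mean[keep]) / sd[keep], columns=names, index=matrix.data.index
    )
    return FeatureMatrix(z, labels=matrix.labels, group=matrix.group), params


def anova_pvalues(df: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """One-way fixed-effects ANOVA F-test p-value per feature column."""
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ContractError("ANOVA needs >= 2 classes")
    groups = []
    for c in classes:
        block = df.to_numpy(dtype=float)[labels == c]
        if block.shape[0] < 2:
            raise ContractError(f"class {c!r} has < 2 samples")
        groups.append(block)
    with warnings.catch_warnings():
        # constant-in-all-groups features produce a harmless 0/0 warning
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups, axis=0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return pd.Series(p, index=df.columns, name="p_value")


def anova_select(
    matrix: FeatureMatrix, labels=None, alpha: float = 0.01
) -> SelectionResult:
    """z-score the features and keep those with ANOVA ``p < alpha`` (strict).

    If no feature clears the threshold the single smallest-p feature is kept
    (flagged via ``fallback_used``) so downstream stages stay total.
    """
    labels = matrix.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ContractError("anova_select requires labels")
    zmat, params = zscore(matrix)
    p = anova_pvalues(zmat.data, labels)
    selected = list(p.index[p < alpha])
    fallback = False
    if not selected:
        selected = [p.idxmin()]
        fallback = True
    return SelectionResult(
        zscore_params=params,
        p_values=p,
        selected_features=selected,
        alpha=alpha,
        fallback_used=fallback,
    )


def pca_reduce(
    selection: SelectionResult,
    zmatrix: FeatureMatrix,
    variance_target: float = 0.97,
    max_components: int | None = None,
) -> SelectionResult:
    """Fit PCA on the selected z-scored features; retain the smallest number
    of components whose cumulative explained variance reaches the target.

    Component signs follow a fixed convention (the largest-magnitude loading
    of each component is positive) so scores are reproducible.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ParameterError(f"variance_target: must be in (0, 1], got {variance_target}")
    z = zmatrix.data[selection.selected_features].to_numpy(dtype=float)
    pca = PCA(svd_solver="full")
    raw_scores = pca.fit_transform(z)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cumvar, variance_target - 1e-12) + 1)
    k = min(k, len(cumvar))
    if max_components is not None:
        k = min(k, max_components)
    # sign convention: largest-|loading| entry of each component is positive
    comp = pca.components_[:k]
    signs = np.sign(comp[np.arange(k), np.abs(comp).argmax(axis=1)])
    signs[signs == 0] = 1.0
    selection.pca = pca
    selection.loading_signs = signs
    selection.n_components = k
    selection.explained_variance_ratio = pca.explained_variance_ratio_
    selection.scores = pd.DataFrame(
        raw_scores[:, :k] * signs,
        columns=[f"PC{i + 1}" for i in range(k)],
        index=zmatrix.data.index,
    )
    return selection


def select_features(
    matrix: FeatureMatrix,
    labels=None,
    alpha: float = 0.01,
    variance_target: float = 0.97,
    max_components: int | None = None,
) -> SelectionResult:
    """Full selection chain: z-score → ANOVA filter → PCA reduction."""
    labels = matrix.labels if labels is None else np.asarray(labels)
    zmat, _ = zscore(matrix)
    sel = anova_select(matrix, labels, alpha=alpha)
    return pca_reduce(sel, zmat, variance_target=variance_target, max_components=max_components)


def feature_correlation(matrix: FeatureMatrix, labels=None) -> pd.DataFrame:
    """Pearson correlations between per-class feature blocks.

    Samples of each class form one block (classes must be balanced so blocks
    align); columns are labelled ``(class, feature)`` and the result is the
    correlation matrix between all such columns — the basis of a class-
    blocked correlation heat map. Entries involving a constant column are
    NaN (flagged undefined).
    """
    labels = matrix.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ContractError("feature_correlation requires labels")
    if matrix.n_samples < 3:
        raise ContractError("feature_correlation needs >= 3 samples")
    classes = pd.unique(labels)
    sizes = {c: int((labels == c).sum()) for c in classes}
    if len(set(sizes.values())) != 1:
        raise ContractError(f"classes must be balanced, got sizes {sizes}")
    blocks = {}
    for c in classes:
        block = matrix.data.loc[labels == c].reset_index(drop=True)
        for col in block.columns:
            blocks[(c, col)] = block[col].to_numpy(dtype=float)
    wide = pd.DataFrame(blocks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns -> NaN correlation
        return wide.corr()
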