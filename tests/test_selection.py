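import numpy as np
import pandas as pd
import pytest
from oracles import anova_f_pvalue

from celltex3d.errors import ContractError, ParameterError
from celltex3d.haralick import FeatureMatrix
from celltex3d.selection import (
    anova_pvalues,
    anova_select,
    feature_correlation,
    pca_reduce,
    select_features,
    zscore,
)


def fm(array, labels=None, columns=None):
    arr = np.asarray(array, dtype=float)
    cols = columns or [f"x{i}" for i in range(arr.shape[1])]
    return FeatureMatrix(pd.DataFrame(arr, columns=cols), labels=labels)


class TestZscore:
    def test_hand_example_sample_sd(self):
        z, params = zscore(fm([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.values.ravel(), [-1.0, 0.0, 1.0])
        assert params.sd[0] == pytest.approx(1.0)  # ddof=1 convention

    def test_columns_standardized(self, rng):
        z, _ = zscore(fm(rng.normal(5, 3, (20, 6))))
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_idempotent(self, rng):
        z1, _ = zscore(fm(rng.normal(size=(15, 4))))
        z2, _ = zscore(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        x = rng.normal(size=(10, 3))
        x[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            z, params = zscore(fm(x))
        assert z.feature_names == ["x0", "x2"]
        assert np.isfinite(z.values).all()

    def test_too_few_samples(self):
        with pytest.raises(ContractError):
            zscore(fm([[1.0, 2.0]]))


class TestAnova:
    def test_pvalues_match_first_principles_oracle(self, rng):
        labels = np.repeat(["a", "b", "c"], 9)
        x = rng.normal(size=(27, 8))
        x[labels == "b", :2] += 1.5
        p = anova_pvalues(pd.DataFrame(x, columns=[f"x{i}" for i in range(8)]), labels)
        for col in range(8):
            groups = [x[labels == c, col] for c in ("a", "b", "c")]
            _, expected = anova_f_pvalue(groups)
            assert p.iloc[col] == pytest.approx(expected, abs=1e-10)

    def test_no_between_class_signal_not_selected(self, rng):
        base = rng.normal(size=27)
        x = np.column_stack([base + rng.normal(0, 1e-6, 27)])
        labels = np.repeat(["BH", "IN", "Ca"], 9)
        rng.shuffle(labels)
        sel = anova_select(fm(x, labels=labels), alpha=0.01)
        assert sel.fallback_used  # nothing genuinely significant

    def test_planted_effect_selected(self, rng):
        labels = np.repeat(["BH", "IN", "Ca"], 9)
        x = rng.normal(size=(27, 5))
        shift = {"BH": 0.0, "IN": 3.0, "Ca": 6.0}
        x[:, 0] += [shift[c] for c in labels]
        sel = anova_select(fm(x, labels=labels), alpha=0.01)
        assert "x0" in sel.selected_features
        assert (sel.p_values < 0.01).sum() <= 2  # noise columns mostly excluded

    def test_small_class_rejected(self, rng):
        labels = np.array(["a"] * 5 + ["b"])
        with pytest.raises(ContractError, match="class"):
            anova_select(fm(rng.normal(size=(6, 3)), labels=labels))


class TestPca:
    def test_rank_two_data_needs_two_components(self, rng):
        basis = rng.normal(size=(2, 10))
        coeff = rng.normal(size=(20, 2))
        x = coeff @ basis + rng.normal(size=(20, 1)) * 0  # exact 2-dim subspace
        labels = np.array(["a", "b"] * 10)
        sel = select_features(fm(x, labels=labels), alpha=1.1, variance_target=1.0)
        assert sel.n_components == 2
        assert sel.cumulative_variance[1] == pytest.approx(1.0)

    def test_retained_count_brackets_the_target(self, rng):
        labels = np.repeat(["a", "b", "c"], 9)
        x = rng.normal(size=(27, 15))
        sel = select_features(fm(x, labels=labels), alpha=1.1, variance_target=0.97)
        k = sel.n_components
        cumvar = sel.cumulative_variance
        assert cumvar[k - 1] >= 0.97
        if k > 1:
            assert cumvar[k - 2] < 0.97

    def test_scores_invariant_to_feature_order(self, rng):
        labels = np.repeat(["a", "b", "c"], 6)
        x = rng.normal(size=(18, 8))
        x[labels == "a"] += 2
        cols = [f"x{i}" for i in range(8)]
        sel1 = select_features(fm(x, labels=labels, columns=cols), alpha=1.1)
        perm = rng.permutation(8)
        sel2 = select_features(
            fm(x[:, perm], labels=labels, columns=[cols[i] for i in perm]), alpha=1.1
        )
        np.testing.assert_allclose(
            sel1.scores.to_numpy(), sel2.scores.to_numpy(), atol=1e-8
        )

    def test_invalid_variance_target(self, rng):
        labels = np.array(["a", "b"] * 5)
        sel = anova_select(fm(rng.normal(size=(10, 3)), labels=labels), alpha=1.1)
        zmat, _ = zscore(fm(rng.normal(size=(10, 3)), labels=labels))
        with pytest.raises(ParameterError, match="variance_target"):
            pca_reduce(sel, zmat, variance_target=1.5)

    def test_transform_reproduces_training_scores(self, rng):
        labels = np.repeat(["a", "b", "c"], 5)
        x = rng.normal(size=(15, 6))
        matrix = fm(x, labels=labels)
        sel = select_features(matrix, alpha=1.1)
        np.testing.assert_allclose(
            sel.transform(matrix.data), sel.scores.to_numpy(), atol=1e-8
        )


class TestFeatureCorrelation:
    def test_blocked_correlation_properties(self, rng):
        x = rng.normal(size=(12, 2))
        x = np.column_stack([x, -x[:, 0]])  # third feature = negated first
        labels = np.repeat(["BH", "IN", "Ca"], 4)
        corr = feature_correlation(fm(x, labels=labels), labels)
        assert corr.shape == (9, 9)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        assert corr.loc[("BH", "x0"), ("BH", "x2")] == pytest.approx(-1.0)

    def test_unbalanced_classes_rejected(self, rng):
        labels = np.array(["a"] * 4 + ["b"] * 5)
        with pytest.raises(ContractError, match="balanced"):
            feature_correlation(fm(rng.normal(size=(9, 2)), labels=labels), labels)


def test_full_chain_on_texture_features(small_features):
    """On the synthetic cohort the chain finds many significant features and
    compresses them into a handful of components."""
    sel = select_features(small_features)
    assert len(sel.selected_features) > 50
    assert 1 <= sel.n_components < len(sel.selected_features)
    assert sel.cumulative_variance[sel.n_components - 1] >= 0.97
    assert (sel.p_values[sel.selected_features] < 0.01).all()
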