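import numpy as np
import pytest
from oracles import literal_haralick

from celltex3d.errors import ContractError, EmptyGLCMError
from celltex3d.glcm import GLCM, Displacement
from celltex3d.haralick import (
    FEATURE_NAMES,
    assemble_group,
    features_from_glcm,
    group_columns,
    mean_feature_table,
)
from celltex3d.preprocess import QuantizedVolume


def glcm_from_counts(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return GLCM(counts, Displacement(1, 0, 0), counts.shape[0])


class TestFeatureValues:
    def test_point_mass_closed_forms(self):
        """A delta GLCM (all mass on one diagonal cell) has extreme values."""
        counts = np.zeros((4, 4), dtype=np.int64)
        counts[2, 2] = 10
        f = features_from_glcm(glcm_from_counts(counts))
        assert f.energy == 1.0
        assert f.entropy == 0.0
        assert f.contrast == 0.0 and f.inertia == 0.0
        assert f.homogeneity == 1.0 and f.inverse_difference_moment == 1.0
        assert f.max_probability == 1.0

    def test_diagonal_half_half(self):
        f = features_from_glcm(glcm_from_counts([[1, 0], [0, 1]]))
        assert f.energy == pytest.approx(0.5)
        assert f.entropy == pytest.approx(np.log(2))
        assert f.contrast == 0.0
        assert f.max_probability == pytest.approx(0.5)
        # sum-mean: i+j is 2 or 4, each with probability 0.5
        assert f.sum_mean == pytest.approx(3.0)

    def test_antidiagonal_half_half(self):
        f = features_from_glcm(glcm_from_counts([[0, 1], [1, 0]]))
        assert f.contrast == pytest.approx(1.0)
        assert f.inertia == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.inverse_difference_moment == pytest.approx(0.5)
        assert f.cluster_shade == pytest.approx(0.0)  # symmetric about the mean

    def test_matches_literal_transcription(self, rng):
        """All 12 functions agree with a term-by-term loop transcription."""
        for _ in range(50):
            counts = rng.integers(0, 20, (4, 4))
            if counts.sum() == 0:
                continue
            g = glcm_from_counts(counts)
            ours = features_from_glcm(g).values
            expected = literal_haralick(g.probabilities)
            np.testing.assert_allclose(ours, expected, atol=1e-10, rtol=0)

    def test_formula_identities_hold_on_random_glcms(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, (6, 6))
            if counts.sum() == 0:
                continue
            f = features_from_glcm(glcm_from_counts(counts))
            assert f.contrast == f.inertia
            assert f.homogeneity == f.inverse_difference_moment

    def test_entropy_extremal_at_uniform(self, rng):
        ng = 5
        uniform = features_from_glcm(glcm_from_counts(np.ones((ng, ng), dtype=int)))
        assert uniform.entropy == pytest.approx(np.log(ng * ng))
        for _ in range(10):
            counts = rng.integers(0, 9, (ng, ng))
            if counts.sum() == 0 or len(np.unique(counts)) == 1:
                continue
            other = features_from_glcm(glcm_from_counts(counts))
            assert other.entropy < uniform.entropy
            assert other.energy > uniform.energy

    def test_degenerate_marginal_flags_correlation(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[1] = [2, 3, 4]  # i is constant -> sigma_x = 0
        f = features_from_glcm(glcm_from_counts(counts))
        assert f.correlation == 0.0
        assert f.degenerate_correlation

    def test_entropy_log_base_option(self):
        g = glcm_from_counts([[1, 0], [0, 1]])
        assert features_from_glcm(g, log_base=2).entropy == pytest.approx(1.0)

    def test_empty_glcm_refused(self):
        g = GLCM(np.zeros((3, 3), dtype=np.int64), Displacement(1, 0, 0), 3)
        with pytest.raises(EmptyGLCMError):
            features_from_glcm(g)


def tiny_samples(rng, n=3, nb=16, size=24, ng=8):
    out = []
    mask = np.zeros((size, size), dtype=bool)
    mask[2:-2, 2:-2] = True
    for _ in range(n):
        levels = rng.integers(0, ng, (nb, size, size))
        out.append((QuantizedVolume(levels, ng), mask))
    return out


class TestAssembleGroup:
    @pytest.mark.parametrize("group,expected", [("G1", 156), ("G3", 156), ("G5", 624)])
    def test_feature_vector_lengths(self, rng, group, expected):
        fm = assemble_group(tiny_samples(rng, n=1), group=group)
        assert fm.n_features == expected

    def test_column_layout_is_versioned_and_offset_major(self):
        cols = group_columns("G5")
        assert len(cols) == 624
        assert cols[0] == "d1_dir00_f1_energy"
        assert cols[12] == "d1_dir01_f1_energy"
        assert cols[156] == "d2_dir00_f1_energy"
        assert cols[-1] == "d8_dir12_f12_inverse_difference_moment"

    def test_identical_volumes_give_identical_rows(self, rng):
        q, mask = tiny_samples(rng, n=1)[0]
        q2 = QuantizedVolume(q.levels.copy(), q.n_levels)
        fm = assemble_group([(q, mask), (q2, mask)], group="G1")
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_sample_order_permutes_rows(self, rng):
        samples = tiny_samples(rng, n=3)
        fm = assemble_group(samples, group="G1", sample_ids=["a", "b", "c"])
        fm_rev = assemble_group(samples[::-1], group="G1", sample_ids=["c", "b", "a"])
        assert np.array_equal(fm.values, fm_rev.values[::-1])

    def test_empty_glcm_identifies_sample(self, rng):
        q, _ = tiny_samples(rng, n=1, nb=16)[0]
        lonely = np.zeros(q.band_shape, dtype=bool)
        lonely[5, 5] = True
        with pytest.raises(EmptyGLCMError, match="sample s0.*direction 0 offset 1"):
            assemble_group([(q, lonely)], group="G1", sample_ids=["s0"])


class TestMeanFeatureTable:
    def test_class_statistics(self, rng):
        samples = tiny_samples(rng, n=3)
        # duplicate one sample into a two-member class
        fm = assemble_group(
            [samples[0], samples[0], samples[1]],
            group="G1",
            labels=["BH", "BH", "Ca"],
        )
        table = mean_feature_table(fm)
        assert table.shape == (12, 4)  # 2 classes x (mean, sd)
        # identical samples: mean equals the value, SD = 0
        np.testing.assert_allclose(table[("BH", "sd")], 0.0, atol=1e-12)
        # single-sample class: SD = 0 under the population convention
        np.testing.assert_allclose(table[("Ca", "sd")], 0.0, atol=1e-12)
        assert list(table.index) == list(FEATURE_NAMES)

    def test_requires_labels(self, rng):
        fm = assemble_group(tiny_samples(rng, n=1), group="G1")
        with pytest.raises(ContractError):
            mean_feature_table(fm)

    def test_entropy_ordered_along_continuum(self, small_features):
        """Mean GLCM entropy must rise from benign to malignant classes."""
        table = mean_feature_table(small_features)
        ent = table.loc["entropy"]
        assert ent[("BH", "mean")] < ent[("IN", "mean")] < ent[("Ca", "mean")]
        eng = table.loc["energy"]
        assert eng[("BH", "mean")] > eng[("IN", "mean")] > eng[("Ca", "mean")]
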